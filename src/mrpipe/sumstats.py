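"""GWAS summary statistics: reading, validation, writing, allele harmonisation.

Two-sample Mendelian randomisation consumes per-SNP association summaries
(effect-allele coded betas with standard errors) from two independent GWAS.
Before any causal estimation, the SNP->outcome effects must be expressed on
the same effect allele as the SNP->exposure effects; this module implements
the standard allele-alignment contract (direct match / allele swap / strand
complement / palindromic-frequency rescue) and LD-based proxy lookup for
instrument SNPs absent from the outcome GWAS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order of the tab-delimited dialect
CANONICAL_COLUMNS = ["SNP", "A1", "A2", "EAF", "BETA", "SE", "P", "N"]


class SumstatsError(ValueError):
    """Invalid summary-statistics input."""


class HarmonisationError(SumstatsError):
    """Exposure and outcome share no usable SNPs."""


@dataclass
class SummaryStatSet:
    """One trait's per-SNP association table plus trait metadata.

    ``table`` uses the canonical columns SNP, A1 (effect allele), A2,
    EAF, BETA, SE, P, N.  For binary traits BETA is on the log-odds scale.
    """

    trait_name: str
    trait_type: str  # "binary" | "continuous"
    table: pd.DataFrame
    n_cases: int | None = None
    n_controls: int | None = None
    h2: float | None = None
    h2_z: float | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise SumstatsError(f"trait_type must be binary or continuous, got {self.trait_type!r}")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise SumstatsError(f"summary table missing canonical columns: {missing}")
        if self.table["SNP"].duplicated().any():
            dups = self.table.loc[self.table["SNP"].duplicated(), "SNP"].tolist()
            raise SumstatsError(f"duplicate variant ids: {dups[:5]}")
        if self.trait_type == "binary" and self.n_cases and self.n_controls:
            n_max = self.table["N"].max()
            if np.isfinite(n_max) and self.n_cases + self.n_controls > n_max + 0.5:
                raise SumstatsError("n_cases + n_controls exceeds per-SNP sample size")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> list[str]:
        return self.table["SNP"].tolist()

    def subset(self, variant_ids: Sequence[str]) -> "SummaryStatSet":
        """Restrict to the given variants (order preserved from the request)."""
        idx = self.table.set_index("SNP")
        keep = [v for v in variant_ids if v in idx.index]
        tab = idx.loc[keep].reset_index()
        return SummaryStatSet(
            trait_name=self.trait_name, trait_type=self.trait_type, table=tab,
            n_cases=self.n_cases, n_controls=self.n_controls,
            h2=self.h2, h2_z=self.h2_z,
        )


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows violating the per-record invariants; return (clean, n_dropped)."""
    n0 = len(df)
    a1 = df["A1"].astype(str).str.upper()
    a2 = df["A2"].astype(str).str.upper()
    ok = (
        a1.isin(VALID_ALLELES)
        & a2.isin(VALID_ALLELES)
        & (a1 != a2)
        & (pd.to_numeric(df["SE"], errors="coerce") > 0)
        & (pd.to_numeric(df["P"], errors="coerce") > 0)
        & (pd.to_numeric(df["P"], errors="coerce") <= 1)
        & pd.to_numeric(df["BETA"], errors="coerce").notna()
        & df["SNP"].notna()
    )
    eaf = pd.to_numeric(df["EAF"], errors="coerce")
    ok &= eaf.isna() | ((eaf > 0) & (eaf < 1))
    clean = df.loc[ok].copy()
    clean["A1"] = a1[ok]
    clean["A2"] = a2[ok]
    for col in ("EAF", "BETA", "SE", "P"):
        clean[col] = pd.to_numeric(clean[col], errors="coerce")
    clean["N"] = pd.to_numeric(clean["N"], errors="coerce")
    return clean.reset_index(drop=True), n0 - len(clean)


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str = "trait",
    trait_type: str = "continuous",
    **meta,
) -> SummaryStatSet:
    """Read a tab-delimited summary-statistics file into a validated set.

    Parameters
    ----------
    path
        Tab-delimited file with a header row; gzip is handled transparently.
    column_map
        Maps canonical names (``SNP``, ``A1``, ``A2``, ``EAF``, ``BETA``,
        ``SE``, ``P``, ``N``) to the file's header names.  Omitted when the
        file already uses the canonical dialect.  ``EAF`` and ``N`` are
        optional; the rest are mandatory.
    meta
        Forwarded to :class:`SummaryStatSet` (``n_cases``, ``h2`` ...).

    Rows failing validation (non-ACGT or identical alleles, SE <= 0,
    p outside (0, 1], EAF outside (0, 1)) are dropped and counted in
    ``n_dropped``.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.empty:
        raise SumstatsError(f"empty summary-statistics file: {path}")
    if column_map:
        rename = {src: canon for canon, src in column_map.items() if src in df.columns}
        absent = [src for src in column_map.values() if src not in df.columns]
        if absent:
            raise SumstatsError(f"column_map names absent from {path}: {absent}")
        df = df.rename(columns={v: k for k, v in column_map.items()})
    mandatory = ["SNP", "A1", "A2", "BETA", "SE", "P"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SumstatsError(f"mandatory columns missing from {path}: {missing}")
    for opt in ("EAF", "N"):
        if opt not in df.columns:
            df[opt] = np.nan
    df = df[CANONICAL_COLUMNS]
    clean, n_dropped = _validate_rows(df)
    if n_dropped:
        logger.info("read_sumstats(%s): dropped %d invalid rows", path, n_dropped)
    out = SummaryStatSet(trait_name=trait_name, trait_type=trait_type, table=clean, **meta)
    out.n_dropped = n_dropped
    return out


def write_sumstats(sset: SummaryStatSet, path: str | Path) -> Path:
    """Write the canonical tab-delimited dialect; inverse of :func:`read_sumstats`."""
    if len(sset) == 0:
        raise SumstatsError("refusing to write an empty SummaryStatSet")
    path = Path(path)
    sset.table[CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


@dataclass
class LDReference:
    """Symmetric matrix of squared allele-count correlations between variants."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.variant_ids)
        if self.r2.shape != (n, n):
            raise SumstatsError(f"r2 matrix shape {self.r2.shape} != ({n}, {n})")
        if not np.allclose(self.r2, self.r2.T):
            raise SumstatsError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise SumstatsError("r2 diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise SumstatsError("r2 entries must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def pair_r2(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])


def read_ld_reference(path: str | Path) -> LDReference:
    """Read an LD reference: square matrix with id column/header, or long triples."""
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    if len(df.columns) == 3 and cols[:2] in (["id1", "id2"], ["snp1", "snp2"]):
        ids = sorted(set(df.iloc[:, 0]) | set(df.iloc[:, 1]))
        idx = {v: i for i, v in enumerate(ids)}
        mat = np.eye(len(ids))
        for a, b, r2 in df.itertuples(index=False):
            mat[idx[a], idx[b]] = r2
            mat[idx[b], idx[a]] = r2
        return LDReference(ids, mat)
    ids = df.iloc[:, 0].astype(str).tolist()
    mat = df.iloc[:, 1:].to_numpy(dtype=float)
    return LDReference(ids, mat)


def write_ld_reference(ld: LDReference, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(ld.r2, columns=ld.variant_ids)
    df.insert(0, "variant_id", ld.variant_ids)
    df.to_csv(path, sep="\t", index=False)
    return path


@dataclass
class HarmonisedData:
    """Per-SNP exposure and outcome effects aligned to a shared effect allele.

    gamma/se_gamma are the SNP->exposure effects, alpha/se_alpha the
    SNP->outcome effects expressed on the exposure's effect allele.
    ``flags`` records every transformation (direct, sign_flipped,
    strand_flipped, proxy:<id>) applied per SNP.
    """

    snp: list[str]
    gamma: np.ndarray
    se_gamma: np.ndarray
    alpha: np.ndarray
    se_alpha: np.ndarray
    eaf: np.ndarray | None = None
    n_exp: np.ndarray | None = None
    n_out: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.se_gamma = np.asarray(self.se_gamma, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.se_alpha = np.asarray(self.se_alpha, dtype=float)
        j = len(self.snp)
        for name in ("gamma", "se_gamma", "alpha", "se_alpha"):
            if getattr(self, name).shape != (j,):
                raise SumstatsError(f"{name} length != number of SNPs")
        if np.any(self.se_gamma <= 0) or np.any(self.se_alpha <= 0):
            raise SumstatsError("standard errors must be positive")
        if len(set(self.snp)) != j:
            raise SumstatsError("duplicate SNPs in harmonised data")
        if not self.flags:
            self.flags = ["direct"] * j

    def __len__(self) -> int:
        return len(self.snp)

    def subset(self, mask: np.ndarray) -> "HarmonisedData":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return HarmonisedData(
            snp=[self.snp[i] for i in idx],
            gamma=self.gamma[idx], se_gamma=self.se_gamma[idx],
            alpha=self.alpha[idx], se_alpha=self.se_alpha[idx],
            eaf=self.eaf[idx] if self.eaf is not None else None,
            n_exp=self.n_exp[idx] if self.n_exp is not None else None,
            n_out=self.n_out[idx] if self.n_out is not None else None,
            flags=[self.flags[i] for i in idx],
            exposure_name=self.exposure_name, outcome_name=self.outcome_name,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "SNP": self.snp, "gamma": self.gamma, "se_gamma": self.se_gamma,
            "alpha": self.alpha, "se_alpha": self.se_alpha, "flag": self.flags,
        })
        if self.eaf is not None:
            df["EAF"] = self.eaf
        return df


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT[a1] == a2


def harmonise_pair(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    palindrome_eaf_limit: float = 0.42,
    proxy_map: Mapping[str, str] | None = None,
) -> HarmonisedData:
    """Align outcome effects onto the exposure's effect alleles.

    Rules, per shared SNP (exposure alleles e1/e2, outcome o1/o2):

    * identical pair (o1,o2)==(e1,e2): taken as is (``direct``);
    * swapped pair (o1,o2)==(e2,e1): outcome beta sign-flipped, EAF mirrored
      (``sign_flipped``);
    * strand complement of either: alleles complemented first
      (``strand_flipped``, possibly combined with the sign flip);
    * palindromic SNPs (A/T or C/G) cannot be strand-resolved from alleles:
      kept only when both EAFs are known, lie on the same side of 0.5 and
      outside [limit, 1-limit]; otherwise dropped;
    * anything else is irreconcilable and dropped.

    ``proxy_map`` maps exposure variant ids to outcome variant ids that stand
    in for them (from :func:`find_proxies`); a proxy is used only when its
    allele labels reconcile with the exposure SNP's.
    """
    if not 0 < palindrome_eaf_limit <= 0.5:
        raise SumstatsError("palindrome_eaf_limit must be in (0, 0.5]")
    exp = exposure.table.set_index("SNP")
    out = outcome.table.set_index("SNP")
    proxy_map = dict(proxy_map or {})

    snps, gam, seg, alp, sea, eafs, nexp, nout, flags = [], [], [], [], [], [], [], [], []
    n_dropped = 0
    for snp in exp.index:
        out_id = snp if snp in out.index else proxy_map.get(snp)
        if out_id is None or out_id not in out.index:
            continue
        erow, orow = exp.loc[snp], out.loc[out_id]
        e1, e2 = erow["A1"], erow["A2"]
        o1, o2 = orow["A1"], orow["A2"]
        flag_parts = [] if out_id == snp else [f"proxy:{out_id}"]

        if (o1, o2) == (e1, e2):
            sign, matched = 1.0, True
        elif (o1, o2) == (e2, e1):
            sign, matched = -1.0, True
            flag_parts.append("sign_flipped")
        elif flag_parts:
            # proxies without stored allele phase: exact label match only
            n_dropped += 1
            continue
        elif (COMPLEMENT[o1], COMPLEMENT[o2]) == (e1, e2):
            sign, matched = 1.0, True
            flag_parts.append("strand_flipped")
        elif (COMPLEMENT[o1], COMPLEMENT[o2]) == (e2, e1):
            sign, matched = -1.0, True
            flag_parts.extend(["strand_flipped", "sign_flipped"])
        else:
            matched = False
        if not matched:
            n_dropped += 1
            continue

        e_eaf = erow["EAF"]
        o_eaf = orow["EAF"] if sign > 0 else (1.0 - orow["EAF"])
        if _is_palindromic(e1, e2):
            lim = palindrome_eaf_limit
            if (
                pd.isna(e_eaf) or pd.isna(o_eaf)
                or min(e_eaf, 1 - e_eaf) >= lim
                or min(o_eaf, 1 - o_eaf) >= lim
                or (e_eaf < 0.5) != (o_eaf < 0.5)
            ):
                n_dropped += 1
                continue
            flag_parts.append("palindromic_kept")

        snps.append(snp)
        gam.append(erow["BETA"])
        seg.append(erow["SE"])
        alp.append(sign * orow["BETA"])
        sea.append(orow["SE"])
        eafs.append(e_eaf)
        nexp.append(erow["N"])
        nout.append(orow["N"])
        flags.append("+".join(flag_parts) if flag_parts else "direct")

    if not snps:
        raise HarmonisationError(
            f"no shared usable SNPs between {exposure.trait_name!r} and {outcome.trait_name!r}"
        )
    return HarmonisedData(
        snp=snps, gamma=np.array(gam), se_gamma=np.array(seg),
        alpha=np.array(alp), se_alpha=np.array(sea),
        eaf=np.array(eafs, dtype=float), n_exp=np.array(nexp, dtype=float),
        n_out=np.array(nout, dtype=float), flags=flags,
        exposure_name=exposure.trait_name, outcome_name=outcome.trait_name,
        n_dropped=n_dropped,
    )


def find_proxies(
    missing: Iterable[str],
    ld: LDReference,
    r2_min: float = 0.8,
    available: Iterable[str] | None = None,
) -> dict[str, str]:
    """Map each missing variant to its best available LD proxy.

    A proxy must be in ``available`` (default: every other variant in the
    reference) and correlated at r2 strictly above ``r2_min``.  The proxy with
    maximal r2 wins; exact ties break to the lexicographically smaller id.
    """
    if not 0 < r2_min <= 1:
        raise SumstatsError("r2_min must be in (0, 1]")
    missing = list(missing)
    avail = set(available) if available is not None else set(ld.variant_ids)
    avail -= set(missing)
    candidates = sorted(v for v in avail if v in ld)
    mapping: dict[str, str] = {}
    for snp in missing:
        if snp not in ld:
            logger.warning("find_proxies: %s absent from the LD reference", snp)
            continue
        best, best_r2 = None, r2_min
        for cand in candidates:
            r2 = ld.pair_r2(snp, cand)
            if r2 > best_r2 or (best is not None and r2 == best_r2 and cand < best):
                best, best_r2 = cand, r2
        if best is not None:
            mapping[snp] = best
    return mapping
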