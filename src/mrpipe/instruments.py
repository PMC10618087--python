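"""Genetic-instrument construction: p-value thresholding, LD clumping, strength.

Instruments are built at two significance tiers: G1 (genome-wide,
p < 5e-8) and G2 (relaxed, p < 1e-6).  Candidates are pruned by greedy
p-value-ordered LD clumping at r2 > 0.001 so retained SNPs are approximately
independent, and instrument strength is summarised by per-SNP F statistics
and variance explained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import HarmonisedData, LDReference, SummaryStatSet

logger = logging.getLogger(__name__)

G1_THRESHOLD = 5e-8
G2_THRESHOLD = 1e-6
DEFAULT_CLUMP_R2 = 0.001


@dataclass
class InstrumentSet:
    threshold_label: str  # "G1" | "G2"
    pvalue_threshold: float
    variants: list[str]
    f_stats: dict[str, float] = field(default_factory=dict)
    r2_explained: dict[str, float] = field(default_factory=dict)


def select_candidates(sset: SummaryStatSet, threshold: float) -> list[str]:
    """Variants with p strictly below ``threshold``, ascending p (ties by id)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    tab = sset.table
    hits = tab.loc[tab["P"] < threshold, ["SNP", "P"]]
    hits = hits.sort_values(["P", "SNP"], kind="mergesort")
    return hits["SNP"].tolist()


def ld_clump(
    candidates: list[str],
    pvalues: dict[str, float] | pd.Series,
    ld: LDReference,
    clump_r2: float = DEFAULT_CLUMP_R2,
) -> list[str]:
    """Greedy p-value-ordered clumping.

    Repeatedly keep the remaining candidate with the smallest p-value and
    discard every remaining candidate correlated with it at r2 > ``clump_r2``.
    Candidates absent from the LD reference are treated as independent (with
    a warning).  The result is in selection (ascending-p) order and every
    retained pair satisfies r2 <= clump_r2.
    """
    if not 0 < clump_r2 < 1:
        raise ValueError("clump_r2 must be in (0, 1)")
    pv = pvalues if isinstance(pvalues, dict) else dict(pvalues)
    remaining = sorted(set(candidates), key=lambda v: (pv[v], v))
    for v in remaining:
        if v not in ld:
            logger.warning("ld_clump: %s absent from LD reference; treated as independent", v)
    kept: list[str] = []
    while remaining:
        lead = remaining.pop(0)
        kept.append(lead)
        if lead in ld:
            remaining = [
                v for v in remaining
                if v not in ld or ld.pair_r2(lead, v) <= clump_r2
            ]
    return kept


def instrument_strength(h: HarmonisedData) -> pd.DataFrame:
    """Per-SNP F statistic and variance explained in the exposure.

    F_j = (gamma_j / se_gamma_j)^2; r2_j = F_j / (F_j + n_j - 2) when the
    exposure sample size is known.  The mean F and summed r2 are available as
    ``df["F"].mean()`` and ``df["r2"].sum()`` on the returned frame.
    """
    if len(h) == 0:
        raise ValueError("empty harmonised data")
    f = (h.gamma / h.se_gamma) ** 2
    df = pd.DataFrame({"SNP": h.snp, "F": f})
    if h.n_exp is not None and np.all(np.isfinite(h.n_exp)):
        df["r2"] = f / (f + h.n_exp - 2)
    return df


@dataclass
class EligibilityResult:
    passed: bool
    reasons: list[str]
    warnings: list[str]


def eligibility_screen(
    sset: SummaryStatSet, gw_threshold: float = G1_THRESHOLD
) -> EligibilityResult:
    """GWAS power screen: >=1 genome-wide hit, h2 >= 0.05 and h2 Z >= 4.

    Heritability metadata is user-supplied; when absent the h2 checks are
    waived with a warning rather than failed.
    """
    reasons: list[str] = []
    warnings: list[str] = []
    if not (sset.table["P"] < gw_threshold).any():
        reasons.append(f"no SNP with p < {gw_threshold:g}")
    if sset.h2 is None:
        warnings.append("heritability metadata not supplied; h2 screen waived")
    else:
        if sset.h2 < 0.05:
            reasons.append("heritability below 0.05")
        if sset.h2_z is None:
            warnings.append("h2 Z-value not supplied; Z screen waived")
        elif sset.h2_z < 4:
            reasons.append("heritability Z-value below 4")
    return EligibilityResult(passed=not reasons, reasons=reasons, warnings=warnings)


def build_instruments(
    sset: SummaryStatSet,
    ld: LDReference | None,
    threshold_label: str = "G1",
    threshold: float | None = None,
    clump_r2: float = DEFAULT_CLUMP_R2,
) -> InstrumentSet:
    """Threshold then clump; convenience wrapper used by the study pipeline."""
    if threshold is None:
        threshold = {"G1": G1_THRESHOLD, "G2": G2_THRESHOLD}[threshold_label]
    cands = select_candidates(sset, threshold)
    if ld is not None and cands:
        pv = dict(zip(sset.table["SNP"], sset.table["P"]))
        cands = ld_clump(cands, pv, ld, clump_r2=clump_r2)
    return InstrumentSet(threshold_label=threshold_label, pvalue_threshold=threshold,
                         variants=cands)


def export_instruments(inst: InstrumentSet, sset: SummaryStatSet, path) -> None:
    tab = sset.table.set_index("SNP").loc[inst.variants]
    out = pd.DataFrame({
        "variant_id": inst.variants,
        "pvalue": tab["P"].to_numpy(),
        "F": [inst.f_stats.get(v, np.nan) for v in inst.variants],
        "r2": [inst.r2_explained.get(v, np.nan) for v in inst.variants],
        "threshold_label": inst.threshold_label,
    })
    out.to_csv(path, sep="\t", index=False)
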