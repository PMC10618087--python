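"""Bidirectional, outcome-wide study orchestration.

Runs the full exposure x outcome grid in both causal directions at the G1
and G2 instrument thresholds, dispatches estimators by instrument count
(Wald ratio for 1 SNP, IVW for 2, the sensitivity battery from 3, RAPS only
at the relaxed G2 tier), runs diagnostics where their preconditions hold,
applies Benjamini-Hochberg FDR within each direction, and checks the
negative-control outcomes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import estimators as est
from . import diagnostics as diag
from .instruments import G1_THRESHOLD, G2_THRESHOLD, DEFAULT_CLUMP_R2, build_instruments
from .sumstats import (HarmonisedData, HarmonisationError, LDReference,
                       SummaryStatSet, find_proxies, harmonise_pair)

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "direction", "exposure", "outcome", "threshold", "method", "n_snps",
    "b", "se", "ci_low", "ci_high", "p_raw", "p_fdr", "effect_size",
    "effect_kind", "negative_control", "status",
]


def dispatch_estimators(n_snps: int, threshold_label: str) -> list[str]:
    """Estimator battery by instrument count and threshold tier.

    1 SNP -> Wald ratio; 2 SNPs -> IVW only; >= 3 SNPs -> IVW plus Egger,
    weighted median and weighted mode, with RAPS added only for G2
    instruments (the relaxed tier is more exposed to weak-instrument bias).
    """
    if n_snps < 1:
        raise ValueError("empty instrument")
    if n_snps == 1:
        return ["wald_ratio"]
    if n_snps == 2:
        return ["ivw"]
    methods = ["ivw", "egger", "weighted_median", "weighted_mode"]
    if threshold_label == "G2":
        methods.append("raps")
    return methods


def bh_fdr(pvalues, m: int | None = None) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values.

    ``m`` is the family size (>= len(pvalues)); grid cells skipped for lack
    of instruments still count towards the family when the caller says so.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("family size m must be >= number of p-values")
    order = np.argsort(p, kind="mergesort")
    adj_sorted = p[order] * m / np.arange(1, p.size + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    adj = np.empty_like(p)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def count_tests(n_exposures: int, n_outcomes: int, n_negative_controls: int = 0) -> int:
    """Grid size for one direction: exposures x (outcomes + negative controls)."""
    return n_exposures * (n_outcomes + n_negative_controls)


@dataclass
class StudyConfig:
    """Datasets and parameters for one bidirectional run.

    ``activity`` and ``disorders`` are the two trait families tested against
    each other in both directions; ``negative_controls`` are extra outcomes
    appended only to the activity->disorder direction.
    """

    activity: dict[str, SummaryStatSet]
    disorders: dict[str, SummaryStatSet]
    negative_controls: dict[str, SummaryStatSet] = field(default_factory=dict)
    ld: LDReference | None = None
    g1_threshold: float = G1_THRESHOLD
    g2_threshold: float = G2_THRESHOLD
    thresholds: tuple[str, ...] = ("G1", "G2")
    clump_r2: float = DEFAULT_CLUMP_R2
    proxy_r2: float = 0.8
    fdr_family: str = "per_direction"  # or "overall"
    sd_scales: dict[str, float] = field(default_factory=dict)
    n_boot: int = 200
    seed: int = 0


@dataclass
class StudyReport:
    estimates: pd.DataFrame
    diagnostics: pd.DataFrame
    tests_per_direction: dict[str, int]
    manifest: dict

    def to_files(self, directory) -> None:
        from pathlib import Path
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.estimates.to_csv(directory / "estimates.tsv", sep="\t", index=False,
                              float_format="%.6g")
        self.diagnostics.to_csv(directory / "diagnostics.tsv", sep="\t", index=False,
                                float_format="%.6g")
        (directory / "manifest.json").write_text(json.dumps(self.manifest, indent=1))


def _estimate_rows(h: HarmonisedData, threshold_label: str, outcome_type: str,
                   sd_scale: float | None, n_boot: int, seed: int) -> list[est.MREstimate]:
    out: list[est.MREstimate] = []
    for method in dispatch_estimators(len(h), threshold_label):
        if method == "wald_ratio":
            e = est.wald_ratio(h)
        elif method == "ivw":
            e = est.ivw(h)
        elif method == "egger":
            slope, intercept = est.mr_egger(h)
            out.append(slope.with_effect_size(outcome_type, sd_scale))
            out.append(intercept)
            continue
        elif method == "weighted_median":
            e = est.weighted_median(h, n_boot=n_boot, seed=seed)
        elif method == "weighted_mode":
            e = est.weighted_mode(h, n_boot=n_boot, seed=seed + 1)
        else:
            e = est.mr_raps(h, overdispersion=True)
        out.append(e.with_effect_size(outcome_type, sd_scale))
    return out


def _diagnostics_row(h: HarmonisedData, seed: int) -> diag.DiagnosticsReport:
    rep = diag.DiagnosticsReport()
    if len(h) >= 2:
        rep.cochran = diag.cochran_q(h)
    if len(h) >= 3:
        rep.rucker = diag.rucker_q(h)
        _, intercept = est.mr_egger(h)
        rep.egger_intercept, rep.egger_intercept_se, rep.egger_intercept_p = (
            diag.egger_intercept_test(intercept))
    if len(h) >= 4:
        rep.presso = diag.mr_presso(h, seed=seed)
    try:
        rep.steiger = diag.steiger_test(h)
        _, rep.steiger_removed = diag.steiger_filter(h)
    except est.EstimationError:
        rep.steiger = None
    return rep


def run_one_analysis(
    exposure: SummaryStatSet, outcome: SummaryStatSet, cfg: StudyConfig,
    threshold_label: str, seed: int,
) -> tuple[list[est.MREstimate], diag.DiagnosticsReport | None, HarmonisedData | None, str]:
    """Instrument the exposure, harmonise against the outcome, estimate.

    Returns (estimates, diagnostics, harmonised data, status)."""
    threshold = cfg.g1_threshold if threshold_label == "G1" else cfg.g2_threshold
    inst = build_instruments(exposure, cfg.ld, threshold_label, threshold, cfg.clump_r2)
    if not inst.variants:
        return [], None, None, "skipped:no_instruments"
    exp_sub = exposure.subset(inst.variants)
    proxy_map = {}
    if cfg.ld is not None:
        missing = [v for v in inst.variants if v not in set(outcome.variant_ids)]
        if missing:
            proxy_map = find_proxies(missing, cfg.ld, cfg.proxy_r2,
                                     available=outcome.variant_ids)
    try:
        h = harmonise_pair(exp_sub, outcome, proxy_map=proxy_map)
    except HarmonisationError:
        return [], None, None, "skipped:no_shared_snps"
    sd_scale = cfg.sd_scales.get(outcome.trait_name)
    try:
        rows = _estimate_rows(h, threshold_label, outcome.trait_type, sd_scale,
                              cfg.n_boot, seed)
    except est.EstimationError as exc:
        return [], None, h, f"failed:{exc}"
    return rows, _diagnostics_row(h, seed), h, "estimated"


def _direction_grid(cfg: StudyConfig, direction: str):
    if direction == "activity_to_disorder":
        outcomes = dict(cfg.disorders)
        outcomes.update(cfg.negative_controls)
        return cfg.activity, outcomes
    return cfg.disorders, cfg.activity


def run_bidirectional(cfg: StudyConfig) -> StudyReport:
    """Run the full study grid in both directions; deterministic given cfg.seed."""
    rows: list[dict] = []
    diag_rows: list[dict] = []
    tests_per_direction: dict[str, int] = {}
    nc_names = set(cfg.negative_controls)
    seed_counter = int(cfg.seed)

    for direction in ("activity_to_disorder", "disorder_to_activity"):
        exposures, outcomes = _direction_grid(cfg, direction)
        tests_per_direction[direction] = count_tests(len(exposures), len(outcomes))
        for threshold_label in cfg.thresholds:
            for exp_name, exposure in exposures.items():
                for out_name, outcome in outcomes.items():
                    seed_counter += 1
                    ests, drep, h, status = run_one_analysis(
                        exposure, outcome, cfg, threshold_label, seed_counter)
                    base = dict(direction=direction, exposure=exp_name,
                                outcome=out_name, threshold=threshold_label,
                                negative_control=out_name in nc_names, status=status)
                    if not ests:
                        rows.append({**base, "method": None, "n_snps": 0,
                                     "b": np.nan, "se": np.nan, "ci_low": np.nan,
                                     "ci_high": np.nan, "p_raw": np.nan,
                                     "p_fdr": np.nan, "effect_size": np.nan,
                                     "effect_kind": None})
                        continue
                    for e in ests:
                        rows.append({
                            **base, "method": e.method, "n_snps": e.n_snps,
                            "b": e.b, "se": e.se, "ci_low": e.ci_low,
                            "ci_high": e.ci_high, "p_raw": e.pvalue, "p_fdr": np.nan,
                            "effect_size": e.effect_size.value if e.effect_size else np.nan,
                            "effect_kind": e.effect_size.kind if e.effect_size else None,
                        })
                    if drep is not None:
                        diag_rows.append(_flatten_diag(base, drep))

    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    _apply_fdr(df, cfg, tests_per_direction)
    manifest = {
        "seed": cfg.seed,
        "thresholds": {"G1": cfg.g1_threshold, "G2": cfg.g2_threshold},
        "clump_r2": cfg.clump_r2, "proxy_r2": cfg.proxy_r2,
        "fdr_family": cfg.fdr_family,
        "tests_per_direction": tests_per_direction,
    }
    return StudyReport(estimates=df, diagnostics=pd.DataFrame(diag_rows),
                       tests_per_direction=tests_per_direction, manifest=manifest)


def _apply_fdr(df: pd.DataFrame, cfg: StudyConfig, tests_per_direction: dict) -> None:
    """FDR on the primary (IVW / Wald ratio) p-values; family = full grid."""
    primary = df["method"].isin(["ivw", "wald_ratio"]) & df["p_raw"].notna()
    if cfg.fdr_family == "overall":
        m_total = sum(tests_per_direction.values())
        mask_groups = [(primary & (df["threshold"] == thr), m_total)
                       for thr in cfg.thresholds]
    else:
        mask_groups = [
            (primary & (df["direction"] == d) & (df["threshold"] == thr),
             tests_per_direction[d])
            for d in tests_per_direction for thr in cfg.thresholds
        ]
    for mask, m in mask_groups:
        if mask.any():
            df.loc[mask, "p_fdr"] = bh_fdr(df.loc[mask, "p_raw"].to_numpy(),
                                           m=max(m, int(mask.sum())))


def _flatten_diag(base: dict, d: diag.DiagnosticsReport) -> dict:
    row = {k: base[k] for k in ("direction", "exposure", "outcome", "threshold")}
    row.update(
        egger_intercept=d.egger_intercept, intercept_p=d.egger_intercept_p,
        Q=d.cochran.statistic if d.cochran else np.nan,
        Q_p=d.cochran.pvalue if d.cochran else np.nan,
        Qprime=d.rucker.statistic if d.rucker else np.nan,
        Qprime_p=d.rucker.pvalue if d.rucker else np.nan,
        presso_global_p=d.presso.global_pvalue if d.presso else np.nan,
        n_outliers=int(d.presso.outlier_flags.sum()) if d.presso else 0,
        distortion_p=(d.presso.distortion_pvalue if d.presso and
                      d.presso.distortion_pvalue is not None else np.nan),
        steiger_z=d.steiger.z if d.steiger else np.nan,
        steiger_direction=d.steiger.direction if d.steiger else None,
        n_steiger_removed=len(d.steiger_removed) if d.steiger_removed is not None else 0,
    )
    return row


@dataclass
class NegativeControlResult:
    passed: bool
    failures: list[tuple[str, str, float]]  # (exposure, outcome, p_fdr)


def negative_control_check(report: StudyReport, level: float = 0.05) -> NegativeControlResult:
    """Pass iff no negative-control analysis is FDR-significant at ``level``."""
    df = report.estimates
    nc = df[df["negative_control"] & df["method"].isin(["ivw", "wald_ratio"])]
    if nc.empty:
        raise ValueError("no negative control configured")
    bad = nc[nc["p_fdr"] < level]
    failures = [(r.exposure, r.outcome, r.p_fdr) for r in bad.itertuples()]
    return NegativeControlResult(passed=not failures, failures=failures)
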