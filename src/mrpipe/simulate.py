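"""Synthetic GWAS summary statistics with known causal ground truth.

Two-sample MR consumes only per-SNP summary effects, so the generator works
directly on that scale.  For SNP j with effect-allele frequency f_j:

* true SNP->exposure effect gamma_j = |Normal(0, gamma_sd^2)| (effect
  alleles are coded as the exposure-increasing allele, the standard
  instrument orientation);
* true SNP->outcome effect alpha_j = beta * gamma_j + a_j, where beta is the
  causal effect of interest and a_j is a horizontal-pleiotropy term that is
  nonzero only for "invalid" SNPs (balanced: mean 0; directional: mean mu_a;
  correlated: routed through a shared confounder, so a_j correlates with
  gamma_j and violates the InSIDE assumption);
* observed effects add independent sampling noise with
  sigma_gamma_j = (2 f_j (1-f_j) n_exp)^(-1/2), and analogously for the
  outcome; binary outcomes are on the log-odds scale with an effective
  sample size n_out * phi * (1-phi) for case fraction phi;
* optional outlier SNPs add a fixed spike (in units of sigma_alpha) to the
  observed outcome effect;
* ``reverse=True`` generates data where the trait labelled "outcome" causes
  the trait labelled "exposure", for directionality (Steiger) testing.

Exposure and outcome noise use separate substreams of the seeded generator,
mirroring non-overlapping GWAS samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import LDReference, SummaryStatSet, CANONICAL_COLUMNS


class SimulationError(ValueError):
    """Infeasible simulation configuration."""


@dataclass
class SimConfig:
    n_snps: int = 50
    n_exp: int = 100_000
    n_out: int = 100_000
    eaf_range: tuple[float, float] = (0.1, 0.9)
    gamma_sd: float = 0.04
    gamma_abs_min: float = 0.0  # floor on |gamma|: instrument-grade effects
    true_beta: float = 0.0
    pleiotropy: str = "none"  # none | balanced | directional | correlated
    mu_a: float = 0.0
    sigma_a: float = 0.0
    confounder_loading: float = 0.0  # correlated regime only
    prop_invalid: float = 0.0
    n_outliers: int = 0
    outlier_sigma: float = 10.0
    reverse: bool = False
    outcome_type: str = "continuous"
    case_fraction: float = 0.5
    ld_blocks: list[tuple[int, float]] | None = None  # (block size, within-block r2)
    scenario: str = "custom"
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise SimulationError("n_snps must be >= 1")
        if min(self.n_exp, self.n_out) <= 3:
            raise SimulationError("sample sizes must exceed 3")
        if not 0 <= self.prop_invalid <= 1:
            raise SimulationError("prop_invalid must be in [0, 1]")
        if self.n_outliers > self.n_snps:
            raise SimulationError("n_outliers cannot exceed n_snps")
        if self.pleiotropy not in ("none", "balanced", "directional", "correlated"):
            raise SimulationError(f"unknown pleiotropy regime {self.pleiotropy!r}")
        if self.outcome_type not in ("binary", "continuous"):
            raise SimulationError("outcome_type must be binary or continuous")


@dataclass
class SimTruth:
    true_beta: float
    gamma: np.ndarray
    pleiotropic_a: np.ndarray
    invalid: np.ndarray
    outlier: np.ndarray
    scenario: str
    seed: int | None

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "true_beta": self.true_beta,
            "gamma": self.gamma.tolist(),
            "pleiotropic_a": self.pleiotropic_a.tolist(),
            "invalid": self.invalid.astype(int).tolist(),
            "outlier": self.outlier.astype(int).tolist(),
            "scenario": self.scenario,
            "seed": self.seed,
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


def _sumstat_table(snps, a1, a2, eaf, beta, se, n) -> pd.DataFrame:
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return pd.DataFrame({
        "SNP": snps, "A1": a1, "A2": a2, "EAF": eaf,
        "BETA": beta, "SE": se, "P": p, "N": n,
    })[CANONICAL_COLUMNS]


def simulate_pair(config: SimConfig) -> tuple[SummaryStatSet, SummaryStatSet, SimTruth]:
    """Generate one exposure/outcome summary-statistics pair plus ground truth."""
    c = config
    rng = np.random.default_rng(c.seed)
    # independent substreams: truth, exposure-sample noise, outcome-sample noise
    truth_rng, exp_rng, out_rng = rng.spawn(3)
    j = c.n_snps

    f = truth_rng.uniform(*c.eaf_range, size=j)
    # effect alleles coded as the exposure-increasing allele (the standard
    # instrument orientation), so gamma_j >= 0 and directional pleiotropy
    # keeps a well-defined sign relative to the instruments
    # gamma_abs_min > 0 emulates effects that have already cleared
    # genome-wide selection (no sign-ambiguous instruments)
    gamma = c.gamma_abs_min + np.abs(truth_rng.normal(0.0, c.gamma_sd, size=j))

    invalid = np.zeros(j, dtype=bool)
    a = np.zeros(j)
    n_invalid = int(round(c.prop_invalid * j))
    if c.pleiotropy != "none" and n_invalid > 0:
        invalid[truth_rng.choice(j, size=n_invalid, replace=False)] = True
        if c.pleiotropy == "balanced":
            a[invalid] = truth_rng.normal(0.0, c.sigma_a, size=n_invalid)
        elif c.pleiotropy == "directional":
            a[invalid] = truth_rng.normal(c.mu_a, c.sigma_a, size=n_invalid)
        else:  # correlated: confounder path ties a_j to gamma_j (InSIDE violated)
            delta = truth_rng.normal(0.0, c.gamma_sd, size=n_invalid)
            gamma[invalid] = gamma[invalid] + delta
            a[invalid] = c.confounder_loading * delta + truth_rng.normal(0.0, c.sigma_a, size=n_invalid)

    alpha_true = c.true_beta * gamma + a

    se_g = 1.0 / np.sqrt(2 * f * (1 - f) * c.n_exp)
    n_eff_out = c.n_out * (c.case_fraction * (1 - c.case_fraction) / 0.25
                           if c.outcome_type == "binary" else 1.0)
    se_a = 1.0 / np.sqrt(2 * f * (1 - f) * n_eff_out)

    if c.reverse:
        # the "outcome" trait is genetically upstream: SNPs act on it
        # directly and the "exposure" inherits beta-scaled effects
        alpha_obs_true = gamma + a
        gamma_obs_true = c.true_beta * alpha_obs_true
    else:
        gamma_obs_true, alpha_obs_true = gamma, alpha_true

    gamma_obs = gamma_obs_true + exp_rng.normal(0.0, se_g)
    alpha_obs = alpha_obs_true + out_rng.normal(0.0, se_a)

    outlier = np.zeros(j, dtype=bool)
    if c.n_outliers:
        outlier[truth_rng.choice(j, size=c.n_outliers, replace=False)] = True
        alpha_obs[outlier] += c.outlier_sigma * se_a[outlier]

    snps = [f"rs{i + 1:05d}" for i in range(j)]
    pairs = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    alleles = [pairs[i % 4] for i in range(j)]
    a1 = [p[0] for p in alleles]
    a2 = [p[1] for p in alleles]

    exposure = SummaryStatSet(
        trait_name="sim_exposure", trait_type="continuous",
        table=_sumstat_table(snps, a1, a2, f, gamma_obs, se_g, c.n_exp),
    )
    n_cases = int(c.case_fraction * c.n_out) if c.outcome_type == "binary" else None
    outcome = SummaryStatSet(
        trait_name="sim_outcome", trait_type=c.outcome_type,
        table=_sumstat_table(snps, a1, a2, f, alpha_obs, se_a, c.n_out),
        n_cases=n_cases,
        n_controls=(c.n_out - n_cases) if n_cases is not None else None,
    )
    truth = SimTruth(true_beta=c.true_beta, gamma=gamma, pleiotropic_a=a,
                     invalid=invalid, outlier=outlier, scenario=c.scenario, seed=c.seed)
    return exposure, outcome, truth


#: study-condition presets; each covers one estimator's advertised regime
_PRESETS: dict[str, dict] = {
    "null": dict(true_beta=0.0, pleiotropy="none", n_snps=50, gamma_sd=0.04),
    "causal": dict(true_beta=0.1, pleiotropy="none", n_snps=50, gamma_sd=0.04),
    "balanced": dict(true_beta=0.1, pleiotropy="balanced", sigma_a=0.02,
                     prop_invalid=1.0, n_snps=50, gamma_sd=0.04),
    "directional": dict(true_beta=0.1, pleiotropy="directional", mu_a=0.02,
                        sigma_a=0.005, prop_invalid=1.0, n_snps=50, gamma_sd=0.04,
                        gamma_abs_min=0.03),
    "inside_violation": dict(true_beta=0.1, pleiotropy="correlated",
                             confounder_loading=2.0, sigma_a=0.005,
                             prop_invalid=0.5, n_snps=50, gamma_sd=0.04,
                             gamma_abs_min=0.05),
    "forty_pct_invalid": dict(true_beta=0.1, pleiotropy="directional", mu_a=0.05,
                              sigma_a=0.01, prop_invalid=0.4, n_snps=50,
                              gamma_sd=0.04),
    "outlier_spike": dict(true_beta=0.1, pleiotropy="none", n_outliers=1,
                          outlier_sigma=10.0, n_snps=8, gamma_sd=0.01,
                          gamma_abs_min=0.06),
    "weak_instruments": dict(true_beta=0.1, pleiotropy="none", n_snps=200,
                             gamma_sd=0.01),
    "reverse": dict(true_beta=0.3, pleiotropy="none", reverse=True, n_snps=50,
                    gamma_sd=0.04),
}


def scenario_preset(name: str, seed: int | None = 0, **overrides) -> SimConfig:
    """A documented study-condition preset by name (see module docstring)."""
    if name not in _PRESETS:
        raise SimulationError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    params = dict(_PRESETS[name])
    params.update(overrides)
    return SimConfig(scenario=name, seed=seed, **params)


def simulate_ld_reference(
    block_sizes: list[int], within_r2: float | list[float],
    variant_ids: list[str] | None = None,
) -> LDReference:
    """Block-diagonal LD: constant r2 within blocks, 0 across, unit diagonal."""
    if isinstance(within_r2, (int, float)):
        within_r2 = [float(within_r2)] * len(block_sizes)
    if any(not 0 <= r < 1 for r in within_r2):
        raise SimulationError("within-block r2 must be in [0, 1)")
    n = sum(block_sizes)
    mat = np.zeros((n, n))
    start = 0
    for size, r2 in zip(block_sizes, within_r2):
        mat[start:start + size, start:start + size] = r2
        start += size
    np.fill_diagonal(mat, 1.0)
    if variant_ids is None:
        variant_ids = [f"rs{i + 1:05d}" for i in range(n)]
    return LDReference(variant_ids, mat)
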