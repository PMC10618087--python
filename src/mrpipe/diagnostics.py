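"""Heterogeneity, pleiotropy and directionality diagnostics.

Covers Cochran's Q (about the IVW fit) and Rucker's Q' (about the Egger
fit), the Egger intercept test for directional pleiotropy, MR-PRESSO
(global residual test, per-SNP outlier test, distortion test with
outlier-corrected re-estimation), and the Steiger directionality test and
filter comparing instrument variance explained in exposure versus outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import EstimationError, MREstimate, _ivw_core, _egger_core, ivw
from .sumstats import HarmonisedData


@dataclass
class QResult:
    statistic: float
    df: int
    pvalue: float
    flavor: str  # "cochran_ivw" | "rucker_egger"


@dataclass
class PressoResult:
    global_rss: float
    global_pvalue: float
    outlier_flags: np.ndarray          # bool per SNP
    outlier_pvalues: np.ndarray        # per-SNP simulation p
    distortion_pvalue: float | None
    corrected_estimate: MREstimate | None


@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    z: float
    pvalue: float
    direction: str  # "exposure_to_outcome" | "outcome_to_exposure" | "undetermined"


def cochran_q(h: HarmonisedData, b_ivw: float | None = None) -> QResult:
    """Cochran's heterogeneity Q about the IVW estimate.

    Q = sum_j w_j (beta_j - b)^2 with beta_j = alpha_j/gamma_j and
    w_j = gamma_j^2 / sigma_alpha_j^2; chi-square reference with J-1 df.
    """
    j = len(h)
    if j < 2:
        raise EstimationError("cochran_q needs >= 2 SNPs")
    if b_ivw is None:
        b_ivw = _ivw_core(h.gamma, h.alpha, h.se_alpha)[0]
    w = h.gamma**2 / h.se_alpha**2
    ratios = h.alpha / h.gamma
    q = float(np.sum(w * (ratios - b_ivw) ** 2))
    return QResult(q, j - 1, float(stats.chi2.sf(q, j - 1)), "cochran_ivw")


def rucker_q(h: HarmonisedData, slope: float | None = None,
             intercept: float | None = None) -> QResult:
    """Rucker's Q' about the Egger fit: weighted RSS with J-2 df; always <= Q."""
    j = len(h)
    if j < 3:
        raise EstimationError("rucker_q needs >= 3 SNPs")
    if slope is None or intercept is None:
        slope, intercept, *_ = _egger_core(h.gamma, h.alpha, h.se_alpha)
    flip = np.sign(h.gamma)
    flip[flip == 0] = 1.0
    resid = h.alpha * flip - intercept - slope * h.gamma * flip
    q = float(np.sum(resid**2 / h.se_alpha**2))
    return QResult(q, j - 2, float(stats.chi2.sf(q, j - 2)), "rucker_egger")


def egger_intercept_test(intercept_est: MREstimate) -> tuple[float, float, float]:
    """Two-sided normal test of Egger intercept = 0: (estimate, se, p)."""
    p = 1.0 if intercept_est.b == 0 else float(
        2 * stats.norm.sf(abs(intercept_est.b) / intercept_est.se))
    return intercept_est.b, intercept_est.se, p


# ---------------------------------------------------------------------------
# MR-PRESSO

def _loo_expected(gamma: np.ndarray, alpha: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW prediction of each alpha_j, in O(J) via totals."""
    num = np.sum(w * gamma * alpha)
    den = np.sum(w * gamma**2)
    b_loo = (num - w * gamma * alpha) / (den - w * gamma**2)
    return b_loo * gamma


def mr_presso(
    h: HarmonisedData,
    n_sim: int = 1000,
    alpha_outlier: float = 0.05,
    seed: int | None = 0,
    n_distortion: int = 500,
) -> PressoResult:
    """MR-PRESSO: global pleiotropy test, outlier flagging, distortion test.

    Global: the observed weighted residual sum of squares about leave-one-out
    IVW predictions is compared with ``n_sim`` parametric simulations under
    the no-pleiotropy model alpha*_j ~ Normal(expected_j, sigma_alpha_j).
    Outliers: per-SNP simulation p of the residual term, flagged below
    alpha_outlier / J (Bonferroni).  Distortion: the change in the IVW
    estimate after removing flagged SNPs is compared with removals of random
    subsets of the same size.  The corrected estimate is IVW on the retained
    SNPs (present iff any SNP is flagged).
    """
    j = len(h)
    if j < 4:
        raise EstimationError("mr_presso needs >= 4 SNPs")
    if n_sim < 100:
        raise EstimationError("mr_presso needs n_sim >= 100")
    rng = np.random.default_rng(seed)
    w = 1.0 / h.se_alpha**2

    expected = _loo_expected(h.gamma, h.alpha, w)
    obs_terms = w * (h.alpha - expected) ** 2
    rss_obs = float(obs_terms.sum())

    # parametric simulations under the no-pleiotropy null (vectorised n_sim x J)
    alpha_sim = rng.normal(expected, h.se_alpha, size=(n_sim, j))
    num = np.sum(w * h.gamma * alpha_sim, axis=1, keepdims=True)
    den = np.sum(w * h.gamma**2)
    b_loo = (num - w * h.gamma * alpha_sim) / (den - w * h.gamma**2)
    sim_terms = w * (alpha_sim - b_loo * h.gamma) ** 2
    sim_rss = sim_terms.sum(axis=1)

    global_p = float((np.sum(sim_rss >= rss_obs) + 1) / (n_sim + 1))
    outlier_p = (np.sum(sim_terms >= obs_terms, axis=0) + 1) / (n_sim + 1)
    flags = outlier_p < alpha_outlier / j

    distortion_p = None
    corrected = None
    if flags.any() and flags.sum() < j - 1:
        corrected = ivw(h.subset(~flags)) if (~flags).sum() >= 2 else None
        b_all = _ivw_core(h.gamma, h.alpha, h.se_alpha)[0]
        if corrected is not None:
            d_obs = abs(b_all - corrected.b)
            k = int(flags.sum())
            d_null = np.empty(n_distortion)
            for i in range(n_distortion):
                drop = rng.choice(j, size=k, replace=False)
                keep = np.setdiff1d(np.arange(j), drop)
                b_sub = _ivw_core(h.gamma[keep], h.alpha[keep], h.se_alpha[keep])[0]
                d_null[i] = abs(b_all - b_sub)
            distortion_p = float((np.sum(d_null >= d_obs) + 1) / (n_distortion + 1))
    return PressoResult(rss_obs, global_p, flags, outlier_p, distortion_p, corrected)


# ---------------------------------------------------------------------------
# Steiger

def _per_snp_r2(beta: np.ndarray, se: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Variance explained from the t statistic: r2 = t^2 / (t^2 + n - 2)."""
    t2 = (beta / se) ** 2
    return t2 / (t2 + n - 2)


def steiger_test(
    h: HarmonisedData, n_exp: float | None = None, n_out: float | None = None
) -> SteigerResult:
    """Steiger directionality test over the instrument set.

    Sums per-SNP variance explained in exposure and outcome, converts each to
    an absolute correlation, and compares them on Fisher's z scale:
    z = (atanh|r_exp| - atanh|r_out|) / sqrt(1/(n_exp-3) + 1/(n_out-3)).
    z > 0 supports exposure -> outcome causation.
    """
    if len(h) < 1:
        raise EstimationError("steiger_test needs >= 1 SNP")
    if n_exp is None:
        n_exp = float(np.median(h.n_exp)) if h.n_exp is not None else None
    if n_out is None:
        n_out = float(np.median(h.n_out)) if h.n_out is not None else None
    if n_exp is None or n_out is None or n_exp <= 3 or n_out <= 3:
        raise EstimationError("steiger_test needs sample sizes > 3 for both traits")
    r2_exp = float(np.sum(_per_snp_r2(h.gamma, h.se_gamma, np.full(len(h), n_exp))))
    r2_out = float(np.sum(_per_snp_r2(h.alpha, h.se_alpha, np.full(len(h), n_out))))
    r2_exp, r2_out = min(r2_exp, 1 - 1e-12), min(r2_out, 1 - 1e-12)
    z_num = np.arctanh(np.sqrt(r2_exp)) - np.arctanh(np.sqrt(r2_out))
    z = float(z_num / np.sqrt(1 / (n_exp - 3) + 1 / (n_out - 3)))
    p = float(2 * stats.norm.sf(abs(z)))
    if z > 0:
        direction = "exposure_to_outcome"
    elif z < 0:
        direction = "outcome_to_exposure"
    else:
        direction = "undetermined"
    return SteigerResult(r2_exp, r2_out, z, p, direction)


def steiger_filter(
    h: HarmonisedData, n_exp: float | None = None, n_out: float | None = None
) -> tuple[HarmonisedData, list[str]]:
    """Remove SNPs explaining more variance in the outcome than the exposure.

    Returns the filtered data and the removed variant ids.  Idempotent.
    """
    if n_exp is None:
        n_exp = float(np.median(h.n_exp)) if h.n_exp is not None else None
    if n_out is None:
        n_out = float(np.median(h.n_out)) if h.n_out is not None else None
    if n_exp is None or n_out is None or n_exp <= 3 or n_out <= 3:
        raise EstimationError("steiger_filter needs sample sizes > 3 for both traits")
    r2e = _per_snp_r2(h.gamma, h.se_gamma, np.full(len(h), n_exp))
    r2o = _per_snp_r2(h.alpha, h.se_alpha, np.full(len(h), n_out))
    keep = r2e > r2o
    removed = [s for s, k in zip(h.snp, keep) if not k]
    return h.subset(keep), removed


@dataclass
class DiagnosticsReport:
    """All diagnostics for one exposure-outcome analysis (fields None when
    the corresponding test's preconditions are not met)."""

    cochran: QResult | None = None
    rucker: QResult | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    presso: PressoResult | None = None
    steiger: SteigerResult | None = None
    steiger_removed: list[str] | None = None
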