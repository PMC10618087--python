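"""Causal-effect estimators for two-sample Mendelian randomisation.

Given harmonised per-SNP effects (gamma_j on the exposure with SE
sigma_gamma_j, alpha_j on the outcome with SE sigma_alpha_j), the causal
effect beta of exposure on outcome is identified under the instrumental
variable assumptions by beta = alpha_j / gamma_j for every valid instrument.
This module implements the estimators combining those ratios:

* Wald ratio (single SNP), b = alpha/gamma with first-order delta-method SE;
* inverse-variance-weighted (IVW) meta-analysis, the zero-intercept weighted
  regression of alpha on gamma with weights 1/sigma_alpha^2, optionally with
  multiplicative random effects (SE inflated by sqrt(Q/(J-1)), never
  deflated);
* MR-Egger regression (free intercept; the intercept estimates the average
  directional pleiotropic effect);
* weighted median and weighted mode of the per-SNP ratios, with parametric
  bootstrap standard errors;
* MR-RAPS, the robust adjusted profile score for weak instruments, solving
  the profile-score equation sum_j psi(t_j) * (gamma_j/s_j
  + b sigma_gamma_j^2 t_j / s_j^2) = 0 with t_j = (alpha_j - b gamma_j)/s_j,
  s_j^2 = sigma_alpha_j^2 + b^2 sigma_gamma_j^2 + tau^2, and optional
  overdispersion tau^2.

Estimates carry normal-theory confidence intervals and are convertible to
the reported effect-size scale (odds ratio for binary outcomes, SD-scaled
beta for continuous ones).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .sumstats import HarmonisedData


class EstimationError(ValueError):
    """Estimator preconditions not met (e.g. too few instruments)."""


@dataclass
class EffectSize:
    value: float
    ci_low: float
    ci_high: float
    kind: str  # "odds_ratio" | "standardised_beta" | "unstandardised_beta"


@dataclass
class MREstimate:
    """One method's causal estimate on the analysis (log-odds / trait-unit) scale."""

    method: str
    b: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    effect_size: EffectSize | None = None

    def with_effect_size(self, outcome_type: str, sd_scale: float | None = None) -> "MREstimate":
        return replace(self, effect_size=to_effect_size(self, outcome_type, sd_scale))


_Z = {}


def _zq(level: float) -> float:
    if level not in _Z:
        _Z[level] = stats.norm.ppf(0.5 + level / 2)
    return _Z[level]


def ci_bounds(b: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Normal-theory confidence bounds b +/- z * se (z exact, not 1.96)."""
    if se <= 0:
        raise EstimationError("se must be positive")
    if not 0 < level < 1:
        raise EstimationError("level must be in (0, 1)")
    z = _zq(level)
    return b - z * se, b + z * se


def _normal_p(b: float, se: float) -> float:
    return float(2 * stats.norm.sf(abs(b) / se))


def _finish(method: str, b: float, se: float, n_snps: int, level: float = 0.95) -> MREstimate:
    lo, hi = ci_bounds(b, se, level)
    return MREstimate(method=method, b=float(b), se=float(se), ci_low=lo, ci_high=hi,
                      pvalue=_normal_p(b, se), n_snps=n_snps)


def to_effect_size(
    est: MREstimate, outcome_type: str, sd_scale: float | None = None
) -> EffectSize:
    """Convert to the reported scale: OR = exp(b) for binary outcomes,
    SD-rescaled beta for continuous ones (pass-through flagged unstandardised
    when no scale is supplied)."""
    if outcome_type == "binary":
        return EffectSize(math.exp(est.b), math.exp(est.ci_low), math.exp(est.ci_high),
                          "odds_ratio")
    if sd_scale is not None:
        return EffectSize(est.b * sd_scale, est.ci_low * sd_scale, est.ci_high * sd_scale,
                          "standardised_beta")
    return EffectSize(est.b, est.ci_low, est.ci_high, "unstandardised_beta")


# ---------------------------------------------------------------------------
# single SNP

def wald_ratio(h: HarmonisedData) -> MREstimate:
    """Single-SNP causal estimate b = alpha/gamma, SE = sigma_alpha/|gamma|."""
    if len(h) != 1:
        raise EstimationError(f"wald_ratio needs exactly 1 SNP, got {len(h)}")
    g, a, sa = h.gamma[0], h.alpha[0], h.se_alpha[0]
    if g == 0:
        raise EstimationError("wald_ratio undefined for gamma = 0")
    return _finish("wald_ratio", a / g, sa / abs(g), 1)


# ---------------------------------------------------------------------------
# IVW

def _ivw_core(gamma: np.ndarray, alpha: np.ndarray, se_alpha: np.ndarray):
    w = 1.0 / se_alpha**2
    swg2 = np.sum(w * gamma**2)
    b = np.sum(w * gamma * alpha) / swg2
    se_fixed = swg2**-0.5
    q = np.sum(w * (alpha - b * gamma) ** 2)  # == sum w_j gamma_j^2 (ratio_j - b)^2
    return b, se_fixed, q


def ivw(h: HarmonisedData, effects_model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted meta-analysis of Wald ratios.

    Equivalent to zero-intercept WLS of alpha on gamma with weights
    1/sigma_alpha^2.  Under ``multiplicative_random`` (the default, matching
    common two-sample MR practice) the SE is inflated by
    max(1, sqrt(Q/(J-1))) where Q is Cochran's heterogeneity statistic.
    """
    j = len(h)
    if j < 2:
        raise EstimationError("ivw needs >= 2 SNPs; use wald_ratio for a single instrument")
    if effects_model not in ("fixed", "multiplicative_random"):
        raise EstimationError(f"unknown effects model {effects_model!r}")
    b, se, q = _ivw_core(h.gamma, h.alpha, h.se_alpha)
    if effects_model == "multiplicative_random":
        se *= max(1.0, math.sqrt(q / (j - 1)))
    return _finish("ivw", b, se, j)


# ---------------------------------------------------------------------------
# MR-Egger

def _egger_core(gamma: np.ndarray, alpha: np.ndarray, se_alpha: np.ndarray):
    """Weighted regression alpha ~ intercept + slope*gamma, weights 1/se_alpha^2.

    Returns slope, intercept, their SEs (multiplicative random effects:
    residual scale floored at 1), and the weighted RSS.
    """
    flip = np.sign(gamma)
    flip[flip == 0] = 1.0
    x = gamma * flip
    y = alpha * flip
    w = 1.0 / se_alpha**2
    sw, swx, swy = w.sum(), (w * x).sum(), (w * y).sum()
    swxx, swxy = (w * x * x).sum(), (w * x * y).sum()
    det = sw * swxx - swx**2
    if det <= 0:
        raise EstimationError("degenerate design for MR-Egger (no spread in gamma)")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swy - slope * swx) / sw
    resid = y - intercept - slope * x
    rss = float(np.sum(w * resid**2))
    j = len(x)
    phi = max(1.0, rss / (j - 2))  # multiplicative overdispersion, never < 1
    se_slope = math.sqrt(phi * sw / det)
    se_int = math.sqrt(phi * swxx / det)
    return slope, intercept, se_slope, se_int, rss


def mr_egger(h: HarmonisedData) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: (slope, intercept) estimates.

    Instruments are oriented so every gamma_j >= 0 (flipping both gamma and
    alpha signs), making the intercept identifiable as the average
    directional pleiotropic effect.  P-values use the normal reference.
    """
    j = len(h)
    if j < 3:
        raise EstimationError("mr_egger needs >= 3 SNPs")
    slope, intercept, se_s, se_i, _ = _egger_core(h.gamma, h.alpha, h.se_alpha)
    return (_finish("egger_slope", slope, se_s, j),
            _finish("egger_intercept", intercept, se_i, j))


# ---------------------------------------------------------------------------
# weighted median

def _weighted_median_core(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Value at cumulative normalised weight 0.5, interpolating between
    adjacent order statistics (midpoint-of-mass convention)."""
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / weights.sum()
    # cumulative weight at the centre of each observation's mass
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, r))


def _ratio_weights(h: HarmonisedData):
    ratios = h.alpha / h.gamma
    var = h.se_alpha**2 / h.gamma**2 + h.alpha**2 * h.se_gamma**2 / h.gamma**4
    return ratios, 1.0 / var


def _bootstrap_se(h: HarmonisedData, point_fn, n_boot: int, seed) -> float:
    rng = np.random.default_rng(seed)
    j = len(h)
    ests = np.empty(n_boot)
    for i in range(n_boot):
        g = rng.normal(h.gamma, h.se_gamma)
        a = rng.normal(h.alpha, h.se_alpha)
        ests[i] = point_fn(g, a)
    return float(ests.std(ddof=1))


def weighted_median(
    h: HarmonisedData, n_boot: int = 1000, seed: int | None = 0
) -> MREstimate:
    """Weighted median of per-SNP Wald ratios; consistent when valid
    instruments contribute more than half of the weight.  SE by parametric
    bootstrap (seeded)."""
    keep = h.gamma != 0
    if not keep.all():
        h = h.subset(keep)
    j = len(h)
    if j < 3:
        raise EstimationError("weighted_median needs >= 3 SNPs with nonzero gamma")
    ratios, w = _ratio_weights(h)
    b = _weighted_median_core(ratios, w)

    def point(g, a):
        ok = g != 0
        r = a[ok] / g[ok]
        vr = h.se_alpha[ok] ** 2 / g[ok] ** 2 + a[ok] ** 2 * h.se_gamma[ok] ** 2 / g[ok] ** 4
        return _weighted_median_core(r, 1.0 / vr)

    se = _bootstrap_se(h, point, n_boot, seed) if n_boot else float("nan")
    if not np.isfinite(se) or se <= 0:
        se = np.sqrt(1.0 / w.sum())  # degenerate bootstrap fallback
    return _finish("weighted_median", b, se, j)


# ---------------------------------------------------------------------------
# weighted mode

def _weighted_mode_core(ratios: np.ndarray, weights: np.ndarray,
                        bandwidth_factor: float, grid_size: int = 10000) -> float:
    mad = np.median(np.abs(ratios - np.median(ratios)))
    bw = bandwidth_factor * 1.4826 * mad
    if bw == 0:
        return float(ratios[0])
    lo, hi = ratios.min() - 3 * bw, ratios.max() + 3 * bw
    grid = np.linspace(lo, hi, grid_size)
    wn = weights / weights.sum()
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / bw) ** 2) @ wn
    return float(grid[np.argmax(dens)])


def weighted_mode(
    h: HarmonisedData, bandwidth_factor: float = 1.0,
    n_boot: int = 1000, seed: int | None = 0,
) -> MREstimate:
    """Mode of the weighted kernel density over per-SNP ratios.

    Bandwidth = bandwidth_factor * 1.4826 * MAD(ratios); argmax taken on a
    10,000-point grid spanning the ratios +/- 3 bandwidths.  Consistent when
    the largest cluster of similar ratios comes from valid instruments.
    """
    keep = h.gamma != 0
    if not keep.all():
        h = h.subset(keep)
    j = len(h)
    if j < 3:
        raise EstimationError("weighted_mode needs >= 3 SNPs with nonzero gamma")
    ratios, w = _ratio_weights(h)
    b = _weighted_mode_core(ratios, w, bandwidth_factor)

    def point(g, a):
        ok = g != 0
        r = a[ok] / g[ok]
        vr = h.se_alpha[ok] ** 2 / g[ok] ** 2 + a[ok] ** 2 * h.se_gamma[ok] ** 2 / g[ok] ** 4
        return _weighted_mode_core(r, 1.0 / vr, bandwidth_factor, grid_size=2000)

    se = _bootstrap_se(h, point, n_boot, seed) if n_boot else float("nan")
    if not np.isfinite(se) or se <= 0:
        se = np.sqrt(1.0 / w.sum())
    return _finish("weighted_mode", b, se, j)


# ---------------------------------------------------------------------------
# MR-RAPS

_HUBER_K = 1.345


def _huber_psi(t: np.ndarray, k: float = _HUBER_K) -> np.ndarray:
    return np.clip(t, -k, k)


def _psi_t_expectation(loss: str) -> float:
    """E[psi(Z) Z] for standard normal Z: 1 for squared, 2*Phi(k)-1 for Huber."""
    if loss == "squared":
        return 1.0
    return float(2 * stats.norm.cdf(_HUBER_K) - 1)


def _raps_score(b: float, h: HarmonisedData, tau2: float, loss: str) -> float:
    """Profile-score estimating function d/db sum_j rho(t_j(b)).

    dt/db = -(gamma_j/s_j + b sigma_gamma_j^2 t_j / s_j^2); the second term
    is the weak-instrument correction that distinguishes this from the naive
    (IVW-weighted) equation and keeps the root consistent when the
    measurement error in gamma is non-negligible.
    """
    s2 = h.se_alpha**2 + b**2 * h.se_gamma**2 + tau2
    s = np.sqrt(s2)
    t = (h.alpha - b * h.gamma) / s
    psi = t if loss == "squared" else _huber_psi(t)
    u = h.gamma / s + b * h.se_gamma**2 * t / s2
    return float(np.sum(psi * u))


def mr_raps(
    h: HarmonisedData, loss: str = "squared", overdispersion: bool = False,
    max_iter: int = 100, tol: float = 1e-10,
) -> MREstimate:
    """Robust adjusted profile score estimator.

    Solves d/db sum_j rho(t_j) = 0 where t_j = (alpha_j - b gamma_j)/s_j,
    s_j^2 = sigma_alpha_j^2 + b^2 sigma_gamma_j^2 + tau^2 and rho is the
    squared or Huber loss; the score includes the weak-instrument correction
    term b sigma_gamma^2 t_j / s_j^2 (see :func:`_raps_score`).
    ``loss="huber"`` bounds the influence of outlying SNPs.  With
    ``overdispersion`` the systematic-pleiotropy variance tau^2 >= 0 is
    estimated from the moment condition mean(psi(t_j) t_j) = E[psi(Z) Z],
    alternating with b.  Initialised at the IVW estimate;
    the sandwich variance of the estimating equation gives the SE.  As
    sigma_gamma -> 0 with squared loss and tau^2 = 0 this reduces exactly
    to IVW.
    """
    j = len(h)
    if j < 3:
        raise EstimationError("mr_raps needs >= 3 SNPs")
    if loss not in ("squared", "huber"):
        raise EstimationError(f"unknown loss {loss!r}")

    b = _ivw_core(h.gamma, h.alpha, h.se_alpha)[0]
    tau2 = 0.0

    def solve_b(tau2: float, b0: float) -> float:
        f = lambda b_: _raps_score(b_, h, tau2, loss)
        # bracket around the current iterate
        step = max(1.0, abs(b0)) * 0.5
        lo, hi = b0 - step, b0 + step
        flo, fhi = f(lo), f(hi)
        for _ in range(60):
            if flo * fhi <= 0:
                break
            step *= 2.0
            lo, hi = b0 - step, b0 + step
            flo, fhi = f(lo), f(hi)
        else:
            raise EstimationError(f"mr_raps failed to bracket a root near b={b0:.4g}")
        return float(optimize.brentq(f, lo, hi, xtol=1e-12))

    for _ in range(max_iter):
        b_new = solve_b(tau2, b)
        if overdispersion:
            delta = _psi_t_expectation(loss)

            def moment(t2):
                s2 = h.se_alpha**2 + b_new**2 * h.se_gamma**2 + t2
                t = (h.alpha - b_new * h.gamma) / np.sqrt(s2)
                psi = t if loss == "squared" else _huber_psi(t)
                return float(np.mean(psi * t) - delta)
            if moment(0.0) <= 0:
                tau2_new = 0.0
            else:
                hi = 1.0
                while moment(hi) > 0 and hi < 1e6:
                    hi *= 10
                tau2_new = float(optimize.brentq(moment, 0.0, hi, xtol=1e-14))
        else:
            tau2_new = 0.0
        if abs(b_new - b) < tol and abs(tau2_new - tau2) < tol:
            b, tau2 = b_new, tau2_new
            break
        b, tau2 = b_new, tau2_new
    else:
        raise EstimationError(f"mr_raps did not converge in {max_iter} iterations "
                              f"(last iterate b={b:.6g}, tau2={tau2:.3g})")

    # sandwich variance: Var(b) ~ B / A^2 with A = d score/db, B = sum psi_j^2 u_j^2
    s2 = h.se_alpha**2 + b**2 * h.se_gamma**2 + tau2
    s = np.sqrt(s2)
    t = (h.alpha - b * h.gamma) / s
    psi = t if loss == "squared" else _huber_psi(t)
    u = h.gamma / s + b * h.se_gamma**2 * t / s2
    bb = float(np.sum(psi**2 * u**2))
    if bb == 0:  # exact fit: fall back to the model-based score variance
        bb = _psi_t_expectation(loss) * float(np.sum(u**2))
    eps = 1e-6 * max(1.0, abs(b))
    aa = (_raps_score(b + eps, h, tau2, loss) - _raps_score(b - eps, h, tau2, loss)) / (2 * eps)
    if aa == 0:
        raise EstimationError("mr_raps: singular estimating equation")
    se = math.sqrt(bb / aa**2)
    return _finish("raps", b, se, j)
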