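"""Causal-effect estimators for two-sample Mendelian randomization.

Given k harmonized instruments with exposure effects ``beta_exp_i`` (SE
``se_exp_i``) and outcome effects ``beta_out_i`` (SE ``se_out_i``), the
per-variant Wald ratio ``beta_out_i / beta_exp_i`` estimates the causal
effect of the exposure on the outcome under the instrumental-variable
assumptions.  The estimators here combine the ratios with different
robustness trade-offs:

``ivw``
    Inverse-variance-weighted meta-analysis of the ratios, equivalent to the
    no-intercept weighted regression of outcome betas on exposure betas with
    weights ``1/se_out^2``.  Efficient when every instrument is valid.
``mr_egger``
    The same regression with a free intercept.  A non-zero intercept
    indicates directional horizontal pleiotropy; the slope remains a
    consistent causal estimate under the InSIDE assumption (pleiotropic
    effects independent of instrument strength).
``weighted_median``
    Inverse-variance-weighted median of the ratios; consistent when
    instruments carrying at least half the weight are valid.
``weighted_mode``
    Mode of a kernel-smoothed, weighted ratio density; consistent when the
    largest group of instruments sharing a causal estimate is valid.

Binary-trait effects are on the log-odds scale throughout; :func:`to_or`
maps an estimate and SE to an odds ratio with a 95% Wald interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .harmonize import HarmonizedInstrument

__all__ = [
    "MREstimate",
    "PleiotropyResult",
    "RatioSet",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "weighted_mode",
    "to_or",
]

#: Normal quantile used for 95% intervals, by reporting convention.
Z_95 = 1.96


@dataclass(frozen=True)
class MREstimate:
    """One method's causal-effect estimate.

    ``beta``/``se`` are on the log-odds scale; ``or_`` with ``ci_low`` /
    ``ci_high`` is the exponentiated effect with its 95% Wald interval.
    ``extra`` carries method-specific detail (bootstrap settings, Egger
    intercept, ...).
    """

    method: str
    n_snp: int
    beta: float
    se: float
    pval: float
    or_: float
    ci_low: float
    ci_high: float
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ci_low <= self.or_ <= self.ci_high:
            raise ValueError("odds-ratio CI does not bracket the point estimate")
        if not 0 < self.pval <= 1:
            raise ValueError(f"pval {self.pval} outside (0, 1]")
        if self.n_snp < 1:
            raise ValueError("n_snp must be >= 1")


@dataclass(frozen=True)
class PleiotropyResult:
    """Egger-intercept test for directional horizontal pleiotropy."""

    intercept: float
    se: float
    pval: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("intercept se must be positive")


@dataclass(frozen=True)
class RatioSet:
    """Per-instrument Wald ratios with first-order SEs and IVW weights."""

    rsids: tuple[str, ...]
    ratios: np.ndarray
    ses: np.ndarray
    weights: np.ndarray

    @classmethod
    def from_instruments(cls, instruments: Sequence[HarmonizedInstrument]) -> "RatioSet":
        bx = np.array([i.beta_exp for i in instruments], dtype=float)
        by = np.array([i.beta_out for i in instruments], dtype=float)
        sy = np.array([i.se_out for i in instruments], dtype=float)
        if np.any(bx == 0):
            raise ValueError("beta_exp must be non-zero for every instrument")
        ratios = by / bx
        ses = sy / np.abs(bx)
        weights = 1.0 / ses**2
        if not np.all(np.isfinite(weights)) or np.any(weights <= 0):
            raise ValueError("ratio weights must be positive and finite")
        return cls(
            rsids=tuple(i.rsid for i in instruments),
            ratios=ratios,
            ses=ses,
            weights=weights,
        )


def to_or(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds effect into (OR, 95% CI low, 95% CI high)."""
    if se < 0:
        raise ValueError("se must be non-negative")
    return (
        float(np.exp(beta)),
        float(np.exp(beta - Z_95 * se)),
        float(np.exp(beta + Z_95 * se)),
    )


def _normal_estimate(method: str, n_snp: int, beta: float, se: float, extra: dict | None = None) -> MREstimate:
    pval = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else (1.0 if beta == 0 else np.nextafter(0, 1))
    pval = min(max(pval, np.nextafter(0, 1)), 1.0)
    or_, lo, hi = to_or(beta, se)
    return MREstimate(
        method=method, n_snp=n_snp, beta=float(beta), se=float(se), pval=pval,
        or_=or_, ci_low=lo, ci_high=hi, extra=extra or {},
    )


def wald_ratio(inst: HarmonizedInstrument) -> MREstimate:
    """Single-instrument causal estimate ``beta_out / beta_exp``.

    The SE is first order (delta method in the outcome beta only),
    ``se_out / |beta_exp|``; the p-value is two-sided standard normal.
    """
    if inst.beta_exp == 0:
        raise ValueError(f"{inst.rsid}: beta_exp is zero; Wald ratio undefined")
    beta = inst.beta_out / inst.beta_exp
    se = inst.se_out / abs(inst.beta_exp)
    return _normal_estimate("wald_ratio", 1, beta, se)


def _ivw_arrays(instruments: Sequence[HarmonizedInstrument]):
    bx = np.array([i.beta_exp for i in instruments], dtype=float)
    by = np.array([i.beta_out for i in instruments], dtype=float)
    w = np.array([1.0 / i.se_out**2 for i in instruments], dtype=float)
    return bx, by, w


def ivw(
    instruments: Sequence[HarmonizedInstrument],
    model: str = "fixed",
) -> MREstimate:
    """Inverse-variance-weighted estimate across instruments.

    The point estimate is the slope of the no-intercept weighted regression
    of ``beta_out`` on ``beta_exp`` with weights ``1/se_out^2``; equivalently
    the inverse-variance-weighted mean of the Wald ratios.

    ``model="fixed"`` uses ``se = (sum beta_exp_i^2 / se_out_i^2)^(-1/2)``;
    ``model="multiplicative_random"`` additionally scales the SE by
    ``max(1, sqrt(Q / (k - 1)))``, inflating it only under excess
    heterogeneity.  P-values are two-sided standard normal.
    """
    if len(instruments) < 2:
        raise ValueError("ivw requires >= 2 instruments; use wald_ratio for a single one")
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    bx, by, w = _ivw_arrays(instruments)
    if np.any(bx == 0):
        raise ValueError("beta_exp must be non-zero for every instrument")
    denom = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / denom
    se = denom**-0.5
    k = len(instruments)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    if model == "multiplicative_random":
        se *= max(1.0, np.sqrt(q / (k - 1)))
    return _normal_estimate("ivw", k, beta, se, extra={"model": model, "q": q})


def _egger_fit(instruments: Sequence[HarmonizedInstrument]):
    """Weighted least squares of beta_out on beta_exp with intercept.

    Instruments are oriented so beta_exp > 0 before fitting (flipping both
    betas where needed) because the intercept is not invariant to allele
    coding.  Coefficient SEs use residual sigma floored at 1 and t(k-2)
    reference distributions.
    """
    import statsmodels.api as sm

    k = len(instruments)
    if k < 3:
        raise ValueError("mr_egger requires >= 3 instruments")
    bx, by, w = _ivw_arrays(instruments)
    if np.any(bx == 0):
        raise ValueError("beta_exp must be non-zero for every instrument")
    flip = np.sign(bx)
    bx, by = bx * flip, by * flip
    X = sm.add_constant(bx)
    res = sm.WLS(by, X, weights=w).fit()
    sigma = float(np.sqrt(res.scale))  # sqrt(weighted RSS / (k - 2))
    sigma_eff = max(1.0, sigma)
    bse = np.sqrt(np.diag(res.normalized_cov_params)) * sigma_eff
    coef = np.asarray(res.params, dtype=float)
    q_egger = float(res.scale * (k - 2))
    pvals = 2.0 * stats.t.sf(np.abs(coef) / bse, df=k - 2)
    return coef, bse, pvals, q_egger, k


def mr_egger(
    instruments: Sequence[HarmonizedInstrument],
) -> tuple[MREstimate, PleiotropyResult]:
    """Egger regression: returns the slope estimate and the intercept test."""
    coef, bse, pvals, q_egger, k = _egger_fit(instruments)
    slope, slope_se = float(coef[1]), float(bse[1])
    or_, lo, hi = to_or(slope, slope_se)
    slope_p = float(min(max(pvals[1], np.nextafter(0, 1)), 1.0))
    estimate = MREstimate(
        method="egger", n_snp=k, beta=slope, se=slope_se, pval=slope_p,
        or_=or_, ci_low=lo, ci_high=hi,
        extra={"intercept": float(coef[0]), "q_egger": q_egger},
    )
    intercept = PleiotropyResult(
        intercept=float(coef[0]),
        se=float(bse[0]),
        pval=float(min(max(pvals[0], np.nextafter(0, 1)), 1.0)),
    )
    return estimate, intercept


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median.

    Ratios are sorted ascending; standardized cumulative weights
    ``p_i = (cumsum(w)_i - w_i / 2) / sum(w)`` define an empirical
    distribution function through whose nodes the 0.5 quantile is linearly
    interpolated.
    """
    order = np.argsort(ratios, kind="stable")
    r, w = ratios[order], weights[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, p, r))


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    k = ratios.size
    sd = float(np.std(ratios, ddof=1)) if k > 1 else 0.0
    mad = float(stats.median_abs_deviation(ratios, scale=1.0 / 1.4826))
    # median_abs_deviation with scale=1/1.4826 == MAD / 0.6745
    spread = min(sd, mad) if mad > 0 else sd
    return phi * 0.9 * spread * k ** (-0.2)


def _weighted_mode(ratios: np.ndarray, weights: np.ndarray, phi: float, grid_size: int = 2048) -> float:
    """Argmax of a Gaussian-kernel-smoothed, weighted ratio density on a grid."""
    h = _mode_bandwidth(ratios, phi)
    if h <= 0 or not np.isfinite(h):
        # degenerate spread: every ratio (essentially) identical
        return float(ratios[0])
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, grid_size)
    with np.errstate(over="ignore", under="ignore"):
        z = np.clip(np.abs(grid[:, None] - ratios[None, :]) / h, 0.0, 40.0)
        dens = np.sum(weights[None, :] * np.exp(-0.5 * z**2), axis=1)
    # the density of a Gaussian mixture peaks inside the convex hull of its
    # centers; clamping removes the one-grid-step excursion outside it
    return float(np.clip(grid[np.argmax(dens)], ratios.min(), ratios.max()))


def _parametric_bootstrap_se(
    instruments: Sequence[HarmonizedInstrument],
    point_fn,
    n_boot: int,
    seed: int | None,
) -> float:
    """SE of a ratio-based estimator under a parametric bootstrap.

    Each replicate redraws every beta from a normal centered at its estimate
    with its reported SE, recomputes ratios and inverse-variance weights
    (SEs held fixed), and re-evaluates the estimator; the SE is the standard
    deviation of the replicate estimates.
    """
    rng = np.random.default_rng(seed)
    bx = np.array([i.beta_exp for i in instruments], dtype=float)
    by = np.array([i.beta_out for i in instruments], dtype=float)
    sx = np.array([i.se_exp for i in instruments], dtype=float)
    sy = np.array([i.se_out for i in instruments], dtype=float)
    k = bx.size
    estimates = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        bx_b = np.where(bx_b == 0.0, np.finfo(float).tiny, bx_b)
        ratios = by_b / bx_b
        ses = sy / np.abs(bx_b)
        estimates[b] = point_fn(ratios, 1.0 / ses**2)
    return float(np.std(estimates, ddof=1))


def weighted_median(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-median causal estimate.

    Consistent when instruments carrying >= 50% of the inverse-variance
    weight are valid.  The SE comes from a seeded parametric bootstrap
    (``n_boot`` >= 100 replicates); the p-value is two-sided normal.
    """
    if len(instruments) < 2:
        raise ValueError("weighted_median requires >= 2 instruments")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for a stable bootstrap SE")
    rs = RatioSet.from_instruments(instruments)
    beta = _weighted_median(rs.ratios, rs.weights)
    se = _parametric_bootstrap_se(instruments, _weighted_median, n_boot, seed)
    return _normal_estimate(
        "weighted_median", len(instruments), beta, se,
        extra={"n_boot": n_boot, "seed": seed},
    )


def weighted_mode(
    instruments: Sequence[HarmonizedInstrument],
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-mode causal estimate.

    The point estimate maximizes a Gaussian-kernel density over the Wald
    ratios, weighted by inverse variance, with bandwidth
    ``phi * 0.9 * min(sd, MAD/0.6745) * k^(-1/5)``; ``phi`` rescales the
    rule-of-thumb bandwidth.  SE via the same parametric bootstrap as the
    weighted median.
    """
    if len(instruments) < 3:
        raise ValueError("weighted_mode requires >= 3 instruments")
    if phi <= 0:
        raise ValueError("phi must be positive")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for a stable bootstrap SE")
    rs = RatioSet.from_instruments(instruments)
    beta = _weighted_mode(rs.ratios, rs.weights, phi)

    def point(ratios: np.ndarray, weights: np.ndarray) -> float:
        return _weighted_mode(ratios, weights, phi)

    se = _parametric_bootstrap_se(instruments, point, n_boot, seed)
    return _normal_estimate(
        "weighted_mode", len(instruments), beta, se,
        extra={"phi": phi, "n_boot": n_boot, "seed": seed},
    )
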