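"""Heterogeneity, pleiotropy and influence diagnostics.

Cochran's Q measures how much the per-instrument causal estimates scatter
around a fitted model beyond what their standard errors explain; its excess
over the residual degrees of freedom, expressed as the fraction I^2,
summarizes heterogeneity.  The Egger intercept tests for directional
horizontal pleiotropy, and the leave-one-out analysis flags instruments
whose removal moves the pooled estimate.

This module also assembles the plain-text plot tables (forest, scatter,
funnel, leave-one-out forest) from which the standard MR figures are drawn;
rendering itself is cosmetic and lives on the results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    MREstimate,
    PleiotropyResult,
    RatioSet,
    Z_95,
    ivw,
    mr_egger,
    wald_ratio,
)
from .harmonize import HarmonizedInstrument

__all__ = [
    "HeterogeneityResult",
    "PleiotropyResult",
    "LeaveOneOutResult",
    "cochran_q",
    "egger_intercept_test",
    "leave_one_out",
    "plot_data",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q about one fit, with I^2 and its chi-square p-value.

    ``df`` is k-1 for the IVW fit and k-2 for the Egger fit; ``i2`` is the
    Higgins fraction ``max(0, (q - df) / q)``, truncated at zero.
    """

    method: str
    q: float
    df: int
    i2: float
    pval: float

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError("q must be non-negative")
        if not 0 <= self.i2 <= 1:
            raise ValueError("i2 must lie in [0, 1]")


@dataclass(frozen=True)
class LeaveOneOutResult:
    """Per-instrument exclusion estimates plus the all-instrument estimate."""

    entries: tuple[tuple[str, MREstimate], ...]
    full: MREstimate


def cochran_q(
    instruments: Sequence[HarmonizedInstrument],
    fit: str = "ivw",
) -> HeterogeneityResult:
    """Cochran's Q statistic about the IVW or Egger fit.

    ``q = sum_i w_i (beta_out_i - fitted_i)^2`` with ``w_i = 1/se_out_i^2``
    and fitted values from the named regression; the p-value is the
    upper-tail chi-square probability on the residual degrees of freedom.
    """
    k = len(instruments)
    if fit == "ivw":
        if k < 2:
            raise ValueError("cochran_q(ivw) requires >= 2 instruments")
        est = ivw(instruments, model="fixed")
        q = est.extra["q"]
        df = k - 1
    elif fit == "egger":
        if k < 3:
            raise ValueError("cochran_q(egger) requires >= 3 instruments")
        est, _ = mr_egger(instruments)
        q = est.extra["q_egger"]
        df = k - 2
    else:
        raise ValueError(f"unknown fit {fit!r}; expected 'ivw' or 'egger'")
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    pval = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(method=fit, q=float(q), df=df, i2=i2, pval=pval)


def egger_intercept_test(instruments: Sequence[HarmonizedInstrument]) -> PleiotropyResult:
    """Directional-pleiotropy test: the Egger regression intercept.

    Shares its implementation with :func:`~twosample_mr.estimators.mr_egger`,
    so intercept, SE and t(k-2) p-value are identical to that fit's.
    """
    _, intercept = mr_egger(instruments)
    return intercept


def leave_one_out(
    instruments: Sequence[HarmonizedInstrument],
    estimator: str = "ivw",
) -> LeaveOneOutResult:
    """Re-estimate the causal effect excluding each instrument in turn.

    Deterministic: only the IVW estimator (fixed-effect) is supported for
    the reduced fits.  Requires k >= 3 so every reduced set still has >= 2
    instruments.
    """
    if estimator != "ivw":
        raise ValueError("leave_one_out supports only the 'ivw' estimator")
    k = len(instruments)
    if k < 3:
        raise ValueError("leave_one_out requires >= 3 instruments")
    entries = []
    for i, inst in enumerate(instruments):
        reduced = [x for j, x in enumerate(instruments) if j != i]
        entries.append((inst.rsid, ivw(reduced)))
    return LeaveOneOutResult(entries=tuple(entries), full=ivw(list(instruments)))


def plot_data(
    instruments: Sequence[HarmonizedInstrument],
    estimates: Sequence[MREstimate],
    loo: LeaveOneOutResult | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble the plot tables behind the standard MR figures.

    Returns a dict of DataFrames:

    ``forest``
        Per-instrument Wald ratios with 95% intervals followed by one
        summary row per method.
    ``scatter``
        Per-instrument (beta_exp, beta_out) points with SEs, plus one slope
        row per method (Egger carrying its intercept, others through the
        origin).
    ``funnel``
        Wald ratio against instrument precision (1/se_ratio).
    ``loo_forest``
        Leave-one-out IVW estimates with intervals (only when ``loo`` is
        given).
    """
    ratios = [wald_ratio(i) for i in instruments]
    forest_rows = [
        {
            "label": inst.rsid,
            "kind": "snp",
            "beta": r.beta,
            "lo": r.beta - Z_95 * r.se,
            "hi": r.beta + Z_95 * r.se,
        }
        for inst, r in zip(instruments, ratios)
    ] + [
        {
            "label": e.method,
            "kind": "summary",
            "beta": e.beta,
            "lo": e.beta - Z_95 * e.se,
            "hi": e.beta + Z_95 * e.se,
        }
        for e in estimates
    ]

    scatter_rows = [
        {
            "kind": "snp",
            "label": i.rsid,
            "beta_exp": i.beta_exp,
            "beta_out": i.beta_out,
            "se_exp": i.se_exp,
            "se_out": i.se_out,
            "slope": np.nan,
            "intercept": np.nan,
        }
        for i in instruments
    ] + [
        {
            "kind": "fit",
            "label": e.method,
            "beta_exp": np.nan,
            "beta_out": np.nan,
            "se_exp": np.nan,
            "se_out": np.nan,
            "slope": e.beta,
            "intercept": e.extra.get("intercept", 0.0),
        }
        for e in estimates
    ]

    rs = RatioSet.from_instruments(instruments)
    funnel = pd.DataFrame(
        {"label": rs.rsids, "ratio": rs.ratios, "precision": 1.0 / rs.ses}
    )

    tables = {
        "forest": pd.DataFrame(forest_rows),
        "scatter": pd.DataFrame(scatter_rows),
        "funnel": funnel,
    }
    if loo is not None and loo.entries:
        loo_rows = [
            {
                "excluded": rsid,
                "beta": e.beta,
                "lo": e.beta - Z_95 * e.se,
                "hi": e.beta + Z_95 * e.se,
            }
            for rsid, e in loo.entries
        ]
        loo_rows.append(
            {
                "excluded": "<none>",
                "beta": loo.full.beta,
                "lo": loo.full.beta - Z_95 * loo.full.se,
                "hi": loo.full.beta + Z_95 * loo.full.se,
            }
        )
        tables["loo_forest"] = pd.DataFrame(loo_rows)
    return tables
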