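"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates, at the summary level, the data structure a
two-sample Mendelian randomization analysis consumes: for each of ``k``
independent variants it draws a minor-allele frequency, a true
variant-exposure effect ``gamma_j``, and an optional direct (pleiotropic)
variant-outcome effect ``alpha_j``, and then produces noisy observed
effects

.. math::

    \\hat\\beta^{exp}_j \\sim N(\\gamma_j, se^{exp}_j), \\qquad
    \\hat\\beta^{out}_j \\sim N(\\theta\\gamma_j + \\alpha_j, se^{out}_j)

where ``theta`` is the true causal effect and the standard errors follow
the standardized-trait approximation ``se = 1 / sqrt(2 N f (1 - f))``.
Pleiotropic effects are drawn independently of instrument strength, so the
InSIDE assumption holds by construction: ``alpha ~ N(mean, sd)`` with
``mean != 0`` giving directional and ``mean = 0, sd > 0`` balanced
pleiotropy.

No LD between variants is simulated; variants are placed on distinct
chromosome/position slots far apart so distance-based pruning keeps them
all.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .harmonize import HarmonizedInstrument, SelectionConfig, compute_f, compute_r2, harmonize
from .summary_io import SummaryDataset, SummaryRecord

__all__ = ["SimulationScenario", "simulate_pair", "simulate_instruments", "scenario_suite"]

# Non-palindromic allele codings cycled across variants.
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C"), ("G", "T"))

_CHROM_SPACING_BP = 25_000_000  # > the default 10,000 kb pruning window


@dataclass(frozen=True)
class SimulationScenario:
    """Generative parameters for one synthetic two-sample dataset.

    Attributes
    ----------
    k : int
        Number of independent instruments.
    n_exp, n_out : int
        Exposure and outcome GWAS sample sizes (>= 100).
    theta : float
        True causal effect of the exposure on the outcome (log-odds per
        exposure unit).
    gamma_low, gamma_high : float
        Bounds of the uniform distribution of true variant-exposure effect
        magnitudes.
    gamma_sign : str
        ``"positive"`` codes every effect allele as exposure-increasing;
        ``"random"`` flips signs with probability 1/2.
    maf_low, maf_high : float
        Bounds of the uniform minor-allele-frequency distribution, within
        (0, 0.5].
    pleiotropy_mean, pleiotropy_sd : float
        Mean and SD of the direct variant-outcome effects; (0, 0) disables
        pleiotropy.
    seed : int
        Seed for the generator; identical scenarios give byte-identical
        datasets.
    """

    k: int
    n_exp: int
    n_out: int
    theta: float
    gamma_low: float = 0.02
    gamma_high: float = 0.1
    gamma_sign: str = "positive"
    maf_low: float = 0.05
    maf_high: float = 0.5
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_exp < 100 or self.n_out < 100:
            raise ValueError("sample sizes must be >= 100")
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("maf bounds must satisfy 0 < low <= high <= 0.5")
        if not (0 < self.gamma_low <= self.gamma_high):
            raise ValueError("gamma bounds must satisfy 0 < low <= high")
        if self.gamma_sign not in ("positive", "random"):
            raise ValueError("gamma_sign must be 'positive' or 'random'")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be non-negative")


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, 1e-300, 1.0)


def simulate_pair(scenario: SimulationScenario) -> tuple[SummaryDataset, SummaryDataset]:
    """Generate matched exposure and outcome summary datasets.

    Returns two :class:`~twosample_mr.summary_io.SummaryDataset` objects with
    identical variant identities (rsid, position, alleles, frequency) and
    independent sampling noise in the effect estimates, reproducible from
    ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    k = scenario.k
    maf = rng.uniform(scenario.maf_low, scenario.maf_high, size=k)
    gamma = rng.uniform(scenario.gamma_low, scenario.gamma_high, size=k)
    if scenario.gamma_sign == "random":
        gamma *= rng.choice([-1.0, 1.0], size=k)
    alpha = (
        rng.normal(scenario.pleiotropy_mean, scenario.pleiotropy_sd, size=k)
        if (scenario.pleiotropy_mean != 0.0 or scenario.pleiotropy_sd > 0.0)
        else np.zeros(k)
    )

    het = 2.0 * maf * (1.0 - maf)
    se_exp = 1.0 / np.sqrt(scenario.n_exp * het)
    se_out = 1.0 / np.sqrt(scenario.n_out * het)
    beta_exp = rng.normal(gamma, se_exp)
    beta_out = rng.normal(scenario.theta * gamma + alpha, se_out)
    p_exp = _pvalues(beta_exp, se_exp)
    p_out = _pvalues(beta_out, se_out)

    exp_records, out_records = [], []
    for j in range(k):
        ea, oa = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
        chrom = str(j % 22 + 1)
        pos = 1_000_000 + (j // 22) * _CHROM_SPACING_BP
        rsid = f"rs9{j + 1:07d}"
        common = dict(rsid=rsid, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa)
        exp_records.append(
            SummaryRecord(
                **common,
                eaf=float(maf[j]),
                beta=float(beta_exp[j]),
                se=float(se_exp[j]),
                pval=float(p_exp[j]),
                n=scenario.n_exp,
            )
        )
        out_records.append(
            SummaryRecord(
                **common,
                eaf=float(maf[j]),
                beta=float(beta_out[j]),
                se=float(se_out[j]),
                pval=float(p_out[j]),
                n=scenario.n_out,
            )
        )
    exposure = SummaryDataset("simulated_exposure", exp_records, n_default=scenario.n_exp)
    outcome = SummaryDataset("simulated_outcome", out_records, n_default=scenario.n_out)
    return exposure, outcome


def simulate_instruments(scenario: SimulationScenario) -> list[HarmonizedInstrument]:
    """Generate a scenario and harmonize it with no selection filters.

    Skipping the significance and instrument-strength filters avoids
    selection (winner's-curse) effects, so estimator-calibration studies see
    exactly the generative model.  The harmonization path is the real one.
    """
    exposure, outcome = simulate_pair(scenario)
    permissive = SelectionConfig(p_threshold=1.0, f_min=0.0)
    return harmonize(
        exposure, outcome, permissive, n_exp=scenario.n_exp, n_out=scenario.n_out
    )


def scenario_suite(seed: int = 20240100) -> dict[str, SimulationScenario]:
    """Named reference scenarios spanning the regimes the estimators face.

    ``null``
        No causal effect, no pleiotropy; calibration of type-I error.
    ``causal``
        theta = 0.1 at biobank-scale sample sizes; parameter recovery.
    ``balanced_pleiotropy``
        Direct effects with zero mean; IVW remains consistent, Q inflates.
    ``directional_pleiotropy``
        Direct effects with positive mean; IVW biased, the Egger slope is
        protected by InSIDE and its intercept should detect the shift.
    ``weak_instruments``
        Effect magnitudes tuned so F-statistics land near the conventional
        F = 10 screening boundary.
    """
    base = dict(n_exp=300_000, n_out=200_000)
    return {
        "null": SimulationScenario(k=50, n_exp=100_000, n_out=100_000, theta=0.0, seed=seed + 1),
        "causal": SimulationScenario(k=100, theta=0.1, seed=seed + 2, **base),
        "balanced_pleiotropy": SimulationScenario(
            k=100, theta=0.1, pleiotropy_mean=0.0, pleiotropy_sd=0.02, seed=seed + 3, **base
        ),
        "directional_pleiotropy": SimulationScenario(
            k=100, theta=0.1, pleiotropy_mean=0.02, pleiotropy_sd=0.01, seed=seed + 4, **base
        ),
        "weak_instruments": SimulationScenario(
            k=50,
            n_exp=100_000,
            n_out=100_000,
            theta=0.1,
            gamma_low=0.012,
            gamma_high=0.03,
            seed=seed + 5,
        ),
    }
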