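"""Instrument selection, allele harmonization and instrument-strength metrics.

Two-sample Mendelian randomization requires the exposure and outcome GWAS to
report their per-variant effects on the *same* allele.  This module

* filters the exposure GWAS to genome-wide-significant, approximately
  independent instruments (:func:`select_instruments`),
* intersects exposure and outcome on shared variants and aligns the outcome
  effect to the exposure effect allele, resolving swapped and
  strand-complemented codings and the ambiguous palindromic (A/T, C/G) case
  (:func:`harmonize`), and
* computes the instrument-strength metrics: the variance in the exposure
  explained by a variant (:func:`compute_r2`) and the corresponding
  F-statistic (:func:`compute_f`); F < 10 conventionally flags a weak
  instrument.

Proxy-variant lookup is deliberately unsupported: a variant absent from the
outcome GWAS is dropped, never substituted by an LD proxy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, MutableMapping, Sequence

import numpy as np
import pandas as pd

from .summary_io import SummaryDataset, SummaryRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Reason codes attached to every variant excluded during harmonization.
DROP_ABSENT = "absent_in_outcome"
DROP_ALLELE_MISMATCH = "allele_mismatch"
DROP_PALINDROMIC = "palindromic_ambiguous_frequency"
DROP_WEAK = "weak_instrument"


class HarmonizationError(ValueError):
    """Raised when selection or harmonization cannot produce any instrument."""


def compute_r2(beta: float, se: float, eaf: float, n: int) -> float:
    """Fraction of exposure variance explained by one variant.

    Computed from summary statistics as

    .. math::

        R^2 = \\frac{2\\beta^2 f(1-f)}{2\\beta^2 f(1-f) + 2\\,SE^2\\,N f(1-f)}

    with effect size ``beta``, its standard error ``se``, effect-allele
    frequency ``f`` and GWAS sample size ``n``.  The allele-frequency factor
    cancels algebraically, but the expression is evaluated as written so the
    implementation matches its definition term for term.

    Returns a value in [0, 1); zero effect explains zero variance.
    """
    if n < 2:
        raise ValueError(f"sample size n={n} must be >= 2")
    if se <= 0:
        raise ValueError(f"se={se} must be > 0")
    if not 0 < eaf < 1:
        raise ValueError(f"eaf={eaf} must lie in (0, 1)")
    q = eaf * (1.0 - eaf)
    num = 2.0 * beta * beta * q
    den = num + 2.0 * se * se * n * q
    return float(num / den)


def compute_f(r2: float, n: int) -> float:
    """Instrument-strength F-statistic, ``F = R^2 (N - 2) / (1 - R^2)``.

    Strictly increasing in both ``r2`` and ``n``; F >= 0.
    """
    if not 0 <= r2 < 1:
        raise ValueError(f"r2={r2} must lie in [0, 1)")
    if n <= 2:
        raise ValueError(f"sample size n={n} must exceed 2")
    return float(r2 * (n - 2) / (1.0 - r2))


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds controlling instrument selection and harmonization.

    Attributes
    ----------
    p_threshold : float
        Exposure genome-wide significance cutoff (default 5e-8).
    ld_r2_max : float
        Maximum pairwise LD r^2 between kept instruments (default 0.01).
    ld_window_kb : float
        Window, in kb, within which LD/distance pruning applies
        (default 10,000 kb).
    f_min : float
        Minimum instrument F-statistic; weaker instruments are excluded
        (default 10).
    palindrome_eaf_band : float
        Half-width of the frequency band around 0.5 inside which a
        palindromic variant's strand cannot be inferred from allele
        frequency; such variants are dropped (default 0.08).
    """

    p_threshold: float = 5e-8
    ld_r2_max: float = 0.01
    ld_window_kb: float = 10_000.0
    f_min: float = 10.0
    palindrome_eaf_band: float = 0.08

    def __post_init__(self) -> None:
        for name in ("p_threshold", "ld_r2_max", "ld_window_kb", "f_min"):
            if getattr(self, name) <= 0 and name != "f_min":
                raise ValueError(f"{name} must be positive")
        if self.f_min < 0:
            raise ValueError("f_min must be non-negative")
        if not 0 < self.palindrome_eaf_band < 0.5:
            raise ValueError("palindrome_eaf_band must lie in (0, 0.5)")


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure and outcome statistics for one variant on a shared effect allele."""

    rsid: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    eaf_exp: float
    pval_exp: float
    beta_out: float
    se_out: float
    eaf_out: float
    pval_out: float
    n_exp: int
    n_out: int
    r2_exp: float
    f_stat: float

    def __post_init__(self) -> None:
        if self.se_exp <= 0 or self.se_out <= 0:
            raise ValueError(f"{self.rsid}: standard errors must be positive")
        if not 0 <= self.r2_exp < 1:
            raise ValueError(f"{self.rsid}: r2_exp outside [0, 1)")
        if self.f_stat < 0:
            raise ValueError(f"{self.rsid}: negative f_stat")


def read_ld_table(path: str | Path) -> dict[frozenset[str], float]:
    """Read a 3-column (rsid_a, rsid_b, r2) delimited table of pairwise LD."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 3:
        raise ValueError("LD table needs columns rsid_a, rsid_b, r2")
    out: dict[frozenset[str], float] = {}
    for a, b, r2 in df.iloc[:, :3].itertuples(index=False):
        out[frozenset((str(a), str(b)))] = float(r2)
    return out


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    try:
        return (int(chrom), "")
    except ValueError:
        return (10**6, chrom)


def select_instruments(
    exposure: SummaryDataset,
    config: SelectionConfig | None = None,
    ld: Mapping[frozenset[str], float] | None = None,
) -> SummaryDataset:
    """Filter the exposure GWAS to significant, approximately independent variants.

    Variants with ``pval <= p_threshold`` are retained and then greedily
    pruned: sorted by ascending p-value, a variant is kept iff its LD r^2
    with every already-kept variant within ``ld_window_kb`` on the same
    chromosome stays below ``ld_r2_max``.  Without a pairwise LD table the
    pruning degrades to distance-only (best p-value per window), which is
    logged because correlated instruments may then survive.

    The result is ordered by (chromosome, position).
    """
    config = config or SelectionConfig()
    significant = [r for r in exposure.records if r.pval <= config.p_threshold]
    if not significant:
        raise HarmonizationError(
            f"no instruments at threshold p <= {config.p_threshold:g} "
            f"in {exposure.trait_label!r}"
        )
    if ld is None:
        logger.warning(
            "select_instruments: no LD table supplied; pruning on distance only "
            "(window %.0f kb)",
            config.ld_window_kb,
        )

    window_bp = config.ld_window_kb * 1_000.0
    kept: list[SummaryRecord] = []
    for rec in sorted(significant, key=lambda r: (r.pval, r.rsid)):
        conflict = False
        for other in kept:
            if other.chrom != rec.chrom or abs(other.pos - rec.pos) > window_bp:
                continue
            if ld is None:
                conflict = True  # distance-only fallback: one variant per window
            else:
                r2 = ld.get(frozenset((rec.rsid, other.rsid)), 0.0)
                conflict = r2 >= config.ld_r2_max
            if conflict:
                logger.info("pruning %s (LD/window conflict with %s)", rec.rsid, other.rsid)
                break
        if not conflict:
            kept.append(rec)

    kept.sort(key=lambda r: (_chrom_sort_key(r.chrom), r.pos))
    return SummaryDataset(
        trait_label=exposure.trait_label, records=kept, n_default=exposure.n_default
    )


def _align_outcome(
    exp: SummaryRecord,
    out: SummaryRecord,
    band: float,
) -> tuple[SummaryRecord | None, str | None]:
    """Align an outcome record to the exposure effect allele.

    Returns (aligned record, None) or (None, drop reason).
    """
    if exp.is_palindromic:
        # Allele letters cannot distinguish strands for A/T and C/G variants:
        # infer orientation from allele-frequency concordance, but only when
        # both frequencies are far enough from 0.5 to be informative.
        if abs(exp.eaf - 0.5) <= band or abs(out.eaf - 0.5) <= band:
            return None, DROP_PALINDROMIC
        if {out.effect_allele, out.other_allele} != {exp.effect_allele, exp.other_allele}:
            return None, DROP_ALLELE_MISMATCH
        same_side = (exp.eaf - 0.5) * (out.eaf - 0.5) > 0
        return (out if same_side else out.flipped()), None

    if (out.effect_allele, out.other_allele) == (exp.effect_allele, exp.other_allele):
        return out, None
    if (out.effect_allele, out.other_allele) == (exp.other_allele, exp.effect_allele):
        return out.flipped(), None
    # try the opposite strand
    comp_ea = _COMPLEMENT[out.effect_allele]
    comp_oa = _COMPLEMENT[out.other_allele]
    if (comp_ea, comp_oa) == (exp.effect_allele, exp.other_allele):
        return out, None
    if (comp_ea, comp_oa) == (exp.other_allele, exp.effect_allele):
        return out.flipped(), None
    return None, DROP_ALLELE_MISMATCH


def harmonize(
    exposure_instruments: SummaryDataset,
    outcome: SummaryDataset,
    config: SelectionConfig | None = None,
    n_exp: int | None = None,
    n_out: int | None = None,
    drop_log: MutableMapping[str, str] | None = None,
) -> list[HarmonizedInstrument]:
    """Intersect exposure instruments with the outcome GWAS and align alleles.

    For each exposure instrument present in the outcome dataset (no proxy
    substitution), the outcome effect is expressed on the exposure effect
    allele: identical codings pass through, swapped codings negate the
    outcome beta and complement its allele frequency, strand-complemented
    codings are complemented first, and anything else is dropped.
    Palindromic variants are kept only when both allele frequencies lie
    outside ``0.5 +/- palindrome_eaf_band``, with strand inferred from
    frequency concordance.  Finally the exposure-side variance explained and
    F-statistic are attached and instruments with ``f_stat < f_min``
    excluded.

    Every dropped variant receives exactly one reason code, logged and — when
    ``drop_log`` (a mutable mapping) is supplied — recorded there keyed by
    rsid.

    Raises :class:`HarmonizationError` when no instrument survives.
    """
    config = config or SelectionConfig()
    drops: MutableMapping[str, str] = drop_log if drop_log is not None else {}

    out_by_rsid = {r.rsid: r for r in outcome.records}
    instruments: list[HarmonizedInstrument] = []
    for exp in exposure_instruments.records:
        out = out_by_rsid.get(exp.rsid)
        if out is None:
            drops[exp.rsid] = DROP_ABSENT
            continue
        aligned, reason = _align_outcome(exp, out, config.palindrome_eaf_band)
        if aligned is None:
            drops[exp.rsid] = reason or DROP_ALLELE_MISMATCH
            continue
        n_e = int(n_exp) if n_exp is not None else int(exp.n)
        n_o = int(n_out) if n_out is not None else int(aligned.n)
        r2 = compute_r2(exp.beta, exp.se, exp.eaf, n_e)
        f = compute_f(r2, n_e)
        if f < config.f_min:
            drops[exp.rsid] = DROP_WEAK
            continue
        instruments.append(
            HarmonizedInstrument(
                rsid=exp.rsid,
                effect_allele=exp.effect_allele,
                other_allele=exp.other_allele,
                beta_exp=exp.beta,
                se_exp=exp.se,
                eaf_exp=exp.eaf,
                pval_exp=exp.pval,
                beta_out=aligned.beta,
                se_out=aligned.se,
                eaf_out=aligned.eaf,
                pval_out=aligned.pval,
                n_exp=n_e,
                n_out=n_o,
                r2_exp=r2,
                f_stat=f,
            )
        )
    for rsid, reason in drops.items():
        logger.info("harmonize: dropped %s (%s)", rsid, reason)
    if not instruments:
        raise HarmonizationError("no instruments survived harmonization")
    return instruments


# ---------------------------------------------------------------------------
# Tabular round-trip for harmonized instruments
# ---------------------------------------------------------------------------

INSTRUMENT_COLUMNS = [
    "rsid", "ea", "oa",
    "beta_exp", "se_exp", "eaf_exp", "pval_exp",
    "beta_out", "se_out", "eaf_out", "pval_out",
    "n_exp", "n_out", "r2_exp", "f_stat",
]


def instruments_to_dataframe(instruments: Sequence[HarmonizedInstrument]) -> pd.DataFrame:
    rows = [
        [
            i.rsid, i.effect_allele, i.other_allele,
            i.beta_exp, i.se_exp, i.eaf_exp, i.pval_exp,
            i.beta_out, i.se_out, i.eaf_out, i.pval_out,
            i.n_exp, i.n_out, i.r2_exp, i.f_stat,
        ]
        for i in instruments
    ]
    return pd.DataFrame(rows, columns=INSTRUMENT_COLUMNS)


def instruments_from_dataframe(df: pd.DataFrame) -> list[HarmonizedInstrument]:
    return [
        HarmonizedInstrument(
            rsid=str(row["rsid"]),
            effect_allele=str(row["ea"]),
            other_allele=str(row["oa"]),
            beta_exp=float(row["beta_exp"]),
            se_exp=float(row["se_exp"]),
            eaf_exp=float(row["eaf_exp"]),
            pval_exp=float(row["pval_exp"]),
            beta_out=float(row["beta_out"]),
            se_out=float(row["se_out"]),
            eaf_out=float(row["eaf_out"]),
            pval_out=float(row["pval_out"]),
            n_exp=int(row["n_exp"]),
            n_out=int(row["n_out"]),
            r2_exp=float(row["r2_exp"]),
            f_stat=float(row["f_stat"]),
        )
        for _, row in df.iterrows()
    ]


def write_instruments(instruments: Sequence[HarmonizedInstrument], path: str | Path) -> None:
    instruments_to_dataframe(instruments).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_instruments(path: str | Path) -> list[HarmonizedInstrument]:
    return instruments_from_dataframe(pd.read_csv(path, sep="\t"))
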