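"""Model/Results interface tying the estimators and diagnostics together.

:class:`MRModel` holds a set of harmonized instruments (built directly, from
exposure/outcome datasets, or from a harmonized table) and its :meth:`fit
<MRModel.fit>` runs the requested estimators plus the sensitivity suite,
returning an :class:`MRResults` that carries the estimates, their
uncertainties, the diagnostics, a ``summary()`` table and the plot products.

Example
-------
>>> from twosample_mr.datasets import load_example_instruments
>>> from twosample_mr.model import MRModel
>>> res = MRModel(load_example_instruments()).fit(seed=7)
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import estimators as est
from . import sensitivity as sens
from .harmonize import (
    HarmonizedInstrument,
    SelectionConfig,
    harmonize,
    instruments_from_dataframe,
    instruments_to_dataframe,
    select_instruments,
)
from .summary_io import SummaryDataset, method_label

DEFAULT_METHODS = ("ivw", "egger", "weighted_median", "weighted_mode")


class MRModel:
    """Two-sample Mendelian randomization model over harmonized instruments.

    Parameters
    ----------
    instruments
        Harmonized instruments (exposure and outcome effects on a shared
        effect allele).
    exposure_label, outcome_label
        Optional trait labels used in the summary header.
    """

    def __init__(
        self,
        instruments: Sequence[HarmonizedInstrument],
        exposure_label: str = "exposure",
        outcome_label: str = "outcome",
    ) -> None:
        instruments = list(instruments)
        if not instruments:
            raise ValueError("MRModel requires at least one instrument")
        self.instruments = instruments
        self.exposure_label = exposure_label
        self.outcome_label = outcome_label

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_datasets(
        cls,
        exposure: SummaryDataset,
        outcome: SummaryDataset,
        config: SelectionConfig | None = None,
        n_exp: int | None = None,
        n_out: int | None = None,
        ld: Mapping[frozenset[str], float] | None = None,
        select: bool = True,
        drop_log: dict | None = None,
    ) -> "MRModel":
        """Select instruments from the exposure GWAS and harmonize with the outcome."""
        config = config or SelectionConfig()
        chosen = select_instruments(exposure, config, ld) if select else exposure
        instruments = harmonize(
            chosen, outcome, config, n_exp=n_exp, n_out=n_out, drop_log=drop_log
        )
        return cls(
            instruments,
            exposure_label=exposure.trait_label,
            outcome_label=outcome.trait_label,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "MRModel":
        """Build from a harmonized-instrument table (canonical column names)."""
        return cls(instruments_from_dataframe(df), **kwargs)

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        methods: Sequence[str] = DEFAULT_METHODS,
        ivw_model: str = "fixed",
        n_boot: int = 1000,
        phi: float = 1.0,
        seed: int | None = None,
    ) -> "MRResults":
        """Run the requested estimators and the sensitivity suite.

        ``seed`` drives the parametric bootstrap of the weighted median and
        weighted mode; identical seeds give bit-identical SEs.  Estimators
        whose minimum instrument count exceeds the available k are skipped
        with a notice recorded in the results.
        """
        k = len(self.instruments)
        estimates: dict[str, est.MREstimate] = {}
        pleiotropy = None
        skipped: dict[str, str] = {}
        for method in methods:
            try:
                if method == "ivw":
                    estimates[method] = (
                        est.wald_ratio(self.instruments[0])
                        if k == 1
                        else est.ivw(self.instruments, model=ivw_model)
                    )
                elif method == "egger":
                    estimates[method], pleiotropy = est.mr_egger(self.instruments)
                elif method == "weighted_median":
                    estimates[method] = est.weighted_median(
                        self.instruments, n_boot=n_boot, seed=seed
                    )
                elif method == "weighted_mode":
                    estimates[method] = est.weighted_mode(
                        self.instruments, phi=phi, n_boot=n_boot, seed=seed
                    )
                elif method == "wald_ratio":
                    estimates[method] = est.wald_ratio(self.instruments[0])
                else:
                    raise ValueError(f"unknown method {method!r}")
            except ValueError as exc:
                if "instruments" in str(exc):
                    skipped[method] = str(exc)
                else:
                    raise

        heterogeneity = []
        if k >= 2:
            heterogeneity.append(sens.cochran_q(self.instruments, fit="ivw"))
        if k >= 3:
            heterogeneity.append(sens.cochran_q(self.instruments, fit="egger"))
        loo = sens.leave_one_out(self.instruments) if k >= 3 else None

        return MRResults(
            model=self,
            estimates=estimates,
            heterogeneity=heterogeneity,
            pleiotropy=pleiotropy,
            loo=loo,
            skipped=skipped,
            settings={
                "ivw_model": ivw_model,
                "n_boot": n_boot,
                "phi": phi,
                "seed": seed,
                "methods": tuple(methods),
            },
        )


@dataclass
class MRResults:
    """Fitted estimates, diagnostics and reporting for an :class:`MRModel`."""

    model: MRModel
    estimates: dict[str, est.MREstimate]
    heterogeneity: list[sens.HeterogeneityResult]
    pleiotropy: est.PleiotropyResult | None
    loo: sens.LeaveOneOutResult | None
    skipped: dict[str, str] = field(default_factory=dict)
    settings: dict = field(default_factory=dict)

    # -- tabular views ----------------------------------------------------

    def estimates_frame(self) -> pd.DataFrame:
        rows = [
            {
                "method": method_label(e.method),
                "nsnp": e.n_snp,
                "beta": e.beta,
                "se": e.se,
                "or": e.or_,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "pval": e.pval,
            }
            for e in self.estimates.values()
        ]
        return pd.DataFrame(rows)

    def heterogeneity_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"method": method_label(h.method), "q": h.q, "df": h.df, "i2": h.i2, "q_pval": h.pval}
                for h in self.heterogeneity
            ]
        )

    def loo_frame(self) -> pd.DataFrame:
        if self.loo is None:
            return pd.DataFrame()
        rows = [
            {"excluded_rsid": rsid, "beta": e.beta, "se": e.se, "or": e.or_, "pval": e.pval}
            for rsid, e in self.loo.entries
        ]
        rows.append(
            {
                "excluded_rsid": "<none>",
                "beta": self.loo.full.beta,
                "se": self.loo.full.se,
                "or": self.loo.full.or_,
                "pval": self.loo.full.pval,
            }
        )
        return pd.DataFrame(rows)

    def plot_data(self) -> dict[str, pd.DataFrame]:
        return sens.plot_data(
            self.model.instruments, list(self.estimates.values()), self.loo
        )

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table in the style of a statistical report."""
        lines = [
            "Two-sample Mendelian randomization",
            f"  exposure: {self.model.exposure_label}",
            f"  outcome:  {self.model.outcome_label}",
            f"  instruments: {len(self.model.instruments)}",
            "",
            "Causal estimates",
        ]
        fmt = "  {:<16} {:>4} {:>9} {:>8} {:>7} {:>14} {:>8}"
        lines.append(fmt.format("method", "nsnp", "beta", "se", "OR", "95% CI", "p"))
        for e in self.estimates.values():
            lines.append(
                fmt.format(
                    method_label(e.method),
                    e.n_snp,
                    f"{e.beta:.4f}",
                    f"{e.se:.4f}",
                    f"{e.or_:.3f}",
                    f"{e.ci_low:.3f}-{e.ci_high:.3f}",
                    f"{e.pval:.3g}",
                )
            )
        if self.heterogeneity:
            lines += ["", "Heterogeneity (Cochran's Q)"]
            for h in self.heterogeneity:
                lines.append(
                    f"  {method_label(h.method):<16} Q = {h.q:.3f}  df = {h.df}"
                    f"  I2 = {h.i2:.3f}  p = {h.pval:.3g}"
                )
        if self.pleiotropy is not None:
            lines += [
                "",
                "Directional pleiotropy (Egger intercept)",
                f"  intercept = {self.pleiotropy.intercept:.3g}"
                f"  se = {self.pleiotropy.se:.3g}  p = {self.pleiotropy.pval:.3g}",
            ]
        if self.skipped:
            lines += [""] + [f"  skipped {m}: {why}" for m, why in self.skipped.items()]
        return "\n".join(lines)

    def instruments_frame(self) -> pd.DataFrame:
        return instruments_to_dataframe(self.model.instruments)

    # -- plotting (cosmetic; the plot_data tables are the product) ---------

    def plot_scatter(self, ax=None):
        """Instrument effects with the fitted method slopes overlaid."""
        import matplotlib.pyplot as plt
        import numpy as np

        if ax is None:
            _, ax = plt.subplots()
        tables = self.plot_data()
        pts = tables["scatter"].query("kind == 'snp'")
        ax.errorbar(
            pts["beta_exp"], pts["beta_out"],
            xerr=est.Z_95 * pts["se_exp"], yerr=est.Z_95 * pts["se_out"],
            fmt="o", color="black", capsize=2,
        )
        xs = np.linspace(0, float(pts["beta_exp"].max()) * 1.1, 50)
        for _, row in tables["scatter"].query("kind == 'fit'").iterrows():
            icpt = 0.0 if pd.isna(row["intercept"]) else row["intercept"]
            ax.plot(xs, icpt + row["slope"] * xs, label=method_label(row["label"]))
        ax.set_xlabel(f"effect on {self.model.exposure_label}")
        ax.set_ylabel(f"effect on {self.model.outcome_label}")
        ax.legend(fontsize="small")
        return ax

    def plot_forest(self, ax=None):
        """Per-variant ratios and method summaries with 95% intervals."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        table = self.plot_data()["forest"]
        ypos = range(len(table))[::-1]
        for y, (_, row) in zip(ypos, table.iterrows()):
            color = "firebrick" if row["kind"] == "summary" else "black"
            ax.plot([row["lo"], row["hi"]], [y, y], color=color)
            ax.plot(row["beta"], y, "o", color=color)
        ax.axvline(0.0, linestyle="--", color="grey")
        ax.set_yticks(list(ypos))
        ax.set_yticklabels([method_label(x) for x in table["label"]])
        ax.set_xlabel("causal effect (log odds)")
        return ax

    def plot_leave_one_out(self, ax=None):
        """Forest of IVW estimates after excluding each instrument in turn."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tables = self.plot_data()
        if "loo_forest" not in tables:
            raise ValueError("no leave-one-out results available")
        table = tables["loo_forest"]
        ypos = range(len(table))[::-1]
        for y, (_, row) in zip(ypos, table.iterrows()):
            color = "firebrick" if row["excluded"] == "<none>" else "black"
            ax.plot([row["lo"], row["hi"]], [y, y], color=color)
            ax.plot(row["beta"], y, "o", color=color)
        ax.axvline(0.0, linestyle="--", color="grey")
        ax.set_yticks(list(ypos))
        ax.set_yticklabels(table["excluded"])
        ax.set_xlabel("IVW causal effect excluding variant")
        return ax
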