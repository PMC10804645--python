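"""Data model and readers/writers for GWAS summary statistics.

A GWAS summary-statistic table carries, per variant, the estimated additive
effect of one allele (the *effect allele*) on a trait together with its
standard error, allele frequency, p-value and sample size.  Two-sample
Mendelian randomization consumes two such tables — one for the exposure and
one for the outcome — so this module defines a validated per-variant record
(:class:`SummaryRecord`), an ordered container (:class:`SummaryDataset`) and
delimited-text I/O for both, plus writers for the result tables the analysis
produces.

Field dialects vary wildly between GWAS resources; canonical field names are
fixed here and arbitrary source headers are supported only through an
explicit ``column_map`` — never guessed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical field names, in canonical column order.
CANONICAL_FIELDS = ("rsid", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n")

VALID_ALLELES = frozenset("ACGT")

# Formatting used by every writer; 12 significant digits round-trips floats
# well beyond the 10-digit contract.
_FLOAT_FMT = "{:.12g}"


class SummaryDataError(ValueError):
    """Raised for structurally invalid summary-statistic input."""


@dataclass(frozen=True)
class SummaryRecord:
    """One variant's association statistics in one GWAS.

    Parameters
    ----------
    rsid : str
        Variant identifier (e.g. dbSNP rsID).
    chrom : str
        Chromosome label, stored as text ("1".."22", "X", ...).
    pos : int
        1-based base-pair position.
    effect_allele, other_allele : str
        Single bases in {A, C, G, T}; the effect allele is the allele whose
        per-copy effect ``beta`` measures.
    eaf : float
        Effect-allele frequency, strictly inside (0, 1).
    beta : float
        Per-allele effect size (log odds ratio for binary traits).
    se : float
        Standard error of ``beta``; strictly positive.
    pval : float
        Association p-value in (0, 1].
    n : int
        GWAS sample size (>= 2).
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int

    def validation_errors(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        errs: list[str] = []
        if self.effect_allele not in VALID_ALLELES:
            errs.append(f"effect allele {self.effect_allele!r} is not a single base A/C/G/T")
        if self.other_allele not in VALID_ALLELES:
            errs.append(f"other allele {self.other_allele!r} is not a single base A/C/G/T")
        if self.effect_allele == self.other_allele:
            errs.append("effect and other allele are identical")
        if not (isinstance(self.pos, int) and self.pos >= 1):
            errs.append(f"position {self.pos!r} is not a positive 1-based integer")
        if not (math.isfinite(self.eaf) and 0.0 < self.eaf < 1.0):
            errs.append(f"eaf {self.eaf!r} outside (0, 1)")
        if not math.isfinite(self.beta):
            errs.append(f"beta {self.beta!r} not finite")
        if not (math.isfinite(self.se) and self.se > 0.0):
            errs.append(f"se {self.se!r} not strictly positive")
        if not (math.isfinite(self.pval) and 0.0 < self.pval <= 1.0):
            errs.append(f"pval {self.pval!r} outside (0, 1]")
        if not (isinstance(self.n, int) and self.n >= 2):
            errs.append(f"n {self.n!r} is not an integer >= 2")
        return errs

    @property
    def is_valid(self) -> bool:
        return not self.validation_errors()

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, whose strand is ambiguous."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})

    def flipped(self) -> "SummaryRecord":
        """Return the same association expressed on the other allele.

        Swapping effect and other allele negates ``beta`` and complements the
        allele frequency; this transformation is an involution.
        """
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=1.0 - self.eaf,
        )


@dataclass
class SummaryDataset:
    """An ordered collection of :class:`SummaryRecord` for one trait."""

    trait_label: str
    records: list[SummaryRecord] = field(default_factory=list)
    n_default: int | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.rsid in seen:
                raise SummaryDataError(
                    f"duplicate rsid {rec.rsid!r} in dataset {self.trait_label!r}"
                )
            seen.add(rec.rsid)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SummaryRecord]:
        return iter(self.records)

    @property
    def rsids(self) -> list[str]:
        return [rec.rsid for rec in self.records]

    def get(self, rsid: str) -> SummaryRecord | None:
        for rec in self.records:
            if rec.rsid == rsid:
                return rec
        return None

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "rsid": r.rsid,
                "chrom": r.chrom,
                "pos": r.pos,
                "ea": r.effect_allele,
                "oa": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pval": r.pval,
                "n": r.n,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_FIELDS))


def _detect_separator(path: Path) -> str:
    """Choose tab vs comma from the header line (tab wins when present)."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:  # type: ignore[operator]
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _coerce_record(
    row: Mapping[str, object], n_default: int | None
) -> tuple[SummaryRecord | None, str | None]:
    """Build a record from one source row; return (record, error) with one None."""
    try:
        n_raw = row.get("n")
        if n_raw is None or (isinstance(n_raw, float) and math.isnan(n_raw)):
            if n_default is None:
                return None, "missing n and no n_default"
            n_val = int(n_default)
        else:
            n_val = int(float(n_raw))  # tolerate "361194.0"
        rec = SummaryRecord(
            rsid=str(row["rsid"]).strip(),
            chrom=str(row["chrom"]).strip(),
            pos=int(float(row["pos"])),
            effect_allele=str(row["ea"]).strip().upper(),
            other_allele=str(row["oa"]).strip().upper(),
            eaf=float(row["eaf"]),
            beta=float(row["beta"]),
            se=float(row["se"]),
            pval=float(row["pval"]),
            n=n_val,
        )
    except (TypeError, ValueError, KeyError) as exc:
        return None, f"unparseable row: {exc}"
    errs = rec.validation_errors()
    if errs:
        return None, "; ".join(errs)
    return rec, None


def read_summary(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    n_default: int | None = None,
    trait_label: str | None = None,
) -> SummaryDataset:
    """Read a delimited-text GWAS summary table into a :class:`SummaryDataset`.

    Parameters
    ----------
    path
        TSV or CSV file (separator auto-detected from the header line);
        ``.gz`` compression accepted.
    column_map
        Mapping from canonical field name (``rsid``, ``chrom``, ``pos``,
        ``ea``, ``oa``, ``eaf``, ``beta``, ``se``, ``pval``, ``n``) to the
        source column header.  Omitted canonical names are assumed to appear
        under their own name; ``n`` may be absent entirely when ``n_default``
        is given.
    n_default
        Sample size used for rows that do not carry their own ``n``.
    trait_label
        Label for the dataset; defaults to the file stem.

    Raises
    ------
    SummaryDataError
        If a mapped column is missing or no row survives validation.

    Notes
    -----
    Rows violating the per-record invariants are dropped, not repaired; the
    dropped count is logged so that kept + dropped always equals the number
    of source data rows.
    """
    path = Path(path)
    sep = _detect_separator(path)
    df = pd.read_csv(path, sep=sep, dtype=str)

    column_map = dict(column_map or {})
    rename: dict[str, str] = {}
    for canon in CANONICAL_FIELDS:
        source = column_map.get(canon, canon)
        if source in df.columns:
            rename[source] = canon
        elif canon in column_map or (canon != "n"):
            # 'n' is the only optional column when unmapped
            if canon == "n" and n_default is not None and "n" not in column_map:
                continue
            raise SummaryDataError(
                f"column {source!r} (for canonical field {canon!r}) not found in {path.name}"
            )
    df = df.rename(columns=rename)

    records: list[SummaryRecord] = []
    dropped = 0
    for _, row in df.iterrows():
        rec, err = _coerce_record(row.to_dict(), n_default)
        if rec is None:
            dropped += 1
            logger.warning("dropping row (%s): %s", err, dict(row))
        else:
            records.append(rec)
    if dropped:
        logger.warning("read_summary(%s): dropped %d of %d rows", path.name, dropped, len(df))
    if not records:
        raise SummaryDataError(f"zero valid rows in {path}")
    return SummaryDataset(
        trait_label=trait_label or path.stem, records=records, n_default=n_default
    )


def write_summary(dataset: SummaryDataset, path: str | Path) -> None:
    """Write a dataset as canonical TSV (lossless to >= 10 significant digits)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(CANONICAL_FIELDS) + "\n")
        for r in dataset.records:
            fh.write(
                "\t".join(
                    [
                        r.rsid,
                        r.chrom,
                        str(r.pos),
                        r.effect_allele,
                        r.other_allele,
                        _FLOAT_FMT.format(r.eaf),
                        _FLOAT_FMT.format(r.beta),
                        _FLOAT_FMT.format(r.se),
                        _FLOAT_FMT.format(r.pval),
                        str(r.n),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Result-table writers
# ---------------------------------------------------------------------------

ESTIMATE_COLUMNS = ["method", "nsnp", "beta", "se", "or", "ci_low", "ci_high", "pval"]
HETEROGENEITY_COLUMNS = ["method", "q", "df", "i2", "q_pval"]
PLEIOTROPY_COLUMNS = ["intercept", "intercept_se", "intercept_pval"]
LOO_COLUMNS = ["excluded_rsid", "nsnp", "beta", "se", "or", "ci_low", "ci_high", "pval"]

_METHOD_LABELS = {
    "ivw": "IVW",
    "egger": "MR Egger",
    "weighted_median": "Weighted median",
    "weighted_mode": "Weighted mode",
    "wald_ratio": "Wald ratio",
}


def method_label(method: str) -> str:
    """Human-readable label for an estimator key (e.g. ``ivw`` -> ``IVW``)."""
    return _METHOD_LABELS.get(method, method)


def _fmt(value: object) -> str:
    if isinstance(value, float):
        return _FLOAT_FMT.format(value)
    return str(value)


def _write_table(path: Path, columns: Sequence[str], rows: Iterable[Sequence[object]]) -> int:
    count = 0
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")
            count += 1
    return count


def write_results(estimates, heterogeneity, pleiotropy, loo, path: str | Path) -> dict[str, Path]:
    """Write the full result bundle under directory ``path``.

    Emits ``estimates.tsv`` (one row per method, shaped like a standard MR
    results table), ``heterogeneity.tsv`` (Cochran's Q rows),
    ``pleiotropy.tsv`` (Egger intercept), ``leave_one_out.tsv``, and a single
    machine-readable ``summary.json`` combining all of them.  Column order is
    fixed by the ``*_COLUMNS`` constants of this module.

    Parameters are the result objects produced by the estimator and
    sensitivity modules; ``heterogeneity``, ``pleiotropy`` and ``loo`` may be
    empty/None, ``estimates`` may not.

    Returns the mapping of logical table name to written path.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("write_results requires at least one estimate")
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    est_rows = [
        [method_label(e.method), e.n_snp, e.beta, e.se, e.or_, e.ci_low, e.ci_high, e.pval]
        for e in estimates
    ]
    written["estimates"] = out / "estimates.tsv"
    _write_table(written["estimates"], ESTIMATE_COLUMNS, est_rows)

    summary: dict[str, object] = {
        "estimates": [
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
            for e in estimates
        ]
    }

    het = list(heterogeneity or [])
    if het:
        written["heterogeneity"] = out / "heterogeneity.tsv"
        _write_table(
            written["heterogeneity"],
            HETEROGENEITY_COLUMNS,
            [[method_label(h.method), h.q, h.df, h.i2, h.pval] for h in het],
        )
        summary["heterogeneity"] = [
            {"method": method_label(h.method), "q": h.q, "df": h.df, "i2": h.i2, "q_pval": h.pval}
            for h in het
        ]

    if pleiotropy is not None:
        written["pleiotropy"] = out / "pleiotropy.tsv"
        _write_table(
            written["pleiotropy"],
            PLEIOTROPY_COLUMNS,
            [[pleiotropy.intercept, pleiotropy.se, pleiotropy.pval]],
        )
        summary["pleiotropy"] = {
            "intercept": pleiotropy.intercept,
            "intercept_se": pleiotropy.se,
            "intercept_pval": pleiotropy.pval,
        }

    if loo is not None and getattr(loo, "entries", None):
        rows = [
            [rsid, e.n_snp, e.beta, e.se, e.or_, e.ci_low, e.ci_high, e.pval]
            for rsid, e in loo.entries
        ]
        f = loo.full
        rows.append(["<none>", f.n_snp, f.beta, f.se, f.or_, f.ci_low, f.ci_high, f.pval])
        written["leave_one_out"] = out / "leave_one_out.tsv"
        _write_table(written["leave_one_out"], LOO_COLUMNS, rows)
        summary["leave_one_out"] = [
            {"excluded_rsid": rsid, "beta": e.beta, "or": e.or_, "pval": e.pval}
            for rsid, e in loo.entries
        ]

    written["summary"] = out / "summary.json"
    with open(written["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return written
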