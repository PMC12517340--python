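"""Reporting-odds-ratio disproportionality screening.

For each (drug, event) pair the database is collapsed into the standard
2x2 contingency table of case counts

    =============  ===========  ==============
    .              event        no event
    drug           a            b
    all others     c            d
    =============  ===========  ==============

and the reporting odds ratio ROR = (a*d)/(b*c) is computed with a Wald
95% confidence interval on the log scale.  A pair is flagged as a safety
signal when the lower confidence bound exceeds 1.  Event selection follows
the two conventions used for the public databases: a minimum report count
(>= 10 by default, the JADER rule) or the top-k most frequent events
(k = 50 by default, the FAERS rule).  An optional Haldane–Anscombe
correction (+0.5 to every cell) keeps the ROR finite in sparse tables and
is applied by the stratified screens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    ContractError,
    EmptyDatabaseError,
    UndefinedCiError,
    UndefinedRorError,
)
from .srs_io import ReportDatabase

__all__ = [
    "ContingencyTable",
    "SignalResult",
    "ScreenConfig",
    "build_contingency",
    "compute_ror",
    "ror_confidence_interval",
    "fisher_exact_p",
    "select_events",
    "screen_drug",
    "results_to_frame",
]

#: standard-normal 97.5% quantile used for the default 95% interval
Z_95 = 1.959964


@dataclass(frozen=True)
class ContingencyTable:
    """The four case counts for one (drug, event) pair.

    ``corrected`` marks the Haldane–Anscombe convention: every cell carries
    an extra 0.5 when the ratio statistics are evaluated, while the stored
    ``a``–``d`` remain the raw integer counts.
    """

    a: int
    b: int
    c: int
    d: int
    corrected: bool = False

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ContractError("contingency cells must be non-negative")

    def cells(self) -> tuple[float, float, float, float]:
        """Cell values as used by the ratio statistics (corrected if requested)."""
        off = 0.5 if self.corrected else 0.0
        return (self.a + off, self.b + off, self.c + off, self.d + off)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def with_correction(self) -> "ContingencyTable":
        return replace(self, corrected=True)


@dataclass(frozen=True)
class SignalResult:
    """ROR screen output for one (drug, event) pair, optionally per stratum."""

    drug_name: str
    pt_term: str
    n_cases: int
    ror: float
    ci_low: float
    ci_high: float
    p_value: float
    signal: bool
    table: ContingencyTable | None = None
    stratum: object = None  # StratumSpec when produced by a stratified screen


@dataclass
class ScreenConfig:
    """Event-selection and correction policy for a screen.

    ``min_count`` mode keeps every event with at least ``min_count`` reports
    for the drug; ``top_k`` keeps the ``k`` most frequent.  ``correction``
    is ``"none"`` for whole-database screens and ``"haldane"`` for
    stratified ones.
    """

    selection_mode: str = "min_count"  # or "top_k"
    min_count: int = 10
    k: int = 50
    correction: str = "none"  # or "haldane"
    ci_level: float = 0.95

    def __post_init__(self):
        if self.selection_mode not in ("min_count", "top_k"):
            raise ConfigurationError(f"unknown selection_mode {self.selection_mode!r}")
        if self.correction not in ("none", "haldane"):
            raise ConfigurationError(f"unknown correction {self.correction!r}")
        if self.min_count < 1 or self.k < 1:
            raise ConfigurationError("min_count and k must be >= 1")


def build_contingency(db: ReportDatabase, drug_name: str, pt_term: str) -> ContingencyTable:
    """Count the 2x2 table for one pair against the whole database.

    The counting unit is the unique case id; a drug absent from the
    database yields ``a = b = 0`` (not an error).
    """
    n = db.n_reports
    if n == 0:
        raise EmptyDatabaseError("cannot build a contingency table on an empty database")
    drug_cases = db.drug_case_ids(drug_name)
    event_cases = db.event_case_ids(pt_term)
    a = len(drug_cases & event_cases)
    b = len(drug_cases) - a
    c = len(event_cases) - a
    d = n - a - b - c
    return ContingencyTable(a=a, b=b, c=c, d=d)


def compute_ror(table: ContingencyTable) -> float:
    """ROR = (a*d)/(b*c) on the (possibly Haldane-corrected) cells."""
    a, b, c, d = table.cells()
    if b == 0 or c == 0:
        raise UndefinedRorError(
            "ROR undefined with a zero off-diagonal cell; rerun with the Haldane "
            "(+0.5) correction to obtain a finite estimate")
    return (a * d) / (b * c)


def ror_confidence_interval(table: ContingencyTable, level: float = 0.95) -> tuple[float, float]:
    """Wald interval on the log-ROR scale: exp(ln ROR -/+ z*sqrt(1/a+1/b+1/c+1/d))."""
    a, b, c, d = table.cells()
    if min(a, b, c, d) == 0:
        raise UndefinedCiError(
            "confidence interval undefined with a zero cell; apply the Haldane correction")
    if not 0 < level < 1:
        raise ConfigurationError("ci level must be in (0, 1)")
    z = Z_95 if level == 0.95 else float(stats.norm.ppf(0.5 + level / 2))
    log_ror = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (math.exp(log_ror - z * se), math.exp(log_ror + z * se))


def fisher_exact_p(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p on the raw integer cells.

    Uses the point-probability convention: the p-value sums the
    hypergeometric probabilities of every table with the observed margins
    whose probability does not exceed the observed table's.
    """
    for cell in (table.a, table.b, table.c, table.d):
        if not float(cell).is_integer():
            raise ContractError("Fisher's exact test applies to raw integer counts only")
    if table.corrected:
        raise ContractError("Fisher's exact test applies to uncorrected counts only")
    p = float(stats.fisher_exact([[table.a, table.b], [table.c, table.d]])[1])
    return min(p, 1.0)


def _drug_event_counts(db: ReportDatabase, drug_name: str) -> pd.Series:
    """Per-PT unique-case counts among the drug's cases, sorted for selection."""
    drug_cases = db.drug_case_ids(drug_name)
    ev = db.events[db.events["case_id"].isin(drug_cases)]
    counts = ev.groupby("pt_term")["case_id"].nunique()
    order = pd.DataFrame({"n": counts})
    order = order.sort_values(["n", "pt_term"], ascending=[False, True], kind="mergesort")
    return order["n"]


def select_events(db: ReportDatabase, drug_name: str, config: ScreenConfig) -> list[str]:
    """Event terms to screen for a drug, in deterministic order.

    ``min_count`` mode returns every PT with at least ``min_count`` reports;
    ``top_k`` returns the ``k`` most frequent.  Order: count descending,
    ties broken lexicographically by PT.
    """
    counts = _drug_event_counts(db, drug_name)
    if config.selection_mode == "min_count":
        counts = counts[counts >= config.min_count]
    else:
        counts = counts.iloc[: config.k]
    return list(counts.index)


def screen_drug(db: ReportDatabase, drug_name: str, config: ScreenConfig,
                events: list[str] | None = None) -> list[SignalResult]:
    """Run the full ROR screen for one drug.

    One :class:`SignalResult` per selected event, sorted by ROR descending
    (ties by PT).  The signal flag is the strict criterion ci_low > 1.
    ``events`` overrides the selection (used by stratified re-screens that
    reuse the whole-database event list).
    """
    if events is None:
        events = select_events(db, drug_name, config)
    results = []
    for pt in events:
        table = build_contingency(db, drug_name, pt)
        p = fisher_exact_p(table)
        if config.correction == "haldane":
            table = table.with_correction()
        ror = compute_ror(table)
        ci_low, ci_high = ror_confidence_interval(table, level=config.ci_level)
        results.append(SignalResult(
            drug_name=drug_name, pt_term=pt, n_cases=table.a, ror=ror,
            ci_low=ci_low, ci_high=ci_high, p_value=p, signal=ci_low > 1.0,
            table=table))
    results.sort(key=lambda r: (-r.ror, r.pt_term))
    return results


def results_to_frame(results: list[SignalResult]) -> pd.DataFrame:
    """Machine CSV layout: full-precision cells alongside the counts."""
    rows = []
    for r in results:
        t = r.table if r.table is not None else ContingencyTable(0, 0, 0, 0)
        row = {
            "drug": r.drug_name, "pt_term": r.pt_term, "n": r.n_cases,
            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "ror": r.ror, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "p_value": r.p_value, "signal": r.signal,
        }
        if r.stratum is not None:
            row["axis"] = r.stratum.axis
            row["level"] = r.stratum.level
        rows.append(row)
    return pd.DataFrame(rows)
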