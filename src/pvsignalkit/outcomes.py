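"""Post-event outcome tabulation for signaled (drug, event) pairs."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .srs_io import ReportDatabase

__all__ = ["OutcomeSummary", "outcome_distribution", "outcomes_to_frame", "KNOWN_OUTCOMES"]

#: outcome levels with an informative value (the fraction denominator)
KNOWN_OUTCOMES = ("recovered", "recovering", "unrecovered", "sequelae", "death", "unknown")


@dataclass
class OutcomeSummary:
    """Outcome fractions for one (drug, event) pair.

    ``fractions`` are over reports with a non-missing outcome
    (``n_with_outcome``); the count with a missing outcome is carried
    separately so both denominators can be reconstructed.
    """

    drug_name: str
    pt_term: str
    n_with_outcome: int
    n_missing: int
    fractions: dict = field(default_factory=dict)

    @property
    def mortality(self) -> float:
        return self.fractions.get("death", 0.0)

    def flag_mortality(self, threshold: float = 0.10) -> bool:
        return self.n_with_outcome > 0 and self.mortality > threshold


def outcome_distribution(db: ReportDatabase, drug_name: str, pt_term: str) -> OutcomeSummary:
    """Tabulate outcomes over the pair's reports.

    The denominator is the number of the pair's reports with a non-missing
    outcome; if every outcome is missing an empty summary is returned with
    a warning.
    """
    drug_cases = db.drug_case_ids(drug_name)
    ev = db.events[(db.events["pt_term"] == pt_term) & db.events["case_id"].isin(drug_cases)]
    counts = ev["outcome"].value_counts()
    n_missing = int(counts.get("missing", 0))
    known = {lvl: int(counts.get(lvl, 0)) for lvl in KNOWN_OUTCOMES}
    n_known = sum(known.values())
    if n_known == 0:
        warnings.warn(f"no outcome-known reports for ({drug_name!r}, {pt_term!r})",
                      stacklevel=2)
        return OutcomeSummary(drug_name, pt_term, 0, n_missing, {lvl: 0.0 for lvl in KNOWN_OUTCOMES})
    fractions = {lvl: known[lvl] / n_known for lvl in KNOWN_OUTCOMES}
    return OutcomeSummary(drug_name, pt_term, n_known, n_missing, fractions)


def outcomes_to_frame(summaries: list[OutcomeSummary], mortality_threshold: float = 0.10) -> pd.DataFrame:
    """Supplementary-table layout: one row per pair, percentage per outcome level."""
    rows = []
    for s in summaries:
        row = {"drug": s.drug_name, "pt_term": s.pt_term,
               "n": s.n_with_outcome, "n_missing_outcome": s.n_missing}
        for lvl in KNOWN_OUTCOMES:
            row[f"pct_{lvl}"] = 100.0 * s.fractions.get(lvl, 0.0)
        row["high_mortality"] = s.flag_mortality(mortality_threshold)
        rows.append(row)
    return pd.DataFrame(rows)
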