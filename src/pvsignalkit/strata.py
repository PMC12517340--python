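"""Demographic stratification of the ROR screen.

Cases are annotated along three axes — sex (male/female), age (<60 vs >=60
years, decided on the decade lower bound of the reported age band: decades
up to 50 count as under 60), and body-mass index (<18.5, 18.5–24.9, >=25
kg/m^2) — and the screen is re-run inside each stratum with the
Haldane–Anscombe +0.5 cell correction, which keeps the ROR defined in the
sparse tables that stratification produces.  Cases with an unknown value on
an axis are excluded from that axis only.

Signaled events are rolled up into six adverse-event categories
(hematological, infection, tumor-related, neurological, skin-related,
other) via an editable YAML term map; unmapped terms fall into "other".
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .disproportionality import ScreenConfig, SignalResult, screen_drug
from .errors import ConfigurationError, InvalidMeasureError
from .srs_io import ReportDatabase

__all__ = [
    "StratumSpec",
    "CategoryMap",
    "STRATA",
    "CATEGORIES",
    "compute_bmi",
    "assign_strata",
    "stratified_screen",
    "categorize_signals",
    "default_category_map",
]

CATEGORIES = ("hematological", "infection", "tumor_related", "neurological", "skin_related", "other")

_LEVELS = {
    "sex": ("male", "female"),
    "age": ("under60", "sixty_plus"),
    "bmi": ("under18_5", "normal_18_5_24_9", "over25"),
}


@dataclass(frozen=True)
class StratumSpec:
    """One level of one stratification axis (e.g. axis="age", level="under60")."""

    axis: str
    level: str

    def __post_init__(self):
        if self.axis not in _LEVELS:
            raise ConfigurationError(f"unknown stratification axis {self.axis!r}")
        if self.level not in _LEVELS[self.axis]:
            raise ConfigurationError(f"level {self.level!r} invalid for axis {self.axis!r}")


#: every stratum, in presentation order
STRATA = tuple(StratumSpec(axis, level) for axis in _LEVELS for level in _LEVELS[axis])


def compute_bmi(height_cm: float | None, weight_kg: float | None) -> float:
    """BMI in kg/m^2 from height (cm) and weight (kg); NaN if either is missing."""
    if height_cm is None or weight_kg is None:
        return float("nan")
    height_cm, weight_kg = float(height_cm), float(weight_kg)
    if np.isnan(height_cm) or np.isnan(weight_kg):
        return float("nan")
    if height_cm <= 0 or weight_kg <= 0:
        raise InvalidMeasureError("height and weight must be positive")
    return weight_kg / (height_cm / 100.0) ** 2


def _bmi_level(bmi: float) -> str | None:
    if np.isnan(bmi):
        return None
    if bmi < 18.5:
        return "under18_5"
    if bmi < 25.0:
        return "normal_18_5_24_9"
    return "over25"


def assign_strata(db: ReportDatabase) -> pd.DataFrame:
    """Per-case stratum levels: columns case_id, sex_level, age_level, bmi_level.

    A level is None when the underlying field is unknown; such cases drop
    out of that axis (only) during stratified screening.
    """
    cases = db.cases
    sex_level = cases["sex"].where(cases["sex"].isin(("male", "female")), None)
    age_level = cases["age_decade"].map(
        lambda d: None if pd.isna(d) else ("under60" if d <= 50 else "sixty_plus"))
    bmi = [compute_bmi(h, w) for h, w in zip(cases["height_cm"], cases["weight_kg"])]
    bmi_level = [_bmi_level(v) for v in bmi]
    return pd.DataFrame({
        "case_id": cases["case_id"],
        "sex_level": sex_level,
        "age_level": age_level,
        "bmi": bmi,
        "bmi_level": bmi_level,
    })


def stratum_case_ids(db: ReportDatabase, stratum: StratumSpec,
                     annotations: pd.DataFrame | None = None) -> set[str]:
    ann = annotations if annotations is not None else assign_strata(db)
    col = f"{stratum.axis}_level"
    return set(ann.loc[ann[col] == stratum.level, "case_id"])


def stratified_screen(db: ReportDatabase, drug_name: str, stratum: StratumSpec,
                      config: ScreenConfig | None = None,
                      events: list[str] | None = None,
                      annotations: pd.DataFrame | None = None) -> list[SignalResult]:
    """Re-run the ROR screen inside one demographic stratum.

    The comparator is the stratum's own background (contingency cells are
    built within the subpopulation) and every cell receives the +0.5
    correction before ROR/CI; reported case counts stay uncorrected.  By
    default the event list is reselected within the stratum; pass ``events``
    to reuse the whole-database selection.
    """
    if config is None:
        config = ScreenConfig(correction="haldane")
    if config.correction != "haldane":
        raise ConfigurationError("stratified screens require the Haldane correction")
    ids = stratum_case_ids(db, stratum, annotations)
    if not ids:
        return []
    sub = db.subset_cases(ids)
    results = screen_drug(sub, drug_name, config, events=events)
    return [replace(r, stratum=stratum) for r in results]


class CategoryMap:
    """Total mapping from preferred terms to the six AE categories."""

    def __init__(self, mapping: dict[str, str]):
        bad = {v for v in mapping.values()} - set(CATEGORIES)
        if bad:
            raise ConfigurationError(f"unknown categories in map: {sorted(bad)}")
        self._map = {k.strip().casefold(): v for k, v in mapping.items()}

    def __getitem__(self, pt_term: str) -> str:
        return self._map.get(pt_term.strip().casefold(), "other")

    @classmethod
    def from_yaml(cls, path) -> "CategoryMap":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})


def default_category_map() -> CategoryMap:
    """The bundled term->category map covering the screened vedotin-ADC events."""
    text = resources.files("pvsignalkit.data").joinpath("category_map.yaml").read_text()
    return CategoryMap(yaml.safe_load(text))


def categorize_signals(results: list[SignalResult], category_map: CategoryMap) -> pd.DataFrame:
    """Count signaled events per (stratum, category).

    Returns the stratum-by-category matrix (rows "axis:level", one column
    per category); only results with ``signal=True`` contribute.
    """
    index = [f"{s.axis}:{s.level}" for s in STRATA]
    counts = pd.DataFrame(0, index=index, columns=list(CATEGORIES))
    for r in results:
        if not r.signal or r.stratum is None:
            continue
        counts.loc[f"{r.stratum.axis}:{r.stratum.level}", category_map[r.pt_term]] += 1
    counts.index.name = "stratum"
    return counts
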