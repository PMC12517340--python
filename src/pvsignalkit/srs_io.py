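"""Readers and the normalized relational view of a spontaneous-report database.

Two CSV dialects are supported, mirroring the public Japanese (JADER) and US
(FAERS) adverse-event report dumps:

* **jader** — four tables: ``demo`` (case demographics), ``drug`` (drug
  mentions with role codes and start dates), ``reac`` (events with onset
  dates and outcomes), ``hist`` (medical history; carried but unused by the
  screens).
* **faers** — ``DEMO``/``DRUG``/``REAC`` mandatory, ``OUTC``/``THER``
  optional; role codes PS/SS/C/I.

Both are normalized into a :class:`ReportDatabase`: three pandas frames
(cases, drug mentions, event mentions) keyed by an opaque ``case_id``, plus a
machine-readable load report counting every dropped row.  The counting unit
throughout the package is the unique case, so exact duplicate mentions are
collapsed at load time.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dates import parse_date
from .errors import ConfigurationError, EmptyDatabaseError, SchemaError

__all__ = [
    "ReportDatabase",
    "load_jader",
    "load_faers",
    "filter_by_role",
    "write_database",
    "JADER_ROLES",
    "FAERS_ROLES",
    "OUTCOME_LEVELS",
]

JADER_ROLES = ("suspect", "concomitant", "interaction")
FAERS_ROLES = ("primary_suspect", "secondary_suspect", "concomitant", "interaction")

#: Closed outcome vocabulary; "missing" means the field was blank.
OUTCOME_LEVELS = ("recovered", "recovering", "unrecovered", "sequelae", "death", "unknown", "missing")

_FAERS_ROLE_MAP = {
    "PS": "primary_suspect",
    "SS": "secondary_suspect",
    "C": "concomitant",
    "I": "interaction",
    "primary_suspect": "primary_suspect",
    "secondary_suspect": "secondary_suspect",
    "concomitant": "concomitant",
    "interaction": "interaction",
}

# FAERS OUTC codes are seriousness codes, not recovery outcomes; only death
# (DE) and disability (DS, mapped to sequelae) translate into the outcome
# vocabulary — the rest are reported as unknown.
_FAERS_OUTC_MAP = {"DE": "death", "DS": "sequelae"}

_JADER_DEMO_COLS = ("case_id", "sex", "age_band", "height_band", "weight_band", "report_quarter")
_JADER_DRUG_COLS = ("case_id", "drug_name", "role", "start_date")
_JADER_REAC_COLS = ("case_id", "pt_term", "onset_date", "outcome")
_FAERS_DEMO_COLS = ("primaryid", "sex", "age", "age_cod", "wt", "wt_cod", "event_dt")
_FAERS_DRUG_COLS = ("primaryid", "drugname", "role_cod")
_FAERS_REAC_COLS = ("primaryid", "pt")


@dataclass
class ReportDatabase:
    """Normalized relational view of a spontaneous-report dump.

    Attributes
    ----------
    cases : pandas.DataFrame
        One row per unique case: ``case_id, sex, age_band, age_decade,
        height_cm, weight_kg, report_quarter``.
    drugs : pandas.DataFrame
        One row per (case, drug, start date) mention:
        ``case_id, drug_name, role, start_date`` (raw date string, may be
        empty).
    events : pandas.DataFrame
        One row per (case, preferred term): ``case_id, pt_term, onset_date,
        outcome``.
    dialect : str
        ``"jader"`` or ``"faers"``.
    load_report : dict
        Rows read/dropped per table with reasons.
    """

    cases: pd.DataFrame
    drugs: pd.DataFrame
    events: pd.DataFrame
    dialect: str
    load_report: dict = field(default_factory=dict)

    @property
    def n_reports(self) -> int:
        return int(self.cases["case_id"].nunique())

    def case_ids(self) -> set[str]:
        return set(self.cases["case_id"])

    def drug_case_ids(self, drug_name: str) -> set[str]:
        """Cases with at least one mention of ``drug_name`` (normalized match)."""
        key = _norm_drug(drug_name)
        mask = self.drugs["drug_name"].map(_norm_drug) == key
        return set(self.drugs.loc[mask, "case_id"])

    def event_case_ids(self, pt_term: str) -> set[str]:
        return set(self.events.loc[self.events["pt_term"] == pt_term, "case_id"])

    def subset_cases(self, keep_ids) -> "ReportDatabase":
        """Restrict the database to a case subpopulation (used by strata)."""
        keep = set(keep_ids)
        return ReportDatabase(
            cases=self.cases[self.cases["case_id"].isin(keep)].reset_index(drop=True),
            drugs=self.drugs[self.drugs["case_id"].isin(keep)].reset_index(drop=True),
            events=self.events[self.events["case_id"].isin(keep)].reset_index(drop=True),
            dialect=self.dialect,
            load_report=self.load_report,
        )

    def relational_content(self) -> tuple:
        """Order-independent multiset view of (cases, drugs, events) for equality checks."""
        def canon(df: pd.DataFrame) -> tuple:
            return tuple(sorted(map(tuple, df.astype(str).values.tolist())))

        return (
            canon(self.cases[["case_id", "sex", "age_band", "report_quarter"]]),
            canon(self.drugs[["case_id", "drug_name", "role", "start_date"]]),
            canon(self.events[["case_id", "pt_term", "onset_date", "outcome"]]),
        )


def _norm_drug(name: object) -> str:
    return str(name).strip().casefold()


def _norm_sex(value: object) -> str:
    s = str(value).strip().casefold()
    if s in ("male", "m", "1"):
        return "male"
    if s in ("female", "f", "2"):
        return "female"
    return "unknown"


_AGE_BAND_RE = re.compile(r"^(\d{1,3})\s*(?:s|'s)?$")
_RANGE_RE = re.compile(r"^(\d+(?:\.\d+)?)\s*[-~〜]\s*(\d+(?:\.\d+)?)")


def _age_decade(value: object) -> float:
    """Decade lower bound from a band like ``"50s"``, ``"50-59"`` or ``"50"``."""
    s = str(value).strip().casefold()
    if not s or s in ("nan", "unknown", "none"):
        return np.nan
    m = _AGE_BAND_RE.match(s)
    if m:
        v = int(m.group(1))
        return float((v // 10) * 10) if v % 10 else float(v)
    m = _RANGE_RE.match(s)
    if m:
        return float((int(float(m.group(1))) // 10) * 10)
    return np.nan


def _measure_value(value: object) -> float:
    """Numeric height/weight, or the midpoint of a band like ``"160-169 cm"``."""
    s = str(value).strip().casefold()
    if not s or s in ("nan", "unknown", "none"):
        return np.nan
    s = re.sub(r"(cm|kg)\s*$", "", s).strip()
    try:
        return float(s)
    except ValueError:
        pass
    m = _RANGE_RE.match(s)
    if m:
        return (float(m.group(1)) + float(m.group(2))) / 2.0
    return np.nan


def _read_csv(path, label: str, required: tuple) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{label} table at {path} lacks mandatory column(s): {', '.join(missing)}")
    return df


def _drop_bad_case_ids(df: pd.DataFrame, col: str) -> tuple[pd.DataFrame, int]:
    ok = df[col].str.strip() != ""
    return df[ok].copy(), int((~ok).sum())


def _onset_sort_key(raw: str) -> str:
    """Deterministic event-dedup priority: full dates first (earliest wins)."""
    p = parse_date(raw)
    if p.is_full:
        return "0" + p.date.isoformat()
    if p.is_partial:
        return "1" + p.raw
    return "2"


def _dedup_events(reac: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    before = len(reac)
    reac = reac.assign(_k=reac["onset_date"].map(_onset_sort_key))
    reac = reac.sort_values(["case_id", "pt_term", "_k"], kind="mergesort")
    reac = reac.drop_duplicates(["case_id", "pt_term"], keep="first").drop(columns="_k")
    return reac.reset_index(drop=True), before - len(reac)


def load_jader(demo_path, drug_path, reac_path, hist_path=None, *, encoding: str = "utf-8") -> ReportDatabase:
    """Load JADER-dialect CSV tables into a :class:`ReportDatabase`.

    Rows with a blank ``case_id`` are dropped and counted; drug/reac rows
    whose case is absent from ``demo`` are dropped as orphans.  When a case
    id repeats in ``demo``, the row with the latest ``report_quarter`` wins.

    ``encoding`` defaults to UTF-8; real JADER dumps use CP932 and can be
    read by passing ``encoding="cp932"``.
    """
    demo = pd.read_csv(demo_path, dtype=str, keep_default_na=False, encoding=encoding)
    missing = [c for c in _JADER_DEMO_COLS if c not in demo.columns]
    if missing:
        raise SchemaError(f"demo table lacks mandatory column(s): {', '.join(missing)}")
    drug = _read_csv(drug_path, "drug", _JADER_DRUG_COLS)
    reac = _read_csv(reac_path, "reac", _JADER_REAC_COLS)
    report: dict = {"dialect": "jader", "rows_read": {"demo": len(demo), "drug": len(drug), "reac": len(reac)},
                    "rows_dropped": {}, "reasons": {}}

    demo, n_bad = _drop_bad_case_ids(demo, "case_id")
    report["reasons"]["demo_missing_case_id"] = n_bad
    if demo.empty:
        raise EmptyDatabaseError("demo table contains no usable case records")

    # Latest-quarter wins on duplicate case ids (stable for ties).
    demo = demo.sort_values(["case_id", "report_quarter"], kind="mergesort")
    n_before = len(demo)
    demo = demo.drop_duplicates("case_id", keep="last")
    report["reasons"]["demo_duplicate_case"] = n_before - len(demo)

    cases = pd.DataFrame({
        "case_id": demo["case_id"].str.strip(),
        "sex": demo["sex"].map(_norm_sex),
        "age_band": demo["age_band"].str.strip(),
        "age_decade": demo["age_band"].map(_age_decade),
        "height_cm": demo["height_band"].map(_measure_value),
        "weight_kg": demo["weight_band"].map(_measure_value),
        "report_quarter": demo["report_quarter"].str.strip(),
    }).sort_values("case_id", kind="mergesort").reset_index(drop=True)
    known = set(cases["case_id"])

    drug, n_bad = _drop_bad_case_ids(drug, "case_id")
    report["reasons"]["drug_missing_case_id"] = n_bad
    orphan = ~drug["case_id"].isin(known)
    report["reasons"]["drug_orphan"] = int(orphan.sum())
    drug = drug[~orphan]
    role_ok = drug["role"].str.strip().str.casefold().isin(JADER_ROLES)
    report["reasons"]["drug_bad_role"] = int((~role_ok).sum())
    drug = drug[role_ok]
    drugs = pd.DataFrame({
        "case_id": drug["case_id"].str.strip(),
        "drug_name": drug["drug_name"].str.strip(),
        "role": drug["role"].str.strip().str.casefold(),
        "start_date": drug["start_date"].str.strip(),
    })
    n_before = len(drugs)
    drugs = drugs.drop_duplicates().sort_values(
        ["case_id", "drug_name", "start_date"], kind="mergesort").reset_index(drop=True)
    report["reasons"]["drug_duplicate_mention"] = n_before - len(drugs)

    reac, n_bad = _drop_bad_case_ids(reac, "case_id")
    report["reasons"]["reac_missing_case_id"] = n_bad
    orphan = ~reac["case_id"].isin(known)
    report["reasons"]["reac_orphan"] = int(orphan.sum())
    reac = reac[orphan == False]  # noqa: E712 — keep non-orphans
    outcome = reac["outcome"].str.strip().str.casefold()
    events = pd.DataFrame({
        "case_id": reac["case_id"].str.strip(),
        "pt_term": reac["pt_term"].str.strip(),
        "onset_date": reac["onset_date"].str.strip(),
        "outcome": outcome.where(outcome.isin(OUTCOME_LEVELS), "missing").where(outcome != "", "missing"),
    })
    nonempty = events["pt_term"] != ""
    report["reasons"]["reac_empty_pt"] = int((~nonempty).sum())
    events, n_dup = _dedup_events(events[nonempty])
    report["reasons"]["reac_duplicate_event"] = n_dup

    report["rows_dropped"] = {k: v for k, v in report["reasons"].items() if v}
    return ReportDatabase(cases=cases, drugs=drugs, events=events, dialect="jader", load_report=report)


def load_faers(table_paths: dict) -> ReportDatabase:
    """Load FAERS-dialect CSV tables (keys ``DEMO``/``DRUG``/``REAC`` mandatory,
    ``OUTC``/``THER`` optional) into a :class:`ReportDatabase`.

    THER start dates are attached case-wide to the case's drug mentions;
    without an OUTC table every outcome is ``missing``.  Duplicate
    ``primaryid`` rows in DEMO keep the last occurrence (latest version).
    """
    paths = {str(k).upper(): v for k, v in table_paths.items()}
    for key in ("DEMO", "DRUG", "REAC"):
        if key not in paths:
            raise SchemaError(f"FAERS table set lacks mandatory table: {key}")
    demo = _read_csv(paths["DEMO"], "DEMO", _FAERS_DEMO_COLS)
    drug = _read_csv(paths["DRUG"], "DRUG", _FAERS_DRUG_COLS)
    reac = _read_csv(paths["REAC"], "REAC", _FAERS_REAC_COLS)
    outc = _read_csv(paths["OUTC"], "OUTC", ("primaryid", "outc_cod")) if "OUTC" in paths else None
    ther = _read_csv(paths["THER"], "THER", ("primaryid", "start_dt")) if "THER" in paths else None
    report: dict = {"dialect": "faers", "rows_read": {"DEMO": len(demo), "DRUG": len(drug), "REAC": len(reac)},
                    "rows_dropped": {}, "reasons": {}}

    demo, n_bad = _drop_bad_case_ids(demo, "primaryid")
    report["reasons"]["demo_missing_case_id"] = n_bad
    if demo.empty:
        raise EmptyDatabaseError("DEMO table contains no usable case records")
    n_before = len(demo)
    demo = demo.drop_duplicates("primaryid", keep="last")
    report["reasons"]["demo_duplicate_case"] = n_before - len(demo)

    age_years = pd.to_numeric(demo["age"], errors="coerce")
    # age_cod DEC means the age is given in decades
    age_years = age_years.where(demo["age_cod"].str.upper() != "DEC", age_years * 10)
    wt = pd.to_numeric(demo["wt"], errors="coerce")
    wt = wt.where(demo["wt_cod"].str.upper() != "LBS", wt * 0.45359237)
    cases = pd.DataFrame({
        "case_id": demo["primaryid"].str.strip(),
        "sex": demo["sex"].map(_norm_sex),
        "age_band": age_years.floordiv(10).mul(10).map(lambda v: "" if pd.isna(v) else f"{int(v)}s"),
        "age_decade": age_years.floordiv(10).mul(10).astype(float),
        "height_cm": np.nan,  # FAERS DEMO carries weight only
        "weight_kg": wt,
        "report_quarter": demo["event_dt"].str.strip(),
    }).sort_values("case_id", kind="mergesort").reset_index(drop=True)
    known = set(cases["case_id"])
    event_dt = dict(zip(demo["primaryid"].str.strip(), demo["event_dt"].str.strip()))

    drug, n_bad = _drop_bad_case_ids(drug, "primaryid")
    report["reasons"]["drug_missing_case_id"] = n_bad
    orphan = ~drug["primaryid"].isin(known)
    report["reasons"]["drug_orphan"] = int(orphan.sum())
    drug = drug[~orphan]
    role = drug["role_cod"].str.strip().map(lambda r: _FAERS_ROLE_MAP.get(r.upper(), _FAERS_ROLE_MAP.get(r.casefold())))
    report["reasons"]["drug_bad_role"] = int(role.isna().sum())
    drugs = pd.DataFrame({
        "case_id": drug["primaryid"].str.strip(),
        "drug_name": drug["drugname"].str.strip(),
        "role": role,
    }).dropna(subset=["role"])
    if ther is not None:
        starts = (ther[ther["primaryid"].isin(known)]
                  .groupby("primaryid")["start_dt"]
                  .apply(lambda s: sorted({x.strip() for x in s if x.strip()})))
        # THER links at case level in this dialect: each start date becomes a
        # row for every drug mention of the case (one row per mention+date).
        drugs = drugs.assign(
            start_date=drugs["case_id"].map(lambda cid: starts.get(cid) or [""]))
        drugs = drugs.explode("start_date", ignore_index=True)
    else:
        drugs["start_date"] = ""
    n_before = len(drugs)
    drugs = drugs.drop_duplicates().sort_values(
        ["case_id", "drug_name", "start_date"], kind="mergesort").reset_index(drop=True)
    report["reasons"]["drug_duplicate_mention"] = n_before - len(drugs)

    reac, n_bad = _drop_bad_case_ids(reac, "primaryid")
    report["reasons"]["reac_missing_case_id"] = n_bad
    orphan = ~reac["primaryid"].isin(known)
    report["reasons"]["reac_orphan"] = int(orphan.sum())
    reac = reac[~orphan]
    if outc is not None:
        out_map = {pid.strip(): _FAERS_OUTC_MAP.get(code.strip().upper(), "unknown")
                   for pid, code in zip(outc["primaryid"], outc["outc_cod"])}
    else:
        out_map = {}
    events = pd.DataFrame({
        "case_id": reac["primaryid"].str.strip(),
        "pt_term": reac["pt"].str.strip(),
    })
    events["onset_date"] = events["case_id"].map(lambda cid: event_dt.get(cid, ""))
    events["outcome"] = events["case_id"].map(lambda cid: out_map.get(cid, "missing"))
    nonempty = events["pt_term"] != ""
    report["reasons"]["reac_empty_pt"] = int((~nonempty).sum())
    events, n_dup = _dedup_events(events[nonempty])
    report["reasons"]["reac_duplicate_event"] = n_dup

    report["rows_dropped"] = {k: v for k, v in report["reasons"].items() if v}
    return ReportDatabase(cases=cases, drugs=drugs, events=events, dialect="faers", load_report=report)


_ROLE_POLICIES = {
    "jader_suspect": {"suspect"},
    "faers_primary_suspect": {"primary_suspect"},
}


def filter_by_role(db: ReportDatabase, policy: str) -> ReportDatabase:
    """Keep only drug mentions whose role matches the extraction policy.

    Cases are never removed: a case that loses all drug mentions stays in
    the comparator background, so ``n_reports`` is invariant.
    """
    if policy not in _ROLE_POLICIES:
        raise ConfigurationError(
            f"unknown role policy {policy!r}; expected one of {sorted(_ROLE_POLICIES)}")
    keep = _ROLE_POLICIES[policy]
    drugs = db.drugs[db.drugs["role"].isin(keep)].reset_index(drop=True)
    return ReportDatabase(cases=db.cases.copy(), drugs=drugs, events=db.events.copy(),
                          dialect=db.dialect, load_report=db.load_report)


def write_database(db: ReportDatabase, out_dir) -> dict:
    """Write a database back to its dialect's CSV files; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if db.dialect == "jader":
        demo = pd.DataFrame({
            "case_id": db.cases["case_id"],
            "sex": db.cases["sex"],
            "age_band": db.cases["age_band"],
            "height_band": db.cases["height_cm"].map(lambda v: "" if pd.isna(v) else f"{v:g}"),
            "weight_band": db.cases["weight_kg"].map(lambda v: "" if pd.isna(v) else f"{v:g}"),
            "report_quarter": db.cases["report_quarter"],
        })
        tables = {
            "demo": demo,
            "drug": db.drugs.rename(columns={})[["case_id", "drug_name", "role", "start_date"]],
            "reac": db.events[["case_id", "pt_term", "onset_date", "outcome"]],
            "hist": pd.DataFrame(columns=["case_id", "condition"]),
        }
    elif db.dialect == "faers":
        demo = pd.DataFrame({
            "primaryid": db.cases["case_id"],
            "sex": db.cases["sex"].map({"male": "M", "female": "F"}).fillna(""),
            "age": db.cases["age_decade"].map(lambda v: "" if pd.isna(v) else f"{int(v)}"),
            "age_cod": db.cases["age_decade"].map(lambda v: "" if pd.isna(v) else "YR"),
            "wt": db.cases["weight_kg"].map(lambda v: "" if pd.isna(v) else f"{v:g}"),
            "wt_cod": db.cases["weight_kg"].map(lambda v: "" if pd.isna(v) else "KG"),
            "event_dt": db.cases["report_quarter"],
        })
        role_back = {"primary_suspect": "PS", "secondary_suspect": "SS", "concomitant": "C", "interaction": "I"}
        tables = {
            "DEMO": demo,
            "DRUG": pd.DataFrame({
                "primaryid": db.drugs["case_id"],
                "drugname": db.drugs["drug_name"],
                "role_cod": db.drugs["role"].map(role_back),
            }),
            "REAC": pd.DataFrame({"primaryid": db.events["case_id"], "pt": db.events["pt_term"]}),
            "THER": db.drugs.loc[db.drugs["start_date"] != "",
                                 ["case_id", "start_date"]].drop_duplicates().rename(
                                     columns={"case_id": "primaryid", "start_date": "start_dt"}),
            "OUTC": pd.DataFrame({
                "primaryid": db.events["case_id"],
                "outc_cod": db.events["outcome"].map(
                    {"death": "DE", "sequelae": "DS", "unknown": "OT"}),
            }).dropna(subset=["outc_cod"]).drop_duplicates(subset=["primaryid"]),
        }
    else:
        raise ConfigurationError(f"unknown dialect {db.dialect!r}")
    for name, frame in tables.items():
        p = out / f"{name}.csv"
        frame.to_csv(p, index=False, lineterminator="\n")
        paths[name] = p
    (out / "load_report.json").write_text(json.dumps(db.load_report, indent=2, sort_keys=True) + "\n")
    return paths
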