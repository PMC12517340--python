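"""Synthetic spontaneous-report databases with known ground truth.

The generator emits JADER- and FAERS-dialect CSV tables whose statistical
structure matches what the screening pipeline assumes: each report draws
one (suspect) drug from a catalog, then each event term independently with
its background probability p0 — except for *injected* (drug, event)
associations, where the event probability among that drug's reports is
raised to the p1 solving

    odds(p1) = true_ror * odds(p0)

so the expected reporting odds ratio of the pair equals the configured
``true_ror`` exactly.  Injections may be restricted to a demographic
stratum (sex/age/BMI level), producing stratum-specific signals.

Onset times are Weibull(alpha, beta) day counts added to a dosing start
date; demographics (sex, age decade, height, weight), outcome mixes and
per-field missingness are configurable.  A ``manifest.json`` records the
full ground truth next to the emitted files.  Generation is deterministic
given the seed.
"""

from __future__ import annotations

import datetime as _dt
import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .srs_io import ReportDatabase, load_jader

__all__ = [
    "Injection",
    "OnsetModel",
    "SimConfig",
    "expected_ror",
    "injected_probability",
    "simulate_frames",
    "simulate_database",
    "generate_database",
    "generate_onsets",
]

_EPOCH = _dt.date(2015, 1, 1)
_WINDOW_DAYS = 2920  # 8-year reporting window


@dataclass(frozen=True)
class Injection:
    """One injected drug–event association with its ground-truth ROR.

    ``stratum`` restricts the excess reporting to one demographic level,
    e.g. ``("sex", "male")``; outside the stratum the pair reports at the
    background rate.
    """

    drug: str
    pt_term: str
    true_ror: float
    stratum: tuple[str, str] | None = None


@dataclass(frozen=True)
class OnsetModel:
    """Weibull time-to-onset ground truth for one pair (days)."""

    alpha: float = 30.0
    beta: float = 1.0


# Background outcome mix typical of serious-AE spontaneous reports.
_DEFAULT_OUTCOME_MIX = {
    "recovered": 0.35, "recovering": 0.15, "unrecovered": 0.20,
    "sequelae": 0.05, "death": 0.10, "unknown": 0.15,
}

# A small vedotin-ADC study catalog over a background of other suspects.
_DEFAULT_DRUGS = [
    ("polatuzumab vedotin", 0.04),
    ("brentuximab vedotin", 0.04),
    ("enfortumab vedotin", 0.03),
    ("vincristine", 0.05),
    ("background drug A", 0.28),
    ("background drug B", 0.28),
    ("background drug C", 0.28),
]

_DEFAULT_EVENTS = [
    ("Peripheral neuropathy", 0.010),
    ("Febrile neutropenia", 0.012),
    ("Myelosuppression", 0.010),
    ("Neutropenia", 0.015),
    ("Thrombocytopenia", 0.012),
    ("Anaemia", 0.015),
    ("Sepsis", 0.008),
    ("Pneumonia", 0.015),
    ("Tumour lysis syndrome", 0.004),
    ("Rash", 0.012),
    ("Pyrexia", 0.015),
    ("Nausea", 0.020),
]


@dataclass
class SimConfig:
    """Full specification of a synthetic report database."""

    n_reports: int = 10_000
    drug_catalog: list = field(default_factory=lambda: list(_DEFAULT_DRUGS))
    event_catalog: list = field(default_factory=lambda: list(_DEFAULT_EVENTS))
    injections: list = field(default_factory=list)
    onset_models: dict = field(default_factory=dict)  # (drug, pt) -> OnsetModel
    default_onset: OnsetModel = field(default_factory=OnsetModel)
    outcome_mix: dict = field(default_factory=lambda: dict(_DEFAULT_OUTCOME_MIX))
    # per-field missing probabilities
    missing_onset: float = 0.15
    missing_start: float = 0.10
    partial_start: float = 0.05
    missing_outcome: float = 0.10
    missing_sex: float = 0.02
    missing_age: float = 0.05
    missing_height: float = 0.30
    missing_weight: float = 0.30
    # demographics
    male_fraction: float = 0.55
    age_decades: list = field(default_factory=lambda: [20, 30, 40, 50, 60, 70, 80])
    age_decade_probs: list = field(default_factory=lambda: [0.05, 0.07, 0.10, 0.16, 0.25, 0.24, 0.13])
    concomitant_rate: float = 0.30
    seed: int = 0

    def __post_init__(self):
        for _, p in list(self.drug_catalog) + list(self.event_catalog):
            if not 0 <= p <= 1:
                raise ConfigurationError("catalog probabilities must be in [0, 1]")
        for inj in self.injections:
            if inj.true_ror <= 0:
                raise ConfigurationError(f"true_ror must be positive for {inj.drug!r}/{inj.pt_term!r}")


def expected_ror(p1: float, p0: float) -> float:
    """Ground-truth ROR implied by event rates p1 (drug) and p0 (background)."""
    if not (0 < p1 < 1 and 0 < p0 < 1):
        raise ConfigurationError("rates must lie strictly inside (0, 1)")
    return (p1 / (1 - p1)) / (p0 / (1 - p0))


def injected_probability(p0: float, true_ror: float) -> float:
    """Solve odds(p1) = true_ror * odds(p0) for p1; must land in (0, 1)."""
    if not 0 < p0 < 1:
        raise ConfigurationError("background rate must lie strictly inside (0, 1)")
    odds1 = true_ror * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    if not 0 < p1 < 1:
        raise ConfigurationError(
            f"injection infeasible: true_ror={true_ror} at p0={p0} gives p1={p1}")
    return p1


def _date_str(d: _dt.date) -> str:
    return d.strftime("%Y%m%d")


def _sample_weibull_days(rng: np.random.Generator, model: OnsetModel, n: int) -> np.ndarray:
    return np.rint(model.alpha * rng.weibull(model.beta, size=n)).astype(int)


def simulate_frames(config: SimConfig) -> dict:
    """Draw a database and return raw JADER/FAERS-dialect frames plus the manifest."""
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    case_ids = np.array([f"C{i + 1:07d}" for i in range(n)])

    drug_names = [d for d, _ in config.drug_catalog]
    drug_probs = np.array([p for _, p in config.drug_catalog], dtype=float)
    drug_probs = drug_probs / drug_probs.sum()
    drug_idx = rng.choice(len(drug_names), size=n, p=drug_probs)

    # demographics (true values; missingness masks applied at emission)
    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")
    decades = rng.choice(np.asarray(config.age_decades), size=n,
                         p=np.asarray(config.age_decade_probs, dtype=float)
                         / np.sum(config.age_decade_probs))
    height = np.where(sex == "male", rng.normal(170.0, 7.0, n), rng.normal(157.0, 6.0, n)).round(1)
    weight = np.where(sex == "male", rng.normal(65.0, 11.0, n), rng.normal(52.0, 9.0, n)).round(1)
    height = np.clip(height, 130.0, 200.0)
    weight = np.clip(weight, 30.0, 130.0)
    bmi = weight / (height / 100.0) ** 2

    def in_stratum(spec: tuple[str, str]) -> np.ndarray:
        axis, level = spec
        if axis == "sex":
            return sex == level
        if axis == "age":
            return decades <= 50 if level == "under60" else decades >= 60
        if axis == "bmi":
            if level == "under18_5":
                return bmi < 18.5
            if level == "normal_18_5_24_9":
                return (bmi >= 18.5) & (bmi < 25.0)
            return bmi >= 25.0
        raise ConfigurationError(f"unknown stratum axis {axis!r}")

    # per-report event probabilities, with injected pairs boosted
    event_names = [e for e, _ in config.event_catalog]
    p0 = {e: p for e, p in config.event_catalog}
    prob = np.tile(np.array([p0[e] for e in event_names]), (n, 1))
    manifest_inj = []
    for inj in config.injections:
        if inj.pt_term not in p0:
            raise ConfigurationError(f"injected event {inj.pt_term!r} not in event catalog")
        if inj.drug not in drug_names:
            raise ConfigurationError(f"injected drug {inj.drug!r} not in drug catalog")
        p1 = injected_probability(p0[inj.pt_term], inj.true_ror)
        mask = drug_idx == drug_names.index(inj.drug)
        if inj.stratum is not None:
            mask = mask & in_stratum(inj.stratum)
        prob[mask, event_names.index(inj.pt_term)] = p1
        manifest_inj.append({"drug": inj.drug, "pt_term": inj.pt_term,
                             "true_ror": inj.true_ror, "p0": p0[inj.pt_term], "p1": p1,
                             "stratum": list(inj.stratum) if inj.stratum else None})
    event_matrix = rng.random((n, len(event_names))) < prob

    # dosing start dates (one per report's suspect mention)
    start_offsets = rng.integers(0, _WINDOW_DAYS, size=n)
    start_dates = np.array([_EPOCH + _dt.timedelta(days=int(o)) for o in start_offsets])
    start_missing = rng.random(n) < config.missing_start
    start_partial = rng.random(n) < config.partial_start

    def start_str(i: int) -> str:
        if start_missing[i]:
            return ""
        if start_partial[i]:
            return start_dates[i].strftime("%Y%m")
        return _date_str(start_dates[i])

    # reac rows: one per (report, drawn event)
    outcome_levels = list(config.outcome_mix)
    outcome_probs = np.array([config.outcome_mix[k] for k in outcome_levels], dtype=float)
    outcome_probs = outcome_probs / outcome_probs.sum()
    reac_rows = []
    rep_idx, ev_idx = np.nonzero(event_matrix)
    delays = np.empty(len(rep_idx), dtype=int)
    # group delay draws by onset model for vectorized sampling
    model_of = [config.onset_models.get((drug_names[drug_idx[i]], event_names[j]),
                                        config.default_onset)
                for i, j in zip(rep_idx, ev_idx)]
    for model in set(model_of):
        sel = np.array([m is model or m == model for m in model_of])
        delays[sel] = _sample_weibull_days(rng, model, int(sel.sum()))
    onset_missing = rng.random(len(rep_idx)) < config.missing_onset
    outcome_missing = rng.random(len(rep_idx)) < config.missing_outcome
    outcome_draw = rng.choice(len(outcome_levels), size=len(rep_idx), p=outcome_probs)
    for k, (i, j) in enumerate(zip(rep_idx, ev_idx)):
        onset = "" if onset_missing[k] else _date_str(start_dates[i] + _dt.timedelta(days=int(delays[k])))
        outcome = "" if outcome_missing[k] else outcome_levels[outcome_draw[k]]
        reac_rows.append((case_ids[i], event_names[j], onset, outcome))

    sex_missing = rng.random(n) < config.missing_sex
    age_missing = rng.random(n) < config.missing_age
    h_missing = rng.random(n) < config.missing_height
    w_missing = rng.random(n) < config.missing_weight

    demo = pd.DataFrame({
        "case_id": case_ids,
        "sex": np.where(sex_missing, "", sex),
        "age_band": ["" if age_missing[i] else f"{int(decades[i])}s" for i in range(n)],
        "height_band": ["" if h_missing[i] else f"{height[i]:g}" for i in range(n)],
        "weight_band": ["" if w_missing[i] else f"{weight[i]:g}" for i in range(n)],
        "report_quarter": [f"{d.year}Q{(d.month - 1) // 3 + 1}" for d in start_dates],
    })

    drug_rows = [(case_ids[i], drug_names[drug_idx[i]], "suspect", start_str(i)) for i in range(n)]
    conco = rng.random(n) < config.concomitant_rate
    conco_pick = rng.choice(len(drug_names), size=n, p=drug_probs)
    for i in np.nonzero(conco)[0]:
        j = conco_pick[i]
        if j != drug_idx[i]:
            drug_rows.append((case_ids[i], drug_names[j], "concomitant", ""))
    drug = pd.DataFrame(drug_rows, columns=["case_id", "drug_name", "role", "start_date"])
    reac = pd.DataFrame(reac_rows, columns=["case_id", "pt_term", "onset_date", "outcome"])
    hist = pd.DataFrame(columns=["case_id", "condition"])

    # FAERS views of the same reports
    faers_demo = pd.DataFrame({
        "primaryid": case_ids,
        "sex": np.where(sex_missing, "", np.where(sex == "male", "M", "F")),
        "age": ["" if age_missing[i] else f"{int(decades[i]) + 5}" for i in range(n)],
        "age_cod": ["" if age_missing[i] else "YR" for i in range(n)],
        "wt": ["" if w_missing[i] else f"{weight[i]:g}" for i in range(n)],
        "wt_cod": ["" if w_missing[i] else "KG" for i in range(n)],
        "event_dt": "",
    })
    first_onset = reac[reac["onset_date"] != ""].groupby("case_id")["onset_date"].min()
    faers_demo["event_dt"] = faers_demo["primaryid"].map(first_onset).fillna("")
    role_map = {"suspect": "PS", "concomitant": "C", "interaction": "I"}
    faers_drug = pd.DataFrame({
        "primaryid": drug["case_id"], "drugname": drug["drug_name"],
        "role_cod": drug["role"].map(role_map),
    })
    faers_reac = pd.DataFrame({"primaryid": reac["case_id"], "pt": reac["pt_term"]})
    faers_ther = drug.loc[drug["start_date"] != "", ["case_id", "start_date"]].rename(
        columns={"case_id": "primaryid", "start_date": "start_dt"})
    outc_map = {"death": "DE", "sequelae": "DS"}
    first_outcome = (reac[reac["outcome"] != ""].groupby("case_id")["outcome"].first())
    faers_outc = pd.DataFrame({
        "primaryid": first_outcome.index,
        "outc_cod": first_outcome.map(lambda o: outc_map.get(o, "OT")).values,
    })

    manifest = {
        "seed": config.seed,
        "n_reports": n,
        "drug_catalog": [[d, float(p)] for d, p in config.drug_catalog],
        "event_catalog": [[e, float(p)] for e, p in config.event_catalog],
        "injections": manifest_inj,
        "onset_models": [
            {"drug": d, "pt_term": e, "alpha": m.alpha, "beta": m.beta}
            for (d, e), m in sorted(config.onset_models.items())],
        "default_onset": asdict(config.default_onset),
        "outcome_mix": config.outcome_mix,
    }
    return {
        "jader": {"demo": demo, "drug": drug, "reac": reac, "hist": hist},
        "faers": {"DEMO": faers_demo, "DRUG": faers_drug, "REAC": faers_reac,
                  "THER": faers_ther, "OUTC": faers_outc},
        "manifest": manifest,
    }


def simulate_database(config: SimConfig) -> ReportDatabase:
    """Draw a database and return it loaded through the JADER reader."""
    frames = simulate_frames(config)["jader"]
    bufs = {name: io.StringIO(df.to_csv(index=False, lineterminator="\n"))
            for name, df in frames.items()}
    return load_jader(bufs["demo"], bufs["drug"], bufs["reac"], bufs["hist"])


def generate_database(config: SimConfig, out_dir) -> dict:
    """Write both dialect file sets plus ``manifest.json``; returns path map.

    Deterministic given ``config.seed``: the same config written twice
    yields byte-identical files.
    """
    out = Path(out_dir)
    frames = simulate_frames(config)
    paths: dict[str, Path] = {}
    for dialect in ("jader", "faers"):
        d = out / dialect
        d.mkdir(parents=True, exist_ok=True)
        for name, df in frames[dialect].items():
            p = d / f"{name}.csv"
            df.to_csv(p, index=False, lineterminator="\n")
            paths[f"{dialect}/{name}"] = p
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(frames["manifest"], indent=2, sort_keys=True) + "\n")
    paths["manifest"] = mpath
    return paths


def generate_onsets(config: SimConfig, pair: tuple[str, str], n: int,
                    partial_fraction: float = 0.0) -> list[tuple[str, str]]:
    """Dated (start, onset) string pairs drawn from the pair's onset model.

    Onset = start + rounded Weibull(alpha, beta) days; a ``partial_fraction``
    of start dates is truncated to year-month (excluded downstream as
    partial).  Dates use the JADER compact format.
    """
    rng = np.random.default_rng(config.seed)
    model = config.onset_models.get(pair, config.default_onset)
    out = []
    if n == 0:
        return out
    offsets = rng.integers(0, _WINDOW_DAYS, size=n)
    delays = _sample_weibull_days(rng, model, n)
    partial = rng.random(n) < partial_fraction
    for i in range(n):
        start = _EPOCH + _dt.timedelta(days=int(offsets[i]))
        onset = start + _dt.timedelta(days=int(delays[i]))
        s = start.strftime("%Y%m") if partial[i] else _date_str(start)
        out.append((s, _date_str(onset)))
    return out
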