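"""Config-driven end-to-end analysis: load → role-filter → screen →
stratify → outcomes → time-to-onset → volcano → consolidated summary.

The YAML config names either dialect input files or a synthetic scenario,
the drugs of interest, and per-stage options; every stage writes its
machine CSV into the output directory and the run closes with a
``summary.json`` (per-drug signal counts, stratum-by-category matrix,
hazard classifications) plus a ``run.log``.  Outputs are deterministic for
a fixed config and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .disproportionality import ScreenConfig, results_to_frame, screen_drug
from .errors import ConfigurationError
from .outcomes import outcome_distribution, outcomes_to_frame
from .srs_io import filter_by_role, load_faers, load_jader
from .strata import (CategoryMap, STRATA, assign_strata, categorize_signals,
                     default_category_map, stratified_screen)
from .synthetic_srs import Injection, OnsetModel, SimConfig, generate_database
from .tto import classify_hazard, collect_onsets, fit_weibull, tto_summary
from .volcano import render_volcano, volcano_frame, volcano_table

__all__ = ["run_pipeline", "sim_config_from_dict"]


def sim_config_from_dict(spec: dict) -> SimConfig:
    """Build a :class:`SimConfig` from the YAML ``synthetic`` section."""
    kwargs = dict(spec)
    kwargs["injections"] = [
        Injection(drug=i["drug"], pt_term=i["pt_term"], true_ror=float(i["true_ror"]),
                  stratum=tuple(i["stratum"]) if i.get("stratum") else None)
        for i in kwargs.pop("injections", [])]
    kwargs["onset_models"] = {
        (m["drug"], m["pt_term"]): OnsetModel(alpha=float(m["alpha"]), beta=float(m["beta"]))
        for m in kwargs.pop("onset_models", [])}
    if "default_onset" in kwargs:
        kwargs["default_onset"] = OnsetModel(**kwargs["default_onset"])
    return SimConfig(**kwargs)


def _load_input(cfg: dict, out: Path):
    src = cfg.get("input", {})
    if "synthetic" in src:
        sim = sim_config_from_dict(src["synthetic"])
        paths = generate_database(sim, out / "synthetic")
        db = load_jader(paths["jader/demo"], paths["jader/drug"],
                        paths["jader/reac"], paths["jader/hist"])
        return db, "jader_suspect"
    if "jader" in src:
        t = src["jader"]
        db = load_jader(t["demo"], t["drug"], t["reac"], t.get("hist"),
                        encoding=t.get("encoding", "utf-8"))
        return db, "jader_suspect"
    if "faers" in src:
        return load_faers(src["faers"]), "faers_primary_suspect"
    raise ConfigurationError("config.input must name 'synthetic', 'jader' or 'faers'")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def run_pipeline(config_path, out_dir=None) -> Path:
    """Run the full analysis described by a YAML config; returns the output dir."""
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    out = Path(out_dir or cfg.get("out_dir", "pvsignal_output"))
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"pvsignalkit {__version__}", f"config: {json.dumps(cfg, sort_keys=True)}"]

    db, policy = _load_input(cfg, out)
    db = filter_by_role(db, cfg.get("role_policy", policy))
    log.append(f"loaded {db.n_reports} reports ({db.dialect}); role policy {policy}")
    (out / "load_report.json").write_text(
        json.dumps(db.load_report, indent=2, sort_keys=True) + "\n")

    screen_cfg = ScreenConfig(**cfg.get("screen", {}))
    drugs = cfg.get("drugs") or []
    if not drugs:
        raise ConfigurationError("config must list at least one drug under 'drugs'")

    cat_map = (CategoryMap.from_yaml(cfg["category_map"])
               if cfg.get("category_map") else default_category_map())
    summary: dict = {"n_reports": db.n_reports, "dialect": db.dialect, "drugs": {}}
    annotations = assign_strata(db)
    all_screens, all_strat, all_outcomes, all_fits, all_tto = [], [], [], [], []

    for drug in drugs:
        results = screen_drug(db, drug, screen_cfg)
        frame = results_to_frame(results)
        all_screens.append(frame)
        signaled = [r for r in results if r.signal]
        if not signaled:
            log.append(f"warning: no signals for {drug!r} "
                       f"(screened {len(results)} events)")
        drug_summary = {"screened_events": len(results),
                        "signals": len(signaled),
                        "signaled_terms": sorted(r.pt_term for r in signaled)}

        if results and cfg.get("volcano", True):
            points = volcano_table(results)
            _write_csv(volcano_frame(points), out / f"volcano_{_slug(drug)}.csv")
            render_volcano(points, out / f"volcano_{_slug(drug)}.png", title=drug)

        for r in signaled:
            all_outcomes.append(outcome_distribution(db, drug, r.pt_term))

        if cfg.get("stratify", True):
            strat_results = []
            parent_events = [r.pt_term for r in results]
            for stratum in STRATA:
                strat_results.extend(stratified_screen(
                    db, drug, stratum, events=parent_events, annotations=annotations))
            all_strat.append(results_to_frame(strat_results))
            matrix = categorize_signals(strat_results, cat_map)
            matrix.to_csv(out / f"strata_categories_{_slug(drug)}.csv", lineterminator="\n")
            drug_summary["stratified_signals"] = int(matrix.values.sum())

        if cfg.get("tto", True):
            tto_floor = int(cfg.get("tto_min_n", 10))
            hazards = {}
            for r in signaled:
                records = collect_onsets(db, drug, r.pt_term)
                all_tto.extend(records)
                usable = [rec.onset_days for rec in records if rec.usable]
                if len(usable) >= tto_floor:
                    fit = fit_weibull(usable, min_n=tto_floor)
                    s = tto_summary(usable)
                    hazards[r.pt_term] = classify_hazard(fit)
                    all_fits.append({
                        "drug": drug, "pt_term": r.pt_term, "n": fit.n_used,
                        "alpha": fit.alpha, "alpha_lo": fit.alpha_ci[0], "alpha_hi": fit.alpha_ci[1],
                        "beta": fit.beta, "beta_lo": fit.beta_ci[0], "beta_hi": fit.beta_ci[1],
                        "hazard_type": classify_hazard(fit),
                        "median_days": s["median"], "q1": s["q1"], "q3": s["q3"],
                    })
            drug_summary["hazard_types"] = hazards
        summary["drugs"][drug] = drug_summary

    if all_screens:
        _write_csv(pd.concat(all_screens, ignore_index=True), out / "screen.csv")
    if all_strat:
        _write_csv(pd.concat(all_strat, ignore_index=True), out / "stratified.csv")
    if all_outcomes:
        _write_csv(outcomes_to_frame(all_outcomes), out / "outcomes.csv")
    if all_fits:
        _write_csv(pd.DataFrame(all_fits), out / "weibull_fits.csv")
    if all_tto:
        _write_csv(pd.DataFrame([{
            "case_id": r.case_id, "drug": r.drug_name, "pt_term": r.pt_term,
            "onset_days": "" if r.onset_days is None else r.onset_days,
            "excluded_reason": r.excluded_reason or "",
        } for r in all_tto]), out / "tto.csv")

    # Screens apply no multiplicity adjustment across events, matching
    # standard disproportionality practice; flag it for readers.
    log.append("note: no multiple-testing adjustment is applied across screened events")
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (out / "run.log").write_text("\n".join(log) + "\n")
    return out


def _slug(name: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in name.strip().casefold())
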