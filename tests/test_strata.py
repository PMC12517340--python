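"""BMI/age/sex annotation, stratified re-screening, category roll-up."""

from __future__ import annotations

import numpy as np
import pytest

from pvsignalkit.disproportionality import ScreenConfig, SignalResult
from pvsignalkit.errors import ConfigurationError, InvalidMeasureError
from pvsignalkit.strata import (
    CATEGORIES,
    STRATA,
    StratumSpec,
    assign_strata,
    categorize_signals,
    compute_bmi,
    default_category_map,
    stratified_screen,
    stratum_case_ids,
)
from pvsignalkit.synthetic_srs import Injection, SimConfig, simulate_database


class TestBmi:
    def test_direct_arithmetic(self):
        assert compute_bmi(160, 64) == pytest.approx(25.0)
        assert compute_bmi(170, 53.5) == pytest.approx(53.5 / 1.7**2)

    def test_missing_input_gives_nan(self):
        assert np.isnan(compute_bmi(float("nan"), 60))
        assert np.isnan(compute_bmi(None, 60))

    def test_nonpositive_measures_rejected(self):
        with pytest.raises(InvalidMeasureError):
            compute_bmi(0, 60)
        with pytest.raises(InvalidMeasureError):
            compute_bmi(170, -1)


class TestAssignStrata:
    def test_age_band_cut_at_sixty(self, four_case_db):
        ann = assign_strata(four_case_db).set_index("case_id")
        assert ann.loc["case1", "age_level"] == "under60"   # 50s
        assert ann.loc["case2", "age_level"] == "sixty_plus"  # 60s

    def test_bmi_bin_boundaries(self, four_case_db):
        from pvsignalkit.strata import _bmi_level

        # bin edges on exact values: [18.5, 25.0) is the normal band
        assert _bmi_level(25.0) == "over25"
        assert _bmi_level(24.9) == "normal_18_5_24_9"
        assert _bmi_level(18.5) == "normal_18_5_24_9"
        assert _bmi_level(18.49) == "under18_5"
        ann = assign_strata(four_case_db).set_index("case_id")
        assert ann.loc["case1", "bmi_level"] == "over25"            # ~25.1
        assert ann.loc["case4", "bmi_level"] == "under18_5"         # ~18.49

    def test_axes_partition_known_cases(self):
        db = simulate_database(SimConfig(n_reports=500, seed=21))
        ann = assign_strata(db)
        for axis in ("sex", "age", "bmi"):
            ids = [stratum_case_ids(db, s, ann) for s in STRATA if s.axis == axis]
            union = set().union(*ids)
            assert sum(len(s) for s in ids) == len(union)  # disjoint
            known = ann[ann[f"{axis}_level"].notna()]
            assert union == set(known["case_id"])

    def test_invalid_stratum_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            StratumSpec("sex", "under60")


class TestStratifiedScreen:
    def test_haldane_example_on_sparse_table(self):
        # (0,10,10,100) + 0.5 => (0.5*100.5)/(10.5*10.5)
        from pvsignalkit.disproportionality import ContingencyTable, compute_ror

        ror = compute_ror(ContingencyTable(0, 10, 10, 100).with_correction())
        assert ror == pytest.approx((0.5 * 100.5) / (10.5 * 10.5), rel=1e-12)
        assert ror == pytest.approx(0.4558, abs=5e-4)

    def test_cells_built_within_stratum_with_correction(self, four_case_db):
        res = stratified_screen(four_case_db, "X", StratumSpec("sex", "male"),
                                ScreenConfig(min_count=1, correction="haldane"))
        (r,) = [x for x in res if x.pt_term == "PN"]
        # males = case1 (X, PN), case2 (X): raw cells (1,1,0,0), +0.5 applied
        assert (r.table.a, r.table.b, r.table.c, r.table.d) == (1, 1, 0, 0)
        assert r.table.corrected
        assert r.ror == pytest.approx((1.5 * 0.5) / (1.5 * 0.5), rel=1e-12)
        assert r.n_cases == 1  # reported uncorrected

    def test_requires_haldane_correction(self, four_case_db):
        with pytest.raises(ConfigurationError):
            stratified_screen(four_case_db, "X", StratumSpec("sex", "male"),
                              ScreenConfig(correction="none"))

    def test_sex_restricted_injection_recovered_in_right_stratum(self):
        cfg = SimConfig(
            n_reports=20_000, seed=13,
            injections=[Injection("polatuzumab vedotin", "Peripheral neuropathy",
                                  10.0, stratum=("sex", "male"))])
        db = simulate_database(cfg)
        male = stratified_screen(db, "polatuzumab vedotin", StratumSpec("sex", "male"),
                                 ScreenConfig(min_count=5, correction="haldane"))
        female = stratified_screen(db, "polatuzumab vedotin", StratumSpec("sex", "female"),
                                   ScreenConfig(min_count=5, correction="haldane"))
        male_pn = [r for r in male if r.pt_term == "Peripheral neuropathy"]
        assert male_pn and male_pn[0].signal
        female_pn = [r for r in female if r.pt_term == "Peripheral neuropathy"]
        assert not any(r.signal for r in female_pn)

    def test_haldane_shrinks_extreme_log_ror_toward_zero(self):
        from pvsignalkit.disproportionality import ContingencyTable, compute_ror

        rng = np.random.default_rng(0)
        for _ in range(100):
            b, c = sorted(rng.integers(1, 20, size=2))
            a, d = rng.integers(c, c + 50, size=2)  # min(a,d) >= max(b,c)
            raw = np.log(compute_ror(ContingencyTable(int(a), int(b), int(c), int(d))))
            cor = np.log(compute_ror(
                ContingencyTable(int(a), int(b), int(c), int(d)).with_correction()))
            assert abs(cor) <= abs(raw) + 1e-12


class TestCategorize:
    def _result(self, pt, signal, stratum):
        return SignalResult(drug_name="X", pt_term=pt, n_cases=5, ror=2.0,
                            ci_low=1.5 if signal else 0.5, ci_high=3.0,
                            p_value=0.01, signal=signal, stratum=stratum)

    def test_zero_signals_gives_zero_matrix(self):
        matrix = categorize_signals([], default_category_map())
        assert matrix.values.sum() == 0
        assert list(matrix.columns) == list(CATEGORIES)

    def test_counts_by_category(self):
        s = StratumSpec("sex", "male")
        cmap = default_category_map()
        results = [self._result("Neutropenia", True, s),
                   self._result("Anaemia", True, s),
                   self._result("Rash", True, s),
                   self._result("Sepsis", False, s)]  # not a signal: ignored
        matrix = categorize_signals(results, cmap)
        row = matrix.loc["sex:male"]
        assert row["hematological"] == 2
        assert row["skin_related"] == 1
        assert row.sum() == 3

    def test_matches_brute_force_group_by(self):
        rng = np.random.default_rng(5)
        cmap = default_category_map()
        pts = ["Neutropenia", "Sepsis", "Rash", "Peripheral neuropathy", "Unmapped term"]
        results, expected = [], {}
        for i in range(20):
            s = STRATA[rng.integers(len(STRATA))]
            pt = pts[rng.integers(len(pts))]
            signal = bool(rng.integers(2))
            results.append(self._result(pt, signal, s))
            if signal:
                key = (f"{s.axis}:{s.level}", cmap[pt])
                expected[key] = expected.get(key, 0) + 1
        matrix = categorize_signals(results, cmap)
        for (stratum, cat), n in expected.items():
            assert matrix.loc[stratum, cat] == n
        assert matrix.values.sum() == sum(expected.values())

    def test_unmapped_terms_fall_into_other(self):
        assert default_category_map()["Completely novel PT"] == "other"
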