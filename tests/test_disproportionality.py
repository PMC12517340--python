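"""Contingency construction, ROR/CI/Fisher statistics, and the screen."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from pvsignalkit.disproportionality import (
    ContingencyTable,
    ScreenConfig,
    build_contingency,
    compute_ror,
    fisher_exact_p,
    ror_confidence_interval,
    screen_drug,
    select_events,
)
from pvsignalkit.errors import ContractError, EmptyDatabaseError, UndefinedCiError, UndefinedRorError
from pvsignalkit.reference import load_reference_signals
from pvsignalkit.srs_io import filter_by_role
from pvsignalkit.synthetic_srs import Injection, SimConfig, simulate_database

Z = 1.959964


class TestBuildContingency:
    def test_hand_countable_four_case_fixture(self, four_case_db):
        t = build_contingency(four_case_db, "X", "PN")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)
        assert not t.corrected

    def test_cells_match_brute_force_on_synthetic(self, synthetic_db_seed11):
        db = synthetic_db_seed11
        for drug, pt in [("polatuzumab vedotin", "Peripheral neuropathy"),
                         ("vincristine", "Sepsis"),
                         ("background drug A", "Nausea")]:
            t = build_contingency(db, drug, pt)
            assert (t.a, t.b, t.c, t.d) == oracles.brute_force_cells(db, drug, pt)
            assert t.n == db.n_reports

    def test_absent_drug_gives_zero_drug_margin(self, four_case_db):
        t = build_contingency(four_case_db, "no such drug", "PN")
        assert (t.a, t.b) == (0, 0)
        assert t.c == 2  # total PN reports
        assert t.n == four_case_db.n_reports

    def test_empty_database_is_error(self, four_case_db):
        empty = four_case_db.subset_cases([])
        with pytest.raises(EmptyDatabaseError):
            build_contingency(empty, "X", "PN")


class TestRorAndCi:
    def test_symmetric_table_gives_unity(self):
        assert compute_ror(ContingencyTable(10, 10, 10, 10)) == 1.0

    def test_direct_formula_example(self):
        assert compute_ror(ContingencyTable(5, 5, 5, 45)) == pytest.approx(9.0, abs=1e-12)

    def test_zero_off_diagonal_requires_correction(self):
        with pytest.raises(UndefinedRorError):
            compute_ror(ContingencyTable(5, 0, 3, 10))
        assert math.isfinite(compute_ror(ContingencyTable(5, 0, 3, 10).with_correction()))

    def test_ci_symmetric_about_one_in_log_space(self):
        lo, hi = ror_confidence_interval(ContingencyTable(10, 10, 10, 10))
        assert lo * hi == pytest.approx(1.0, abs=1e-9)

    def test_ci_matches_direct_evaluation(self):
        lo, hi = ror_confidence_interval(ContingencyTable(5, 5, 5, 45))
        exp_lo = math.exp(math.log(9.0) - Z * math.sqrt(1 / 5 + 1 / 5 + 1 / 5 + 1 / 45))
        assert lo == pytest.approx(exp_lo, rel=1e-12)
        assert lo < 9.0 < hi

    def test_interval_widens_with_level(self):
        t = ContingencyTable(8, 4, 6, 30)
        widths = []
        for level in (0.80, 0.90, 0.95, 0.99):
            lo, hi = ror_confidence_interval(t, level=level)
            widths.append(math.log(hi) - math.log(lo))
        assert widths == sorted(widths)

    def test_zero_cell_ci_requires_correction(self):
        with pytest.raises(UndefinedCiError):
            ror_confidence_interval(ContingencyTable(0, 5, 5, 5))

    @given(st.tuples(*[st.integers(1, 300)] * 4))
    @settings(max_examples=200, deadline=None)
    def test_inversion_property(self, cells):
        a, b, c, d = cells
        prod = compute_ror(ContingencyTable(a, b, c, d)) * compute_ror(ContingencyTable(b, a, d, c))
        assert prod == pytest.approx(1.0, rel=1e-12)


class TestFisherExact:
    @pytest.mark.parametrize("cells,expected", [
        ((1, 1, 1, 1), 1.0),            # enumeration over a in {0,1,2}: 1/6+4/6+1/6
        ((3, 1, 1, 3), 34 / 70),        # enumeration over a in {0..4}, C(8,4)=70
        ((5, 0, 0, 5), 2 / 252),        # two extreme tables, each 1/252
    ])
    def test_frozen_enumeration_examples(self, cells, expected):
        assert fisher_exact_p(ContingencyTable(*cells)) == pytest.approx(expected, rel=1e-9)

    def test_corrected_table_rejected(self):
        with pytest.raises(ContractError):
            fisher_exact_p(ContingencyTable(1, 1, 1, 1).with_correction())

    @given(st.tuples(*[st.integers(0, 15)] * 4).filter(lambda t: 0 < sum(t) <= 60))
    @settings(max_examples=300, deadline=None)
    def test_matches_exhaustive_enumeration_small_tables(self, cells):
        a, b, c, d = cells
        p_impl = fisher_exact_p(ContingencyTable(a, b, c, d))
        p_oracle = oracles.exhaustive_fisher_p(a, b, c, d)
        assert p_impl == pytest.approx(p_oracle, rel=1e-7, abs=1e-12)

    @given(st.tuples(*[st.integers(1, 40)] * 4))
    @settings(max_examples=100, deadline=None)
    def test_transpose_invariance(self, cells):
        a, b, c, d = cells
        t1, t2 = ContingencyTable(a, b, c, d), ContingencyTable(a, c, b, d)
        assert fisher_exact_p(t1) == pytest.approx(fisher_exact_p(t2), rel=1e-9)
        assert compute_ror(t1) == pytest.approx(compute_ror(t2), rel=1e-12)


class TestSelection:
    def test_min_count_boundary(self):
        db = _db_with_event_count(9)
        assert select_events(db, "X", ScreenConfig(min_count=10)) == []
        db = _db_with_event_count(10)
        assert select_events(db, "X", ScreenConfig(min_count=10)) == ["PN"]

    def test_top_k_matches_brute_force_rank(self, synthetic_db_seed11):
        db = synthetic_db_seed11
        cfg = ScreenConfig(selection_mode="top_k", k=5)
        got = select_events(db, "polatuzumab vedotin", cfg)
        expected = [pt for pt, _ in oracles.event_frequency_rank(db, "polatuzumab vedotin")[:5]]
        assert got == expected


class TestScreen:
    def test_reference_rows_reflagged_by_strict_criterion(self):
        from pvsignalkit.reference import signal_counts

        table = load_reference_signals("jader")
        counts = signal_counts(table)
        assert counts == {"polatuzumab vedotin": 25, "brentuximab vedotin": 19,
                          "enfortumab vedotin": 24}
        # a boundary row with ci_low exactly 1.00 must NOT signal
        boundary = table.iloc[:1].assign(drug="Z", ci_low=1.00)
        import pandas as pd

        assert "Z" not in signal_counts(pd.concat([table, boundary]))

    def test_injected_association_is_flagged(self, synthetic_db_seed11):
        db = filter_by_role(synthetic_db_seed11, "jader_suspect")
        results = screen_drug(db, "polatuzumab vedotin", ScreenConfig(min_count=10))
        flagged = {r.pt_term for r in results if r.signal}
        assert "Peripheral neuropathy" in flagged

    def test_results_sorted_by_ror_and_signal_consistent(self, synthetic_db_seed11):
        db = filter_by_role(synthetic_db_seed11, "jader_suspect")
        results = screen_drug(db, "vincristine", ScreenConfig(min_count=5))
        rors = [r.ror for r in results]
        assert rors == sorted(rors, reverse=True)
        for r in results:
            assert r.signal == (r.ci_low > 1.0)
            assert r.ci_low <= r.ror <= r.ci_high
            t = r.table
            assert t.a + t.b + t.c + t.d == db.n_reports


def _db_with_event_count(k: int):
    from conftest import jader_db_from_rows

    n = k + 5
    demo = [(f"c{i}", "male", "50s", "", "", "q") for i in range(n)]
    drugs = [(f"c{i}", "X", "suspect", "") for i in range(n)]
    reacs = [(f"c{i}", "PN", "", "") for i in range(k)]
    return jader_db_from_rows(demo, drugs, reacs)
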