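"""GMT parsing, hypergeometric/EASE p-values, BH adjustment, enrichment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppihub import simulate
from ppihub.enrichment import (
    GeneSetCollection,
    bh_adjust,
    enrich,
    parse_gmt,
    set_pvalue,
    write_gmt,
)

import oracles


class TestParseGmt:
    def test_basic_line_with_class_label(self, tmp_path):
        f = tmp_path / "c.gmt"
        f.write_text("S1\tCancer\tA\tB\tC\n")
        col = parse_gmt(f)
        assert col.sets == {"S1": {"A", "B", "C"}}
        assert col.classes == {"S1": "Cancer"}

    def test_dot_description_means_unclassified(self, tmp_path):
        f = tmp_path / "c.gmt"
        f.write_text("S1\t.\tA\tB\n")
        col = parse_gmt(f)
        assert "S1" not in col.classes
        assert col.class_sets() == {"unclassified": {"A", "B"}}

    def test_duplicate_name_rejected(self, tmp_path):
        f = tmp_path / "c.gmt"
        f.write_text("S1\t.\tA\nS1\t.\tB\n")
        with pytest.raises(ValueError, match="duplicate"):
            parse_gmt(f)

    def test_empty_set_skipped_with_warning(self, tmp_path, caplog):
        f = tmp_path / "c.gmt"
        f.write_text("S2\t.\t\nS3\t.\tA\n")
        col = parse_gmt(f)
        assert set(col.sets) == {"S3"}

    def test_round_trip(self, tmp_path):
        col = GeneSetCollection(
            sets={"S1": {"A", "B"}, "S2": {"C"}}, classes={"S1": "Cardio"}
        )
        path = write_gmt(col, tmp_path / "out.gmt")
        back = parse_gmt(path)
        assert back.sets == col.sets
        assert back.classes == col.classes


class TestSetPvalue:
    def test_perfect_overlap_hypergeometric(self):
        # P(X >= 5) with all margins 5 of 20 = 1 / C(20, 5)
        assert set_pvalue(5, 5, 5, 20, "hypergeometric") == pytest.approx(
            1 / 15504, rel=1e-12
        )

    def test_perfect_overlap_ease(self):
        # tail re-computed from k - 1 = 4: (C(5,4) C(15,1) + 1) / C(20,5)
        assert set_pvalue(5, 5, 5, 20, "ease") == pytest.approx(
            76 / 15504, rel=1e-12
        )

    def test_zero_overlap_is_one(self):
        assert set_pvalue(0, 5, 5, 20, "hypergeometric") == 1.0
        assert set_pvalue(0, 5, 5, 20, "ease") == 1.0
        assert set_pvalue(1, 5, 5, 20, "ease") == 1.0  # floor at k - 1 = 0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            set_pvalue(6, 5, 5, 20)
        with pytest.raises(ValueError):
            set_pvalue(2, 25, 5, 20)

    def test_matches_combinatorial_oracle_exhaustively(self):
        """Exact agreement with direct pmf summation on every consistent
        table with universe size up to 16."""
        for N in (5, 9, 16):
            for K in range(1, N + 1):
                for n in range(1, N + 1):
                    for k in range(0, min(n, K) + 1):
                        expected = oracles.brute_hypergeom_upper_tail(k, n, K, N)
                        got = set_pvalue(k, n, K, N, "hypergeometric")
                        assert got == pytest.approx(expected, rel=1e-10, abs=1e-300)

    @given(
        st.integers(6, 25).flatmap(
            lambda N: st.tuples(
                st.just(N),
                st.integers(1, N),
                st.integers(1, N),
            ).flatmap(
                lambda t: st.tuples(
                    st.just(t[0]), st.just(t[1]), st.just(t[2]),
                    st.integers(0, min(t[1], t[2])),
                )
            )
        )
    )
    @settings(deadline=None, max_examples=150)
    def test_ease_never_below_hypergeometric(self, tnk):
        N, n, K, k = tnk
        assert set_pvalue(k, n, K, N, "ease") >= set_pvalue(
            k, n, K, N, "hypergeometric"
        )


class TestBhAdjust:
    def test_hand_evaluated_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        assert bh_adjust([0.5]) == [0.5]

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
    @settings(deadline=None)
    def test_matches_textbook_formula_and_dominates_raw(self, pvals):
        got = bh_adjust(pvals)
        expected = oracles.brute_bh(pvals)
        assert np.allclose(got, expected)
        assert all(a >= p - 1e-12 for a, p in zip(got, pvals))


class TestEnrich:
    def make_collection(self):
        return GeneSetCollection(
            sets={
                "S1": {f"G{i}" for i in range(10)},
                "S2": {f"G{i}" for i in range(8, 20)},
                "S3": {f"G{i}" for i in range(30, 40)},
            },
            classes={"S1": "Cancer", "S2": "Cancer"},
        )

    def test_planted_query_hits_its_set_first(self):
        col = self.make_collection()
        universe = {f"G{i}" for i in range(50)}
        query = {f"G{i}" for i in range(8)}  # 8 of S1's 10 genes
        result = enrich(query, col, universe, method="hypergeometric")
        assert result.table.iloc[0]["name"] == "S1"

    def test_class_rows_aggregate_member_sets(self):
        col = self.make_collection()
        universe = {f"G{i}" for i in range(50)}
        result = enrich({"G0", "G15"}, col, universe)
        cancer = result.class_table.set_index("name").loc["Cancer"]
        assert cancer["overlap"] == 2  # G0 in S1, G15 in S2
        assert cancer["set_size"] == 20

    def test_coverage_reported(self):
        col = self.make_collection()
        universe = {f"G{i}" for i in range(50)}
        result = enrich({"G0"}, col, universe)
        # genes in >= 1 set: G0..G19 and G30..G39 = 30 of 50
        assert result.coverage == pytest.approx(0.6)

    def test_disjoint_query_yields_empty_table_but_coverage(self):
        col = self.make_collection()
        universe = {f"G{i}" for i in range(50)}
        result = enrich({"G45"}, col, universe, universe_mode="all")
        assert len(result.table) == 0
        assert result.coverage == pytest.approx(0.6)

    def test_universe_mode_changes_background(self):
        col = self.make_collection()
        universe = {f"G{i}" for i in range(50)}
        query = {f"G{i}" for i in range(5)}
        annotated = enrich(query, col, universe, universe_mode="annotated")
        full = enrich(query, col, universe, universe_mode="all")
        assert annotated.universe_size == 30
        assert full.universe_size == 50

    def test_query_outside_universe_rejected(self):
        col = self.make_collection()
        with pytest.raises(ValueError):
            enrich({"NOPE"}, col, {"G0"})
        with pytest.raises(ValueError):
            enrich({"G0"}, col, set())

    def test_null_query_raw_p_calibration(self):
        """Uniformly drawn queries produce raw p <= 0.05 for about 5% of
        set tests (null calibration, scaled replicate count)."""
        rng = np.random.default_rng(0)
        universe = [f"G{i:03d}" for i in range(400)]
        col, _, _ = simulate.generate_gene_sets(
            universe, n_sets=40, set_size_range=(20, 60),
            query_size=30, enriched_fraction=0.0, seed=1,
        )
        hits = total = 0
        for _ in range(60):
            query = rng.choice(universe, size=30, replace=False)
            res = enrich(set(query), col, set(universe), method="hypergeometric")
            hits += int((res.table["p_value"] <= 0.05).sum())
            total += len(col.sets)
        rate = hits / total
        assert 0.02 <= rate <= 0.09


def test_planted_enrichment_recovered_from_generator():
    universe = [f"G{i:03d}" for i in range(300)]
    col, query, truth = simulate.generate_gene_sets(
        universe, n_sets=30, set_size_range=(20, 50),
        query_size=40, enriched_fraction=0.8, seed=3,
    )
    res = enrich(set(query), col, set(universe), method="hypergeometric")
    assert res.table.iloc[0]["name"] == truth["enriched_set"]
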