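import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from interomix import (GeneSet, GeneSetCollection, bh_adjust, enrich_collection,
                       map_query_to_set, write_enrichment_tsv)
from interomix.datasets import load_reference_tables
from interomix.errors import ValidationError


def step_up_oracle(ps):
    """Naive BH step-up computed directly from the definition."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    out = [0.0] * m
    sorted_ps = [ps[i] for i in order]
    q = [min(1.0, m * p / (r + 1)) for r, p in enumerate(sorted_ps)]
    for r in range(m - 2, -1, -1):
        q[r] = min(q[r], q[r + 1])
    for r, i in enumerate(order):
        out[i] = q[r]
    return out


class TestMapping:
    def test_reference_table_nhej_row(self):
        """The printed NHEJ members map exactly when queried with the table union."""
        tables = load_reference_tables()
        wg = tables["webgestalt"]
        query = wg.member_union()
        mapped = map_query_to_set(query, wg["W_NHEJ"].members)
        assert set(mapped) == {"PRKDC", "XRCC5", "XRCC6"} and len(mapped) == 3

    def test_disjoint_sets(self):
        assert map_query_to_set({"A"}, {"B"}) == ()

    def test_subset_query(self):
        assert map_query_to_set({"A", "B", "C"}, {"B", "A"}) == ("A", "B")


class TestBH:
    def test_single_value_identity(self):
        assert bh_adjust([0.05]) == [0.05]

    def test_step_up_worked_examples(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_adjust([0.04, 0.01]) == pytest.approx([0.04, 0.02])

    def test_out_of_range_rejected(self):
        for bad in ([0.0], [1.2], [-0.1]):
            with pytest.raises(ValidationError):
                bh_adjust(bad)

    def test_bonferroni_and_none(self):
        assert bh_adjust([0.01, 0.4], method="bonferroni") == pytest.approx([0.02, 0.8])
        assert bh_adjust([0.3], method="none") == [0.3]

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=12))
    def test_matches_definition_and_is_monotone(self, ps):
        got = bh_adjust(ps)
        assert got == pytest.approx(step_up_oracle(ps))
        for i, pi in enumerate(ps):
            for j, pj in enumerate(ps):
                if pi <= pj:
                    assert got[i] <= got[j] + 1e-12

    @settings(derandomize=True, max_examples=50)
    @given(st.permutations(list(range(6))))
    def test_permutation_equivariance(self, perm):
        ps = [0.01, 0.2, 0.05, 0.9, 0.33, 0.07]
        shuffled = [ps[i] for i in perm]
        base = bh_adjust(ps)
        assert bh_adjust(shuffled) == pytest.approx([base[i] for i in perm])


class TestEnrichCollection:
    def _collection(self):
        return GeneSetCollection(sets=(
            GeneSet("S1", "first", frozenset({"A", "B"})),
            GeneSet("S2", "second", frozenset({"C"})),
        ))

    def test_small_enumerated_example(self):
        rows = enrich_collection({"A", "B"}, self._collection(), {"A", "B", "C", "D"})
        by_id = {r.set_id: r for r in rows}
        s1 = by_id["S1"]
        assert (s1.k, s1.K, s1.n, s1.N) == (2, 2, 2, 4)
        assert s1.p_unadjusted == pytest.approx(1 / 6, rel=1e-12)
        assert by_id["S2"].k == 0 and by_id["S2"].p_unadjusted == 1.0
        assert rows[0].set_id == "S1"  # sorted ascending by p

    def test_empty_query_all_p_one(self):
        rows = enrich_collection(set(), self._collection(), {"A", "B", "C"})
        assert all(r.k == 0 and r.p_unadjusted == 1.0 for r in rows)

    def test_set_equal_universe_is_certain(self):
        coll = GeneSetCollection(sets=(GeneSet("U", "all", frozenset({"A", "B"})),))
        rows = enrich_collection({"A"}, coll, {"A", "B"})
        assert rows[0].k == rows[0].n and rows[0].p_unadjusted == 1.0

    def test_default_universe_is_member_union(self):
        rows = enrich_collection({"A", "Z"}, self._collection())
        assert rows[0].N == 3 and rows[0].n == 1  # Z dropped

    def test_adjusted_never_below_unadjusted(self, small_sim):
        rows = enrich_collection(small_sim.truth.module_genes, small_sim.collection)
        assert all(r.p_adjusted >= r.p_unadjusted - 1e-12 for r in rows)

    def test_row_pvalues_match_enumeration_oracle(self):
        from test_integration import enumeration_tail
        rows = enrich_collection({"A", "B", "C"}, self._collection(),
                                 {"A", "B", "C", "D", "E"})
        for r in rows:
            oracle = enumeration_tail(r.k, r.K, r.n, r.N)
            assert r.p_unadjusted == pytest.approx(float(oracle), rel=1e-12)

    def test_tsv_output_round_numbers(self, tmp_path):
        rows = enrich_collection({"A", "B"}, self._collection(), {"A", "B", "C", "D"})
        path = write_enrichment_tsv(rows, tmp_path / "enr.tsv")
        lines = path.read_text().splitlines()
        assert lines[0].startswith("set\tname\tk")
        assert lines[1].split("\t")[0] == "S1"
        assert lines[1].split("\t")[-1] == "A;B"
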