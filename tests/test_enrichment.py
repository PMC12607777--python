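"""Enrichment scoring against a literal two-loop transcription of the
running-sum definition, plus its boundary and invariance properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import spectratype as st
from spectratype.enrichment import DegenerateSetError


# --- independent oracle: direct per-rank loop over the two sums -----------

def oracle_running_sum(ordered_genes, metric_values, members, p):
    n = len(ordered_genes)
    hits = [g in members for g in ordered_genes]
    n_hit = sum(hits)
    n_r = sum(abs(v) ** p for v, h in zip(metric_values, hits) if h)
    traj, p_hit, p_miss = [], 0.0, 0.0
    for i in range(n):
        if hits[i]:
            p_hit += abs(metric_values[i]) ** p / n_r
        else:
            p_miss += 1.0 / (n - n_hit)
        traj.append(p_hit - p_miss)
    return traj


def oracle_es(ordered_genes, metric_values, members, p):
    traj = oracle_running_sum(ordered_genes, metric_values, members, p)
    return max(traj, key=lambda v: (abs(v), -traj.index(v)))


def _ranked(values, ids=None):
    ids = ids or [f"g{i}" for i in range(len(values))]
    expr = st.ExpressionMatrix(ids, ["s"], np.asarray(values, float)[:, None])
    return st.rank_sample(expr, "s")


class TestRankSample:
    def test_descending_order(self, tiny_expression):
        rs = st.rank_sample(tiny_expression, "s1")
        assert rs.ordered_gene_ids == ["G1", "G3", "G2"]

    def test_tie_broken_by_gene_id(self):
        expr = st.ExpressionMatrix(
            ["Gb", "Ga"], ["s"], np.array([[3.0], [3.0]])
        )
        rs = st.rank_sample(expr, "s")
        assert rs.ordered_gene_ids == ["Ga", "Gb"]

    def test_unknown_sample(self, tiny_expression):
        with pytest.raises(KeyError):
            st.rank_sample(tiny_expression, "nope")

    def test_matches_stable_sort_oracle(self):
        rng = np.random.default_rng(7)
        ids = [f"g{i:03d}" for i in range(100)]
        values = rng.choice([0.0, 1.0, 2.0, 3.0], size=100)  # many ties
        expr = st.ExpressionMatrix(ids, ["s"], values[:, None])
        rs = st.rank_sample(expr, "s")
        expected = [g for g, _ in sorted(zip(ids, values), key=lambda t: (-t[1], t[0]))]
        assert rs.ordered_gene_ids == expected


class TestRunningSum:
    def test_hand_computed_trajectory(self):
        rs = _ranked([5, 4, 3, 2, 1])
        traj = st.running_sum(rs, {"g0", "g2"}, st.EnrichmentParams())
        np.testing.assert_allclose(
            traj, [0.625, 0.625 - 1 / 3, 1 - 1 / 3, 1 - 2 / 3, 0.0], atol=1e-12
        )

    def test_top_ranked_members_reach_one(self):
        rs = _ranked([9, 8, 7, 2, 1])
        traj = st.running_sum(rs, {"g0", "g1", "g2"}, st.EnrichmentParams())
        assert traj[2] == pytest.approx(1.0)

    @pytest.mark.parametrize("p", [0.0, 1.0, 2.0])
    def test_final_value_zero(self, p):
        rng = np.random.default_rng(int(p) + 1)
        rs = _ranked(rng.normal(size=40))
        traj = st.running_sum(rs, {f"g{i}" for i in range(0, 40, 5)},
                              st.EnrichmentParams(weight_exponent=p))
        assert abs(traj[-1]) < 1e-12

    def test_degenerate_sets_rejected(self):
        rs = _ranked([3, 2, 1])
        with pytest.raises(DegenerateSetError):
            st.running_sum(rs, {"absent"}, st.EnrichmentParams())
        with pytest.raises(DegenerateSetError):
            st.running_sum(rs, {"g0", "g1", "g2"}, st.EnrichmentParams())


class TestEnrichmentScore:
    def test_hand_example(self):
        rs = _ranked([5, 4, 3, 2, 1])
        es = st.enrichment_score(rs, {"g0", "g2"}, st.EnrichmentParams())
        assert es == pytest.approx(2 / 3)

    def test_bottom_ranked_members_hit_minus_one(self):
        rs = _ranked([5, 4, 3, 2, 1])
        es = st.enrichment_score(rs, {"g3", "g4"}, st.EnrichmentParams())
        assert es == pytest.approx(-1.0)
        assert es == pytest.approx(oracle_es(rs.ordered_gene_ids, rs.metric_values,
                                             {"g3", "g4"}, 1.0))

    def test_top_ranked_members_hit_plus_one(self):
        rs = _ranked([5, 4, 3, 2, 1])
        assert st.enrichment_score(rs, {"g0", "g1"}, st.EnrichmentParams()) == 1.0

    @given(hst.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        rs = _ranked(rng.normal(size=n))
        members = {f"g{i}" for i in rng.choice(n, size=int(rng.integers(1, n)), replace=False)}
        es = st.enrichment_score(rs, members, st.EnrichmentParams())
        assert -1.0 <= es <= 1.0

    def test_rank_only_invariance_at_p_zero(self):
        rng = np.random.default_rng(12)
        values = rng.normal(size=30)
        members = {f"g{i}" for i in range(0, 30, 4)}
        params = st.EnrichmentParams(weight_exponent=0.0)
        es1 = st.enrichment_score(_ranked(values), members, params)
        es2 = st.enrichment_score(_ranked(np.exp(values) + 7), members, params)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_absent_genes_contribute_nothing(self):
        rng = np.random.default_rng(13)
        values = rng.normal(size=20)
        members = {"g1", "g5", "g9"}
        padded = members | {"NOT_MEASURED_1", "NOT_MEASURED_2"}
        params = st.EnrichmentParams()
        assert st.enrichment_score(_ranked(values), members, params) == pytest.approx(
            st.enrichment_score(_ranked(values), padded, params)
        )


class TestFunctionalSpectra:
    def test_composition_matches_single_pair(self, tiny_expression):
        coll = st.GeneSetCollection(
            {
                "A": ("d", frozenset({"G1", "G2"})),
                "B": ("d", frozenset({"G3"})),
                "C": ("d", frozenset({"G2", "G3"})),
            }
        )
        params = st.EnrichmentParams(min_set_size=1)
        em = st.functional_spectra(tiny_expression, coll, params)
        assert em.scores.shape == (2, 3)
        for i, sid in enumerate(em.sample_ids):
            rs = st.rank_sample(tiny_expression, sid)
            for j, name in enumerate(em.set_names):
                expected = st.enrichment_score(rs, coll.members(name), params)
                assert em.scores[i, j] == pytest.approx(expected, abs=1e-12)

    def test_sample_permutation_permutes_rows_only(self, small_study):
        expr = small_study.expression
        params = st.EnrichmentParams()
        em = st.functional_spectra(expr, small_study.gene_sets, params)
        rng = np.random.default_rng(4)
        perm = rng.permutation(expr.n_samples)
        shuffled = st.ExpressionMatrix(
            expr.gene_ids,
            [expr.sample_ids[i] for i in perm],
            expr.values[:, perm],
        )
        em2 = st.functional_spectra(shuffled, small_study.gene_sets, params)
        np.testing.assert_allclose(em2.scores, em.scores[perm], atol=1e-12)

    def test_matches_two_loop_oracle_on_random_pairs(self, small_study, small_spectra):
        """Vectorized scores equal the literal transcription on 100 pairs."""
        rng = np.random.default_rng(99)
        em = small_spectra
        coll = small_study.gene_sets
        for _ in range(100):
            i = int(rng.integers(len(em.sample_ids)))
            j = int(rng.integers(len(em.set_names)))
            rs = st.rank_sample(small_study.expression, em.sample_ids[i])
            expected = oracle_es(
                rs.ordered_gene_ids, rs.metric_values, coll.members(em.set_names[j]), 1.0
            )
            assert em.scores[i, j] == pytest.approx(expected, abs=1e-10)

    def test_small_sets_dropped_and_zero_survivors_error(self, tiny_expression):
        coll = st.GeneSetCollection({"A": ("d", frozenset({"G1"}))})
        with pytest.raises(DegenerateSetError):
            st.functional_spectra(tiny_expression, coll, st.EnrichmentParams(min_set_size=2))


class TestSpectraTransformer:
    def test_fit_transform_records_vocabulary(self, small_study):
        tr = st.SpectraTransformer(gene_sets=small_study.gene_sets)
        em = tr.fit_transform(small_study.expression)
        assert tr.set_names_ == em.set_names
        assert em.scores.shape[0] == small_study.expression.n_samples

    def test_sklearn_params_round_trip(self, small_study):
        tr = st.SpectraTransformer(gene_sets=small_study.gene_sets, weight_exponent=0.5)
        assert tr.get_params()["weight_exponent"] == 0.5
        tr.set_params(min_set_size=3)
        assert tr.min_set_size == 3
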