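"""Hypergeometric over-representation and GSEA running-sum mechanics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from budmir.enrich import (
    GeneSet,
    gsea_es,
    gsea_permutation_test,
    hypergeometric_enrich,
    rank_metric,
)


def _enumeration_oracle(query, background, members):
    """Exhaustive draws: P(overlap >= k_obs) over all C(N, n) query draws."""
    bg = sorted(background)
    in_set = members & background
    k_obs = len(query & in_set)
    total = 0
    at_least = 0
    for draw in itertools.combinations(bg, len(query)):
        total += 1
        if len(set(draw) & in_set) >= k_obs:
            at_least += 1
    return at_least / total


class TestHypergeometric:
    def test_query_equal_to_set_exact_value(self):
        background = {f"g{i}" for i in range(10)}
        query = {f"g{i}" for i in range(5)}
        sets = [GeneSet("s", frozenset(query))]
        res = hypergeometric_enrich(query, background, sets)
        assert res.loc[0, "hyper_p"] == pytest.approx(1 / math.comb(10, 5))

    def test_matches_enumeration_oracle_on_small_universes(self):
        rng = np.random.default_rng(2)
        background = {f"g{i}" for i in range(10)}
        for _ in range(10):
            query = set(rng.choice(sorted(background), size=4, replace=False))
            members = frozenset(
                rng.choice(sorted(background), size=5, replace=False))
            res = hypergeometric_enrich(query, background,
                                        [GeneSet("s", members)])
            oracle = _enumeration_oracle(query, background, set(members))
            assert res.loc[0, "hyper_p"] == pytest.approx(oracle, abs=1e-12)

    def test_query_equals_background_forces_p_one(self):
        background = {f"g{i}" for i in range(8)}
        sets = [GeneSet("s", frozenset(list(background)[:3]))]
        res = hypergeometric_enrich(set(background), background, sets)
        assert res.loc[0, "hyper_p"] == pytest.approx(1.0)

    def test_zero_background_overlap_skipped(self):
        background = {"g1", "g2"}
        sets = [GeneSet("alien", frozenset({"x1", "x2"}))]
        res = hypergeometric_enrich({"g1"}, background, sets)
        assert res.empty

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError, match="orphan"):
            hypergeometric_enrich({"orphan"}, {"g1"}, [])


def _expr(data, cols=None):
    cols = cols or [f"LD_{i}" for i in (1, 2, 3)] + \
        [f"SD_{i}" for i in (1, 2, 3)]
    return pd.DataFrame(data, columns=cols)


class TestRankMetric:
    def test_identical_groups_score_zero(self):
        expr = _expr({f"LD_{i}": [5.0] for i in (1, 2, 3)} |
                     {f"SD_{i}": [5.0] for i in (1, 2, 3)})
        expr.index = ["g1"]
        out = rank_metric(expr, ["LD"] * 3 + ["SD"] * 3, positive_group="SD")
        assert out.loc[0, "score"] == 0.0

    def test_signal_to_noise_with_floor_inactive(self):
        # means 10 vs 2 with sds 3 and 1: floors (2.0, 0.4) are below the
        # sample sds, so score = 8 / 4 = 2
        expr = pd.DataFrame([[7.0, 10.0, 13.0, 1.0, 2.0, 3.0]],
                            index=["g1"],
                            columns=["SD_1", "SD_2", "SD_3",
                                     "LD_1", "LD_2", "LD_3"])
        out = rank_metric(expr, ["SD"] * 3 + ["LD"] * 3, positive_group="SD")
        assert out.loc[0, "score"] == pytest.approx(8.0 / 4.0)

    def test_sd_floor_guards_tiny_variance(self):
        # constant groups: sd 0 floored at max(0.2*mean, 0.2)
        expr = pd.DataFrame([[10.0, 10.0, 10.0, 2.0, 2.0, 2.0]],
                            index=["g1"],
                            columns=["SD_1", "SD_2", "SD_3",
                                     "LD_1", "LD_2", "LD_3"])
        out = rank_metric(expr, ["SD"] * 3 + ["LD"] * 3, positive_group="SD")
        assert out.loc[0, "score"] == pytest.approx(8.0 / (2.0 + 0.4))

    def test_reversing_groups_negates_scores(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.uniform(1, 100, size=(20, 6)),
                            index=[f"g{i}" for i in range(20)],
                            columns=["LD_1", "LD_2", "LD_3",
                                     "SD_1", "SD_2", "SD_3"])
        groups = ["LD"] * 3 + ["SD"] * 3
        sd_pos = rank_metric(expr, groups, positive_group="SD")
        ld_pos = rank_metric(expr, groups, positive_group="LD")
        merged = sd_pos.merge(ld_pos, on="gene_id", suffixes=("_sd", "_ld"))
        assert np.allclose(merged["score_sd"], -merged["score_ld"])

    def test_single_replicate_rejected(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["LD_1", "SD_1"])
        with pytest.raises(ValueError):
            rank_metric(expr, ["LD", "SD"])


def _ranked(genes, scores):
    return pd.DataFrame({"gene_id": genes, "score": scores})


class TestGseaEs:
    def test_top_gene_set_scores_one_unweighted(self):
        ranked = _ranked(["a", "b", "c", "d"], [3.0, 2.0, 1.0, 0.5])
        assert gsea_es(ranked, GeneSet("s", frozenset({"a"})), weight=0) == \
            pytest.approx(1.0)

    def test_bottom_gene_set_scores_minus_one_unweighted(self):
        ranked = _ranked(["a", "b", "c", "d"], [3.0, 2.0, 1.0, 0.5])
        assert gsea_es(ranked, GeneSet("s", frozenset({"d"})), weight=0) == \
            pytest.approx(-1.0)

    def test_es_invariant_under_monotone_transform_when_unweighted(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(30)]
        scores = np.sort(rng.normal(size=30))[::-1]
        members = frozenset(rng.choice(genes, size=6, replace=False))
        es1 = gsea_es(_ranked(genes, scores), GeneSet("s", members), weight=0)
        es2 = gsea_es(_ranked(genes, 10 * scores + 3), GeneSet("s", members),
                      weight=0)
        assert es1 == pytest.approx(es2)

    def test_es_depends_only_on_hit_positions_and_scores(self):
        genes = [f"g{i}" for i in range(10)]
        scores = list(np.linspace(5, -5, 10))
        members = frozenset({"g2", "g7"})
        base = gsea_es(_ranked(genes, scores), GeneSet("s", members))
        relabeled = [g if g in members else f"x{i}"
                     for i, g in enumerate(genes)]
        relab = gsea_es(_ranked(relabeled, scores), GeneSet("s", members))
        assert base == pytest.approx(relab)

    def test_degenerate_sets_rejected(self):
        ranked = _ranked(["a", "b"], [1.0, -1.0])
        with pytest.raises(ValueError):
            gsea_es(ranked, GeneSet("none", frozenset({"zz"})))
        with pytest.raises(ValueError):
            gsea_es(ranked, GeneSet("all", frozenset({"a", "b"})))


@pytest.fixture(scope="module")
def null_expr():
    rng = np.random.default_rng(8)
    genes = [f"g{i}" for i in range(60)]
    return pd.DataFrame(rng.uniform(10, 100, size=(60, 6)), index=genes,
                        columns=["LD_1", "LD_2", "LD_3",
                                 "SD_1", "SD_2", "SD_3"])


class TestGseaPermutation:
    def test_small_sets_excluded(self, null_expr):
        sets = [GeneSet("small", frozenset(list(null_expr.index[:6]))),
                GeneSet("ok", frozenset(list(null_expr.index[:9])))]
        res = gsea_permutation_test(null_expr, ["LD"] * 3 + ["SD"] * 3, sets,
                                    n_perm=100, min_size=7, seed=0)
        assert list(res["set_name"]) == ["ok"]

    def test_p_values_in_valid_range_and_seeded_determinism(self, null_expr):
        sets = [GeneSet(f"s{k}", frozenset(
            list(null_expr.index[k * 8:(k + 1) * 8]))) for k in range(4)]
        groups = ["LD"] * 3 + ["SD"] * 3
        r1 = gsea_permutation_test(null_expr, groups, sets, n_perm=200, seed=5)
        r2 = gsea_permutation_test(null_expr, groups, sets, n_perm=200, seed=5)
        pd.testing.assert_frame_equal(r1, r2)
        assert ((r1["nominal_p"] >= 1 / 201) & (r1["nominal_p"] <= 1)).all()

    def test_phenotype_permutation_runs(self, null_expr):
        sets = [GeneSet("s", frozenset(list(null_expr.index[:10])))]
        res = gsea_permutation_test(null_expr, ["LD"] * 3 + ["SD"] * 3, sets,
                                    n_perm=100, seed=1, permute="phenotype")
        assert len(res) == 1
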