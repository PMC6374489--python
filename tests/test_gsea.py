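import itertools

import numpy as np
import pandas as pd
import pytest

import drugpath as dp
from drugpath.gsea import normalize_and_fdr, permutation_null
from oracles import exhaustive_es_distribution, gsea_running_sum, nes_ratio_fdr


def _ranked(metrics, genes=None):
    genes = genes or [f"G{i:02d}" for i in range(len(metrics))]
    return dp.RankedGeneList(
        table=pd.DataFrame({"gene": genes, "metric": metrics})
    )


class TestEnrichmentScore:
    def test_top_gene_singleton_scores_one(self, ranked_list_50):
        es, _, lead = dp.enrichment_score(ranked_list_50, {ranked_list_50.genes[0]})
        assert es == pytest.approx(1.0)
        assert lead == [ranked_list_50.genes[0]]

    def test_bottom_gene_singleton_matches_oracle(self):
        rl = _ranked([5.0, 4.0, 3.0, 2.0, 1.0])
        es, _, lead = dp.enrichment_score(rl, {rl.genes[-1]}, weight_exponent=0.0)
        es_oracle, _ = gsea_running_sum(rl.metrics, [False] * 4 + [True], 0.0)
        assert es == pytest.approx(es_oracle)
        assert es == pytest.approx(-1.0)  # four misses of 1/4 before the hit
        assert lead == [rl.genes[-1]]

    def test_scale_invariance_at_weight_one(self, ranked_list_50):
        gs = set(ranked_list_50.genes[3:9])
        es1, _, _ = dp.enrichment_score(ranked_list_50, gs)
        scaled = _ranked(ranked_list_50.metrics * 17.0, ranked_list_50.genes)
        es2, _, _ = dp.enrichment_score(scaled, gs)
        assert es1 == pytest.approx(es2)

    def test_matches_bruteforce_on_all_subsets_of_small_universes(self):
        """ES equals the brute-force running sum on every subset, N <= 6."""
        rng = np.random.default_rng(29)
        for _trial in range(5):
            metrics = np.sort(rng.normal(scale=2.0, size=6))[::-1]
            rl = _ranked(metrics)
            for p in (0.0, 1.0):
                for r in range(1, 6):
                    for combo in itertools.combinations(range(6), r):
                        gs = {rl.genes[i] for i in combo}
                        mask = [i in combo for i in range(6)]
                        es, _, _ = dp.enrichment_score(rl, gs, weight_exponent=p)
                        es_oracle, _ = gsea_running_sum(metrics, mask, p)
                        assert es == pytest.approx(es_oracle), (p, combo)

    def test_reversed_list_negates_es(self):
        rng = np.random.default_rng(31)
        metrics = np.sort(rng.normal(size=12))[::-1]
        rl = _ranked(metrics)
        rev = dp.RankedGeneList(
            table=pd.DataFrame(
                {"gene": rl.genes[::-1], "metric": -metrics[::-1]}
            )
        )
        for size in (1, 3, 5):
            gs = set(rl.genes[2 : 2 + size])
            es_f, _, _ = dp.enrichment_score(rl, gs)
            es_r, _, _ = dp.enrichment_score(rev, gs)
            assert es_f == pytest.approx(-es_r)

    def test_es_bounded_by_one(self, ranked_list_50):
        rng = np.random.default_rng(33)
        for _ in range(50):
            size = rng.integers(1, 49)
            gs = set(rng.choice(ranked_list_50.genes, size=size, replace=False))
            es, _, _ = dp.enrichment_score(ranked_list_50, gs)
            assert abs(es) <= 1.0 + 1e-12

    def test_whole_universe_set_rejected(self, ranked_list_50):
        with pytest.raises(ValueError):
            dp.enrichment_score(ranked_list_50, set(ranked_list_50.genes))


class TestPermutationNull:
    def test_same_seed_reproducible(self, ranked_list_50):
        a = permutation_null(ranked_list_50, {"S": 5}, n_perm=50, seed=9)
        b = permutation_null(ranked_list_50, {"S": 5}, n_perm=50, seed=9)
        assert np.array_equal(a["S"], b["S"])

    def test_sampled_null_converges_to_exhaustive(self):
        """Universe of 6, |gs| = 2: sampled ES frequencies match the 15
        exhaustive memberships."""
        rng = np.random.default_rng(41)
        metrics = np.sort(rng.normal(size=6))[::-1]
        rl = _ranked(metrics)
        exhaustive = exhaustive_es_distribution(metrics, 2, 1.0)
        sampled = permutation_null(rl, {"S": 2}, n_perm=6000, seed=13)["S"]
        # compare distribution moments and extremes
        assert np.mean(sampled) == pytest.approx(np.mean(exhaustive), abs=0.03)
        assert set(np.round(sampled, 10)) <= set(np.round(exhaustive, 10))

    def test_sampled_tail_probability_matches_exhaustive(self):
        """Nominal p from sampling converges to exhaustive enumeration
        (N = 8, |gs| = 3)."""
        rng = np.random.default_rng(43)
        metrics = np.sort(rng.normal(size=8))[::-1]
        rl = _ranked(metrics)
        gs = set(rl.genes[:3])
        es, _, _ = dp.enrichment_score(rl, gs)
        exhaustive = exhaustive_es_distribution(metrics, 3, 1.0)
        pos = exhaustive[exhaustive > 0]
        p_exhaustive = (pos >= es).sum() / pos.size
        null = permutation_null(rl, {"S": 3}, n_perm=20000, seed=17)["S"]
        pos_s = null[null > 0]
        p_sampled = (pos_s >= es).sum() / pos_s.size
        assert p_sampled == pytest.approx(p_exhaustive, abs=0.02)

    def test_null_mean_near_zero_for_symmetric_metrics(self):
        metrics = np.linspace(2.0, -2.0, 21)
        rl = _ranked(metrics)
        null = permutation_null(rl, {"S": 4}, n_perm=3000, seed=19)["S"]
        assert abs(np.mean(null)) < 0.05


class TestNormalizeAndFdr:
    def test_zero_es_maps_to_zero_nes_p_one(self):
        observed = pd.DataFrame([{"name": "S", "size": 3, "es": 0.0}])
        out = normalize_and_fdr(observed, {"S": np.array([0.4, -0.3, 0.2])})
        assert out["nes"].iloc[0] == 0.0
        assert out["p_nominal"].iloc[0] == 1.0

    def test_underflow_flagged_when_observed_beats_all_nulls(self):
        observed = pd.DataFrame([{"name": "S", "size": 3, "es": 0.99}])
        null = np.array([0.1, 0.2, -0.15, 0.05, -0.3])
        out = normalize_and_fdr(observed, {"S": null})
        assert out["p_nominal"].iloc[0] == 0.0
        assert bool(out["p_underflow"].iloc[0])

    def test_no_same_sign_null_flagged_missing(self):
        observed = pd.DataFrame([{"name": "S", "size": 3, "es": -0.5}])
        out = normalize_and_fdr(observed, {"S": np.array([0.1, 0.2, 0.3])})
        assert np.isnan(out["nes"].iloc[0])
        assert out["flag"].iloc[0] == "no_same_sign_null"

    def test_fdr_matches_naive_nes_ratio_on_toy_instance(self):
        rng = np.random.default_rng(47)
        observed = pd.DataFrame(
            [
                {"name": "S1", "size": 4, "es": 0.8},
                {"name": "S2", "size": 4, "es": 0.3},
                {"name": "S3", "size": 4, "es": -0.6},
            ]
        )
        nulls = {n: rng.normal(scale=0.3, size=200) for n in ("S1", "S2", "S3")}
        out = normalize_and_fdr(observed, nulls)
        # rebuild the pooled normalized null exactly as defined
        pool = []
        for n, null in nulls.items():
            pos, neg = null[null > 0], null[null < 0]
            pool.extend(pos / pos.mean())
            pool.extend(neg / np.abs(neg).mean())
        q_oracle = nes_ratio_fdr(out["nes"].tolist(), pool)
        assert np.allclose(out["fdr_q"].to_numpy(), q_oracle)


class TestRunGsea:
    def test_planted_head_set_retained(self, ranked_list_50):
        coll = dp.GeneSetCollection(
            {
                "HEAD": ("head genes", ranked_list_50.genes[:5]),
                "RAND": ("scattered", ranked_list_50.genes[7::9]),
            }
        )
        res = dp.run_gsea(ranked_list_50, coll, n_perm=500, seed=3)
        head = res.table.set_index("name").loc["HEAD"]
        assert head["es"] > 0
        assert head["fdr_q"] < 0.25
        assert "HEAD" in set(res.passing["name"])

    def test_degenerate_single_permutation_completes(self, ranked_list_50):
        coll = dp.GeneSetCollection({"S": ("d", ranked_list_50.genes[:4])})
        res = dp.run_gsea(ranked_list_50, coll, n_perm=1, seed=0)
        assert len(res.table) == 1

    def test_empty_collection_rejected(self, ranked_list_50):
        with pytest.raises(ValueError, match="empty"):
            dp.run_gsea(
                ranked_list_50,
                dp.GeneSetCollection({}),
                n_perm=10,
                seed=0,
            )

    def test_out_of_universe_and_size_filtered_sets_skipped(self, ranked_list_50):
        coll = dp.GeneSetCollection(
            {
                "MISSING": ("d", ["ZZ1", "ZZ2", "ZZ3"]),
                "TINY": ("d", [ranked_list_50.genes[0]]),
                "OK": ("d", ranked_list_50.genes[:5]),
            }
        )
        res = dp.run_gsea(ranked_list_50, coll, n_perm=20, seed=0)
        assert set(res.table["name"]) == {"OK"}
        assert len(res.skipped) == 2

    def test_false_positive_rate_of_random_sets_bounded(self, ranked_list_50):
        """Random sets on a random metric rarely pass FDR < 0.25."""
        rng = np.random.default_rng(51)
        fp = total = 0
        for trial in range(10):
            metrics = rng.normal(size=50)
            order = np.argsort(metrics)[::-1]
            rl = dp.RankedGeneList(
                table=pd.DataFrame(
                    {
                        "gene": [ranked_list_50.genes[i] for i in order],
                        "metric": metrics[order],
                    }
                )
            )
            sets = {
                f"R{j}": ("d", sorted(rng.choice(rl.genes, size=6, replace=False)))
                for j in range(8)
            }
            res = dp.run_gsea(rl, dp.GeneSetCollection(sets), n_perm=200, seed=trial)
            fp += len(res.passing)
            total += len(res.table)
        assert fp / total <= 0.25
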