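import numpy as np
import pandas as pd
import pytest

from crcsubtype import (
    CoClusterMatrix,
    ExpressionMatrix,
    INMFConfig,
    SyntheticConfig,
    WeakStructureError,
    cocluster_counts,
    extract_core_clusters,
    generate_hierarchical_expression,
    modal_rank,
    run_inmf,
    sample_probe_groups,
)

from conftest import planted_two_block


SMALL_CFG = INMFConfig(
    n_groups=20,
    group_size=80,
    core_threshold=16,
    seed=1,
    ranks=(2, 3),
    n_runs=5,
    min_cluster_size=8,
    n_top_variance=500,
)


def small_synthetic(seed=3):
    cfg = SyntheticConfig(
        samples_per_subtype=8,
        n_probes=600,
        type_signature_size=60,
        subtype_signature_size=60,
        hierarchy={"1": ("1.1", "1.2"), "2": ("2.1", "2.2")},
        seed=seed,
    )
    return generate_hierarchical_expression(cfg)


class TestProbeGroups:
    def test_reproducible_under_seed(self):
        ids = [f"p{i}" for i in range(200)]
        g1 = sample_probe_groups(ids, n_groups=5, group_size=50, seed=9)
        g2 = sample_probe_groups(ids, n_groups=5, group_size=50, seed=9)
        assert g1 == g2

    def test_full_universe_groups(self):
        ids = [f"p{i}" for i in range(30)]
        groups = sample_probe_groups(ids, n_groups=2, group_size=30, seed=0)
        for g in groups:
            assert sorted(g) == sorted(ids)

    def test_oversized_group_raises(self):
        with pytest.raises(ValueError, match="group_size"):
            sample_probe_groups(["a", "b"], n_groups=1, group_size=3, seed=0)

    def test_inclusion_frequency_is_binomial(self):
        # 10000 draws of 100 from 5000: inclusion ~ Binomial(10000, 0.02)
        ids = [f"p{i}" for i in range(5000)]
        groups = sample_probe_groups(ids, n_groups=10000, group_size=100, seed=17)
        counts = pd.Series(0, index=ids)
        hits = pd.Series([p for g in groups for p in g]).value_counts()
        counts[hits.index] = hits
        expected = 10000 * 100 / 5000
        sd = np.sqrt(10000 * 0.02 * 0.98)
        within = np.abs(counts - expected) <= 3 * sd
        # per-probe 3-sigma band: essentially all probes inside, mean on target
        assert within.mean() >= 0.99
        assert counts.mean() == pytest.approx(expected, rel=1e-12)


class TestModalRank:
    @pytest.mark.parametrize("ranks,expected", [([2, 2, 3], 2), ([2, 3], 2), ([4], 4)])
    def test_known_modes(self, ranks, expected):
        assert modal_rank(ranks) == expected

    def test_matches_brute_force_mode(self, rng):
        for _ in range(20):
            ranks = list(rng.integers(2, 6, size=rng.integers(1, 30)))
            counts = {k: ranks.count(k) for k in set(ranks)}
            best = sorted(counts, key=lambda k: (-counts[k], k))[0]
            assert modal_rank(ranks) == best

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            modal_rank([])


class TestCoclusterCounts:
    def test_planted_blocks_count_cleanly(self):
        expr, labels = planted_two_block(n_probes=120, n_per_block=6, effect=4.0, seed=5)
        groups = sample_probe_groups(expr.probe_ids, n_groups=10, group_size=60, seed=2)
        cfg = INMFConfig(n_groups=10, group_size=60, core_threshold=8, seed=2, n_runs=5)
        cc = cocluster_counts(expr, groups, 2, cfg)
        same = labels[:, None] == labels[None, :]
        assert cc.n_groups == 10
        np.testing.assert_array_equal(cc.counts[same], 10)
        np.testing.assert_array_equal(cc.counts[~same], 0)

    def test_single_group_counts_binary(self):
        expr, _ = planted_two_block(n_probes=100, n_per_block=5, effect=4.0, seed=6)
        groups = sample_probe_groups(expr.probe_ids, n_groups=1, group_size=50, seed=3)
        cfg = INMFConfig(n_groups=1, group_size=50, core_threshold=1, seed=3, n_runs=4)
        cc = cocluster_counts(expr, groups, 2, cfg)
        off = cc.counts[~np.eye(len(cc.sample_ids), dtype=bool)]
        assert set(np.unique(off)) <= {0, 1}

    def test_counts_equal_tally_of_returned_labels(self):
        expr, _ = planted_two_block(n_probes=100, n_per_block=5, effect=2.0, seed=7)
        groups = sample_probe_groups(expr.probe_ids, n_groups=6, group_size=50, seed=4)
        cfg = INMFConfig(n_groups=6, group_size=50, core_threshold=5, seed=4, n_runs=4)
        cc, labels = cocluster_counts(expr, groups, 2, cfg, return_labels=True)
        manual = np.zeros_like(cc.counts)
        for lab in labels:
            manual += (lab[:, None] == lab[None, :]).astype(int)
        np.testing.assert_array_equal(cc.counts, manual)

    def test_symmetry_and_diagonal_invariant(self):
        expr, _ = planted_two_block(n_probes=100, n_per_block=5, effect=2.0, seed=8)
        groups = sample_probe_groups(expr.probe_ids, n_groups=4, group_size=40, seed=5)
        cfg = INMFConfig(n_groups=4, group_size=40, core_threshold=3, seed=5, n_runs=4)
        cc = cocluster_counts(expr, groups, 2, cfg)
        np.testing.assert_array_equal(cc.counts, cc.counts.T)
        np.testing.assert_array_equal(np.diag(cc.counts), cc.n_groups)


class TestCoreClusters:
    def make_cc(self, counts, n_groups=100):
        ids = [f"s{i}" for i in range(counts.shape[0])]
        return CoClusterMatrix(counts=counts, sample_ids=ids, n_groups=n_groups)

    def test_planted_blocks_fully_retained(self):
        counts = np.zeros((10, 10), dtype=int)
        counts[:5, :5] = 100
        counts[5:, 5:] = 100
        cores = extract_core_clusters(self.make_cc(counts), 2, 80)
        assert sorted(len(c) for c in cores.clusters) == [5, 5]
        assert cores.excluded == []

    def test_degenerate_all_equal_counts(self):
        counts = np.full((6, 6), 100, dtype=int)
        cores1 = extract_core_clusters(self.make_cc(counts), 1, 80)
        assert len(cores1.clusters) == 1 and len(cores1.clusters[0]) == 6
        cores2 = extract_core_clusters(self.make_cc(counts), 2, 80)
        assert len(cores2.clusters) == 2
        assert sorted(s for c in cores2.clusters for s in c) == [f"s{i}" for i in range(6)]
        assert cores2.excluded == []

    @pytest.mark.parametrize("low,threshold,kept", [(79, 80, False), (80, 80, True)])
    def test_mean_count_boundary(self, low, threshold, kept):
        # one cluster of 5; sample s4 co-clusters `low` times with each other member
        counts = np.full((5, 5), 100, dtype=int)
        counts[4, :4] = low
        counts[:4, 4] = low
        np.fill_diagonal(counts, 100)
        cores = extract_core_clusters(self.make_cc(counts), 1, threshold)
        assert ("s4" in cores.clusters[0]) is kept
        assert ("s4" in cores.excluded) is not kept

    def test_iterative_removal_of_outlier_restores_core(self):
        # 6 samples: 5 agree (100), one co-clusters 50 with everyone
        counts = np.full((6, 6), 100, dtype=int)
        counts[5, :5] = 50
        counts[:5, 5] = 50
        cores = extract_core_clusters(self.make_cc(counts), 1, 80)
        assert cores.excluded == ["s5"]
        assert len(cores.clusters[0]) == 5

    def test_too_many_clusters_raises(self):
        counts = np.full((3, 3), 10, dtype=int)
        with pytest.raises(ValueError, match="clusters"):
            extract_core_clusters(self.make_cc(counts, n_groups=10), 4, 8)


class TestRunINMF:
    def test_recovers_planted_hierarchy(self):
        from sklearn.metrics import adjusted_rand_score

        expr, truth = small_synthetic()
        res = run_inmf(expr, SMALL_CFG)
        tf = truth.to_frame()
        af = res.assignment.frame.loc[tf.index]
        assert adjusted_rand_score(tf["type"], af["type"]) >= 0.95
        assert adjusted_rand_score(tf["subtype"], af["subtype"]) >= 0.9
        assert res.level1.modal_k == 2

    def test_deterministic_under_seed(self):
        expr, _ = small_synthetic(seed=4)
        res1 = run_inmf(expr, SMALL_CFG)
        res2 = run_inmf(expr, SMALL_CFG)
        pd.testing.assert_frame_equal(res1.assignment.frame, res2.assignment.frame)
        assert res1.level1.per_group_ranks == res2.level1.per_group_ranks
        np.testing.assert_array_equal(res1.level1.cocluster.counts, res2.level1.cocluster.counts)

    def test_homogeneous_noise_flags_weak_structure(self):
        rng = np.random.default_rng(12)
        data = pd.DataFrame(
            np.clip(rng.normal(7, 1, (400, 30)), 0, None),
            index=[f"p{i}" for i in range(400)],
            columns=[f"s{i}" for i in range(30)],
        )
        cfg = INMFConfig(
            n_groups=10, group_size=60, core_threshold=8, seed=2,
            ranks=(2, 3), n_runs=5, min_cluster_size=8, n_top_variance=400,
        )
        try:
            res = run_inmf(ExpressionMatrix(data), cfg)
        except WeakStructureError as err:
            assert err.max_cophenetic is None or err.max_cophenetic < 1.0
        else:
            assert res.level1.weak_structure
            assert res.provenance["max_cophenetic_level1"] < 0.98

    def test_core_stability_under_more_groups(self):
        from sklearn.metrics import adjusted_rand_score

        expr, _ = small_synthetic(seed=9)
        cfg_small = SMALL_CFG
        cfg_big = INMFConfig(
            n_groups=60, group_size=80, core_threshold=48, seed=1,
            ranks=(2, 3), n_runs=5, min_cluster_size=8, n_top_variance=500,
        )
        res_a = run_inmf(expr, cfg_small)
        res_b = run_inmf(expr, cfg_big)
        la, lb = res_a.core_labels(), res_b.core_labels()
        common = sorted(set(la) & set(lb))
        assert len(common) >= 20
        ari = adjusted_rand_score([la[s] for s in common], [lb[s] for s in common])
        assert ari >= 0.95

    def test_nested_level2_labels(self):
        expr, _ = small_synthetic(seed=5)
        res = run_inmf(expr, SMALL_CFG)
        for _, row in res.assignment.frame.iterrows():
            if row["subtype"]:
                assert row["subtype"].startswith(row["type"] + ".")

    def test_negative_input_rejected(self):
        data = pd.DataFrame(-np.ones((20, 10)))
        with pytest.raises(ValueError, match="nonnegative"):
            run_inmf(ExpressionMatrix(data), SMALL_CFG)
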