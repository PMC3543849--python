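import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from crcsubtype import (
    ExpressionMatrix,
    SubtypeModel,
    SyntheticConfig,
    compare_stratifications,
    generate_hierarchical_expression,
    label_clusters,
    pearson_complete_clustering,
    two_step_assign,
)


def truth_model(truth):
    """SubtypeModel built directly from planted signature blocks."""
    return SubtypeModel(
        level1={t: list(sig) for t, sig in truth.type_signatures.items()},
        level2={
            t: {
                sub: list(truth.subtype_signatures[sub])
                for sub in subs
            }
            for t, subs in {"1": ("1.1", "1.2", "1.3"), "2": ("2.1", "2.2")}.items()
        },
    )


class TestPearsonCompleteClustering:
    def test_orthogonal_patterns_cocluster_copies(self):
        a = [1.0, 5.0, 1.0, 5.0, 1.0]
        b = [5.0, 1.0, 5.0, 1.0, 5.0]
        data = pd.DataFrame(
            np.column_stack([a, a, b, b]), columns=["a1", "a2", "b1", "b2"]
        )
        out = pearson_complete_clustering(ExpressionMatrix(data), 2)
        assert out["a1"] == out["a2"]
        assert out["b1"] == out["b2"]
        assert out["a1"] != out["b1"]

    def test_identical_samples_always_cocluster(self, rng):
        base = rng.normal(0, 1, 20)
        data = pd.DataFrame(
            np.column_stack([base, base, rng.normal(0, 1, (20, 3)).T.reshape(20, 3)]),
            columns=["dup1", "dup2", "x", "y", "z"],
        )
        for k in (2, 3, 4):
            out = pearson_complete_clustering(ExpressionMatrix(data), k)
            assert out["dup1"] == out["dup2"]

    def test_matches_exhaustive_complete_linkage(self, rng):
        data = pd.DataFrame(rng.normal(0, 1, (12, 7)), columns=[f"s{i}" for i in range(7)])
        got = pearson_complete_clustering(ExpressionMatrix(data), 3)
        # independent naive complete-linkage agglomeration on 1 - correlation
        D = 1 - np.corrcoef(data.to_numpy().T)
        clusters = [{i} for i in range(7)]
        while len(clusters) > 3:
            best = None
            for i, j in itertools.combinations(range(len(clusters)), 2):
                d = max(D[a, b] for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
            _, i, j = best
            clusters[i] |= clusters[j]
            del clusters[j]
        expected = {}
        for ci, members in enumerate(clusters):
            for m in members:
                expected[f"s{m}"] = ci
        same_expected = np.array(
            [[expected[a] == expected[b] for a in got.index] for b in got.index]
        )
        same_got = np.array([[got[a] == got[b] for a in got.index] for b in got.index])
        np.testing.assert_array_equal(same_got, same_expected)

    def test_zero_variance_sample_named(self):
        data = pd.DataFrame(
            {"ok": [1.0, 2.0, 3.0], "flat": [4.0, 4.0, 4.0], "ok2": [3.0, 1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="flat"):
            pearson_complete_clustering(ExpressionMatrix(data), 2)


class TestLabelClusters:
    def make_signature_data(self, swap=False):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 0.1, (40, 8))
        X[:10, :4] += 3.0   # sigA probes high in first 4 samples
        X[10:20, 4:] += 3.0  # sigB probes high in last 4
        data = pd.DataFrame(X, index=[f"p{i}" for i in range(40)], columns=[f"s{i}" for i in range(8)])
        clusters = pd.Series([1, 1, 1, 1, 2, 2, 2, 2], index=data.columns)
        sigs = {"A": [f"p{i}" for i in range(10)], "B": [f"p{i}" for i in range(10, 20)]}
        if swap:
            sigs = {"A": sigs["B"], "B": sigs["A"]}
        return ExpressionMatrix(data), clusters, sigs

    def test_overexpressed_signature_wins(self):
        expr, clusters, sigs = self.make_signature_data()
        assert label_clusters(expr, clusters, sigs) == {1: "A", 2: "B"}

    def test_swapped_patterns_swap_labels(self):
        expr, clusters, sigs = self.make_signature_data(swap=True)
        assert label_clusters(expr, clusters, sigs) == {1: "B", 2: "A"}

    def test_greedy_matches_best_bipartite_assignment(self, rng):
        # well-separated random planted data: greedy equals exhaustive optimum
        X = rng.normal(0, 0.1, (30, 9))
        for c, block in enumerate([(0, 3), (3, 6), (6, 9)]):
            X[c * 10 : (c + 1) * 10, block[0] : block[1]] += 4.0
        data = pd.DataFrame(X, index=[f"p{i}" for i in range(30)], columns=[f"s{i}" for i in range(9)])
        clusters = pd.Series([1, 1, 1, 2, 2, 2, 3, 3, 3], index=data.columns)
        sigs = {lab: [f"p{i}" for i in range(c * 10, (c + 1) * 10)] for c, lab in enumerate("XYZ")}
        got = label_clusters(ExpressionMatrix(data), clusters, sigs)
        centered = data.sub(data.mean(axis=1), axis=0)
        score = {
            (c, lab): centered.loc[sigs[lab], clusters.index[clusters == c]].to_numpy().mean()
            for c in (1, 2, 3)
            for lab in "XYZ"
        }
        best_perm = max(
            itertools.permutations("XYZ"),
            key=lambda perm: sum(score[(c, lab)] for c, lab in zip((1, 2, 3), perm)),
        )
        assert got == dict(zip((1, 2, 3), best_perm))

    def test_mismatched_counts_raise(self):
        expr, clusters, sigs = self.make_signature_data()
        with pytest.raises(ValueError, match="one-to-one"):
            label_clusters(expr, clusters, {"A": sigs["A"]})


@pytest.fixture(scope="module")
def planted():
    cfg = SyntheticConfig(
        samples_per_subtype=10,
        n_probes=1200,
        type_signature_size=100,
        subtype_signature_size=100,
        seed=21,
    )
    expr, truth = generate_hierarchical_expression(cfg)
    return expr, truth, truth_model(truth)


class TestTwoStepAssign:
    def test_planted_templates_assigned_correctly(self, planted):
        expr, truth, model = planted
        assignment = two_step_assign(expr, model)
        tf = truth.to_frame()
        af = assignment.frame.loc[tf.index]
        correct = (af["subtype"] == tf["subtype"]).mean()
        assert correct >= 0.95

    def test_duplicated_sample_gets_identical_labels(self, planted):
        expr, _, model = planted
        data = expr.data.copy()
        data["dup_of_first"] = data.iloc[:, 0]
        assignment = two_step_assign(ExpressionMatrix(data), model)
        first = assignment.frame.iloc[0]
        dup = assignment.frame.loc["dup_of_first"]
        assert (first["type"], first["subtype"]) == (dup["type"], dup["subtype"])

    def test_extra_probes_do_not_change_assignment(self, planted, rng):
        expr, _, model = planted
        assignment = two_step_assign(expr, model)
        extra = pd.DataFrame(
            rng.uniform(0, 10, (50, expr.shape[1])),
            index=[f"extra{i}" for i in range(50)],
            columns=expr.sample_ids,
        )
        bigger = ExpressionMatrix(pd.concat([expr.data, extra]))
        assignment2 = two_step_assign(bigger, model)
        pd.testing.assert_frame_equal(assignment.frame, assignment2.frame)

    def test_sample_order_invariance(self, planted, rng):
        expr, _, model = planted
        perm = list(rng.permutation(expr.sample_ids))
        shuffled = ExpressionMatrix(expr.data[perm])
        a1 = two_step_assign(expr, model).frame
        a2 = two_step_assign(shuffled, model).frame
        pd.testing.assert_frame_equal(a1.sort_index(), a2.sort_index())

    def test_low_coverage_raises_listing_missing(self, planted):
        expr, _, model = planted
        keep = [p for p in expr.probe_ids if p not in set(model.level1["1"][:80])]
        reduced = expr.subset(probes=keep)
        with pytest.raises(ValueError, match="coverage"):
            two_step_assign(reduced, model, min_coverage=0.5)

    def test_model_json_round_trip(self, planted, tmp_path):
        _, _, model = planted
        path = tmp_path / "model.json"
        model.to_json(path)
        back = SubtypeModel.from_json(path)
        assert back.level1 == model.level1
        assert back.level2 == model.level2


class TestCompareStratifications:
    def test_identical_binary_labelings(self):
        labels = {f"s{i}": ("A" if i < 10 else "B") for i in range(20)}
        p = compare_stratifications(labels, labels)
        # closed form: two-sided Fisher for the 10/0|0/10 table
        table_p = 1 / sps.hypergeom(20, 10, 10).pmf(10) ** -1
        assert p < 1e-4
        assert p == pytest.approx(2 * table_p, rel=1e-6)

    def test_swapped_labels_same_p(self):
        a = {f"s{i}": ("A" if i < 10 else "B") for i in range(20)}
        b = {s: ("B" if v == "A" else "A") for s, v in a.items()}
        assert compare_stratifications(a, a) == pytest.approx(compare_stratifications(a, b))

    def test_null_pvalues_roughly_uniform_multiclass(self):
        rng = np.random.default_rng(5)
        pvals = []
        for seed in range(100):
            a = {f"s{i}": str(rng.integers(0, 3)) for i in range(60)}
            b = {f"s{i}": str(rng.integers(0, 3)) for i in range(60)}
            try:
                pvals.append(compare_stratifications(a, b, n_sim=499, seed=seed))
            except ValueError:
                continue  # degenerate single-class draw
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_single_class_raises(self):
        a = {"s1": "A", "s2": "A"}
        b = {"s1": "X", "s2": "Y"}
        with pytest.raises(ValueError, match="classes"):
            compare_stratifications(a, b)

    def test_planted_association_detected_multiclass(self):
        rng = np.random.default_rng(7)
        a = {f"s{i}": str(i % 3) for i in range(45)}
        b = {f"s{i}": str(i % 3) if rng.uniform() < 0.8 else str(rng.integers(0, 3)) for i in range(45)}
        p = compare_stratifications(a, b, n_sim=999, seed=1)
        assert p < 0.01
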