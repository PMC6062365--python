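"""Metric arithmetic, paired comparisons, AUC, AD profiling, Mantel tests,
importance aggregation and neighbor contrasts."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from toxtriad.evaluation import (
    ad_profile,
    aggregate_importance,
    confusion_metrics,
    mantel_test,
    neighbor_contrast,
    paired_improvement,
    roc_auc,
    summarize,
)
from toxtriad.modeling import ModelResult
from toxtriad.preprocessing import PreprocessState


def make_result(repeat, fold, truth, pred, combo=("chemical",), p_toxic=None,
                kept_rows=(), importances=None):
    """Minimal ModelResult for evaluation-layer tests."""
    ids = [f"e{repeat}_{fold}_{i}" for i in range(len(truth))]
    preds = pd.DataFrame(
        {
            "truth": truth,
            "prediction": pred,
            "p_toxic": p_toxic if p_toxic is not None else list(pred),
        },
        index=pd.Index(ids, name="compound_id"),
    )
    return ModelResult(
        repeat=repeat,
        fold=fold,
        combo=combo,
        predictions=preds,
        state=PreprocessState({}, {}, list(kept_rows)),
        importances=importances if importances is not None else pd.Series(dtype=float),
        seed=0,
    )


class TestConfusionMetrics:
    def test_reference_operating_point(self):
        # sensitivity 0.72 and selectivity 0.84 average to CCR 0.78
        truth = np.array([1] * 100 + [0] * 100)
        pred = np.array([1] * 72 + [0] * 28 + [0] * 84 + [1] * 16)
        sens, sel, ccr = confusion_metrics(truth, pred)
        assert (sens, sel, ccr) == (0.72, 0.84, 0.78)

    def test_perfect_predictions(self):
        sens, sel, ccr = confusion_metrics([1, 0, 1, 0], [1, 0, 1, 0])
        assert (sens, sel, ccr) == (1.0, 1.0, 1.0)

    def test_hand_counted_table(self):
        # truth (T,T,N,N), pred (T,N,N,N): sens 0.5, sel 1.0, CCR 0.75
        assert confusion_metrics([1, 1, 0, 0], [1, 0, 0, 0]) == (0.5, 1.0, 0.75)

    def test_single_class_truth_fails(self):
        with pytest.raises(ValueError, match="both classes"):
            confusion_metrics([1, 1], [1, 0])


class TestSummarize:
    def test_identical_cells_have_zero_sd(self):
        results = [make_result(r, f, [1, 1, 0, 0], [1, 0, 0, 0])
                   for r in range(2) for f in range(2)]
        s = summarize(results)
        assert s.mean["ccr"] == 0.75
        assert s.sd["ccr"] == 0.0

    def test_mean_matches_independent_recomputation(self):
        rng = np.random.default_rng(0)
        results = []
        expected = []
        for r in range(3):
            truth = [1] * 5 + [0] * 5
            pred = list((rng.random(10) < 0.7).astype(int))
            results.append(make_result(r, 0, truth, pred))
            expected.append(confusion_metrics(truth, pred)[2])
        s = summarize(results)
        assert s.mean["ccr"] == pytest.approx(np.mean(expected))

    def test_ccr_identity_holds_per_cell(self):
        rng = np.random.default_rng(1)
        results = [
            make_result(r, 0, [1] * 6 + [0] * 6, list((rng.random(12) < 0.6).astype(int)))
            for r in range(4)
        ]
        s = summarize(results)
        assert (
            s.per_cell["ccr"]
            == 0.5 * (s.per_cell["sensitivity"] + s.per_cell["selectivity"])
        ).all()

    def test_mixed_combos_rejected(self):
        results = [make_result(0, 0, [1, 0], [1, 0], combo=("chemical",)),
                   make_result(0, 1, [1, 0], [1, 0], combo=("target",))]
        with pytest.raises(ValueError, match="mixed"):
            summarize(results)


class TestPairedImprovement:
    def _cells(self, n_cells=100, miss_one=False):
        a_results, b_results = [], []
        truth = [1] * 5 + [0] * 5
        perfect = [1] * 5 + [0] * 5
        for i in range(n_cells):
            r, f = divmod(i, 5)
            a_results.append(make_result(r, f, truth, perfect))
            pred_b = list(perfect)
            if miss_one and i == 0:
                pred_b[0] = 0  # sens 0.8 -> CCR 0.9: delta exactly 0.1
            b_results.append(make_result(r, f, truth, pred_b))
        return a_results, b_results

    def test_self_comparison_is_null(self):
        a, _ = self._cells(10)
        rec = paired_improvement(a, a)
        assert rec.mean == 0.0
        assert rec.p_value == 1.0

    def test_single_spike_mean_and_se(self):
        a, b = self._cells(100, miss_one=True)
        rec = paired_improvement(a, b)
        assert rec.mean == pytest.approx(0.001, abs=1e-15)
        assert rec.se == pytest.approx(0.001, abs=1e-6)

    def test_mismatched_plans_rejected(self):
        a, b = self._cells(10)
        # different held-out compounds in one cell
        b[0].predictions.index = pd.Index(
            [f"other{i}" for i in range(10)], name="compound_id"
        )
        with pytest.raises(ValueError, match="split plans"):
            paired_improvement(a, b)


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_four_point_toy_matches_pair_count(self):
        truth = [1, 0, 1, 0]
        score = [0.9, 0.6, 0.5, 0.2]
        # pairs (pos, neg): (0.9,0.6)+ (0.9,0.2)+ (0.5,0.6)- (0.5,0.2)+ -> 3/4
        assert roc_auc(truth, score) == 0.75

    def test_ties_count_half(self):
        assert roc_auc([1, 0], [0.5, 0.5]) == 0.5

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        truth = rng.integers(0, 2, size=50)
        truth[0], truth[1] = 0, 1
        s = rng.random(50)
        assert roc_auc(truth, s) == roc_auc(truth, np.exp(5 * s))


class TestADProfile:
    def test_external_compound_at_zero_distance_lands_in_first_bin(self):
        idx = pd.Index(["m1", "m2", "e1", "e2"], name="compound_id")
        chem = pd.DataFrame({"x": [0.0, 1.0, 0.0, 10.0]}, index=idx)
        r = make_result(0, 0, [1, 0], [1, 0])
        r.predictions.index = pd.Index(["e1", "e2"], name="compound_id")
        r.state.kept_rows = ["m1", "m2"]
        profile = ad_profile({("chemical",): [r]}, chem, n_bins=2)
        d = profile.distances.set_index("compound_id")["distance"]
        assert d["e1"] == 0.0 and d["e2"] == 9.0
        bins = profile.distances.set_index("compound_id")["bin"]
        assert bins["e1"] == 0 and bins["e2"] == 1

    def test_distances_use_each_cells_own_modeling_set(self):
        """Guard: the same external compound must get different distances in
        cells with different modelling sets."""
        idx = pd.Index(["m1", "m2", "e1"], name="compound_id")
        chem = pd.DataFrame({"x": [0.0, 5.0, 1.0]}, index=idx)
        r1 = make_result(0, 0, [1, 0], [1, 0])
        r1.predictions = r1.predictions.iloc[:1]
        r1.predictions.index = pd.Index(["e1"], name="compound_id")
        r1.state.kept_rows = ["m1"]
        r2 = make_result(0, 1, [1, 0], [1, 0])
        r2.predictions = r2.predictions.iloc[:1]
        r2.predictions.index = pd.Index(["e1"], name="compound_id")
        r2.state.kept_rows = ["m2"]
        profile = ad_profile({("chemical",): [r1, r2]}, chem, n_bins=2)
        d = profile.distances.set_index(["repeat", "fold"])["distance"]
        assert d.loc[(0, 0)] == 1.0  # |1 - 0|
        assert d.loc[(0, 1)] == 4.0  # |1 - 5|

    def test_empty_bin_reported_missing(self):
        idx = pd.Index(["m1", "e1"], name="compound_id")
        chem = pd.DataFrame({"x": [0.0, 1.0]}, index=idx)
        r = make_result(0, 0, [1, 0], [1, 0])
        r.predictions = r.predictions.iloc[:1]
        r.predictions.index = pd.Index(["e1"], name="compound_id")
        r.state.kept_rows = ["m1"]
        profile = ad_profile({("chemical",): [r]}, chem, n_bins=3)
        assert profile.per_bin["ccr"].isna().all()  # one-class bins are NaN


class TestMantel:
    @staticmethod
    def _dist(v):
        from scipy.spatial.distance import pdist, squareform

        return squareform(pdist(np.asarray(v, dtype=float).reshape(-1, 1)))

    def test_self_correlation_is_one(self):
        A = self._dist([1, 4, 2, 8, 5])
        res = mantel_test(A, A, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_independent_matrices_near_zero(self):
        rng = np.random.default_rng(0)
        from scipy.spatial.distance import pdist, squareform

        A = squareform(pdist(rng.normal(size=(40, 3))))
        B = squareform(pdist(rng.normal(size=(40, 3))))
        res = mantel_test(A, B, n_perm=199, seed=1)
        assert abs(res.r) < 0.15
        assert res.p_value > 0.05

    def test_exhaustive_p_matches_manual_enumeration(self):
        A = self._dist([1.0, 4.0, 2.0, 8.0, 5.0])
        B = self._dist([2.0, 3.0, 7.0, 1.0, 6.0])
        res = mantel_test(A, B, exhaustive=True)
        iu = np.triu_indices(5, k=1)
        count = 0
        for perm in itertools.permutations(range(5)):
            p = np.asarray(perm)
            r = np.corrcoef(A[iu], B[np.ix_(p, p)][iu])[0, 1]
            if r >= res.r - 1e-12:
                count += 1
        assert res.n_permutations == 120
        assert res.p_value == pytest.approx(count / 120)

    def test_agrees_with_reference_implementation(self):
        from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

        rng = np.random.default_rng(7)
        from scipy.spatial.distance import pdist, squareform

        X = rng.normal(size=(15, 2))
        A = squareform(pdist(X))
        B = squareform(pdist(X + 0.5 * rng.normal(size=(15, 2))))
        ours = mantel_test(A, B, n_perm=999, seed=0)
        theirs_r, theirs_p, _ = skbio_mantel(
            DistanceMatrix(A), DistanceMatrix(B), method="pearson",
            permutations=999, alternative="greater",
        )
        assert ours.r == pytest.approx(float(theirs_r), abs=1e-12)
        assert ours.p_value == pytest.approx(float(theirs_p), abs=0.05)

    def test_symmetry_in_arguments(self):
        A = self._dist([1, 4, 2, 8, 5, 3])
        B = self._dist([2, 3, 7, 1, 6, 9])
        assert mantel_test(A, B, n_perm=9, seed=0).r == pytest.approx(
            mantel_test(B, A, n_perm=9, seed=0).r
        )

    def test_asymmetric_input_rejected(self):
        M = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            mantel_test(M, M)


class TestImportanceAggregation:
    def test_single_model_range_scaling(self):
        imp = pd.Series([2.0, 4.0, 6.0], index=["a", "b", "c"])
        r = make_result(0, 0, [1, 0], [1, 0], importances=imp)
        domains = pd.Series({"a": "chemical", "b": "target", "c": "cytotox"})
        table = aggregate_importance([r], domains)
        got = table.set_index("descriptor")["average_importance"]
        assert got["a"] == 0.0 and got["b"] == 50.0 and got["c"] == 100.0

    def test_average_skips_models_lacking_the_descriptor(self):
        r1 = make_result(0, 0, [1, 0], [1, 0],
                         importances=pd.Series([1.0, 0.0], index=["a", "b"]))
        r2 = make_result(0, 1, [1, 0], [1, 0],
                         importances=pd.Series([0.0, 1.0], index=["a", "c"]))
        domains = pd.Series({"a": "chemical", "b": "chemical", "c": "chemical"})
        table = aggregate_importance([r1, r2], domains).set_index("descriptor")
        assert table.loc["a", "average_importance"] == 50.0
        assert table.loc["a", "n_models"] == 2
        assert table.loc["b", "n_models"] == 1


class TestNeighborContrast:
    def _blocks(self):
        idx = pd.Index(["q", "n1", "n2", "n3"], name="compound_id")
        chem = pd.DataFrame({"x": [0.0, 0.1, 0.2, 5.0]}, index=idx)
        target = pd.DataFrame(
            {"t1": [1.0, 1.0, 1.0, 1.0], "t2": [2.0, 2.0, 2.0, 2.0], "t3": [0.5, 0.5, 0.5, 0.5]},
            index=idx,
        )
        labels = pd.Series([1, 0, 0, 0], index=idx)
        return chem, target, labels

    def test_identical_scores_break_ties_by_target_id(self):
        chem, target, labels = self._blocks()
        table = neighbor_contrast("q", chem, target, labels, k=2, m=2)
        first = table[table.neighbor_id == "n1"].sort_values("rank")
        assert first["target_id"].tolist() == ["t1", "t2"]
        assert (first["score_increase"] == 0.0).all()

    def test_perturbed_target_tops_the_list(self):
        chem, target, labels = self._blocks()
        target.loc["n1", "t3"] -= 0.4
        table = neighbor_contrast("q", chem, target, labels, k=1, m=3)
        assert table.sort_values("rank")["target_id"].iloc[0] == "t3"

    def test_recurring_targets_flagged(self):
        chem, target, labels = self._blocks()
        for n in ("n1", "n2", "n3"):
            target.loc[n, "t2"] -= 1.0
        table = neighbor_contrast("q", chem, target, labels, k=3, m=1, flag_threshold=3)
        assert (table["target_id"] == "t2").all()
        assert table["flagged"].all()

    def test_too_few_neighbors_warns(self):
        chem, target, labels = self._blocks()
        with pytest.warns(UserWarning, match="eligible neighbors"):
            table = neighbor_contrast("q", chem, target, labels, k=5, m=1)
        assert table["neighbor_id"].nunique() == 3

    def test_nontoxic_query_rejected(self):
        chem, target, labels = self._blocks()
        with pytest.raises(ValueError, match="toxic"):
            neighbor_contrast("n1", chem, target, labels)
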