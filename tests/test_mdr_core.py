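import numpy as np
import pytest
from scipy.special import xlogy

from modemdr import mdr_core
from modemdr.data_io import CVFoldAssignment, GenotypeMatrix, balanced_cv_split
from modemdr.mdr_core import (
    EMPTY,
    HIGH,
    LOW,
    ConfusionCounts,
    ContingencyCells,
    ccr,
    chi2_significance,
    classify_cells,
    confusion_counts,
    evaluate_batch,
    evaluate_combination,
    nmi,
    tabulate_cells,
)
from modemdr.mdr_core import testing_ratio as theta_testing
from modemdr.mdr_core import training_ratio as theta_training


def make_cells(train_cases, train_controls, test_cases=None, test_controls=None):
    tc = np.asarray(train_cases)
    t0 = np.asarray(train_controls)
    return ContingencyCells(
        train_cases=tc,
        train_controls=t0,
        test_cases=np.asarray(test_cases if test_cases is not None else np.zeros_like(tc)),
        test_controls=np.asarray(test_controls if test_controls is not None else np.zeros_like(t0)),
        n_plus1=int(tc.sum()),
        n_plus0=int(t0.sum()),
    )


def entropy_route_nmi(c: ConfusionCounts) -> float:
    """Independent oracle: NMI from the H(y), H(y|x) entropy definitions."""
    table = np.array([[c.TP, c.FP], [c.FN, c.TN]], dtype=float)  # x rows, y cols
    n = table.sum()
    if n == 0:
        return 0.0
    p = table / n
    py = p.sum(axis=0)
    h_y = -sum(xlogy(v, v) for v in py) / np.log(2)
    px = p.sum(axis=1)
    h_yx = 0.0
    for i in range(2):
        if px[i] > 0:
            cond = p[i] / px[i]
            h_yx += px[i] * (-sum(xlogy(v, v) for v in cond) / np.log(2))
    if h_y <= 0:
        return 0.0
    return (h_y - h_yx) / h_y


class TestTabulation:
    def test_hand_tally_single_snp(self, toy_data):
        # folds: samples 0,3 -> fold 1 (test); rest train
        folds = CVFoldAssignment(np.array([1, 2, 3, 1, 2, 3]), 3)
        cells = tabulate_cells(toy_data, (0,), folds, test_fold=1)
        # training samples: idx 1,2 cases (g0 = 1,2), idx 4,5 controls (1,2)
        assert cells.train_cases.tolist() == [0, 1, 1]
        assert cells.train_controls.tolist() == [0, 1, 1]
        assert cells.test_cases.tolist() == [1, 0, 0]
        assert cells.test_controls.tolist() == [1, 0, 0]
        assert cells.n_plus1 == 2 and cells.n_plus0 == 2

    def test_cell_sums_conserve_fold_sizes(self, null_data, folds_of):
        folds = folds_of(null_data)
        cells = tabulate_cells(null_data, (2, 7), folds, test_fold=3)
        n_test = int(folds.test_mask(3).sum())
        assert (
            cells.test_cases.sum() + cells.test_controls.sum() == n_test
        )
        assert (
            cells.train_cases.sum() + cells.train_controls.sum()
            == null_data.n_samples - n_test
        )

    def test_two_locus_combo_has_nine_cells(self, null_data, folds_of):
        cells = tabulate_cells(null_data, (0, 1), folds_of(null_data), 1)
        assert cells.n_cells == 9

    def test_invalid_fold_rejected(self, null_data, folds_of):
        with pytest.raises(ValueError):
            tabulate_cells(null_data, (0, 1), folds_of(null_data), 9)


class TestRatios:
    def test_balanced_theta_training(self):
        cells = make_cells([3, 5], [1, 7])  # n_+1 = 8, n_+0 = 8
        assert theta_training(cells, 0) == pytest.approx(3.0)

    def test_unbalanced_correction(self):
        cells = make_cells([5, 45], [10, 140])  # n_+1 = 50, n_+0 = 150
        assert theta_training(cells, 0) == pytest.approx(1.5)

    def test_empty_cell_is_nan_pure_case_cell_is_inf(self):
        cells = make_cells([0, 4, 1], [0, 4, 0])
        assert np.isnan(theta_training(cells, 0))
        assert theta_training(cells, 2) == np.inf

    def test_testing_ratio_uses_training_margins(self):
        cells = make_cells([100, 200], [50, 50], [6, 0], [1, 4])
        # n_+0 = 100, n_+1 = 300 -> theta = (100*6)/(300*1) = 2
        assert theta_testing(cells, 0) == pytest.approx(2.0)
        assert theta_testing(cells, 1) == pytest.approx(0.0)

    def test_balanced_testing_ratio_of_even_cell_is_one(self):
        cells = make_cells([4, 4], [4, 4], [2, 1], [2, 3])
        assert theta_testing(cells, 0) == pytest.approx(1.0)


class TestClassification:
    def test_exact_tie_is_high(self):
        cells = make_cells([2, 1], [2, 3])  # cell 0: ratio exactly 1
        labels = classify_cells(cells).labels
        assert labels[0] == HIGH and labels[1] == LOW

    def test_just_below_one_is_low(self):
        cells = make_cells([99, 101], [100, 100])
        assert classify_cells(cells).labels[0] == LOW

    def test_all_empty_training_gives_all_empty(self):
        cells = make_cells([0, 0], [0, 0], [1, 1], [1, 1])
        assert (classify_cells(cells).labels == EMPTY).all()

    def test_empty_cell_low_policy(self):
        cells = make_cells([0, 1], [0, 1])
        assert classify_cells(cells, empty_cell="low").labels[0] == LOW


class TestConfusionAndMeasures:
    def test_two_cell_toy(self):
        cells = make_cells([5, 1], [1, 5], [3, 1], [1, 4])
        counts = confusion_counts(classify_cells(cells), cells)
        assert (counts.TP, counts.FP, counts.FN, counts.TN) == (3, 1, 1, 4)

    def test_all_high_labels_empty_negatives(self):
        cells = make_cells([5, 5], [1, 1], [2, 2], [3, 3])
        counts = confusion_counts(classify_cells(cells), cells)
        assert counts.FN == 0 and counts.TN == 0

    def test_empty_cells_excluded_from_counts(self):
        cells = make_cells([0, 5], [0, 1], [7, 1], [2, 1])
        counts = confusion_counts(classify_cells(cells), cells)
        assert counts.TP + counts.FP + counts.FN + counts.TN == 2

    @pytest.mark.parametrize(
        "counts,expected",
        [((10, 10, 10, 10), 0.5), ((30, 10, 20, 40), 0.7), ((5, 0, 0, 5), 1.0)],
    )
    def test_ccr_values(self, counts, expected):
        tp, fp, fn, tn = counts
        assert ccr(ConfusionCounts(tp, fp, fn, tn)) == pytest.approx(expected)

    def test_ccr_zero_denominator_contributes_zero(self):
        assert ccr(ConfusionCounts(3, 0, 1, 0)) == pytest.approx(0.5 * 0.75)

    def test_ccr_invariant_under_control_scaling(self, rng):
        for _ in range(100):
            tp, fp, fn, tn = rng.integers(1, 50, size=4)
            scaled = ConfusionCounts(tp, 3 * fp, fn, 3 * tn)
            assert ccr(ConfusionCounts(tp, fp, fn, tn)) == pytest.approx(
                ccr(scaled)
            )

    @pytest.mark.parametrize("k", [1, 4, 17])
    def test_nmi_zero_under_independence(self, k):
        assert nmi(ConfusionCounts(k, k, k, k)) == pytest.approx(0.0, abs=1e-12)

    def test_nmi_perfect_and_inverted_are_one(self):
        assert nmi(ConfusionCounts(5, 0, 0, 5)) == pytest.approx(1.0)
        # mutual information is symmetric: a perfectly wrong classifier is
        # equally informative
        assert nmi(ConfusionCounts(0, 5, 5, 0)) == pytest.approx(1.0)

    def test_nmi_single_class_fold_is_zero(self):
        assert nmi(ConfusionCounts(4, 0, 2, 0)) == 0.0

    def test_closed_form_matches_entropy_route(self, rng):
        """The log-sum closed form equals the H(y), H(y|x) composition on
        10^4 random confusion tables to 1e-12."""
        counts = rng.integers(0, 200, size=(10_000, 4))
        for tp, fp, fn, tn in counts:
            c = ConfusionCounts(int(tp), int(fp), int(fn), int(tn))
            assert nmi(c) == pytest.approx(entropy_route_nmi(c), abs=1e-12)
            assert 0.0 <= nmi(c) <= 1.0 + 1e-12


class TestEvaluateCombination:
    def test_perfect_predictor_is_perfect(self, perfect_data, folds_of):
        folds = folds_of(perfect_data, k=4)
        fp = evaluate_combination(perfect_data, (0,), folds)
        assert fp.ccr == pytest.approx(1.0)
        assert fp.nmi == pytest.approx(1.0)

    def test_null_combination_near_chance(self, folds_of):
        r = np.random.default_rng(41)
        g = r.integers(0, 3, size=(2000, 4))
        data = GenotypeMatrix(g, np.repeat([1, 0], 1000), list("abcd"))
        folds = folds_of(data)
        fp = evaluate_combination(data, (0, 1), folds)
        # chance level 0.5; generous 3-sigma band for a 400-sample test fold
        assert abs(fp.ccr - 0.5) < 0.1
        assert fp.nmi < 0.05

    def test_fold_relabeling_invariance(self, null_data, folds_of):
        folds = folds_of(null_data, k=4)
        relabel = {1: 3, 2: 1, 3: 4, 4: 2}
        perm = CVFoldAssignment(
            np.vectorize(relabel.get)(folds.fold_index), 4
        )
        a = evaluate_combination(null_data, (1, 5), folds)
        b = evaluate_combination(null_data, (1, 5), perm)
        assert a == pytest.approx(b)

    def test_never_nan_on_degenerate_data(self, folds_of):
        # one genotype column constant, tiny folds
        g = np.zeros((8, 2), dtype=int)
        g[:, 1] = [0, 1, 2, 0, 1, 2, 0, 1]
        data = GenotypeMatrix(g, np.repeat([1, 0], 4), ["a", "b"])
        folds = folds_of(data, k=2)
        for combo in [(0,), (1,), (0, 1)]:
            fp = evaluate_combination(data, combo, folds)
            assert np.isfinite(fp.ccr) and np.isfinite(fp.nmi)

    @pytest.mark.parametrize("rule", ["training", "joint"])
    @pytest.mark.parametrize("empty_cell", ["exclude", "low"])
    def test_batch_kernel_matches_stepwise_route(
        self, null_data, folds_of, rule, empty_cell
    ):
        """The vectorized kernel agrees with the step-by-step operations
        composed per fold."""
        folds = folds_of(null_data)
        combos = [(0, 1), (2, 9), (4, 5), (3,), (8,)]
        for combo in combos:
            ccrs, nmis = [], []
            for t in range(1, folds.k + 1):
                cells = tabulate_cells(null_data, combo, folds, t)
                if rule == "training":
                    labels = classify_cells(cells, empty_cell=empty_cell)
                    counts = confusion_counts(labels, cells)
                else:
                    counts = _joint_rule_counts(cells, empty_cell)
                ccrs.append(ccr(counts))
                nmis.append(nmi(counts))
            got = evaluate_combination(
                null_data, combo, folds, rule=rule, empty_cell=empty_cell
            )
            assert got.ccr == pytest.approx(np.mean(ccrs))
            assert got.nmi == pytest.approx(np.mean(nmis))

    def test_balanced_folds_preserve_global_ratio(self, folds_of):
        g = np.zeros((350, 2), dtype=int)
        g[:, 1] = 1
        data = GenotypeMatrix(g, np.repeat([1, 0], [150, 200]), ["a", "b"])
        folds = folds_of(data)
        for t in range(1, 6):
            cells = tabulate_cells(data, (0,), folds, t)
            assert abs(cells.n_plus1 - 150 * 4 / 5) <= 1
            assert abs(cells.n_plus0 - 200 * 4 / 5) <= 1


def _joint_rule_counts(cells, empty_cell):
    """Literal reading of the TP/FP/FN/TN sums: a cell contributes only when
    training and testing ratios agree on its risk side."""
    tp = fp = fn = tn = 0
    for a in range(cells.n_cells):
        tr_occ = cells.train_cases[a] + cells.train_controls[a] > 0
        te_occ = cells.test_cases[a] + cells.test_controls[a] > 0
        if empty_cell == "exclude" and not tr_occ:
            continue
        if not te_occ:
            continue
        tr_high = (
            cells.n_plus0 * cells.train_cases[a]
            >= cells.n_plus1 * cells.train_controls[a]
        ) and tr_occ
        te_high = (
            cells.n_plus0 * cells.test_cases[a]
            >= cells.n_plus1 * cells.test_controls[a]
        )
        if tr_high and te_high:
            tp += cells.test_cases[a]
            fp += cells.test_controls[a]
        elif not tr_high and not te_high:
            fn += cells.test_cases[a]
            tn += cells.test_controls[a]
    return ConfusionCounts(int(tp), int(fp), int(fn), int(tn))


class TestChi2:
    def test_matches_textbook_two_by_two(self):
        """A dataset engineered to pool into the 2x2 table (90,10 / 10,90)
        reproduces the closed-form Pearson statistic."""
        from scipy.stats import chi2 as chi2_dist

        g = np.zeros((200, 2), dtype=int)
        phen = np.repeat([1, 0], 100)
        # SNP 0 genotype 0 -> mostly cases (90/10); genotype 1 -> 10/90
        g[:, 0] = np.concatenate([np.repeat([0, 1], [90, 10]),
                                  np.repeat([0, 1], [10, 90])])
        g[:100, 1] = np.arange(100) % 3
        g[100:, 1] = np.arange(100) % 3
        data = GenotypeMatrix(g, phen, ["a", "b"])
        p = chi2_significance(data, (0,))
        expected_stat = 200 * (90 * 90 - 10 * 10) ** 2 / (100 * 100 * 100 * 100)
        assert p == pytest.approx(float(chi2_dist.sf(expected_stat, 1)))

    def test_perfect_separation_is_extreme(self, perfect_data):
        assert chi2_significance(perfect_data, (0,)) < 1e-10

    def test_degenerate_table_warns_and_returns_one(self):
        g = np.zeros((10, 2), dtype=int)
        g[:, 1] = 1
        data = GenotypeMatrix(g, np.repeat([1, 0], 5), ["a", "b"])
        with pytest.warns(RuntimeWarning):
            assert chi2_significance(data, (0,)) == 1.0

    def test_null_p_values_genotype_table_uniform_pooled_inflated(self):
        """Under independence the raw genotype-table p-value is uniform,
        while the pooled high/low table (labels fitted on the same data) is
        anticonservative - its null p-values pile up near zero."""
        from scipy.stats import kstest

        p_geno, p_pooled = [], []
        for rep in range(500):
            r = np.random.default_rng(1000 + rep)
            g = r.integers(0, 3, size=(2000, 2))
            data = GenotypeMatrix(g, np.repeat([1, 0], 1000), ["a", "b"])
            p_geno.append(chi2_significance(data, (0, 1), table="genotype"))
            p_pooled.append(chi2_significance(data, (0, 1)))
        assert kstest(p_geno, "uniform").pvalue > 0.01
        assert np.median(p_pooled) < 0.1  # selection bias of fitted pooling
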