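"""MDR contingency machinery and the two fitness measures (CCR, NMI).

For a d-SNP combination the samples fall into 3^d multifactor cells (three
genotype levels per locus). Within one CV round, each cell is labelled high
or low risk from the *training* case:control ratio

    theta_hat_a = (n_+0 * n_a1) / (n_+1 * n_a0),

where n_ab counts training samples of class b in cell a and n_+b is the
training class total; the n_+0/n_+1 factor corrects for unbalanced data so
the chance level sits at 1. Testing samples are then classified against the
training labels, giving TP/FP/FN/TN, from which the correct classification
rate (balanced accuracy)

    CCR = 0.5 * (TP/(TP+FN) + TN/(FP+TN))

and the normalized mutual information NMI = (H(y) - H(y|x)) / H(y) are
computed and averaged over folds.

Two APIs are provided: scalar step-by-step operations mirroring the
procedure above (tabulate_cells -> classify_cells -> confusion_counts ->
ccr/nmi), and a vectorized kernel (:func:`evaluate_batch`) used by the
search engine; tests pin the two routes to each other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats
from scipy.special import xlogy

from .data_io import CVFoldAssignment, GenotypeMatrix

HIGH, LOW, EMPTY = 1, 0, -1


class FitnessPair(NamedTuple):
    """The two objectives attached to a SNP combination."""

    ccr: float
    nmi: float


@dataclass
class ContingencyCells:
    """Per-cell case/control counts for one train/test split of one combo."""

    train_cases: np.ndarray
    train_controls: np.ndarray
    test_cases: np.ndarray
    test_controls: np.ndarray
    n_plus1: int  # total training cases
    n_plus0: int  # total training controls

    @property
    def n_cells(self) -> int:
        return self.train_cases.size


@dataclass
class RiskLabeling:
    """Per-cell risk label: HIGH (1), LOW (0) or EMPTY (-1)."""

    labels: np.ndarray


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int


def _cell_codes(data: GenotypeMatrix, combo: Sequence[int]) -> np.ndarray:
    combo = tuple(int(c) for c in combo)
    if len(set(combo)) != len(combo):
        raise ValueError(f"combo indices must be distinct, got {combo}")
    if any(not 0 <= c < data.n_snps for c in combo):
        raise ValueError(f"combo {combo} out of range for {data.n_snps} SNPs")
    codes = np.zeros(data.n_samples, dtype=np.int64)
    for c in combo:
        codes = codes * 3 + data.genotypes[:, c]
    return codes


def tabulate_cells(
    data: GenotypeMatrix,
    combo: Sequence[int],
    folds: CVFoldAssignment,
    test_fold: int,
) -> ContingencyCells:
    """Tally case/control counts per multifactor cell for one CV round.

    Training data is every fold except ``test_fold``.
    """
    codes = _cell_codes(data, combo)
    n_cells = 3 ** len(tuple(combo))
    test = folds.test_mask(test_fold)
    case = data.phenotype == 1

    def tally(mask: np.ndarray) -> np.ndarray:
        return np.bincount(codes[mask], minlength=n_cells)

    cells = ContingencyCells(
        train_cases=tally(~test & case),
        train_controls=tally(~test & ~case),
        test_cases=tally(test & case),
        test_controls=tally(test & ~case),
        n_plus1=int((~test & case).sum()),
        n_plus0=int((~test & ~case).sum()),
    )
    return cells


def training_ratio(cells: ContingencyCells, a: int) -> float:
    """Unbalance-corrected training ratio theta_hat_a.

    Returns +inf for a cell with cases but no controls and NaN for an empty
    cell (no training samples at all).
    """
    na1 = int(cells.train_cases[a])
    na0 = int(cells.train_controls[a])
    if na0 == 0:
        return np.nan if na1 == 0 else np.inf
    return (cells.n_plus0 * na1) / (cells.n_plus1 * na0)


def testing_ratio(cells: ContingencyCells, a: int) -> float:
    """Testing-data ratio theta_a; n_+b still come from the training data."""
    ta1 = int(cells.test_cases[a])
    ta0 = int(cells.test_controls[a])
    if ta0 == 0:
        return np.nan if ta1 == 0 else np.inf
    return (cells.n_plus0 * ta1) / (cells.n_plus1 * ta0)


def classify_cells(
    cells: ContingencyCells, empty_cell: str = "exclude"
) -> RiskLabeling:
    """Label each cell HIGH iff theta_hat_a >= 1, LOW otherwise.

    Cells with no training samples are EMPTY when ``empty_cell="exclude"``
    (the default) or LOW when ``empty_cell="low"``.
    """
    na1 = cells.train_cases.astype(np.int64)
    na0 = cells.train_controls.astype(np.int64)
    # integer cross-multiplication keeps theta_hat >= 1 exact and covers the
    # +inf case (na0 == 0, na1 > 0) without special-casing
    high = cells.n_plus0 * na1 >= cells.n_plus1 * na0
    labels = np.where(high, HIGH, LOW).astype(np.int64)
    empty = (na1 == 0) & (na0 == 0)
    if empty_cell == "exclude":
        labels[empty] = EMPTY
    elif empty_cell == "low":
        labels[empty] = LOW  # no evidence defaults to low risk
    else:
        raise ValueError(f"unknown empty_cell policy {empty_cell!r}")
    return RiskLabeling(labels)


def confusion_counts(
    labels: RiskLabeling, cells: ContingencyCells
) -> ConfusionCounts:
    """Classify testing samples against the training risk labels.

    Testing samples that fall in EMPTY-labelled cells are excluded.
    """
    high = labels.labels == HIGH
    low = labels.labels == LOW
    return ConfusionCounts(
        TP=int(cells.test_cases[high].sum()),
        FP=int(cells.test_controls[high].sum()),
        FN=int(cells.test_cases[low].sum()),
        TN=int(cells.test_controls[low].sum()),
    )


def ccr(c: ConfusionCounts) -> float:
    """Correct classification rate (balanced accuracy).

    A class term with zero denominator contributes 0, keeping the measure
    bounded and pessimistic on degenerate folds.
    """
    sens = c.TP / (c.TP + c.FN) if c.TP + c.FN > 0 else 0.0
    spec = c.TN / (c.FP + c.TN) if c.FP + c.TN > 0 else 0.0
    return 0.5 * (sens + spec)


def nmi(c: ConfusionCounts) -> float:
    """Normalized mutual information (H(y) - H(y|x)) / H(y) of the 2x2
    prediction-vs-status table, with 0 log 0 = 0 and NMI = 0 when H(y) = 0
    (single-class testing fold)."""
    tp, fp, fn, tn = float(c.TP), float(c.FP), float(c.FN), float(c.TN)
    n = tp + fp + fn + tn
    num = (
        xlogy(n, n)
        + xlogy(tp, tp) + xlogy(fn, fn) + xlogy(tn, tn) + xlogy(fp, fp)
        - xlogy(tp + fp, tp + fp) - xlogy(tp + fn, tp + fn)
        - xlogy(tn + fp, tn + fp) - xlogy(tn + fn, tn + fn)
    )
    den = xlogy(n, n) - xlogy(tp + fn, tp + fn) - xlogy(tn + fp, tn + fp)
    if den <= 0.0:
        return 0.0
    return float(min(max(num / den, 0.0), 1.0))  # clamp float round-off


def _counts_tensor(
    data: GenotypeMatrix,
    combos: np.ndarray,
    folds: CVFoldAssignment,
) -> np.ndarray:
    """Cell x class x fold counts for many combos in one bincount.

    Returns int64 array of shape ``(m, n_cells, 2, k)``; class axis is
    0 = control, 1 = case; fold axis is fold-1.
    """
    combos = np.asarray(combos, dtype=np.int64)
    m, d = combos.shape
    k = folds.k
    n_cells = 3 ** d
    codes = np.zeros((data.n_samples, m), dtype=np.int64)
    for t in range(d):
        codes = codes * 3 + data.genotypes[:, combos[:, t]]
    offs = data.phenotype * k + (folds.fold_index - 1)  # (n,) in [0, 2k)
    stride = n_cells * 2 * k
    idx = codes * (2 * k) + offs[:, None] + np.arange(m) * stride
    counts = np.bincount(idx.ravel(), minlength=m * stride)
    return counts.reshape(m, n_cells, 2, k)


def evaluate_batch(
    data: GenotypeMatrix,
    combos,
    folds: CVFoldAssignment,
    rule: str = "training",
    empty_cell: str = "exclude",
    return_training_ccr: bool = False,
    return_folds: bool = False,
):
    """Fold-averaged (CCR, NMI) for many combos at once.

    Parameters
    ----------
    combos
        Integer array-like of shape ``(m, d)``; indices within each row must
        be distinct.
    rule
        ``"training"`` (default): risk labels from training ratios only.
        ``"joint"``: a literal reading under which a cell contributes to
        TP/FP (resp. FN/TN) only when training and testing ratios agree on
        high (resp. low); disagreeing cells are dropped.
    return_training_ccr
        Also return the per-fold CCR of the *training* samples against their
        own labels, shape ``(m, k)`` (used by the exhaustive MDR comparator).
    return_folds
        Return per-fold ``(m, k)`` CCR and NMI arrays instead of means.

    Returns
    -------
    ``(ccr, nmi)`` arrays of shape ``(m,)`` (or ``(m, k)``), optionally
    followed by the training-CCR array.
    """
    combos = np.atleast_2d(np.asarray(combos, dtype=np.int64))
    for row in combos:
        if len(set(row.tolist())) != row.size:
            raise ValueError(f"combo indices must be distinct, got {tuple(row)}")
        if (row < 0).any() or (row >= data.n_snps).any():
            raise ValueError(f"combo {tuple(row)} out of range")
    if rule not in ("training", "joint"):
        raise ValueError(f"unknown rule {rule!r}")
    if empty_cell not in ("exclude", "low"):
        raise ValueError(f"unknown empty_cell policy {empty_cell!r}")
    counts = _counts_tensor(data, combos, folds)  # (m, c, 2, k)
    total = counts.sum(axis=3)
    test = counts
    train = total[..., None] - test
    tr_ctrl, tr_case = train[:, :, 0, :], train[:, :, 1, :]
    te_ctrl, te_case = test[:, :, 0, :], test[:, :, 1, :]
    n_tr_ctrl = tr_ctrl.sum(axis=1)[:, None, :]  # n_+0 per fold
    n_tr_case = tr_case.sum(axis=1)[:, None, :]  # n_+1 per fold
    high = n_tr_ctrl * tr_case >= n_tr_case * tr_ctrl
    if empty_cell == "exclude":
        occupied = (tr_case > 0) | (tr_ctrl > 0)
    else:
        occupied = np.ones_like(high)
        high &= (tr_case > 0) | (tr_ctrl > 0)  # empty -> LOW
    if rule == "training":
        in_high = high & occupied
        in_low = ~high & occupied
    else:
        te_high = n_tr_ctrl * te_case >= n_tr_case * te_ctrl
        te_occupied = (te_case > 0) | (te_ctrl > 0)
        in_high = high & te_high & occupied & te_occupied
        in_low = ~high & ~te_high & occupied & te_occupied
    tp = (te_case * in_high).sum(axis=1).astype(float)
    fp = (te_ctrl * in_high).sum(axis=1).astype(float)
    fn = (te_case * in_low).sum(axis=1).astype(float)
    tn = (te_ctrl * in_low).sum(axis=1).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        spec = np.where(fp + tn > 0, tn / np.maximum(fp + tn, 1), 0.0)
    ccr_folds = 0.5 * (sens + spec)

    n = tp + fp + fn + tn
    num = (
        xlogy(n, n)
        + xlogy(tp, tp) + xlogy(fn, fn) + xlogy(tn, tn) + xlogy(fp, fp)
        - xlogy(tp + fp, tp + fp) - xlogy(tp + fn, tp + fn)
        - xlogy(tn + fp, tn + fp) - xlogy(tn + fn, tn + fn)
    )
    den = xlogy(n, n) - xlogy(tp + fn, tp + fn) - xlogy(tn + fp, tn + fp)
    nmi_folds = np.clip(np.where(den > 0, num / np.maximum(den, 1e-300), 0.0), 0.0, 1.0)

    if return_folds:
        out = (ccr_folds, nmi_folds)
    else:
        out = (ccr_folds.mean(axis=1), nmi_folds.mean(axis=1))
    if return_training_ccr:
        tr_in_high = high & occupied
        tr_in_low = ~high & occupied
        ttp = (tr_case * tr_in_high).sum(axis=1).astype(float)
        tfp = (tr_ctrl * tr_in_high).sum(axis=1).astype(float)
        tfn = (tr_case * tr_in_low).sum(axis=1).astype(float)
        ttn = (tr_ctrl * tr_in_low).sum(axis=1).astype(float)
        tsens = np.where(ttp + tfn > 0, ttp / np.maximum(ttp + tfn, 1), 0.0)
        tspec = np.where(tfp + ttn > 0, ttn / np.maximum(tfp + ttn, 1), 0.0)
        out = out + (0.5 * (tsens + tspec),)
    return out


def evaluate_combination(
    data: GenotypeMatrix,
    combo: Sequence[int],
    folds: CVFoldAssignment,
    rule: str = "training",
    empty_cell: str = "exclude",
) -> FitnessPair:
    """Fold-averaged fitness pair of one SNP combination."""
    ccr_mean, nmi_mean = evaluate_batch(
        data, np.asarray([combo]), folds, rule=rule, empty_cell=empty_cell
    )
    return FitnessPair(float(ccr_mean[0]), float(nmi_mean[0]))


def chi2_significance(
    data: GenotypeMatrix,
    combo: Sequence[int],
    continuity: bool = False,
    table: str = "pooled",
) -> float:
    """Pearson chi-square p-value of the association between a SNP
    combination and case/control status on the full dataset (no CV).

    ``table="pooled"`` (default): cells are labelled high/low with the
    full-data ratio and pooled into a 2x2 high/low x case/control table
    (1 df). Because the labels are fitted on the same data, this statistic
    is anticonservative under the null - its p-values are *not* uniform -
    so it ranks candidate models rather than calibrates error rates.
    ``table="genotype"``: the raw (3^d)x2 genotype-by-status table, whose
    p-value is well calibrated under independence.

    If a margin of the table is empty the statistic is undefined; the
    function warns and returns p = 1.
    """
    codes = _cell_codes(data, combo)
    n_cells = 3 ** len(tuple(combo))
    case = data.phenotype == 1
    na1 = np.bincount(codes[case], minlength=n_cells)
    na0 = np.bincount(codes[~case], minlength=n_cells)
    n_plus1, n_plus0 = int(na1.sum()), int(na0.sum())
    if table == "pooled":
        high = (n_plus0 * na1 >= n_plus1 * na0) & ((na1 > 0) | (na0 > 0))
        low = ~high & ((na1 > 0) | (na0 > 0))
        table_arr = np.array(
            [
                [na1[high].sum(), na0[high].sum()],
                [na1[low].sum(), na0[low].sum()],
            ],
            dtype=np.int64,
        )
    elif table == "genotype":
        occupied = (na1 > 0) | (na0 > 0)
        table_arr = np.column_stack([na1[occupied], na0[occupied]])
    else:
        raise ValueError(f"unknown table kind {table!r}")
    if (table_arr.sum(axis=0) == 0).any() or (table_arr.sum(axis=1) == 0).any() \
            or table_arr.shape[0] < 2:
        warnings.warn(
            f"degenerate pooled table for combo {tuple(combo)}; p set to 1",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    result = stats.chi2_contingency(table_arr, correction=continuity)
    return float(result.pvalue)
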