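"""Exhaustive-search oracles, detection benchmarks and method comparison.

Provides a brute-force Pareto front over all d-SNP combinations (the ground
truth the stochastic search is checked against), the classic exhaustive MDR
comparator with cross-validation consistency (CVC), the detection-success-
rate protocol used in the simulation study, and a Wilcoxon signed-rank
summary for paired per-model rate comparisons.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import mdr_core, mode_engine
from .data_io import CVFoldAssignment, GenotypeMatrix, balanced_cv_split
from .mdr_core import FitnessPair
from .mode_engine import MODEConfig, TargetVector
from .simulator import SimulatedDataset, generate_pure_epistatic_model, simulate_dataset

COMBINATION_GUARD = 10**6


@dataclass
class DetectionResult:
    """Outcome of one detection attempt on one simulated dataset."""

    dataset_id: int
    detected: bool
    reported_pairs: list[tuple[tuple[int, ...], FitnessPair]]


def _all_combos(n_snps: int, d: int) -> np.ndarray:
    n_combos = math.comb(n_snps, d)
    if n_combos > COMBINATION_GUARD:
        raise ValueError(
            f"{n_combos} combinations exceed the enumeration guard "
            f"({COMBINATION_GUARD})"
        )
    return np.array(list(itertools.combinations(range(n_snps), d)), dtype=np.int64)


_CHUNK = 10_000


def _nondominated_mask(f: np.ndarray, dominance: str) -> np.ndarray:
    """Mask of points not dominated by any other, by plane sweep.

    ``f`` is ``(m, 2)``. Strict rule: dominated iff some point is strictly
    greater in both coordinates. Weak rule additionally counts ties in one
    coordinate with strict improvement in the other.
    """
    m = f.shape[0]
    order = np.lexsort((-f[:, 1], -f[:, 0]))  # ccr desc, nmi desc
    dominated = np.zeros(m, dtype=bool)
    best_nmi_strict = -np.inf  # max nmi among points with strictly higher ccr
    i = 0
    while i < m:
        j = i
        while j < m and f[order[j], 0] == f[order[i], 0]:
            j += 1
        group = order[i:j]
        if dominance == "strict":
            dominated[group] = f[group, 1] < best_nmi_strict
        else:
            dominated[group] = f[group, 1] <= best_nmi_strict
            # ties in ccr: dominated when another tied point has higher nmi
            group_max = f[group, 1].max()
            dominated[group] |= f[group, 1] < group_max
        best_nmi_strict = max(best_nmi_strict, f[group, 1].max())
        i = j
    return ~dominated


def exhaustive_pareto(
    data: GenotypeMatrix,
    d: int,
    folds: CVFoldAssignment,
    dominance: str = "strict",
    rule: str = "training",
    empty_cell: str = "exclude",
) -> list[TargetVector]:
    """Uncapped nondominated set over every d-SNP combination."""
    combos = _all_combos(data.n_snps, d)
    parts = [
        mdr_core.evaluate_batch(
            data, combos[i : i + _CHUNK], folds, rule=rule, empty_cell=empty_cell
        )
        for i in range(0, combos.shape[0], _CHUNK)
    ]
    ccr_m = np.concatenate([p[0] for p in parts])
    nmi_m = np.concatenate([p[1] for p in parts])
    keep = _nondominated_mask(np.column_stack([ccr_m, nmi_m]), dominance)
    front = [
        TargetVector(tuple(c), FitnessPair(float(cc), float(nm)))
        for c, cc, nm, kp in zip(combos, ccr_m, nmi_m, keep)
        if kp
    ]
    front.sort(key=lambda m: (-m.fitness.ccr, -m.fitness.nmi, m.key))
    return front


def exhaustive_best_by_cvc(
    data: GenotypeMatrix, d: int, folds: CVFoldAssignment
) -> tuple[tuple[int, ...], int, FitnessPair]:
    """Classic exhaustive MDR: per-fold best combo by training CCR, then the
    modal combo across folds and its cross-validation consistency (CVC).

    Ties (in training CCR within a fold, or in fold counts across folds) are
    broken toward the lexicographically first combination. Returns the modal
    combo, its CVC, and its fold-averaged testing fitness.
    """
    combos = _all_combos(data.n_snps, d)
    best_ccr = np.full(folds.k, -np.inf)
    best_combo = [None] * folds.k
    for i in range(0, combos.shape[0], _CHUNK):
        chunk = combos[i : i + _CHUNK]
        _, _, training_ccr = mdr_core.evaluate_batch(
            data, chunk, folds, return_training_ccr=True, return_folds=True
        )
        for t in range(folds.k):
            b = int(np.argmax(training_ccr[:, t]))
            if training_ccr[b, t] > best_ccr[t]:
                best_ccr[t] = training_ccr[b, t]
                best_combo[t] = tuple(int(x) for x in chunk[b])
    winners = best_combo
    counts: dict[tuple[int, ...], int] = {}
    for w in winners:
        counts[w] = counts.get(w, 0) + 1
    modal = min(counts, key=lambda c: (-counts[c], c))
    fitness = mdr_core.evaluate_combination(data, modal, folds)
    return modal, counts[modal], fitness


def modemdr_detector(
    config: MODEConfig,
) -> Callable[[SimulatedDataset, int], DetectionResult]:
    """Detection method wrapping the full multiobjective DE search.

    A dataset counts as detected when the planted functional pair appears
    anywhere in the final Pareto archive.
    """

    def method(dataset: SimulatedDataset, seed: int) -> DetectionResult:
        cfg = replace(config, seed=seed, upper=None)
        archive = mode_engine.run(dataset.data, cfg)
        target = tuple(sorted(dataset.functional_indices))
        pairs = [(m.key, m.fitness) for m in archive.members]
        return DetectionResult(seed, any(k == target for k, _ in pairs), pairs)

    return method


def mdr_cvc_detector(
    d: int, k: int, cvc_threshold: int
) -> Callable[[SimulatedDataset, int], DetectionResult]:
    """Exhaustive-MDR detection: the modal combo must equal the planted pair
    and reach the CVC threshold."""

    def method(dataset: SimulatedDataset, seed: int) -> DetectionResult:
        rng = np.random.default_rng(seed)
        folds = balanced_cv_split(dataset.data, k, rng)
        modal, cvc, fitness = exhaustive_best_by_cvc(dataset.data, d, folds)
        target = tuple(sorted(dataset.functional_indices))
        detected = tuple(sorted(modal)) == target and cvc >= cvc_threshold
        return DetectionResult(seed, detected, [(tuple(sorted(modal)), fitness)])

    return method


def detection_success_rate(
    replicates: Sequence[SimulatedDataset],
    method: Callable[[SimulatedDataset, int], DetectionResult],
    seeds: Sequence[int] | None = None,
) -> float:
    """Fraction of replicate datasets in which the planted pair is detected."""
    if seeds is None:
        seeds = range(len(replicates))
    results = [method(ds, int(s)) for ds, s in zip(replicates, seeds)]
    return sum(r.detected for r in results) / len(results)


@dataclass
class WilcoxonSummary:
    """Signed-rank comparison of paired per-model detection rates."""

    n_pos: int
    n_neg: int
    n_tie: int
    w_pos: float
    w_neg: float
    z: float
    p_value: float


def wilcoxon_method_comparison(
    rates_a: Sequence[float], rates_b: Sequence[float]
) -> WilcoxonSummary:
    """Wilcoxon signed-rank test on paired rates (a vs b).

    Tied pairs are set aside (counted in ``n_tie``). The z statistic is the
    normal approximation without continuity correction applied to the
    smaller rank sum; below 15 non-tied pairs an exact p-value is used
    instead.
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    diff = a - b
    nz = diff != 0
    n = int(nz.sum())
    n_tie = diff.size - n
    if n == 0:
        return WilcoxonSummary(0, 0, n_tie, 0.0, 0.0, 0.0, 1.0)
    ranks = stats.rankdata(np.abs(diff[nz]))
    w_pos = float(ranks[diff[nz] > 0].sum())
    w_neg = float(ranks[diff[nz] < 0].sum())
    mean = n * (n + 1) / 4.0
    sd = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = (min(w_pos, w_neg) - mean) / sd
    if n < 15:
        p = float(
            stats.wilcoxon(
                diff[nz], zero_method="wilcox", alternative="two-sided",
                method="exact",
            ).pvalue
        )
    else:
        p = float(2.0 * stats.norm.cdf(z))
    return WilcoxonSummary(
        int((diff[nz] > 0).sum()),
        int((diff[nz] < 0).sum()),
        n_tie,
        w_pos,
        w_neg,
        z,
        p,
    )


METHOD_BUILDERS = {
    "modemdr": lambda p: modemdr_detector(
        MODEConfig(**{**p, "objectives": ("ccr", "nmi")})
    ),
    "demdr_ccr": lambda p: modemdr_detector(
        MODEConfig(**{**p, "objectives": ("ccr",)})
    ),
    "demdr_nmi": lambda p: modemdr_detector(
        MODEConfig(**{**p, "objectives": ("nmi",)})
    ),
    "mdr_cvc3": lambda p: mdr_cvc_detector(p.get("d", 2), p.get("k", 5), 3),
    "mdr_cvc4": lambda p: mdr_cvc_detector(p.get("d", 2), p.get("k", 5), 4),
}


def run_benchmark(
    grid: Sequence[dict],
    n_replicates: int,
    methods: Sequence[str],
    seed: int,
    engine_params: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detection-success-rate benchmark over a grid of model settings.

    Each grid entry is a dict with keys ``maf``, ``h2``, ``cases``,
    ``controls``, ``snps``. One pure model is searched per setting, then
    ``n_replicates`` datasets are simulated and every requested method is
    run on each. Returns ``(rates, detail)`` data frames; fully seeded.
    """
    unknown = [m for m in methods if m not in METHOD_BUILDERS]
    if unknown:
        raise ValueError(f"unknown methods {unknown}")
    engine_params = dict(engine_params or {})
    root = np.random.SeedSequence(seed)
    rate_rows = []
    detail_rows = []
    for si, setting in enumerate(grid):
        s_model, s_data, s_search = root.spawn(3)
        model_rng = np.random.default_rng(s_model.generate_state(1)[0] % 2**31)
        model = generate_pure_epistatic_model(
            setting["maf"], setting["h2"], model_rng
        )
        data_seeds = s_data.generate_state(n_replicates) % 2**31
        search_seeds = s_search.generate_state(n_replicates) % 2**31
        replicates = [
            simulate_dataset(
                model,
                setting["cases"],
                setting["controls"],
                setting["snps"],
                np.random.default_rng(int(ds)),
            )
            for ds in data_seeds
        ]
        for name in methods:
            method = METHOD_BUILDERS[name](engine_params)
            n_detected = 0
            for ri, (ds, ss) in enumerate(zip(replicates, search_seeds)):
                result = method(ds, int(ss))
                n_detected += result.detected
                detail_rows.append(
                    {
                        "setting": si,
                        "maf": setting["maf"],
                        "h2": setting["h2"],
                        "method": name,
                        "replicate": ri,
                        "detected": bool(result.detected),
                    }
                )
            rate_rows.append(
                {
                    "setting": si,
                    "maf": setting["maf"],
                    "h2": setting["h2"],
                    "cases": setting["cases"],
                    "controls": setting["controls"],
                    "snps": setting["snps"],
                    "method": name,
                    "rate": n_detected / n_replicates,
                }
            )
    return pd.DataFrame(rate_rows), pd.DataFrame(detail_rows)
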