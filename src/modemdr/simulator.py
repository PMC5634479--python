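"""Penetrance-model simulation of case-control SNP data under HWE.

A disease model is a d-locus penetrance table: for each multi-locus genotype
g the table gives f(g) = P(disease | g). Genotypes at each locus follow
Hardy-Weinberg proportions for the locus's minor-allele frequency, loci are
independent, and disease status is Bernoulli(f(g)). The module also searches
for *pure* epistatic models - tables whose per-locus marginal penetrances all
equal the prevalence, so no single locus carries any signal - at a requested
broad-sense heritability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_io import GenotypeMatrix

__all__ = [
    "PenetranceModel",
    "SimulatedDataset",
    "ModelSearchError",
    "SimulationBudgetError",
    "hwe_genotype_frequencies",
    "compute_prevalence",
    "compute_heritability",
    "compute_marginal_penetrances",
    "max_marginal_deviation",
    "generate_pure_epistatic_model",
    "simulate_dataset",
    "MARGINAL_EFFECT_MODELS",
]


class ModelSearchError(RuntimeError):
    """Pure-model search exhausted its budget without meeting tolerance."""


class SimulationBudgetError(RuntimeError):
    """Case/control quotas could not be filled within the draw budget."""


def hwe_genotype_frequencies(maf: float) -> np.ndarray:
    """Genotype probabilities ((1-p)^2, 2p(1-p), p^2) for minor-allele
    frequency p, indexed by minor-allele count 0/1/2."""
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    p = float(maf)
    q = 1.0 - p
    return np.array([q * q, 2.0 * p * q, p * p])


@dataclass
class PenetranceModel:
    """d-locus disease model: per-locus MAFs and a 3^d penetrance table.

    ``penetrance`` has shape ``(3,) * d``; axis ``l`` is indexed by the
    minor-allele count at locus ``l``.
    """

    mafs: np.ndarray
    penetrance: np.ndarray

    def __post_init__(self) -> None:
        self.mafs = np.asarray(self.mafs, dtype=float)
        self.penetrance = np.asarray(self.penetrance, dtype=float)
        if self.mafs.ndim != 1 or self.mafs.size < 1:
            raise ValueError("mafs must be a nonempty 1-D vector")
        d = self.mafs.size
        if self.penetrance.shape != (3,) * d:
            raise ValueError(
                f"penetrance shape {self.penetrance.shape} does not match "
                f"(3,)*{d}"
            )
        if ((self.mafs <= 0) | (self.mafs > 0.5)).any():
            raise ValueError("every MAF must lie in (0, 0.5]")
        if ((self.penetrance < 0) | (self.penetrance > 1)).any():
            raise ValueError("penetrance values must lie in [0, 1]")

    @property
    def order(self) -> int:
        return self.mafs.size

    def genotype_probabilities(self) -> np.ndarray:
        """Joint HWE genotype probabilities, shape ``(3,) * d``."""
        probs = hwe_genotype_frequencies(self.mafs[0])
        for maf in self.mafs[1:]:
            probs = np.multiply.outer(probs, hwe_genotype_frequencies(maf))
        return probs


def compute_prevalence(model: PenetranceModel) -> float:
    """Disease prevalence K = sum_g P_HWE(g) f(g)."""
    return float(np.sum(model.genotype_probabilities() * model.penetrance))


def compute_heritability(model: PenetranceModel) -> float:
    """Broad-sense heritability h^2 = sum_g P(g) (f(g)-K)^2 / (K (1-K))."""
    k = compute_prevalence(model)
    if not 0.0 < k < 1.0:
        raise ValueError(f"degenerate model: prevalence K = {k}")
    probs = model.genotype_probabilities()
    var = float(np.sum(probs * (model.penetrance - k) ** 2))
    return var / (k * (1.0 - k))


def compute_marginal_penetrances(model: PenetranceModel) -> np.ndarray:
    """Per-locus marginal penetrances, shape ``(d, 3)``.

    Entry ``(l, a)`` is the penetrance of genotype ``a`` at locus ``l``
    averaged over the HWE distribution of the other loci. A model is pure
    (no marginal effects) iff every entry equals the prevalence K.
    """
    d = model.order
    probs = model.genotype_probabilities()
    joint = probs * model.penetrance
    out = np.empty((d, 3))
    for locus in range(d):
        axes = tuple(ax for ax in range(d) if ax != locus)
        w = hwe_genotype_frequencies(model.mafs[locus])
        out[locus] = joint.sum(axis=axes) / w
    return out


def max_marginal_deviation(model: PenetranceModel) -> float:
    """Largest absolute deviation of any marginal penetrance from K."""
    k = compute_prevalence(model)
    return float(np.abs(compute_marginal_penetrances(model) - k).max())


def generate_pure_epistatic_model(
    maf: float,
    h2_target: float,
    rng: np.random.Generator,
    tol: float = 1e-3,
    max_restarts: int = 10_000,
) -> PenetranceModel:
    """Search for a two-locus pure epistatic model at a target heritability.

    Random restarts propose a 3x3 table; weighted double-centering projects
    it onto the subspace of zero marginal effects (both HWE-weighted row and
    column means equal the overall mean), and an affine rescale
    ``f <- K + c (f - K)`` sets the heritability exactly. A proposal is
    accepted when the rescaled table stays inside [0, 1]; purity and
    heritability then hold to numerical precision, well inside ``tol``.

    Deterministic for a given generator state. Raises ModelSearchError with
    the best deviation found if no proposal is feasible within the budget.
    """
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    if not 0.0 < h2_target < 1.0:
        raise ValueError(f"h2_target must be in (0, 1), got {h2_target}")
    w = hwe_genotype_frequencies(maf)
    best_gap = np.inf
    for _ in range(max_restarts):
        f0 = rng.random((3, 3))
        row = f0 @ w            # HWE-weighted row means
        col = w @ f0            # HWE-weighted column means
        mean = float(w @ f0 @ w)
        centered = f0 - (row[:, None] - mean) - (col[None, :] - mean)
        var = float(np.sum(np.outer(w, w) * (centered - mean) ** 2))
        if var <= 0.0:
            continue
        scale = np.sqrt(h2_target * mean * (1.0 - mean) / var)
        table = mean + scale * (centered - mean)
        if table.min() < 0.0 or table.max() > 1.0:
            # infeasible at this prevalence/variance; record how close
            overshoot = max(0.0 - table.min(), table.max() - 1.0)
            best_gap = min(best_gap, overshoot)
            continue
        model = PenetranceModel(np.array([maf, maf]), table)
        if (
            abs(compute_heritability(model) - h2_target) <= tol
            and max_marginal_deviation(model) <= tol
        ):
            return model
    raise ModelSearchError(
        f"no pure model with maf={maf}, h2={h2_target} found in "
        f"{max_restarts} restarts (best bound overshoot {best_gap:.3g})"
    )


@dataclass
class SimulatedDataset:
    """A simulated dataset with its ground-truth disease loci."""

    data: GenotypeMatrix
    functional_indices: tuple[int, ...]
    model: PenetranceModel

    def __post_init__(self) -> None:
        self.functional_indices = tuple(int(i) for i in self.functional_indices)
        if len(set(self.functional_indices)) != len(self.functional_indices):
            raise ValueError("functional indices must be distinct")
        if any(
            not 0 <= i < self.data.n_snps for i in self.functional_indices
        ):
            raise ValueError("functional index out of column range")


def _sample_functional_genotypes(
    model: PenetranceModel,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
    draw_budget: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample disease-locus genotypes until both quotas fill."""
    d = model.order
    cum = np.stack(
        [np.cumsum(hwe_genotype_frequencies(m)) for m in model.mafs]
    )
    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    n_case_drawn = n_control_drawn = 0
    drawn = 0
    chunk = 4096
    while n_case_drawn < n_cases or n_control_drawn < n_controls:
        if drawn >= draw_budget:
            raise SimulationBudgetError(
                f"draw budget {draw_budget} exhausted with "
                f"{n_case_drawn}/{n_cases} cases and "
                f"{n_control_drawn}/{n_controls} controls"
            )
        u = rng.random((chunk, d))
        geno = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
        pen = model.penetrance[tuple(geno.T)]
        is_case = rng.random(chunk) < pen
        drawn += chunk
        need_cases = n_cases - n_case_drawn
        if need_cases > 0:
            take = geno[is_case][:need_cases]
            cases.append(take)
            n_case_drawn += take.shape[0]
        need_controls = n_controls - n_control_drawn
        if need_controls > 0:
            take = geno[~is_case][:need_controls]
            controls.append(take)
            n_control_drawn += take.shape[0]
    return np.concatenate(cases), np.concatenate(controls)


def simulate_dataset(
    model: PenetranceModel,
    n_cases: int,
    n_controls: int,
    n_snps: int,
    rng: np.random.Generator,
    maf_range: tuple[float, float] = (0.05, 0.5),
    draw_budget: int | None = None,
) -> SimulatedDataset:
    """Simulate a case-control dataset with one planted disease-locus set.

    Disease-locus genotypes are drawn under HWE from ``model.mafs`` and
    status Bernoulli(f(g)); samples are kept until the case and control
    quotas fill (rejection sampling, bounded by ``draw_budget``, default
    ``1000 * (n_cases + n_controls)``). The remaining ``n_snps - d`` columns
    are null background SNPs, independent of status, each with a MAF drawn
    uniformly from ``maf_range``. The disease loci are placed at
    generator-chosen distinct column positions recorded in
    ``functional_indices``. Cases occupy the first ``n_cases`` rows.
    """
    d = model.order
    if n_snps < d:
        raise ValueError(f"n_snps={n_snps} below model order {d}")
    if n_cases < 1 or n_controls < 1:
        raise ValueError("need at least one case and one control")
    if draw_budget is None:
        draw_budget = 1000 * (n_cases + n_controls)
    case_geno, control_geno = _sample_functional_genotypes(
        model, n_cases, n_controls, rng, draw_budget
    )
    n = n_cases + n_controls
    n_background = n_snps - d
    genotypes = np.empty((n, n_snps), dtype=np.int64)
    functional = np.concatenate([case_geno, control_geno])
    if n_background:
        bg_mafs = rng.uniform(maf_range[0], maf_range[1], size=n_background)
        background = rng.binomial(2, bg_mafs, size=(n, n_background))
    positions = rng.choice(n_snps, size=d, replace=False)
    mask = np.zeros(n_snps, dtype=bool)
    mask[positions] = True
    genotypes[:, positions] = functional
    if n_background:
        genotypes[:, ~mask] = background
    phenotype = np.concatenate(
        [np.ones(n_cases, dtype=np.int64), np.zeros(n_controls, dtype=np.int64)]
    )
    names = [f"SNP{i}" for i in range(n_snps)]
    data = GenotypeMatrix(genotypes, phenotype, names)
    return SimulatedDataset(data, tuple(int(p) for p in positions), model)


def _two_locus_model(mafs: Sequence[float], table) -> PenetranceModel:
    return PenetranceModel(np.asarray(mafs, float), np.asarray(table, float))


#: Small library of classic two-locus penetrance architectures *with*
#: marginal effects (synthetic textbook forms, not any published catalogue):
#: a multiplicative risk model, a dominant-dominant threshold model, and an
#: XOR-style pattern whose symmetric form also shows how marginal effects
#: vanish at MAF 0.5. Users supply their own tables for anything else.
MARGINAL_EFFECT_MODELS: dict[str, PenetranceModel] = {
    "multiplicative": _two_locus_model(
        [0.25, 0.25],
        [
            [0.02, 0.03, 0.045],
            [0.03, 0.045, 0.0675],
            [0.045, 0.0675, 0.101],
        ],
    ),
    "threshold": _two_locus_model(
        [0.3, 0.3],
        [
            [0.02, 0.02, 0.02],
            [0.02, 0.09, 0.09],
            [0.02, 0.09, 0.09],
        ],
    ),
    "xor": _two_locus_model(
        [0.4, 0.4],
        [
            [0.00, 0.10, 0.00],
            [0.10, 0.00, 0.10],
            [0.00, 0.10, 0.00],
        ],
    ),
}
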