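"""Multiobjective differential evolution over SNP-combination vectors.

Each individual is a d-tuple of distinct SNP column indices. A generation
applies the classic DE rand/1 operators - mutation V = X_r1 + F (X_r2 - X_r3)
with donors drawn from the population or, with probability PV each, from the
elite Pareto archive; binomial crossover with constant CR; boundary repair
redrawing out-of-range or duplicated components - followed by Pareto
selection (a trial replaces its target only when strictly better in every
objective) and an archive update. The archive keeps mutually nondominated
individuals, capped at 20% of the population size by crowding-distance
pruning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import mdr_core
from .data_io import CVFoldAssignment, GenotypeMatrix, balanced_cv_split
from .mdr_core import FitnessPair

logger = logging.getLogger(__name__)

OBJECTIVE_INDEX = {"ccr": 0, "nmi": 1}


@dataclass(frozen=True)
class TargetVector:
    """A candidate SNP combination with (optionally) attached fitness."""

    params: tuple[int, ...]
    fitness: FitnessPair | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "params", tuple(int(p) for p in self.params)
        )
        if len(set(self.params)) != len(self.params):
            raise ValueError(f"params must be distinct, got {self.params}")

    @property
    def key(self) -> tuple[int, ...]:
        """Order-insensitive identity of the combination."""
        return tuple(sorted(self.params))


@dataclass
class ParetoArchive:
    """Capacity-bounded set of mutually nondominated target vectors."""

    members: list[TargetVector] = field(default_factory=list)
    capacity: int = 20

    def __len__(self) -> int:
        return len(self.members)

    def contains_combo(self, combo: Sequence[int]) -> bool:
        key = tuple(sorted(int(c) for c in combo))
        return any(m.key == key for m in self.members)


@dataclass
class MODEConfig:
    """Search parameters.

    Defaults follow the published simulation protocol: population 100,
    300 generations, F = CR = 0.5, order-2 interactions, 5-fold CV, archive
    capped at 20% of the population. PV (probability that a mutation donor
    is taken from the archive rather than the population) defaults to 0.5.
    """

    pop_size: int = 100
    gen_size: int = 300
    F: float = 0.5
    CR: float = 0.5
    PV: float = 0.5
    d: int = 2
    k: int = 5
    lower: int = 0
    upper: int | None = None
    seed: int = 0
    archive_capacity: int | None = None
    objectives: tuple[str, ...] = ("ccr", "nmi")
    dominance: str = "strict"
    rule: str = "training"
    empty_cell: str = "exclude"

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4 (DE needs three donors)")
        if self.gen_size < 0:
            raise ValueError("gen_size must be >= 0")
        if not 0.0 <= self.F < 2.0:
            raise ValueError("F must lie in [0, 2)")
        if not 0.0 <= self.CR < 1.0:
            raise ValueError("CR must lie in [0, 1)")
        if not 0.0 <= self.PV < 1.0:
            raise ValueError("PV must lie in [0, 1)")
        if self.d < 1:
            raise ValueError("interaction order d must be >= 1")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.upper is not None and self.upper - self.lower + 1 < self.d:
            raise ValueError(
                f"bounds [{self.lower}, {self.upper}] cannot hold "
                f"{self.d} distinct indices"
            )
        if not self.objectives or any(
            o not in OBJECTIVE_INDEX for o in self.objectives
        ):
            raise ValueError(f"unknown objectives {self.objectives}")
        if self.dominance not in ("strict", "weak"):
            raise ValueError(f"unknown dominance rule {self.dominance!r}")

    @property
    def effective_capacity(self) -> int:
        if self.archive_capacity is not None:
            return self.archive_capacity
        return max(1, round(0.2 * self.pop_size))


def dominates(
    a: FitnessPair,
    b: FitnessPair,
    objectives: tuple[str, ...] = ("ccr", "nmi"),
    mode: str = "strict",
) -> bool:
    """Whether fitness ``a`` dominates ``b``.

    ``strict`` (the method's stated rule): a is strictly better in *every*
    objective; any tie blocks domination. ``weak`` is the conventional
    Pareto rule: at least as good everywhere and strictly better somewhere.
    """
    av = [a[OBJECTIVE_INDEX[o]] for o in objectives]
    bv = [b[OBJECTIVE_INDEX[o]] for o in objectives]
    if mode == "strict":
        return all(x > y for x, y in zip(av, bv))
    return all(x >= y for x, y in zip(av, bv)) and any(
        x > y for x, y in zip(av, bv)
    )


def _draw_index(config: MODEConfig, rng: np.random.Generator) -> int:
    """One component draw: rand * (upper - lower) + lower, rounded."""
    return int(round(rng.random() * (config.upper - config.lower) + config.lower))


def initialize_population(
    config: MODEConfig, rng: np.random.Generator
) -> list[TargetVector]:
    """Random initial population; within-vector duplicates are redrawn."""
    if config.upper is None:
        raise ValueError("config.upper must be set before initialization")
    return [
        TargetVector(_distinct_draw(config, rng)) for _ in range(config.pop_size)
    ]


def _distinct_draw(config: MODEConfig, rng: np.random.Generator) -> tuple[int, ...]:
    out: list[int] = []
    attempts = 0
    while len(out) < config.d:
        v = _draw_index(config, rng)
        if v not in out:
            out.append(v)
        attempts += 1
        if attempts > 100 * config.d:
            pool = [
                x
                for x in range(config.lower, config.upper + 1)
                if x not in out
            ]
            need = config.d - len(out)
            out.extend(int(x) for x in rng.choice(pool, size=need, replace=False))
    return tuple(out)


def mutate(
    i: int,
    population: Sequence[TargetVector],
    archive: ParetoArchive,
    config: MODEConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mutant vector V = X_r1 + F (X_r2 - X_r3), rounded to integers.

    Each of the three donors is independently taken from the archive with
    probability PV (when the archive is nonempty), otherwise from the
    population. Donors are pairwise distinct within their source and
    population donors exclude index ``i``. If the archive holds fewer
    members than requested the surplus donors fall back to the population.
    """
    n = len(population)
    if n < 4:
        raise ValueError("population must hold at least 4 vectors")
    from_archive = [
        bool(len(archive) > 0 and rng.random() <= config.PV) for _ in range(3)
    ]
    n_arch = sum(from_archive)
    if n_arch > len(archive):  # not enough elites to draw distinctly
        surplus = n_arch - len(archive)
        for j in range(3):
            if surplus == 0:
                break
            if from_archive[j]:
                from_archive[j] = False
                surplus -= 1
    donors: list[TargetVector] = []
    used_pop: set[int] = {i}
    used_arch: set[int] = set()
    for j in range(3):
        if from_archive[j]:
            while True:
                r = int(rng.integers(len(archive)))
                if r not in used_arch:
                    used_arch.add(r)
                    donors.append(archive.members[r])
                    break
        else:
            while True:
                r = int(rng.integers(n))
                if r not in used_pop:
                    used_pop.add(r)
                    donors.append(population[r])
                    break
    x1, x2, x3 = (np.asarray(d.params, dtype=float) for d in donors)
    return np.rint(x1 + config.F * (x2 - x3)).astype(np.int64)


def recombine(
    target: TargetVector,
    mutant: np.ndarray,
    config: MODEConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binomial crossover: each component comes from the mutant when
    randb(j) <= CR, and component rnbr always does."""
    d = config.d
    mutant = np.asarray(mutant, dtype=np.int64)
    x = np.asarray(target.params, dtype=np.int64)
    take = rng.random(d) <= config.CR
    take[int(rng.integers(d))] = True  # rnbr: at least one mutant component
    return np.where(take, mutant, x)


def enforce_bounds(
    u, config: MODEConfig, rng: np.random.Generator
) -> tuple[int, ...]:
    """Repair a trial vector to d distinct in-range indices.

    Out-of-range components and duplicates (first occurrence kept) are
    redrawn from the initialization distribution; after a bounded number of
    rounds any still-infeasible slots are filled by sampling the remaining
    index pool without replacement.
    """
    u = np.asarray(u, dtype=np.int64).copy()
    for _ in range(50):
        bad = (u < config.lower) | (u > config.upper)
        seen: set[int] = set()
        for j, v in enumerate(u.tolist()):
            if bad[j]:
                continue
            if v in seen:
                bad[j] = True
            else:
                seen.add(v)
        if not bad.any():
            return tuple(int(v) for v in u)
        for j in np.flatnonzero(bad):
            u[j] = _draw_index(config, rng)
    kept = {int(v) for j, v in enumerate(u) if config.lower <= v <= config.upper}
    pool = [x for x in range(config.lower, config.upper + 1) if x not in kept]
    bad = np.flatnonzero(
        (u < config.lower) | (u > config.upper)
        | (np.array([list(u[:j]).count(v) > 0 for j, v in enumerate(u)]))
    )
    fill = rng.choice(pool, size=bad.size, replace=False)
    u[bad] = fill
    return tuple(int(v) for v in u)


def select(
    target: TargetVector, trial: TargetVector, config: MODEConfig
) -> TargetVector:
    """Greedy Pareto selection: the trial survives only if it dominates."""
    if target.fitness is None or trial.fitness is None:
        raise ValueError("both vectors must be evaluated before selection")
    if dominates(trial.fitness, target.fitness, config.objectives, config.dominance):
        return trial
    return target


def _fitness_array(
    members: Sequence[TargetVector], objectives: tuple[str, ...]
) -> np.ndarray:
    idx = [OBJECTIVE_INDEX[o] for o in objectives]
    return np.array([[m.fitness[j] for j in idx] for m in members], dtype=float)


def _crowding_prune(
    members: list[TargetVector], capacity: int, objectives: tuple[str, ...]
) -> list[TargetVector]:
    """Drop lowest-crowding-distance members until within capacity.

    Objective-extreme members carry infinite distance and are never dropped.
    Deterministic: members are pre-sorted canonically and argmin breaks ties
    by position.
    """
    members = sorted(
        members, key=lambda m: (-m.fitness.ccr, -m.fitness.nmi, m.key)
    )
    while len(members) > capacity:
        f = _fitness_array(members, objectives)
        n, n_obj = f.shape
        dist = np.zeros(n)
        for j in range(n_obj):
            order = np.argsort(f[:, j], kind="stable")
            span = f[order[-1], j] - f[order[0], j]
            dist[order[0]] = dist[order[-1]] = np.inf
            if span > 0:
                dist[order[1:-1]] += (f[order[2:], j] - f[order[:-2], j]) / span
        members.pop(int(np.argmin(dist)))
    return members


def update_archive(
    archive: ParetoArchive,
    candidates: Sequence[TargetVector],
    config: MODEConfig,
) -> ParetoArchive:
    """Admit nondominated candidates, purge dominated members, enforce
    capacity.

    The admission-then-purge steps reduce to keeping the nondominated subset
    of the union of old members and candidates (order-independent under the
    strict rule). Duplicate combinations are kept once.
    """
    pool: list[TargetVector] = []
    seen: set[tuple[int, ...]] = set()
    for m in list(archive.members) + list(candidates):
        if m.fitness is None:
            raise ValueError("archive candidates must be evaluated")
        if m.key not in seen:
            seen.add(m.key)
            pool.append(m)
    if not pool:
        return ParetoArchive([], archive.capacity)
    f = _fitness_array(pool, config.objectives)
    if config.dominance == "strict":
        dominated = (f[:, None, :] > f[None, :, :]).all(axis=2)
    else:
        dominated = (f[:, None, :] >= f[None, :, :]).all(axis=2) & (
            f[:, None, :] > f[None, :, :]
        ).any(axis=2)
    keep = ~dominated.any(axis=0)
    members = [m for m, kp in zip(pool, keep) if kp]
    if len(members) > archive.capacity:
        members = _crowding_prune(members, archive.capacity, config.objectives)
    members.sort(key=lambda m: (-m.fitness.ccr, -m.fitness.nmi, m.key))
    return ParetoArchive(members, archive.capacity)


class _CachedEvaluator:
    """Order-insensitive fitness cache over the batch MDR kernel."""

    def __init__(
        self, data: GenotypeMatrix, folds: CVFoldAssignment, config: MODEConfig
    ) -> None:
        self.data = data
        self.folds = folds
        self.config = config
        self.cache: dict[tuple[int, ...], FitnessPair] = {}
        self.n_evaluations = 0

    def evaluate(self, vectors: list[TargetVector]) -> list[TargetVector]:
        keys = [v.key for v in vectors]
        missing = sorted({k for k in keys if k not in self.cache})
        if missing:
            ccr_m, nmi_m = mdr_core.evaluate_batch(
                self.data,
                np.array(missing, dtype=np.int64),
                self.folds,
                rule=self.config.rule,
                empty_cell=self.config.empty_cell,
            )
            for key, c, m in zip(missing, ccr_m, nmi_m):
                self.cache[key] = FitnessPair(float(c), float(m))
            self.n_evaluations += len(missing)
        return [
            replace(v, fitness=self.cache[k]) for v, k in zip(vectors, keys)
        ]


def run(
    data: GenotypeMatrix,
    config: MODEConfig,
    history: list | None = None,
) -> ParetoArchive:
    """Full search: one balanced CV split, then gen_size DE generations.

    Returns the final archive sorted by CCR (descending). Fully
    deterministic for a given ``config.seed``. If ``history`` is a list, a
    per-generation record (archive size, best CCR, best NMI) is appended.
    """
    if config.upper is None:
        config = replace(config, upper=data.n_snps - 1)
    if config.upper >= data.n_snps:
        raise ValueError("config.upper exceeds the SNP index range")
    rng = np.random.default_rng(config.seed)
    folds = balanced_cv_split(data, config.k, rng)
    evaluator = _CachedEvaluator(data, folds, config)

    population = evaluator.evaluate(initialize_population(config, rng))
    archive = update_archive(
        ParetoArchive([], config.effective_capacity), population, config
    )
    for gen in range(config.gen_size):
        trials = []
        for i in range(config.pop_size):
            v = mutate(i, population, archive, config, rng)
            u = recombine(population[i], v, config, rng)
            trials.append(TargetVector(enforce_bounds(u, config, rng)))
        trials = evaluator.evaluate(trials)
        population = [
            select(population[i], trials[i], config)
            for i in range(config.pop_size)
        ]
        archive = update_archive(archive, population, config)
        if history is not None or logger.isEnabledFor(logging.DEBUG):
            best_ccr = max(m.fitness.ccr for m in archive.members)
            best_nmi = max(m.fitness.nmi for m in archive.members)
            if history is not None:
                history.append(
                    {
                        "generation": gen + 1,
                        "archive_size": len(archive),
                        "best_ccr": best_ccr,
                        "best_nmi": best_nmi,
                    }
                )
            logger.debug(
                "gen %d: archive=%d best_ccr=%.4f best_nmi=%.4f",
                gen + 1,
                len(archive),
                best_ccr,
                best_nmi,
            )
    return archive
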