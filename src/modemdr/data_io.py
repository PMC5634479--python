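"""Case-control genotype datasets: container, TSV I/O and balanced CV splitting.

The on-disk dialect is the tab-separated layout emitted by common epistasis
simulators: one header row of SNP names followed by a literal ``Class``
column, then one row per sample with genotypes coded 0/1/2 (minor-allele
count) and the class coded 0 (control) / 1 (case).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CLASS_COLUMN = "Class"


class DatasetParseError(ValueError):
    """Raised when a dataset file cannot be parsed (bad layout, ragged rows)."""


class DatasetValidationError(ValueError):
    """Raised when parsed values violate the genotype/phenotype coding."""


class InfeasibleSplitError(ValueError):
    """Raised when a class has fewer members than the requested fold count."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs matrix of minor-allele counts with a binary phenotype.

    Parameters
    ----------
    genotypes
        Integer array of shape ``(n_samples, n_snps)`` with values in
        ``{0, 1, 2}``.
    phenotype
        Integer vector of length ``n_samples``; 1 = case, 0 = control.
    snp_names
        Unique column labels, one per SNP.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_names: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int64)
        self.snp_names = list(self.snp_names)
        if self.genotypes.ndim != 2:
            raise DatasetValidationError("genotypes must be a 2-D array")
        n, m = self.genotypes.shape
        if n < 1:
            raise DatasetValidationError("at least one sample is required")
        if m < 2:
            raise DatasetValidationError("at least two SNPs are required")
        if self.phenotype.shape != (n,):
            raise DatasetValidationError(
                f"phenotype length {self.phenotype.shape} does not match "
                f"{n} samples"
            )
        if len(self.snp_names) != m:
            raise DatasetValidationError(
                f"{len(self.snp_names)} SNP names for {m} columns"
            )
        if len(set(self.snp_names)) != m:
            raise DatasetValidationError("SNP names must be unique")
        bad = ~np.isin(self.genotypes, (0, 1, 2))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise DatasetValidationError(
                f"genotype {self.genotypes[r, c]} at sample {r}, "
                f"SNP {self.snp_names[c]!r} is not in {{0,1,2}}"
            )
        if not np.isin(self.phenotype, (0, 1)).all():
            raise DatasetValidationError("phenotype values must be 0 or 1")
        if self.n_cases == 0 or self.n_controls == 0:
            raise DatasetValidationError(
                "dataset must contain at least one case and one control"
            )

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return int(self.n_samples - self.phenotype.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.snp_names == other.snp_names
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.phenotype, other.phenotype)
        )


@dataclass
class CVFoldAssignment:
    """Partition of samples into k folds, numbered 1..k."""

    fold_index: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.fold_index = np.asarray(self.fold_index, dtype=np.int64)
        if self.k < 2:
            raise ValueError("k must be >= 2")
        counts = np.bincount(self.fold_index, minlength=self.k + 1)
        if counts[0] != 0 or self.fold_index.max(initial=0) > self.k:
            raise ValueError("fold indices must lie in 1..k")
        if (counts[1:] == 0).any():
            raise ValueError("every fold must be nonempty")

    def test_mask(self, fold: int) -> np.ndarray:
        if not 1 <= fold <= self.k:
            raise ValueError(f"fold {fold} outside 1..{self.k}")
        return self.fold_index == fold

    def train_mask(self, fold: int) -> np.ndarray:
        return ~self.test_mask(fold)


def read_dataset(path) -> GenotypeMatrix:
    """Read a tab-delimited case-control genotype file.

    The final header field must be ``Class``; all preceding fields are SNP
    names. Body rows hold 0/1/2 genotypes and a 0/1 class label.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=0)
    except pd.errors.ParserError as exc:  # ragged rows: pandas names the line
        raise DatasetParseError(f"{path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise DatasetParseError(f"{path}: file is empty") from exc
    if df.shape[1] < 3:
        raise DatasetParseError(
            f"{path}: expected at least 2 SNP columns plus a class column, "
            f"found {df.shape[1]} columns"
        )
    if str(df.columns[-1]).strip().lower() != CLASS_COLUMN.lower():
        raise DatasetParseError(
            f"{path}: last header field must be {CLASS_COLUMN!r}, "
            f"found {df.columns[-1]!r}"
        )
    if df.isna().any().any():
        line = int(df.isna().any(axis=1).to_numpy().argmax()) + 2
        raise DatasetParseError(f"{path}: missing value in line {line}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.integer):
            raise DatasetValidationError(
                f"{path}: column {col!r} contains non-integer values"
            )
    genotypes = df.iloc[:, :-1].to_numpy(dtype=np.int64)
    phenotype = df.iloc[:, -1].to_numpy(dtype=np.int64)
    return GenotypeMatrix(genotypes, phenotype, [str(c) for c in df.columns[:-1]])


def write_dataset(data: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix in the tab-delimited dialect of read_dataset."""
    header = "\t".join([*data.snp_names, CLASS_COLUMN])
    body = np.column_stack([data.genotypes, data.phenotype])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        for row in body:
            fh.write("\t".join(str(int(v)) for v in row) + "\n")


def balanced_cv_split(
    data: GenotypeMatrix, k: int, rng: np.random.Generator
) -> CVFoldAssignment:
    """Balance-strategy k-fold split.

    Cases and controls are shuffled independently, then each class list is
    dealt round-robin to folds 1..k, so every fold's case:control ratio
    matches the global ratio to within one sample per class. Deterministic
    for a given generator state; the case list is shuffled first.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    case_idx = np.flatnonzero(data.phenotype == 1)
    control_idx = np.flatnonzero(data.phenotype == 0)
    for name, idx in (("case", case_idx), ("control", control_idx)):
        if idx.size < k:
            raise InfeasibleSplitError(
                f"only {idx.size} {name} samples for {k} folds"
            )
    fold = np.zeros(data.n_samples, dtype=np.int64)
    for idx in (case_idx, control_idx):
        shuffled = rng.permutation(idx)
        fold[shuffled] = np.arange(shuffled.size) % k + 1
    return CVFoldAssignment(fold, k)
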