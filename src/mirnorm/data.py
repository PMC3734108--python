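"""In-memory container for left-censored expression matrices.

A miRNA microarray experiment here is a genes x arrays matrix of
natural-log intensities where some entries are only known to lie below
the array's detection limit (left-censored).  The censoring mask is
authoritative: a censored cell stores no observed value (NaN), and the
per-array detection limit is the upper bound for that latent value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DataValidationError(ValueError):
    """Base class for malformed expression data."""


class DuplicateGeneIdError(DataValidationError):
    """Gene identifiers in a matrix file are not unique."""


class ArrayMismatchError(DataValidationError):
    """Matrix columns and sample-sheet rows do not describe the same arrays."""


class MissingDetectionLimitError(DataValidationError):
    """A censored cell sits on an array without a finite detection limit."""


@dataclass
class CensoredExpressionMatrix:
    """Log-scale expression with per-array detection limits.

    Parameters
    ----------
    values : (G, A) float array
        Natural-log intensities; NaN wherever ``censored`` is True.
    censored : (G, A) bool array
        True for cells reported below the array's detection limit.
    condition : (A,) int array
        Two-group condition label per array, in {1, 2}.
    replicate : (A,) int array
        Replicate index of the array within its condition (0-based).
    detection_limit : (A,) float array
        Detection limit per array, on the same natural-log scale as
        ``values``.  Must be finite for any array with censored cells.
    """

    values: np.ndarray
    censored: np.ndarray
    condition: np.ndarray
    replicate: np.ndarray
    detection_limit: np.ndarray
    gene_ids: list | None = None
    array_ids: list | None = None
    # +1 for condition 2, -1 for condition 1 (delta = mean(c2) - mean(c1))
    sign: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        self.condition = np.asarray(self.condition, dtype=int)
        self.replicate = np.asarray(self.replicate, dtype=int)
        self.detection_limit = np.asarray(self.detection_limit, dtype=float)
        if self.gene_ids is None:
            self.gene_ids = [f"g{i}" for i in range(self.values.shape[0])]
        if self.array_ids is None:
            self.array_ids = [f"a{j}" for j in range(self.values.shape[1])]
        self.validate()
        self.sign = np.where(self.condition == 2, 1.0, -1.0)

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.values.shape[1]

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())

    def arrays_in_condition(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.condition == c)

    # ------------------------------------------------------------------
    def validate(self) -> None:
        g, a = self.values.shape
        if self.censored.shape != (g, a):
            raise DataValidationError(
                f"censored mask shape {self.censored.shape} != values shape {(g, a)}"
            )
        for name, vec in (
            ("condition", self.condition),
            ("replicate", self.replicate),
            ("detection_limit", self.detection_limit),
        ):
            if vec.shape != (a,):
                raise DataValidationError(f"{name} must have length {a}, got {vec.shape}")
        labels = set(np.unique(self.condition).tolist())
        if not labels <= {1, 2}:
            raise DataValidationError(f"condition labels must be in {{1, 2}}, got {sorted(labels)}")
        for c in (1, 2):
            if int(np.sum(self.condition == c)) < 2:
                raise DataValidationError(f"condition {c} needs at least 2 arrays")
        if len(self.gene_ids) != g:
            raise DataValidationError("gene_ids length mismatch")
        if len(set(self.gene_ids)) != g:
            raise DuplicateGeneIdError("gene ids are not unique")
        if len(self.array_ids) != a:
            raise DataValidationError("array_ids length mismatch")
        # the mask is authoritative: censored cells must not carry values
        if np.any(np.isfinite(self.values[self.censored])):
            raise DataValidationError("censored cells must not store observed values")
        if np.any(~self.censored & ~np.isfinite(self.values)):
            raise DataValidationError("non-censored cells must hold finite values")
        needs_dl = self.censored.any(axis=0)
        if np.any(needs_dl & ~np.isfinite(self.detection_limit)):
            bad = [self.array_ids[j] for j in np.flatnonzero(needs_dl & ~np.isfinite(self.detection_limit))]
            raise MissingDetectionLimitError(
                f"arrays with censored cells lack a finite detection limit: {bad}"
            )

    def copy(self) -> "CensoredExpressionMatrix":
        return CensoredExpressionMatrix(
            values=self.values.copy(),
            censored=self.censored.copy(),
            condition=self.condition.copy(),
            replicate=self.replicate.copy(),
            detection_limit=self.detection_limit.copy(),
            gene_ids=list(self.gene_ids),
            array_ids=list(self.array_ids),
        )
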