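"""Pairwise distance/similarity matrices over a labelled genome set."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np

from .errors import DataError

KINDS = ("distance", "similarity")


def n_pairs(n: int) -> int:
    """Number of unordered pairs among n genomes: n(n-1)/2."""
    return n * (n - 1) // 2


def iter_pairs(labels: list[str]) -> Iterator[tuple[int, int]]:
    """Index pairs (i, j), i < j, in row-major upper-triangle order."""
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            yield i, j


@dataclass
class DistanceMatrix:
    """Symmetric pairwise matrix with per-entry defined flags.

    ``kind`` records whether larger values mean farther ('distance') or
    closer ('similarity'). Entries for which an estimator could not
    produce a value (e.g. no surviving alignment) carry ``defined=False``
    and a placeholder value of 0.
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "distance"
    method: dict = field(default_factory=dict)
    defined: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise DataError("duplicate labels in distance matrix")
        if self.kind not in KINDS:
            raise DataError(f"kind must be one of {KINDS}, got {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise DataError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-9, equal_nan=True):
            raise DataError("matrix is not symmetric")
        if self.defined is None:
            self.defined = np.ones((n, n), dtype=bool)
        else:
            self.defined = np.asarray(self.defined, dtype=bool)
            if self.defined.shape != (n, n):
                raise DataError("defined mask shape does not match labels")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_pairs(self) -> int:
        return n_pairs(self.n)

    def condensed(self) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangle values and defined flags in row-major pair order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu], self.defined[iu]

    @classmethod
    def from_pairs(
        cls,
        labels: list[str],
        func: Callable[[int, int], float | None],
        kind: str,
        method: dict | None = None,
    ) -> "DistanceMatrix":
        """Build a matrix by evaluating ``func(i, j)`` for every i < j.

        ``func`` may return None (or NaN) to flag a pair as undefined.
        """
        n = len(labels)
        values = np.zeros((n, n), dtype=float)
        defined = np.ones((n, n), dtype=bool)
        for i, j in iter_pairs(labels):
            v = func(i, j)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                values[i, j] = values[j, i] = 0.0
                defined[i, j] = defined[j, i] = False
            else:
                values[i, j] = values[j, i] = float(v)
        if kind == "similarity":
            np.fill_diagonal(values, values.max(initial=1.0))
        return cls(
            labels=list(labels),
            values=values,
            kind=kind,
            method=dict(method or {}),
            defined=defined,
        )
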