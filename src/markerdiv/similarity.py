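"""Pairwise similarity of genotypes from binary band profiles.

For two genotypes let ``a`` be the number of loci where both show the
band, ``b``/``c`` the presences exclusive to each, and ``d`` the joint
absences.  Dominant-marker studies conventionally use the Dice
coefficient, which ignores joint absences:

    Dice            S = 2a / (2a + b + c)
    Jaccard         S = a / (a + b + c)
    simple matching S = (a + d) / (a + b + c + d)

Dice >= Jaccard always (both count only shared presences, Dice weighs
them double).  Distances for clustering are the complement ``1 - S``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io_formats import BandMatrix

_ATOL = 1e-9


def _check_square(ids: list[str], matrix: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(matrix, dtype=float)
    n = len(ids)
    if arr.shape != (n, n):
        raise ValidationError(f"{name} must be {n}x{n}, got {arr.shape}")
    if not np.allclose(arr, arr.T, atol=_ATOL):
        raise ValidationError(f"{name} must be symmetric")
    return (arr + arr.T) / 2.0  # exact symmetry


@dataclass
class SimilarityMatrix:
    """Symmetric genotype x genotype similarity in [0, 1], unit diagonal."""

    genotype_ids: list[str]
    values: np.ndarray
    method: str = "dice"

    def __post_init__(self) -> None:
        arr = _check_square(self.genotype_ids, self.values, "similarity matrix")
        if (arr < -_ATOL).any() or (arr > 1 + _ATOL).any():
            raise ValidationError("similarities must lie in [0, 1]")
        if not np.allclose(np.diag(arr), 1.0, atol=_ATOL):
            raise ValidationError("similarity diagonal must be 1")
        np.fill_diagonal(arr, 1.0)
        self.values = np.clip(arr, 0.0, 1.0)

    def pair(self, i: str, j: str) -> float:
        gi, gj = self.genotype_ids.index(i), self.genotype_ids.index(j)
        return float(self.values[gi, gj])


@dataclass
class DistanceMatrix:
    """Symmetric non-negative genotype x genotype dissimilarity, zero diagonal."""

    genotype_ids: list[str]
    values: np.ndarray
    method: str = "distance"

    def __post_init__(self) -> None:
        arr = _check_square(self.genotype_ids, self.values, "distance matrix")
        if (arr < -_ATOL).any():
            raise ValidationError("distances must be non-negative")
        if not np.allclose(np.diag(arr), 0.0, atol=_ATOL):
            raise ValidationError("distance diagonal must be 0")
        np.fill_diagonal(arr, 0.0)
        self.values = np.clip(arr, 0.0, None)

    def pair(self, i: str, j: str) -> float:
        gi, gj = self.genotype_ids.index(i), self.genotype_ids.index(j)
        return float(self.values[gi, gj])


def _contingency(m: BandMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Pairwise (a, b, c) count matrices and the locus count."""
    x = m.values.astype(np.int64)
    a = x @ x.T                          # shared presences
    row = x.sum(axis=1)
    b = row[:, None] - a                 # exclusive to i
    c = row[None, :] - a                 # exclusive to j
    return a, b, c, m.n_loci


def _require_bands(m: BandMatrix) -> None:
    empty = [g for g, s in zip(m.genotype_ids, m.values.sum(axis=1)) if s == 0]
    if empty:
        raise ValidationError(
            "genotype(s) with no band, similarity undefined: " + ", ".join(empty)
        )


def dice_similarity(m: BandMatrix) -> SimilarityMatrix:
    """Dice coefficient 2a/(2a+b+c) for every genotype pair."""
    _require_bands(m)
    a, b, c, _ = _contingency(m)
    s = 2.0 * a / (2.0 * a + b + c)
    return SimilarityMatrix(list(m.genotype_ids), s, method="dice")


def jaccard_similarity(m: BandMatrix) -> SimilarityMatrix:
    """Jaccard coefficient a/(a+b+c) for every genotype pair."""
    _require_bands(m)
    a, b, c, _ = _contingency(m)
    s = a / (a + b + c)
    return SimilarityMatrix(list(m.genotype_ids), s, method="jaccard")


def simple_matching(m: BandMatrix) -> SimilarityMatrix:
    """Simple matching coefficient (a+d)/(a+b+c+d); counts joint absences."""
    a, b, c, n = _contingency(m)
    d = n - a - b - c
    s = (a + d) / n
    return SimilarityMatrix(list(m.genotype_ids), s, method="simple_matching")


_METHODS = {
    "dice": dice_similarity,
    "jaccard": jaccard_similarity,
    "simple_matching": simple_matching,
}


def compute_similarity(m: BandMatrix, method: str = "dice") -> SimilarityMatrix:
    """Dispatch to one of the registered coefficients by name."""
    try:
        fn = _METHODS[method]
    except KeyError:
        raise ValidationError(
            f"unknown similarity method {method!r}; choose from {sorted(_METHODS)}"
        ) from None
    return fn(m)


def to_distance(s: SimilarityMatrix) -> DistanceMatrix:
    """Complement distance D = 1 - S (diagonal exactly zero)."""
    d = 1.0 - s.values
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(s.genotype_ids), d, method=f"1-{s.method}")
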