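import numpy as np
import pandas as pd
import pytest

from markerdiv import BandMatrix, DistanceMatrix, TraitTable


@pytest.fixture
def worked_distance() -> DistanceMatrix:
    """4-taxon matrix whose WPGMA tree is (((A,B),C),D) at heights 1, 3, 4.5."""
    ids = ["A", "B", "C", "D"]
    d = np.array(
        [
            [0.0, 2.0, 6.0, 10.0],
            [2.0, 0.0, 6.0, 10.0],
            [6.0, 6.0, 0.0, 8.0],
            [10.0, 10.0, 8.0, 0.0],
        ]
    )
    return DistanceMatrix(ids, d)


@pytest.fixture
def small_band_matrix() -> BandMatrix:
    """5 genotypes x 6 loci across two primers, hand-checkable classes."""
    ids = ["g1", "g2", "g3", "g4", "g5"]
    loci = [
        "RAPD:OPA7:1",  # monomorphic
        "RAPD:OPA7:2",  # unique to g2
        "RAPD:OPA7:3",  # polymorphic (3 carriers)
        "SCoT:SCoT3:1",  # monomorphic
        "SCoT:SCoT3:2",  # polymorphic (2 carriers)
        "SCoT:SCoT3:3",  # unique to g5
    ]
    values = np.array(
        [
            [1, 0, 1, 1, 1, 0],
            [1, 1, 1, 1, 0, 0],
            [1, 0, 1, 1, 0, 0],
            [1, 0, 0, 1, 1, 0],
            [1, 0, 0, 1, 0, 1],
        ]
    )
    return BandMatrix(ids, loci, values)


def random_band_values(rng: np.random.Generator, n_genotypes: int, n_loci: int):
    """Random 0/1 matrix with no all-zero locus column."""
    values = rng.integers(0, 2, size=(n_genotypes, n_loci))
    for j in range(n_loci):
        if values[:, j].sum() == 0:
            values[rng.integers(n_genotypes), j] = 1
    return values


def make_band_matrix(values, system="RAPD", primer="OPA2") -> BandMatrix:
    values = np.asarray(values)
    n, k = values.shape
    ids = [f"g{i + 1}" for i in range(n)]
    loci = [f"{system}:{primer}:{j + 1}" for j in range(k)]
    return BandMatrix(ids, loci, values)


@pytest.fixture
def worked_lsd_table() -> TraitTable:
    """Three groups with unit within-group variance: A far from B ~ C."""
    rows = []
    for g, vals in (("A", (1, 2, 3)), ("B", (11, 12, 13)), ("C", (11.5, 12.5, 13.5))):
        for r, v in enumerate(vals, start=1):
            rows.append({"genotype": g, "trait": "plant_height_cm", "replicate": r, "value": v})
    return TraitTable(pd.DataFrame(rows))
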