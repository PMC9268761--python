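"""Seeded synthetic band matrices and trait tables.

No gel-scored accession is publicly deposited for the five-genotype
kalanchoe panel this package was built around, so every pipeline stage
is exercised on synthetic data generated here:

* :func:`generate_band_matrix` turns a :class:`BandSpec` — per-primer
  counts of total / monomorphic / polymorphic / unique loci — into a
  concrete 0/1 matrix whose locus-class census matches the spec
  *exactly* (the key correctness property, tested by round-trip through
  the classifier).
* :func:`generate_trait_table` draws independent normal replicates
  around per-(genotype, trait) means.
* :func:`kalanchoe_fixture` ships the published per-primer locus counts
  of the kalanchoe panel (4 RAPD + 4 ISSR + 4 SCoT primers, 70 loci, 35
  polymorphic, 9 unique) together with a morphology fixture anchored at
  the panel's printed trait maxima.
* :func:`planted_partition_spec` builds matrices with a known cluster
  structure (one outlier genotype plus two tight pairs) for evaluating
  whether similarity + clustering recovers a planted partition.

All randomness flows through ``numpy.random.default_rng(seed)``; the
same spec and seed always produce byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import ValidationError
from .io_formats import BandMatrix, TraitTable
import pandas as pd


@dataclass(frozen=True)
class PrimerBlockSpec:
    """Locus-class counts for one primer's block of columns.

    ``unique_owners`` optionally pins which genotype carries each unique
    band (default: drawn uniformly); ``carriers`` optionally pins the
    carrier set of each non-unique polymorphic column (default: uniform
    random count in [2, n-1] and uniform random carrier subset).
    """

    system: str
    primer: str
    n_total: int
    n_monomorphic: int
    n_polymorphic: int
    n_unique: int
    unique_owners: tuple[str, ...] | None = None
    carriers: tuple[tuple[str, ...], ...] | None = None


@dataclass(frozen=True)
class BandSpec:
    """Complete recipe for one synthetic band matrix."""

    genotype_ids: tuple[str, ...]
    blocks: tuple[PrimerBlockSpec, ...]
    seed: int = 0


@dataclass(frozen=True)
class TraitEntry:
    genotype: str
    trait: str
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class MorphoSpec:
    """Recipe for a synthetic trait table: normal noise around means."""

    entries: tuple[TraitEntry, ...]
    seed: int = 0


def validate_band_spec(spec: BandSpec) -> None:
    """Raise :class:`ValidationError` naming the first violated constraint."""
    n = len(spec.genotype_ids)
    if n < 2:
        raise ValidationError("band spec needs at least 2 genotypes")
    if len(set(spec.genotype_ids)) != n:
        raise ValidationError("duplicate genotype ids in band spec")
    if not spec.blocks:
        raise ValidationError("band spec has no primer blocks")
    seen: dict[str, str] = {}
    for b in spec.blocks:
        tag = f"{b.system}:{b.primer}"
        if any(v < 0 for v in (b.n_total, b.n_monomorphic, b.n_polymorphic, b.n_unique)):
            raise ValidationError(f"{tag}: negative locus count")
        if b.n_total < 1:
            raise ValidationError(f"{tag}: a primer block needs >= 1 locus")
        if b.n_monomorphic + b.n_polymorphic != b.n_total:
            raise ValidationError(
                f"{tag}: monomorphic ({b.n_monomorphic}) + polymorphic "
                f"({b.n_polymorphic}) != total ({b.n_total})"
            )
        if b.n_unique > b.n_polymorphic:
            raise ValidationError(
                f"{tag}: unique ({b.n_unique}) exceeds polymorphic ({b.n_polymorphic})"
            )
        if b.n_polymorphic - b.n_unique > 0 and n < 3:
            raise ValidationError(
                f"{tag}: non-unique polymorphic columns need >= 3 genotypes "
                "(presence count must lie strictly between 1 and n)"
            )
        if b.unique_owners is not None:
            if len(b.unique_owners) != b.n_unique:
                raise ValidationError(f"{tag}: unique_owners length != n_unique")
            unknown = set(b.unique_owners) - set(spec.genotype_ids)
            if unknown:
                raise ValidationError(f"{tag}: unknown unique owner(s) {unknown}")
        if b.carriers is not None:
            if len(b.carriers) != b.n_polymorphic - b.n_unique:
                raise ValidationError(
                    f"{tag}: carriers length != n_polymorphic - n_unique"
                )
            for cs in b.carriers:
                if not 2 <= len(set(cs)) <= n - 1:
                    raise ValidationError(
                        f"{tag}: carrier set {cs} must contain 2..n-1 distinct genotypes"
                    )
                unknown = set(cs) - set(spec.genotype_ids)
                if unknown:
                    raise ValidationError(f"{tag}: unknown carrier(s) {unknown}")
        if b.primer in seen and seen[b.primer] != b.system:
            raise ValidationError(f"primer {b.primer} appears under two systems")
        seen[b.primer] = b.system


def generate_band_matrix(spec: BandSpec) -> BandMatrix:
    """Materialize a band matrix whose class census matches *spec* exactly."""
    validate_band_spec(spec)
    rng = np.random.default_rng(spec.seed)
    genotypes = list(spec.genotype_ids)
    n = len(genotypes)
    gidx = {g: i for i, g in enumerate(genotypes)}

    locus_ids: list[str] = []
    columns: list[np.ndarray] = []
    for b in spec.blocks:
        block_cols: list[np.ndarray] = []
        for _ in range(b.n_monomorphic):
            block_cols.append(np.ones(n, dtype=np.int8))
        for u in range(b.n_unique):
            col = np.zeros(n, dtype=np.int8)
            if b.unique_owners is not None:
                owner = gidx[b.unique_owners[u]]
            else:
                owner = int(rng.integers(n))
            col[owner] = 1
            block_cols.append(col)
        for c in range(b.n_polymorphic - b.n_unique):
            col = np.zeros(n, dtype=np.int8)
            if b.carriers is not None:
                members = [gidx[g] for g in b.carriers[c]]
            else:
                count = int(rng.integers(2, n))  # uniform on [2, n-1]
                members = rng.choice(n, size=count, replace=False)
            col[list(members)] = 1
            block_cols.append(col)
        order = rng.permutation(len(block_cols))
        for rank, src in enumerate(order):
            locus_ids.append(f"{b.system}:{b.primer}:{rank + 1}")
            columns.append(block_cols[src])
    values = np.column_stack(columns)
    return BandMatrix(genotypes, locus_ids, values)


def generate_trait_table(spec: MorphoSpec) -> TraitTable:
    """Draw replicate values ~ Normal(mean, sd) per spec entry."""
    for e in spec.entries:
        if e.sd < 0:
            raise ValidationError(f"{e.genotype}/{e.trait}: sd must be >= 0")
        if e.n < 2:
            raise ValidationError(f"{e.genotype}/{e.trait}: needs >= 2 replicates")
    rng = np.random.default_rng(spec.seed)
    rows = []
    for e in spec.entries:
        draws = e.mean + e.sd * rng.standard_normal(e.n)
        for r, v in enumerate(draws, start=1):
            rows.append(
                {"genotype": e.genotype, "trait": e.trait, "replicate": r,
                 "value": float(v)}
            )
    return TraitTable(pd.DataFrame(rows, columns=["genotype", "trait", "replicate", "value"]))


# ---------------------------------------------------------------------------
# The kalanchoe study fixture
# ---------------------------------------------------------------------------

#: the five flower-colour genotypes of the panel
KALANCHOE_GENOTYPES = ("red", "yellow", "purple", "orange", "violet")

# (system, primer, total, monomorphic, polymorphic, unique) per published row
_KALANCHOE_BLOCKS = (
    ("RAPD", "OPA2", 2, 1, 1, 0),
    ("RAPD", "OPA7", 8, 2, 6, 2),
    ("RAPD", "OPA9", 3, 1, 2, 2),
    ("RAPD", "OPA10", 2, 1, 1, 0),
    ("ISSR", "ISSR-3", 4, 4, 0, 0),
    ("ISSR", "ISSR-5", 3, 3, 0, 0),
    ("ISSR", "ISSR-8", 6, 4, 2, 0),
    ("ISSR", "ISSR-10", 4, 3, 1, 0),
    ("SCoT", "SCoT3", 9, 3, 6, 3),
    ("SCoT", "SCoT11", 9, 5, 4, 1),
    ("SCoT", "SCoT13", 11, 4, 7, 1),
    ("SCoT", "SCoT14", 9, 4, 5, 0),
)

# Morphology fixture: means anchored at the panel's printed maxima
# (yellow 40 cm tall; orange 9 inflorescences, 321 flowers, 2.1 cm flower
# length; violet 40 petals, widest flower).  All other means and every sd
# are synthetic values shaped to the panel's reported significance
# pattern; they are fixtures, not measurements.
_KALANCHOE_TRAITS: dict[str, dict[str, tuple[float, float]]] = {
    # trait -> genotype -> (mean, sd)
    "plant_height_cm": {
        "yellow": (40.0, 2.0), "orange": (37.5, 2.0), "red": (28.0, 2.0),
        "purple": (30.0, 2.0), "violet": (26.0, 2.0),
    },
    "n_inflorescences": {
        "orange": (9.0, 0.8), "violet": (8.2, 0.8), "purple": (7.4, 0.8),
        "red": (5.0, 0.8), "yellow": (5.3, 0.8),
    },
    "n_flowers": {
        "orange": (321.0, 18.0), "violet": (300.0, 18.0), "purple": (255.0, 18.0),
        "red": (150.0, 18.0), "yellow": (160.0, 18.0),
    },
    "flower_length_cm": {
        "orange": (2.1, 0.07), "yellow": (1.7, 0.07), "violet": (1.25, 0.07),
        "purple": (1.28, 0.07), "red": (1.30, 0.07),
    },
    "flower_diameter_mm": {
        "violet": (28.0, 1.2), "orange": (27.0, 1.2), "red": (21.0, 1.2),
        "purple": (19.5, 1.2), "yellow": (12.0, 1.2),
    },
    "n_petals": {
        "violet": (40.0, 1.5), "red": (8.0, 1.5), "yellow": (8.4, 1.5),
        "purple": (9.0, 1.5), "orange": (8.2, 1.5),
    },
}

#: replicate counts: plant-level traits measured on 10 plants; flower-level
#: traits analyzed as per-plant means over 10 plants (50 flowers each)
N_PLANTS = 10


def kalanchoe_fixture(seed: int = 0) -> tuple[BandSpec, MorphoSpec]:
    """Band and morphology specs emulating the five-genotype kalanchoe panel."""
    blocks = tuple(
        PrimerBlockSpec(system=s, primer=p, n_total=t, n_monomorphic=m,
                        n_polymorphic=po, n_unique=u)
        for s, p, t, m, po, u in _KALANCHOE_BLOCKS
    )
    band = BandSpec(genotype_ids=KALANCHOE_GENOTYPES, blocks=blocks, seed=seed)
    entries = tuple(
        TraitEntry(genotype=g, trait=trait, mean=mu, sd=sd, n=N_PLANTS)
        for trait, per_gen in _KALANCHOE_TRAITS.items()
        for g, (mu, sd) in per_gen.items()
    )
    morpho = MorphoSpec(entries=entries, seed=seed + 1)
    return band, morpho


def planted_partition_spec(
    seed: int,
    outlier: str = "yellow",
    pairs: Sequence[tuple[str, str]] = (("orange", "violet"), ("red", "purple")),
    n_monomorphic: int = 5,
    n_outlier_unique: int = 6,
    n_pair_bands: int = 10,
    n_noise: int = 8,
) -> BandSpec:
    """Band spec with a planted {outlier} / {pair} / {pair} structure.

    The outlier carries several bands no one else has; each pair shares
    a block of pair-exclusive bands; noise columns get uniform random
    carrier sets.  Dice similarity is therefore high within pairs and
    low between groups, so cutting a WPGMA tree at k = 3 should recover
    the planted partition.
    """
    genotypes = (outlier,) + tuple(g for pair in pairs for g in pair)
    blocks = [
        PrimerBlockSpec(
            system="SIM", primer="CORE", n_total=n_monomorphic,
            n_monomorphic=n_monomorphic, n_polymorphic=0, n_unique=0,
        ),
        PrimerBlockSpec(
            system="SIM", primer="OUT", n_total=n_outlier_unique,
            n_monomorphic=0, n_polymorphic=n_outlier_unique,
            n_unique=n_outlier_unique,
            unique_owners=(outlier,) * n_outlier_unique,
        ),
    ]
    for i, pair in enumerate(pairs, start=1):
        blocks.append(
            PrimerBlockSpec(
                system="SIM", primer=f"PAIR{i}", n_total=n_pair_bands,
                n_monomorphic=0, n_polymorphic=n_pair_bands, n_unique=0,
                carriers=(tuple(pair),) * n_pair_bands,
            )
        )
    blocks.append(
        PrimerBlockSpec(
            system="SIM", primer="NOISE", n_total=n_noise,
            n_monomorphic=0, n_polymorphic=n_noise, n_unique=0,
        )
    )
    return BandSpec(genotype_ids=genotypes, blocks=tuple(blocks), seed=seed)


# ---------------------------------------------------------------------------
# Spec (de)serialization
# ---------------------------------------------------------------------------

def band_spec_to_dict(spec: BandSpec) -> dict:
    d = asdict(spec)
    d["genotype_ids"] = list(d["genotype_ids"])
    d["blocks"] = [
        {k: (list(v) if isinstance(v, tuple) else v) for k, v in b.items() if v is not None}
        for b in d["blocks"]
    ]
    return d


def band_spec_from_dict(d: dict) -> BandSpec:
    blocks = tuple(
        PrimerBlockSpec(
            system=b["system"], primer=b["primer"], n_total=b["n_total"],
            n_monomorphic=b["n_monomorphic"], n_polymorphic=b["n_polymorphic"],
            n_unique=b["n_unique"],
            unique_owners=tuple(b["unique_owners"]) if b.get("unique_owners") else None,
            carriers=tuple(tuple(c) for c in b["carriers"]) if b.get("carriers") else None,
        )
        for b in d["blocks"]
    )
    return BandSpec(
        genotype_ids=tuple(d["genotype_ids"]), blocks=blocks, seed=int(d.get("seed", 0))
    )


def load_band_spec(path: str | Path) -> BandSpec:
    """Load a band spec from YAML or JSON (decided by extension)."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return band_spec_from_dict(json.loads(text))
    return band_spec_from_dict(yaml.safe_load(text))


def save_band_spec(spec: BandSpec, path: str | Path) -> None:
    d = band_spec_to_dict(spec)
    if str(path).endswith(".json"):
        Path(path).write_text(json.dumps(d, indent=2) + "\n")
    else:
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
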