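"""File formats and domain containers for dominant-marker diversity data.

Two containers travel through the whole pipeline:

``BandMatrix``
    A genotypes x loci binary presence/absence matrix as scored from
    electrophoresis gels of dominant markers (RAPD, ISSR, SCoT, ...).
    Each locus belongs to exactly one primer and each primer to exactly
    one marker system; both are encoded in the locus id as
    ``SYSTEM:PRIMER:index`` (e.g. ``RAPD:OPA7:3``), so a single CSV file
    carries the matrix and its metadata.

``TraitTable``
    Long-format replicate-level morphological measurements
    (genotype, trait, replicate, value).

Newick serialization of dendrograms lives here too, so every on-disk
format has one home.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .clustering import Dendrogram

#: Default morphological trait vocabulary (units encoded in the names).
DEFAULT_TRAIT_VOCABULARY: tuple[str, ...] = (
    "plant_height_cm",
    "n_inflorescences",
    "n_flowers",
    "flower_length_cm",
    "flower_diameter_mm",
    "n_petals",
)


@dataclass(frozen=True)
class LocusMeta:
    """Per-locus metadata: the amplifying primer and its marker system."""

    primer: str
    system: str


def parse_locus_id(locus_id: str) -> LocusMeta:
    """Parse a ``SYSTEM:PRIMER:index`` locus id into its metadata.

    Raises
    ------
    FormatError
        If the id does not have exactly three non-empty ``:``-separated
        fields or the trailing index is not a positive integer.
    """
    parts = locus_id.split(":")
    if len(parts) != 3 or not all(parts):
        raise FormatError(
            f"locus id {locus_id!r} does not follow SYSTEM:PRIMER:index"
        )
    system, primer, index = parts
    if not index.isdigit() or int(index) < 1:
        raise FormatError(
            f"locus id {locus_id!r} has a non positive-integer index"
        )
    return LocusMeta(primer=primer, system=system)


class BandMatrix:
    """Binary genotypes x loci band-presence matrix with locus metadata.

    Parameters
    ----------
    genotype_ids
        Ordered unique genotype labels (rows); at least two.
    locus_ids
        Ordered unique ``SYSTEM:PRIMER:index`` locus labels (columns).
    values
        Array-like of 0/1 of shape ``(n_genotypes, n_loci)``.

    Invariants enforced at construction: entries are exactly 0 or 1 with
    no missing values, no locus column is all-zero (a band scored from a
    gel must appear in at least one lane), and every primer maps to
    exactly one marker system.
    """

    def __init__(
        self,
        genotype_ids: Sequence[str],
        locus_ids: Sequence[str],
        values: np.ndarray | Sequence[Sequence[int]],
    ) -> None:
        self.genotype_ids = list(genotype_ids)
        self.locus_ids = list(locus_ids)
        arr = np.asarray(values)
        if arr.ndim != 2 or arr.shape != (len(self.genotype_ids), len(self.locus_ids)):
            raise FormatError(
                f"values shape {arr.shape} does not match "
                f"{len(self.genotype_ids)} genotypes x {len(self.locus_ids)} loci"
            )
        if len(self.genotype_ids) < 2:
            raise ValidationError("a band matrix needs at least 2 genotypes")
        if len(self.locus_ids) < 1:
            raise ValidationError("a band matrix needs at least 1 locus")
        for label, ids in (("genotype", self.genotype_ids), ("locus", self.locus_ids)):
            dupes = [k for k, c in Counter(ids).items() if c > 1]
            if dupes:
                raise FormatError(f"duplicate {label} id(s): {', '.join(map(str, dupes))}")
        if arr.dtype == object or not np.isin(arr, (0, 1)).all():
            bad = arr[~np.isin(arr, (0, 1))]
            raise FormatError(
                f"band-matrix cells must be 0 or 1; found {bad.ravel()[0]!r}"
            )
        self.values = arr.astype(np.int8)
        zero_cols = np.flatnonzero(self.values.sum(axis=0) == 0)
        if zero_cols.size:
            raise ValidationError(
                "locus column(s) with no band in any genotype: "
                + ", ".join(self.locus_ids[j] for j in zero_cols)
            )
        self.locus_meta: list[LocusMeta] = [parse_locus_id(l) for l in self.locus_ids]
        primer_system: dict[str, str] = {}
        for meta in self.locus_meta:
            prev = primer_system.setdefault(meta.primer, meta.system)
            if prev != meta.system:
                raise FormatError(
                    f"primer {meta.primer!r} assigned to two systems: {prev}, {meta.system}"
                )

    # -- introspection -------------------------------------------------

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def primers(self) -> list[str]:
        """Primer codes in order of first appearance."""
        return list(dict.fromkeys(m.primer for m in self.locus_meta))

    @property
    def systems(self) -> list[str]:
        """Marker systems in order of first appearance."""
        return list(dict.fromkeys(m.system for m in self.locus_meta))

    def system_of_primer(self, primer: str) -> str:
        for meta in self.locus_meta:
            if meta.primer == primer:
                return meta.system
        from .errors import LookupKeyError

        raise LookupKeyError(f"unknown primer: {primer!r}")

    def loci_of_primer(self, primer: str) -> np.ndarray:
        """Column indices of the loci amplified by *primer*."""
        idx = np.array(
            [j for j, m in enumerate(self.locus_meta) if m.primer == primer], dtype=int
        )
        if idx.size == 0:
            from .errors import LookupKeyError

            raise LookupKeyError(f"unknown primer: {primer!r}")
        return idx

    def primers_of_system(self, system: str) -> list[str]:
        primers = list(
            dict.fromkeys(m.primer for m in self.locus_meta if m.system == system)
        )
        if not primers:
            from .errors import LookupKeyError

            raise LookupKeyError(f"unknown system: {system!r}")
        return primers

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.genotype_ids, name="genotype"),
            columns=self.locus_ids,
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BandMatrix)
            and self.genotype_ids == other.genotype_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return (
            f"BandMatrix({self.n_genotypes} genotypes x {self.n_loci} loci, "
            f"systems={self.systems})"
        )


@dataclass
class TraitTable:
    """Replicate-level morphological measurements in long format.

    ``records`` holds columns ``genotype``, ``trait``, ``replicate``,
    ``value``.  Replicates are positive integers; values are finite reals.
    An optional declared ``vocabulary`` restricts trait names;
    ``units`` carries free-form per-trait unit metadata.
    """

    records: pd.DataFrame
    vocabulary: tuple[str, ...] | None = None
    units: Mapping[str, str] = field(default_factory=dict)

    REQUIRED = ("genotype", "trait", "replicate", "value")

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"trait table missing column(s): {', '.join(missing)}")
        df = df.loc[:, list(self.REQUIRED)].copy()
        if len(df):
            rep = pd.to_numeric(df["replicate"], errors="coerce")
            if rep.isna().any() or (rep != rep.astype(int)).any() or (rep < 1).any():
                raise FormatError("replicate must be a positive integer")
            df["replicate"] = rep.astype(int)
            val = pd.to_numeric(df["value"], errors="coerce")
            if val.isna().any():
                bad = df.loc[val.isna(), "value"].iloc[0]
                raise FormatError(f"non-numeric trait value: {bad!r}")
            if not np.isfinite(val).all():
                raise ValidationError("trait values must be finite")
            df["value"] = val.astype(float)
        else:
            df = df.astype({"replicate": int, "value": float})
        if self.vocabulary is not None:
            unknown = sorted(set(df["trait"]) - set(self.vocabulary))
            if unknown:
                raise ValidationError(
                    f"trait(s) outside declared vocabulary: {', '.join(unknown)}"
                )
        self.records = df.reset_index(drop=True)

    @property
    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self.records["genotype"]))

    @property
    def traits(self) -> list[str]:
        return list(dict.fromkeys(self.records["trait"]))

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def read_band_matrix(path: str | Path) -> BandMatrix:
    """Read a band-matrix CSV: header ``genotype,<locus>,...``, cells 0/1."""
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse band-matrix CSV: {exc}") from None
    if df.columns[0] != "genotype":
        raise FormatError(
            f"first column of a band-matrix CSV must be 'genotype', got {df.columns[0]!r}"
        )
    locus_ids = list(df.columns[1:])
    genotype_ids = list(df["genotype"])
    cells = df.iloc[:, 1:].to_numpy()
    try:
        values = cells.astype(int)
    except ValueError as exc:
        raise FormatError(f"non-integer band-matrix cell: {exc}") from None
    if not (cells == values.astype(str)).all():
        raise FormatError("band-matrix cells must be written as integers 0/1")
    return BandMatrix(genotype_ids, locus_ids, values)


def write_band_matrix(m: BandMatrix, path: str | Path) -> None:
    """Write *m* so that :func:`read_band_matrix` reproduces it exactly."""
    m.to_dataframe().to_csv(path, lineterminator="\n")


def read_trait_table(
    path: str | Path, vocabulary: Iterable[str] | None = None
) -> TraitTable:
    """Read a trait CSV with columns ``genotype,trait,replicate,value``."""
    try:
        df = pd.read_csv(
            path, dtype={"genotype": str, "trait": str},
            float_precision="round_trip",
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse trait CSV: {exc}") from None
    vocab = tuple(vocabulary) if vocabulary is not None else None
    return TraitTable(df, vocabulary=vocab)


def write_trait_table(t: TraitTable, path: str | Path) -> None:
    # repr round-trips doubles exactly; pandas' default formatter may not
    t.records.to_csv(
        path, index=False, lineterminator="\n",
        float_format=lambda v: repr(float(v)),
    )


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def _fmt_branch(x: float) -> str:
    """Format a branch length compactly but always with a decimal point."""
    if x < 0 and x > -1e-12:  # guard tiny negative round-off
        x = 0.0
    s = f"{x:.10g}"
    if "." not in s and "e" not in s and "E" not in s:
        s += ".0"
    return s


def newick_string(tree: "Dendrogram") -> str:
    """Render an ultrametric dendrogram as Newick.

    Branch lengths are ``parent height - child height``, so the
    leaf-to-leaf path length through the lowest common ancestor equals
    the cophenetic distance.
    """

    def render(node, parent_height: float | None) -> str:
        if node.is_leaf:
            body = node.label
        else:
            body = "(" + ",".join(render(c, node.height) for c in node.children) + ")"
        if parent_height is None:
            return body
        return f"{body}:{_fmt_branch(parent_height - node.height)}"

    return render(tree.root, None) + ";"


def write_newick(tree: "Dendrogram", path: str | Path) -> None:
    Path(path).write_text(newick_string(tree) + "\n")


# ---------------------------------------------------------------------------
# Square matrix CSV (similarity / distance)
# ---------------------------------------------------------------------------

def write_square_matrix(ids: Sequence[str], matrix: np.ndarray, path: str | Path) -> None:
    """Write a labelled square matrix (similarity or distance) as CSV."""
    pd.DataFrame(matrix, index=pd.Index(ids, name="genotype"), columns=ids).to_csv(
        path, lineterminator="\n", float_format="%.6g"
    )


def read_square_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError("square-matrix CSV must have identical row and column labels")
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise FormatError("square-matrix CSV contains non-finite values")
    return list(df.index), values
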