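"""Polymorphism statistics for dominant-marker band matrices.

Classifies each scored locus as monomorphic (band in every genotype),
polymorphic (band in some but not all) or unique (band in exactly one
genotype; a special case of polymorphic), aggregates the counts per
primer and per marker system, and computes the percentage-fidelity index
that contrasts two systems' unique-band yield against their total-band
yield:

    fidelity = 100 * u_A / u_B  -  100 * l_A / l_B

where ``u`` are unique-locus counts and ``l`` total-locus counts.  Both
terms are rounded half-up to two decimals before subtraction, matching
how such tables print the intermediate ratios.

Percentage conventions
----------------------
Per-primer polymorphism is ``100 * polymorphic / total``.  Published
marker-survey tables typically print this truncated to an integer
(2/3 -> 66, not 67); the per-system "average polymorphism" is then the
arithmetic mean of those printed values.  Both the raw and the printed
flavours are always reported so the convention stays auditable.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np

from .errors import LookupKeyError, ValidationError
from .io_formats import BandMatrix


class LocusClass(enum.Enum):
    """Diversity class of one locus column."""

    MONOMORPHIC = "monomorphic"
    POLYMORPHIC = "polymorphic"
    UNIQUE = "unique"

    @property
    def is_polymorphic(self) -> bool:
        """Unique loci are polymorphic for counting purposes."""
        return self is not LocusClass.MONOMORPHIC


def classify_locus(column: np.ndarray) -> LocusClass:
    """Classify one binary presence column over genotypes.

    Monomorphic iff the band is present in every genotype, unique iff in
    exactly one; otherwise polymorphic.  An all-zero column is invalid
    (such a band was never scored).
    """
    col = np.asarray(column)
    if col.size < 2:
        raise ValidationError("a locus column needs at least 2 genotypes")
    if not np.isin(col, (0, 1)).all():
        raise ValidationError("locus column entries must be 0 or 1")
    s = int(col.sum())
    if s == 0:
        raise ValidationError("all-zero locus column cannot be classified")
    if s == col.size:
        return LocusClass.MONOMORPHIC
    if s == 1:
        return LocusClass.UNIQUE
    return LocusClass.POLYMORPHIC


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at *ndigits* decimals (4.005 -> 4.01)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PrimerSummary:
    """One primer's locus counts and polymorphism percentage."""

    primer_code: str
    system: str
    n_total: int
    n_monomorphic: int
    n_polymorphic: int
    n_unique: int
    polymorphism_pct_raw: float
    polymorphism_pct_printed: int  # floor of the raw percentage

    def __post_init__(self) -> None:
        if self.n_monomorphic + self.n_polymorphic != self.n_total:
            raise ValidationError(
                f"{self.primer_code}: monomorphic + polymorphic != total"
            )
        if self.n_unique > self.n_polymorphic:
            raise ValidationError(f"{self.primer_code}: unique > polymorphic")


@dataclass(frozen=True)
class SystemSummary:
    """Aggregate of one marker system's primers (totals and averages)."""

    system: str
    primers: tuple[PrimerSummary, ...]
    n_total: int
    n_monomorphic: int
    n_polymorphic: int
    n_unique: int
    avg_total: float
    avg_monomorphic: float
    avg_polymorphic: float
    avg_unique: float
    #: arithmetic mean of the per-primer *printed* (floored) percentages
    polymorphism_pct_mean: float
    #: the mean rounded half-up to 2 decimals, as a table would display it
    polymorphism_pct_display: float


@dataclass(frozen=True)
class FidelityResult:
    """Percentage fidelity of system A relative to system B."""

    system_a: str
    system_b: str
    u_a: int
    u_b: int
    l_a: int
    l_b: int
    term_unique: float  # round2(100 * u_a / u_b)
    term_total: float   # round2(100 * l_a / l_b)
    fidelity_pct: float


def primer_summary(m: BandMatrix, primer_code: str) -> PrimerSummary:
    """Count locus classes for one primer's block of the matrix."""
    cols = m.loci_of_primer(primer_code)
    classes = [classify_locus(m.values[:, j]) for j in cols]
    n_total = len(classes)
    n_mono = sum(c is LocusClass.MONOMORPHIC for c in classes)
    n_unique = sum(c is LocusClass.UNIQUE for c in classes)
    n_poly = n_total - n_mono
    raw = 100.0 * n_poly / n_total
    return PrimerSummary(
        primer_code=primer_code,
        system=m.system_of_primer(primer_code),
        n_total=n_total,
        n_monomorphic=n_mono,
        n_polymorphic=n_poly,
        n_unique=n_unique,
        polymorphism_pct_raw=raw,
        polymorphism_pct_printed=math.floor(raw),
    )


def system_summary(m: BandMatrix, system: str) -> SystemSummary:
    """Aggregate counts over every primer of one marker system."""
    primers = tuple(primer_summary(m, p) for p in m.primers_of_system(system))
    k = len(primers)
    tot = sum(p.n_total for p in primers)
    mono = sum(p.n_monomorphic for p in primers)
    poly = sum(p.n_polymorphic for p in primers)
    uniq = sum(p.n_unique for p in primers)
    pct_mean = sum(p.polymorphism_pct_printed for p in primers) / k
    return SystemSummary(
        system=system,
        primers=primers,
        n_total=tot,
        n_monomorphic=mono,
        n_polymorphic=poly,
        n_unique=uniq,
        avg_total=tot / k,
        avg_monomorphic=mono / k,
        avg_polymorphic=poly / k,
        avg_unique=uniq / k,
        polymorphism_pct_mean=pct_mean,
        polymorphism_pct_display=round_half_up(pct_mean, 2),
    )


def fidelity_percent(summary_a: SystemSummary, summary_b: SystemSummary) -> FidelityResult:
    """Percentage fidelity of system A relative to system B.

    Each ratio is computed exactly and rounded half-up to 2 decimals
    before the subtraction, so e.g. (4, 5, 15, 38) gives
    80.00 - 39.47 = 40.53.
    """
    u_a, u_b = summary_a.n_unique, summary_b.n_unique
    l_a, l_b = summary_a.n_total, summary_b.n_total
    if u_b == 0:
        raise ValidationError(
            f"fidelity undefined: system {summary_b.system!r} has no unique loci"
        )
    if l_b == 0:
        raise ValidationError(
            f"fidelity undefined: system {summary_b.system!r} has no loci"
        )
    term_unique = float(
        (Decimal(100 * u_a) / Decimal(u_b)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )
    term_total = float(
        (Decimal(100 * l_a) / Decimal(l_b)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )
    return FidelityResult(
        system_a=summary_a.system,
        system_b=summary_b.system,
        u_a=u_a,
        u_b=u_b,
        l_a=l_a,
        l_b=l_b,
        term_unique=term_unique,
        term_total=term_total,
        fidelity_pct=round(term_unique - term_total, 10),
    )


@dataclass(frozen=True)
class MarkerReport:
    """Full per-primer / per-system report plus grand totals."""

    systems: tuple[SystemSummary, ...]
    grand_total: int
    grand_monomorphic: int
    grand_polymorphic: int
    grand_unique: int
    fidelity: FidelityResult | None = None


def marker_report(
    m: BandMatrix, fidelity_pair: tuple[str, str] | None = None
) -> MarkerReport:
    """Summarize every system of *m*; optionally add a fidelity line.

    ``fidelity_pair=(A, B)`` computes the fidelity of system A relative
    to system B.  When omitted and both RAPD and SCoT are present, the
    conventional RAPD-vs-SCoT fidelity is included automatically.
    """
    systems = tuple(system_summary(m, s) for s in m.systems)
    by_name = {s.system: s for s in systems}
    fid = None
    if fidelity_pair is None and {"RAPD", "SCoT"} <= set(by_name):
        fidelity_pair = ("RAPD", "SCoT")
    if fidelity_pair is not None:
        a, b = fidelity_pair
        for name in (a, b):
            if name not in by_name:
                raise LookupKeyError(f"unknown system: {name!r}")
        fid = fidelity_percent(by_name[a], by_name[b])
    return MarkerReport(
        systems=systems,
        grand_total=sum(s.n_total for s in systems),
        grand_monomorphic=sum(s.n_monomorphic for s in systems),
        grand_polymorphic=sum(s.n_polymorphic for s in systems),
        grand_unique=sum(s.n_unique for s in systems),
        fidelity=fid,
    )


def _num(x: float) -> str:
    """Trim trailing zeros of a float for table display (3.75, 1, 60.25)."""
    return f"{x:g}"


def report_to_tsv(report: MarkerReport) -> str:
    """Render a report as TSV: primer rows, Average/Total rows, fidelity."""
    lines = [
        "system\tprimer\tn_loci\tn_monomorphic\tn_polymorphic\tn_unique\tpolymorphism_pct"
    ]
    for s in report.systems:
        for p in s.primers:
            lines.append(
                f"{s.system}\t{p.primer_code}\t{p.n_total}\t{p.n_monomorphic}"
                f"\t{p.n_polymorphic}\t{p.n_unique}\t{p.polymorphism_pct_printed}%"
            )
        lines.append(
            f"{s.system}\tAverage\t{_num(s.avg_total)}\t{_num(s.avg_monomorphic)}"
            f"\t{_num(s.avg_polymorphic)}\t{_num(s.avg_unique)}"
            f"\t{_num(s.polymorphism_pct_display)}%"
        )
        lines.append(
            f"{s.system}\tTotal\t{s.n_total}\t{s.n_monomorphic}"
            f"\t{s.n_polymorphic}\t{s.n_unique}\t"
        )
    lines.append(
        f"all\tTotal\t{report.grand_total}\t{report.grand_monomorphic}"
        f"\t{report.grand_polymorphic}\t{report.grand_unique}\t"
    )
    if report.fidelity is not None:
        f = report.fidelity
        lines.append(
            f"fidelity\t{f.system_a}/{f.system_b}\t{f.term_unique:.2f}"
            f"\t{f.term_total:.2f}\t\t\t{f.fidelity_pct:.2f}%"
        )
    return "\n".join(lines) + "\n"


def report_to_dict(report: MarkerReport) -> dict:
    """JSON-ready nested dict of a marker report."""
    out: dict = {"systems": [], "grand_total": {
        "n_loci": report.grand_total,
        "n_monomorphic": report.grand_monomorphic,
        "n_polymorphic": report.grand_polymorphic,
        "n_unique": report.grand_unique,
    }}
    for s in report.systems:
        out["systems"].append(
            {
                "system": s.system,
                "primers": [
                    {
                        "primer": p.primer_code,
                        "n_loci": p.n_total,
                        "n_monomorphic": p.n_monomorphic,
                        "n_polymorphic": p.n_polymorphic,
                        "n_unique": p.n_unique,
                        "polymorphism_pct_raw": p.polymorphism_pct_raw,
                        "polymorphism_pct_printed": p.polymorphism_pct_printed,
                    }
                    for p in s.primers
                ],
                "total": {
                    "n_loci": s.n_total,
                    "n_monomorphic": s.n_monomorphic,
                    "n_polymorphic": s.n_polymorphic,
                    "n_unique": s.n_unique,
                },
                "average": {
                    "n_loci": s.avg_total,
                    "n_monomorphic": s.avg_monomorphic,
                    "n_polymorphic": s.avg_polymorphic,
                    "n_unique": s.avg_unique,
                    "polymorphism_pct_mean": s.polymorphism_pct_mean,
                    "polymorphism_pct_display": s.polymorphism_pct_display,
                },
            }
        )
    if report.fidelity is not None:
        f = report.fidelity
        out["fidelity"] = {
            "system_a": f.system_a,
            "system_b": f.system_b,
            "u_a": f.u_a,
            "u_b": f.u_b,
            "l_a": f.l_a,
            "l_b": f.l_b,
            "term_unique": f.term_unique,
            "term_total": f.term_total,
            "fidelity_pct": f.fidelity_pct,
        }
    return out


def write_report(report: MarkerReport, tsv_path: str | Path, json_path: str | Path) -> None:
    Path(tsv_path).write_text(report_to_tsv(report))
    Path(json_path).write_text(json.dumps(report_to_dict(report), indent=2) + "\n")
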