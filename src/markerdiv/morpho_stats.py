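"""Morphological trait analysis: summaries, Fisher's LSD, trait distances.

For each trait a one-way ANOVA over genotypes pools the within-group
variance into a single mean-square error (MSE).  Fisher's (unprotected)
least significant difference then declares genotypes i, j different at
level alpha when

    |mean_i - mean_j|  >  t(1 - alpha/2, df_within) * sqrt(MSE * (1/n_i + 1/n_j))

The pairwise outcome is summarized as a compact letter display (CLD):
genotypes share at least one letter exactly when they are *not*
significantly different.  Letters are the maximal cliques of the
non-significance graph, lettered in genotype order.

A z-score-standardized Euclidean distance over per-genotype trait means
feeds the morphology dendrogram; standardization keeps count-valued
traits (hundreds of flowers) from swamping centimetre-scale ones.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .errors import LookupKeyError, MarkerdivError, ValidationError
from .io_formats import TraitTable
from .similarity import DistanceMatrix


def summarize(t: TraitTable) -> pd.DataFrame:
    """Per-(genotype, trait) replicate count, mean and standard error.

    SE uses the n-1 sample standard deviation; groups with a single
    replicate get ``NaN`` SE and ``se_defined=False``.
    """
    if len(t) == 0:
        return pd.DataFrame(
            columns=["genotype", "trait", "n", "mean", "se", "se_defined"]
        )
    g = t.records.groupby(["genotype", "trait"], sort=False)["value"]
    out = g.agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1)).reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out["se_defined"] = out["n"] >= 2
    return out.drop(columns="sd")


@dataclass
class LsdResult:
    """One trait's ANOVA, pairwise LSD outcomes and letter display."""

    trait: str
    alpha: float
    genotypes: list[str]
    means: dict[str, float]
    ns: dict[str, int]
    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    mse: float
    #: common LSD threshold when the design is balanced, else None
    lsd_value: float | None
    #: boolean DataFrame, True where the pair differs significantly
    significant: pd.DataFrame
    letters: dict[str, str]


def _letters_from_nonsig(genotypes: list[str], nonsig: nx.Graph) -> dict[str, str]:
    """Compact letter display from the non-significance graph.

    Letters are the maximal cliques; two genotypes share a letter iff
    they are adjacent (not significantly different).  Cliques are
    ordered by their first member in genotype order and lettered
    a, b, ..., z, aa, ab, ...
    """
    order = {g: i for i, g in enumerate(genotypes)}
    cliques = [sorted(c, key=order.__getitem__) for c in nx.find_cliques(nonsig)]
    cliques.sort(key=lambda c: [order[g] for g in c])

    def letter(i: int) -> str:
        letters = string.ascii_lowercase
        if i < 26:
            return letters[i]
        return letters[i // 26 - 1] + letters[i % 26]

    assigned: dict[str, list[str]] = {g: [] for g in genotypes}
    for i, clique in enumerate(cliques):
        for g in clique:
            assigned[g].append(letter(i))
    return {g: "".join(ls) for g, ls in assigned.items()}


def lsd_test(t: TraitTable, trait: str, alpha: float = 0.05) -> LsdResult:
    """One-way ANOVA plus Fisher's LSD pairwise comparisons for *trait*.

    Requires >= 2 genotypes with >= 2 replicates each.  ``alpha`` is the
    per-comparison level (the display convention is p <= 0.05); values
    above 0.5 are accepted but flagged as degenerate with a warning.
    """
    if trait not in set(t.records["trait"]):
        raise LookupKeyError(f"trait {trait!r} not present in the table")
    if not 0.0 < alpha <= 1.0:
        raise MarkerdivError(f"alpha must be in (0, 1], got {alpha}")
    if alpha > 0.5:
        warnings.warn(
            f"degenerate alpha={alpha}: nearly every non-identical pair will "
            "be declared significant",
            stacklevel=2,
        )
    sub = t.records[t.records["trait"] == trait]
    groups = {g: v["value"].to_numpy() for g, v in sub.groupby("genotype", sort=False)}
    genotypes = list(groups)
    if len(genotypes) < 2:
        raise MarkerdivError(f"LSD needs >= 2 genotypes for trait {trait!r}")
    small = [g for g, v in groups.items() if len(v) < 2]
    if small:
        raise ValidationError(
            f"genotype(s) with < 2 replicates for {trait!r}: {', '.join(small)}"
        )

    ns = {g: len(v) for g, v in groups.items()}
    means = {g: float(v.mean()) for g, v in groups.items()}
    n_total = sum(ns.values())
    k = len(genotypes)
    grand = sum(v.sum() for v in groups.values()) / n_total
    ss_between = sum(ns[g] * (means[g] - grand) ** 2 for g in genotypes)
    ss_within = sum(((v - means[g]) ** 2).sum() for g, v in groups.items())
    df_between, df_within = k - 1, n_total - k
    mse = ss_within / df_within
    if mse > 0:
        f_stat = (ss_between / df_between) / mse
        p_value = float(stats.f.sf(f_stat, df_between, df_within))
    elif ss_between > 0:  # perfectly separated groups
        f_stat, p_value = float("inf"), 0.0
    else:  # zero variance everywhere, equal means
        f_stat, p_value = float("nan"), 1.0

    t_crit = float(stats.t.ppf(1 - alpha / 2, df_within))
    sig = pd.DataFrame(False, index=genotypes, columns=genotypes)
    for i, gi in enumerate(genotypes):
        for gj in genotypes[i + 1:]:
            thresh = t_crit * np.sqrt(mse * (1 / ns[gi] + 1 / ns[gj]))
            is_sig = abs(means[gi] - means[gj]) > thresh
            sig.loc[gi, gj] = sig.loc[gj, gi] = bool(is_sig)

    balanced = len(set(ns.values())) == 1
    lsd_value = (
        float(t_crit * np.sqrt(2 * mse / next(iter(ns.values())))) if balanced else None
    )

    nonsig = nx.Graph()
    nonsig.add_nodes_from(genotypes)
    for i, gi in enumerate(genotypes):
        for gj in genotypes[i + 1:]:
            if not sig.loc[gi, gj]:
                nonsig.add_edge(gi, gj)
    letters = _letters_from_nonsig(genotypes, nonsig)

    return LsdResult(
        trait=trait,
        alpha=alpha,
        genotypes=genotypes,
        means=means,
        ns=ns,
        f_stat=f_stat,
        p_value=p_value,
        df_between=df_between,
        df_within=df_within,
        mse=mse,
        lsd_value=lsd_value,
        significant=sig,
        letters=letters,
    )


def pairwise_t_test(t: TraitTable, trait: str, alpha: float = 0.05) -> pd.DataFrame:
    """Plain two-sample Welch t-tests per pair, for comparison with LSD."""
    sub = t.records[t.records["trait"] == trait]
    groups = {g: v["value"].to_numpy() for g, v in sub.groupby("genotype", sort=False)}
    genotypes = list(groups)
    rows = []
    for i, gi in enumerate(genotypes):
        for gj in genotypes[i + 1:]:
            res = stats.ttest_ind(groups[gi], groups[gj], equal_var=False)
            rows.append(
                {
                    "genotype_a": gi,
                    "genotype_b": gj,
                    "t": float(res.statistic),
                    "p": float(res.pvalue),
                    "significant": bool(res.pvalue <= alpha),
                }
            )
    return pd.DataFrame(rows)


def morpho_distance(summary: pd.DataFrame, standardize: bool = True) -> DistanceMatrix:
    """Euclidean distance between genotype trait-mean profiles.

    ``summary`` is the output of :func:`summarize`.  With
    ``standardize`` (default) each trait's means are z-scored across
    genotypes first; traits constant across genotypes carry no
    information and are dropped with a warning.
    """
    profile = summary.pivot(index="genotype", columns="trait", values="mean")
    if profile.isna().any().any():
        missing = profile.stack(dropna=False)
        pairs = missing[missing.isna()].index.tolist()
        raise ValidationError(f"missing trait means for: {pairs}")
    if standardize:
        sd = profile.std(ddof=1)
        constant = list(sd.index[(sd == 0) | sd.isna()])
        if constant:
            warnings.warn(
                f"dropping constant trait(s) before standardization: {constant}",
                stacklevel=2,
            )
            profile = profile.drop(columns=constant)
            sd = sd.drop(index=constant)
        if profile.shape[1] == 0:
            raise ValidationError("no varying trait left after dropping constants")
        profile = (profile - profile.mean()) / sd
    d = squareform(pdist(profile.to_numpy(), metric="euclidean"))
    return DistanceMatrix(list(profile.index), d, method="euclidean-traits")


def lsd_report_tsv(results: list[LsdResult], summary: pd.DataFrame) -> str:
    """TSV report: one block per trait with means +/- SE and letters."""
    lines = ["trait\tgenotype\tn\tmean\tse\tletter\tF\tp\tlsd"]
    se_lookup = {
        (r.genotype, r.trait): r.se for r in summary.itertuples(index=False)
    }
    for res in results:
        lsd_str = f"{res.lsd_value:.4g}" if res.lsd_value is not None else "unbalanced"
        for g in res.genotypes:
            se = se_lookup.get((g, res.trait), float("nan"))
            lines.append(
                f"{res.trait}\t{g}\t{res.ns[g]}\t{res.means[g]:.4g}\t{se:.4g}"
                f"\t{res.letters[g]}\t{res.f_stat:.4g}\t{res.p_value:.4g}\t{lsd_str}"
            )
    return "\n".join(lines) + "\n"
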