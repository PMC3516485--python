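"""Expression-side tests: switch models, differential expression, enrichment.

The switch model predicts a step change in expression between allele
classes rather than a graded response, so it is tested by comparing mean
expression between allele classes directly (two-sample t-test for two
classes, one-way ANOVA for three).  Differential expression between the
two populations is a per-gene two-sample t-test on RPKM.  Enrichment of
promoter TRs among differentially expressed (or never-expressed) genes
uses a two-sided Fisher exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeTable


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x isolates RPKM matrix from TSV (first column gene_id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def rpkm_from_counts(counts: pd.DataFrame, transcript_lengths: pd.Series,
                     mapped_totals: pd.Series) -> pd.DataFrame:
    """RPKM = count * 1e9 / (transcript length [bp] * mapped reads in sample)."""
    lengths = transcript_lengths.reindex(counts.index)
    totals = mapped_totals.reindex(counts.columns)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive transcript length")
    if totals.isna().any() or (totals <= 0).any():
        raise ValueError("every isolate needs a positive mapped-read total")
    return counts.mul(1e9).div(lengths, axis=0).div(totals, axis=1)


# ---------------------------------------------------------------- switch test

@dataclass(frozen=True)
class SwitchResult:
    locus_id: str
    grouping: str
    allele_classes: dict[float, list[str]]  # allele length -> isolates
    n_classes: int
    test: str  # "t_test" or "anova"
    statistic: float | None
    p: float | None
    underpowered: bool = False
    significant_nominal: bool | None = None
    significant_bonferroni: bool | None = None


def eligible_switch_loci(genotypes: GenotypeTable, grouping: str = "popA",
                         min_freq: float = 0.25) -> dict[str, dict[float, list[str]]]:
    """Loci with 2 or 3 allele classes at within-grouping frequency >= min_freq.

    Frequencies are computed over non-missing calls in the grouping;
    isolates carrying rarer alleles are dropped from the returned classes
    (they do not enter the test).  Loci with one qualifying class (no
    contrast) or more than three are not eligible.
    """
    isolates = genotypes.isolates_of(grouping)
    out: dict[str, dict[float, list[str]]] = {}
    for locus in genotypes.lengths.index:
        calls = genotypes.lengths.loc[locus, isolates].dropna()
        if calls.empty:
            continue
        freqs = calls.value_counts(normalize=True)
        classes = {
            float(allele): sorted(calls.index[calls == allele])
            for allele, f in freqs.items() if f >= min_freq - 1e-12
        }
        if len(classes) in (2, 3):
            out[locus] = dict(sorted(classes.items()))
    return out


def switch_test(expression_by_class: Mapping[float, Sequence[float]], *,
                locus_id: str = "", grouping: str = "", equal_var: bool = True) -> SwitchResult:
    """Step-change test: t-test for two allele classes, one-way ANOVA for three.

    A class with fewer than two observations leaves the test without
    error degrees of freedom; the result is flagged underpowered and
    carries no p-value.
    """
    classes = {float(k): list(v) for k, v in expression_by_class.items()}
    n_classes = len(classes)
    if n_classes not in (2, 3):
        raise ValueError(f"switch test needs 2 or 3 allele classes, got {n_classes}")
    groups = [np.asarray(v, dtype=float) for v in classes.values()]
    test = "t_test" if n_classes == 2 else "anova"
    iso_classes = {k: [str(i) for i in range(len(v))] for k, v in classes.items()}
    if any(len(g) < 2 for g in groups):
        return SwitchResult(locus_id, grouping, iso_classes, n_classes, test,
                            None, None, underpowered=True)
    if n_classes == 2:
        stat, p = stats.ttest_ind(groups[0], groups[1], equal_var=equal_var)
    else:
        stat, p = stats.f_oneway(*groups)
    if math.isnan(p):  # zero variance everywhere: no evidence of a step
        diff = any(abs(g.mean() - groups[0].mean()) > 0 for g in groups[1:])
        stat, p = (math.inf, 0.0) if diff else (0.0, 1.0)
    return SwitchResult(locus_id, grouping, iso_classes, n_classes, test,
                        float(stat), float(p))


def run_switch_scan(genotypes: GenotypeTable, expression: pd.DataFrame,
                    locus_to_gene: Mapping[str, str], grouping: str = "popA", *,
                    min_freq: float = 0.25, alpha_nominal: float = 0.01,
                    alpha_family: float = 0.05, equal_var: bool = True,
                    bonferroni_m: int | None = None) -> list[SwitchResult]:
    """Run switch tests over all eligible loci of a grouping.

    The Bonferroni cutoff divides ``alpha_family`` by the number of tests
    that produced a p-value, unless ``bonferroni_m`` overrides it.
    """
    eligible = eligible_switch_loci(genotypes, grouping, min_freq)
    results: list[SwitchResult] = []
    for locus, classes in eligible.items():
        gene = locus_to_gene.get(locus)
        if gene is None or gene not in expression.index:
            continue
        by_class = {allele: expression.loc[gene, isolates].to_numpy(dtype=float)
                    for allele, isolates in classes.items()}
        res = switch_test(by_class, locus_id=locus, grouping=grouping, equal_var=equal_var)
        results.append(SwitchResult(res.locus_id, res.grouping, classes, res.n_classes,
                                    res.test, res.statistic, res.p, res.underpowered))
    m = bonferroni_m if bonferroni_m is not None else sum(1 for r in results if r.p is not None)
    cutoff = alpha_family / m if m else math.nan
    return [
        SwitchResult(r.locus_id, r.grouping, r.allele_classes, r.n_classes, r.test,
                     r.statistic, r.p, r.underpowered,
                     None if r.p is None else r.p < alpha_nominal,
                     None if r.p is None else r.p < cutoff)
        for r in results
    ]


# -------------------------------------------------- differential expression

def _pooled_t(a: np.ndarray, b: np.ndarray, equal_var: bool = True) -> tuple[float, float]:
    import warnings

    with warnings.catch_warnings():
        # near-constant samples trip scipy's precision-loss warning; the
        # degenerate outcomes are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if math.isnan(p):  # both samples constant
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.inf, 0.0
    return float(stat), float(p)


def de_genes(expression: pd.DataFrame, genotypes_or_pops, alpha: float = 0.05, *,
             equal_var: bool = True) -> pd.DataFrame:
    """Per-gene two-sample t-test of RPKM between the two populations.

    ``genotypes_or_pops`` is either a :class:`GenotypeTable` or a mapping
    isolate -> population label.  Returns a DataFrame indexed by gene with
    columns t, p and de (p < alpha).
    """
    if isinstance(genotypes_or_pops, GenotypeTable):
        pop = genotypes_or_pops.population
    else:
        pop = pd.Series(dict(genotypes_or_pops))
    pop = pop.reindex(expression.columns)
    if pop.isna().any():
        raise ValueError("every expression column needs a population label")
    labels = [lbl for i, lbl in enumerate(pop.unique()) if i < 2]
    if pop.nunique() != 2:
        raise ValueError("expected exactly 2 populations")
    cols_a = expression.columns[pop == labels[0]]
    cols_b = expression.columns[pop == labels[1]]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >=2 isolates per population")
    rows = {}
    A = expression[cols_a].to_numpy(dtype=float)
    B = expression[cols_b].to_numpy(dtype=float)
    for i, gene in enumerate(expression.index):
        t, p = _pooled_t(A[i], B[i], equal_var)
        rows[gene] = (t, p, p < alpha)
    return pd.DataFrame.from_dict(rows, orient="index", columns=["t", "p", "de"])


# ------------------------------------------------------------- Fisher tests

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows = condition, columns = outcome."""

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_two_sided: float


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> ContingencyTable2x2:
    """Two-sided Fisher exact test (minimum-likelihood method).

    The p-value sums hypergeometric probabilities of all tables with the
    same margins whose probability does not exceed the observed table's.
    The odds ratio is the sample estimate ad/bc (infinite when bc = 0 and
    ad > 0).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        p = 1.0
    else:
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return ContingencyTable2x2(a, b, c, d, odds, float(p))


def tr_enrichment(de_set: set[str], tr_gene_set: set[str], universe: set[str]) -> ContingencyTable2x2:
    """Fisher test of promoter-TR presence among differentially expressed genes.

    Table rows: promoter contains a TR or not; columns: gene
    differentially expressed or not; counted over the gene universe.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not de_set <= universe or not tr_gene_set <= universe:
        raise ValueError("de_set and tr_gene_set must be subsets of the universe")
    a = len(tr_gene_set & de_set)
    b = len(tr_gene_set - de_set)
    c = len(de_set - tr_gene_set)
    d = len(universe - de_set - tr_gene_set)
    return fisher_exact_2x2(a, b, c, d)


def unexpressed_genes(expression: pd.DataFrame) -> set[str]:
    """Genes with zero RPKM in every isolate."""
    return set(expression.index[(expression == 0).all(axis=1)])


def unexpressed_enrichment(expression: pd.DataFrame, tr_gene_set: set[str],
                           universe: set[str] | None = None) -> ContingencyTable2x2:
    """Fisher test of never-expressed status vs promoter-TR presence.

    A gene counts as unexpressed when its RPKM is zero in every isolate
    (the heterochromatin-silencing prediction).
    """
    if universe is None:
        universe = set(expression.index)
    if not universe:
        raise ValueError("empty gene universe")
    silent = unexpressed_genes(expression) & universe
    tr = tr_gene_set & universe
    a = len(tr & silent)
    b = len(tr - silent)
    c = len(silent - tr)
    d = len(universe - tr - silent)
    return fisher_exact_2x2(a, b, c, d)
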