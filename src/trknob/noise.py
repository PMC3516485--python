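"""Expression-noise comparisons: TR genes versus matched background gene sets.

If promoter tandem repeats make expression noisy, genes carrying them
should show larger expression variance than comparable genes without
them.  Two background constructions control for confounders: genomic
neighbours (the two nearest genes on each side of every TR gene, which
share the local chromatin environment) and function-matched random sets
(one same-category gene sampled per TR gene, repeated for several
independent sets).  Group differences in per-gene variance are assessed
by one-way ANOVA with Tukey-Kramer adjusted pairwise comparisons, which
handle unequal group sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .genotypes import FTestResult, variance_ratio_test

logger = logging.getLogger(__name__)


def per_gene_variance(expression: pd.DataFrame, isolates: Sequence[str] | None = None,
                      log_scale: bool = False, eps: float = 1e-6) -> pd.Series:
    """Unbiased per-gene RPKM variance across the chosen isolates (default all).

    ``log_scale`` returns log10(variance + eps), a robustness option for
    heavy-tailed expression distributions.
    """
    sub = expression if isolates is None else expression[list(isolates)]
    v = sub.var(axis=1, ddof=1)
    return np.log10(v + eps) if log_scale else v


def genomic_neighbor_backgrounds(
    tr_genes: Iterable[str],
    gene_order: Mapping[str, Sequence[str]],
    strands: Mapping[str, str] | None = None,
    offset: int = 2,
) -> tuple[set[str], set[str]]:
    """Collect the ``offset`` nearest genes on each side of every TR gene.

    ``gene_order`` maps chromosome -> genes in genomic order.  "Upstream"
    follows the focal gene's strand (for a minus-strand gene the upstream
    neighbours sit at higher genomic positions); with no strand map all
    genes are treated as plus-strand.  Neighbours that themselves carry
    promoter TRs are dropped, as are positions off the chromosome.
    Returns deduplicated (upstream, downstream) sets.
    """
    tr_set = set(tr_genes)
    index: dict[str, tuple[str, int]] = {}
    for chrom, genes in gene_order.items():
        for i, g in enumerate(genes):
            index[g] = (chrom, i)
    upstream: set[str] = set()
    downstream: set[str] = set()
    for gene in tr_set:
        if gene not in index:
            raise KeyError(f"TR gene {gene!r} absent from gene order")
        chrom, i = index[gene]
        genes = gene_order[chrom]
        strand = (strands or {}).get(gene, "+")
        left = [genes[j] for j in range(i - offset, i) if j >= 0]
        right = [genes[j] for j in range(i + 1, i + 1 + offset) if j < len(genes)]
        up, down = (left, right) if strand == "+" else (right, left)
        if not up and not down:
            logger.warning("TR gene %s has no usable neighbours", gene)
        upstream.update(g for g in up if g not in tr_set)
        downstream.update(g for g in down if g not in tr_set)
    return upstream, downstream


def functional_backgrounds(
    tr_genes: Iterable[str],
    categories: Mapping[str, str | Sequence[str]],
    all_genes: Iterable[str],
    n_sets: int = 10,
    seed: int | np.random.Generator = 0,
) -> list[set[str]]:
    """Build ``n_sets`` random background sets matched on functional category.

    Each set contains, for every TR gene, one uniformly sampled non-TR
    gene of the same category, without replacement within a set, so every
    set reproduces the TR set's category frequencies exactly (except where
    a category has too few non-TR members, which is logged and skipped).
    Genes annotated with several categories are resolved to one by a
    seeded uniform choice.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tr_set = set(tr_genes)

    def resolve(gene: str) -> str | None:
        cat = categories.get(gene)
        if cat is None:
            return None
        if isinstance(cat, str):
            return cat
        cats = list(cat)
        return cats[rng.integers(len(cats))] if cats else None

    resolved = {g: resolve(g) for g in set(all_genes) | tr_set}
    missing = [g for g in sorted(tr_set) if resolved.get(g) is None]
    if missing:
        raise ValueError(f"TR genes without a functional category: {missing}")
    pool_by_cat: dict[str, list[str]] = {}
    for g in sorted(set(all_genes) - tr_set):
        c = resolved[g]
        if c is not None:
            pool_by_cat.setdefault(c, []).append(g)

    sets: list[set[str]] = []
    for _ in range(n_sets):
        chosen: set[str] = set()
        for gene in sorted(tr_set):
            pool = [g for g in pool_by_cat.get(resolved[gene], []) if g not in chosen]
            if not pool:
                logger.warning("no non-TR gene left in category %r for %s; slot skipped",
                               resolved[gene], gene)
                continue
            chosen.add(pool[rng.integers(len(pool))])
        sets.append(chosen)
    return sets


@dataclass
class VarianceReport:
    """ANOVA over group variances plus Tukey-Kramer pairwise comparisons."""

    groups: dict[str, list[str]]
    anova_F: float
    anova_p: float
    pairwise: pd.DataFrame  # columns: group1, group2, meandiff, p_adj


def variance_anova(groups: Mapping[str, Iterable[str]],
                   gene_variance: pd.Series) -> VarianceReport:
    """One-way ANOVA of per-gene variance across gene sets, with Tukey-Kramer.

    Groups with fewer than two genes (after dropping genes without a
    variance value) are excluded with a warning.
    """
    usable: dict[str, list[str]] = {}
    for label, genes in groups.items():
        present = [g for g in genes if g in gene_variance.index]
        if len(present) < 2:
            logger.warning("group %r has <2 usable genes; dropped", label)
            continue
        usable[label] = present
    if len(usable) < 2:
        raise ValueError("need at least two usable groups")
    arrays = [gene_variance[g].to_numpy(dtype=float) for g in usable.values()]
    F, p = stats.f_oneway(*arrays)
    values = np.concatenate(arrays)
    labels = np.concatenate([[lbl] * len(v) for lbl, v in zip(usable, arrays)])
    tukey = pairwise_tukeyhsd(values, labels)
    pair = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    pair = pair.rename(columns={"p-adj": "p_adj"})[["group1", "group2", "meandiff", "p_adj"]]
    pair["p_adj"] = pair["p_adj"].astype(float)
    pair["meandiff"] = pair["meandiff"].astype(float)
    return VarianceReport(groups=usable, anova_F=float(F), anova_p=float(p), pairwise=pair)


def expression_variance_species_test(
    expression: pd.DataFrame,
    population: pd.Series,
    genes: Iterable[str] | None = None,
    alpha: float = 0.05,
    m_tests: int | None = None,
) -> list[FTestResult]:
    """Per-gene two-sided F-test of RPKM variance between the two populations.

    The Bonferroni threshold is alpha/m_tests; by default m_tests is the
    number of genes tested.
    """
    population = population.reindex(expression.columns)
    labels = population.dropna().unique()
    if len(labels) != 2:
        raise ValueError("expected exactly two populations")
    cols_a = expression.columns[population == labels[0]]
    cols_b = expression.columns[population == labels[1]]
    gene_list = list(genes) if genes is not None else list(expression.index)
    m = m_tests if m_tests is not None else len(gene_list)
    out = []
    for gene in gene_list:
        out.append(variance_ratio_test(
            expression.loc[gene, cols_a].to_numpy(dtype=float),
            expression.loc[gene, cols_b].to_numpy(dtype=float),
            locus_id=gene, label_a=str(labels[0]), label_b=str(labels[1]),
            alpha=alpha, m_tests=m))
    return out
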