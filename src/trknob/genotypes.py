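"""Amplicon-length genotypes, normalized allele length (NAL) and allelic-variance tests.

Amplicon length is a proxy for repeat copy number; rather than convert
lengths to copy numbers, each allele is expressed as NAL = amplicon length
divided by the smallest amplicon length observed at that locus, so the
shortest allele at every locus has NAL exactly 1.  Isolates are haploid
(single allele per locus); two populations are expected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

GROUPINGS = ("popA", "popB", "combined")


@dataclass
class GenotypeTable:
    """Locus x isolate amplicon lengths plus an isolate -> population map.

    ``lengths`` is a DataFrame indexed by locus_id with isolate_id columns;
    missing calls are NaN.  ``population`` maps each isolate to one of
    exactly two population labels.
    """

    lengths: pd.DataFrame
    population: pd.Series

    def __post_init__(self) -> None:
        self.population = self.population.reindex(self.lengths.columns)
        if self.population.isna().any():
            missing = list(self.population.index[self.population.isna()])
            raise ValueError(f"isolates without population label: {missing}")
        pops = self.population.unique()
        if len(pops) != 2:
            raise ValueError(f"expected exactly 2 populations, got {list(pops)}")
        vals = self.lengths.to_numpy(dtype=float)
        if np.isfinite(vals).any() and np.nanmin(vals) <= 0:
            raise ValueError("amplicon lengths must be positive")

    @property
    def populations(self) -> tuple[str, str]:
        seen: list[str] = []
        for p in self.population:
            if p not in seen:
                seen.append(p)
        return seen[0], seen[1]

    def isolates_of(self, grouping: str) -> list[str]:
        """Isolate ids belonging to a grouping ('popA', 'popB' or 'combined')."""
        a, b = self.populations
        if grouping == "popA":
            return [i for i in self.lengths.columns if self.population[i] == a]
        if grouping == "popB":
            return [i for i in self.lengths.columns if self.population[i] == b]
        if grouping == "combined":
            return list(self.lengths.columns)
        raise ValueError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")

    @classmethod
    def from_tsv(cls, genotype_path: str | Path, population_path: str | Path) -> "GenotypeTable":
        """Read long-format genotypes (locus_id, isolate_id, amplicon_length)
        and a population map (isolate_id, population)."""
        long = pd.read_csv(genotype_path, sep="\t")
        pops = pd.read_csv(population_path, sep="\t")
        wide = long.pivot(index="locus_id", columns="isolate_id", values="amplicon_length")
        pop = pops.set_index("isolate_id")["population"]
        return cls(lengths=wide, population=pop)

    def to_tsv(self, genotype_path: str | Path, population_path: str | Path) -> None:
        long = (self.lengths.stack().rename("amplicon_length").reset_index())
        long.columns = ["locus_id", "isolate_id", "amplicon_length"]
        long.to_csv(genotype_path, sep="\t", index=False)
        self.population.rename("population").rename_axis("isolate_id").reset_index().to_csv(
            population_path, sep="\t", index=False)


def compute_nal(table: GenotypeTable, per_population: bool = False) -> pd.DataFrame:
    """NAL(l, i) = amplicon_length(l, i) / min amplicon length at locus l.

    By default the minimum is taken jointly over all isolates of both
    populations; ``per_population=True`` normalizes within each population
    instead.  Missing entries stay missing.  A locus with no calls at all
    is an error.
    """
    lengths = table.lengths
    all_missing = lengths.isna().all(axis=1)
    if all_missing.any():
        bad = list(lengths.index[all_missing])
        raise ValueError(f"loci with no amplicon length calls: {bad}")
    if not per_population:
        return lengths.div(lengths.min(axis=1), axis=0)
    parts = []
    for grouping in ("popA", "popB"):
        cols = table.isolates_of(grouping)
        sub = lengths[cols]
        parts.append(sub.div(sub.min(axis=1), axis=0))
    return pd.concat(parts, axis=1)[lengths.columns]


def is_fixed(table: GenotypeTable, locus: str, grouping: str = "combined") -> bool:
    """True iff all non-missing amplicon lengths in the grouping are identical.

    A grouping with a single (or zero) non-missing call counts as fixed:
    there is no allelic variance to regress on.
    """
    cols = table.isolates_of(grouping)
    vals = table.lengths.loc[locus, cols].dropna()
    return vals.nunique() <= 1


@dataclass(frozen=True)
class FTestResult:
    """Two-sided variance-ratio test between two samples."""

    locus_id: str
    variance_a: float
    variance_b: float
    F: float
    df_a: int
    df_b: int
    p: float
    threshold: float
    reduced_in: str | None  # label of the lower-variance sample, None on tie
    significant: bool
    degenerate: bool = False


def variance_ratio_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    *,
    locus_id: str = "",
    label_a: str = "a",
    label_b: str = "b",
    alpha: float = 0.05,
    m_tests: int = 1,
) -> FTestResult:
    """Two-sided F-test of equal variances (unbiased sample variances).

    F is the larger variance over the smaller; the two-sided p doubles the
    appropriate tail (capped at 1).  Significance compares p to the
    Bonferroni threshold alpha/m_tests.  Zero variance on both sides is
    degenerate with p = 1; zero variance on one side only is degenerate
    with p = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"{locus_id or 'test'}: need >=2 observations per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    threshold = alpha / m_tests
    df_a, df_b = len(a) - 1, len(b) - 1
    if va == 0 and vb == 0:
        return FTestResult(locus_id, va, vb, 1.0, df_a, df_b, 1.0, threshold,
                           None, False, degenerate=True)
    if va == 0 or vb == 0:
        reduced = label_a if va < vb else label_b
        return FTestResult(locus_id, va, vb, math.inf, df_a, df_b, 0.0, threshold,
                           reduced, True, degenerate=True)
    if va >= vb:
        F, dfn, dfd = va / vb, df_a, df_b
    else:
        F, dfn, dfd = vb / va, df_b, df_a
    p = min(1.0, 2.0 * stats.f.sf(F, dfn, dfd))
    reduced = None if va == vb else (label_a if va < vb else label_b)
    return FTestResult(locus_id, va, vb, F, df_a, df_b, p, threshold,
                       reduced, p < threshold)


def allelic_variance_test(
    table: GenotypeTable,
    locus: str,
    alpha: float = 0.05,
    m_tests: int = 1,
) -> FTestResult:
    """Between-population F-test on amplicon-length variance at one locus."""
    a, b = table.populations
    va = table.lengths.loc[locus, table.isolates_of("popA")].to_numpy(dtype=float)
    vb = table.lengths.loc[locus, table.isolates_of("popB")].to_numpy(dtype=float)
    return variance_ratio_test(va, vb, locus_id=locus, label_a=a, label_b=b,
                               alpha=alpha, m_tests=m_tests)
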