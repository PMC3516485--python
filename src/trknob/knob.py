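"""The "knob" regression battery: AICc-selected curve fits of expression on NAL.

For each tandem-repeat locus, gene expression (RPKM) is regressed on
normalized allele length under seven candidate mean models chosen to
represent distinct biological modes of repeat action:

==================  =====================  ========  ==========
model_id            mean model             K         pattern
==================  =====================  ========  ==========
linear              b0 + b1·x              2         volume
linear_log          b0 + b1·ln x           2         volume
linear_sqrt         b0 + b1·sqrt(x)        2         volume
linear_squared      b0 + b1·x²             2         volume
linear_reciprocal   b0 + b1/x              2         volume
quadratic           b0 + b1·x + b2·x²      3         optimality
cubic               b0 + ... + b3·x³       4         tuning
==================  =====================  ========  ==========

A monotone (volume-knob) relationship turns expression up or down with
copy number; a concave quadratic (optimality) peaks at an intermediate
copy number; a cubic (tuning) allows an oscillating response.  The best
model minimizes the small-sample corrected Akaike criterion

    AICc = ln(RSS) + 2K + 2K(K+1)/(n - K - 1)          ("published" form)

where RSS is the residual sum of squares, K the number of mean-model
coefficients and n the number of observations.  The published form omits
the sample-size multiplier on the log-likelihood term; the textbook
variant n·ln(RSS/n) + 2K + 2K(K+1)/(n-K-1) is available as
``aicc="standard"`` and is far more willing to accept the higher-order
models (see docs/methods.md).  The winning model's F-ratio p-value is
reported unadjusted for the selection step.

Transforms apply to the predictor; NAL >= 1 keeps ln, sqrt and 1/x
well-defined.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GROUPINGS, GenotypeTable, compute_nal, is_fixed

RSS_FLOOR = 1e-12

VOLUME, OPTIMALITY, TUNING = "volume", "optimality", "tuning"

#: model_id -> (predictor column builders, K, pattern label)
MODEL_SPECS: dict[str, tuple[tuple, int, str]] = {
    "linear": ((lambda x: x,), 2, VOLUME),
    "linear_log": ((np.log,), 2, VOLUME),
    "linear_sqrt": ((np.sqrt,), 2, VOLUME),
    "linear_squared": ((lambda x: x**2,), 2, VOLUME),
    "linear_reciprocal": ((lambda x: 1.0 / x,), 2, VOLUME),
    "quadratic": ((lambda x: x, lambda x: x**2), 3, OPTIMALITY),
    "cubic": ((lambda x: x, lambda x: x**2, lambda x: x**3), 4, TUNING),
}
MODEL_ORDER = tuple(MODEL_SPECS)

FIXED_ALLELES = "fixed_alleles"
UNEXPRESSED = "unexpressed"
NO_EXPRESSION_DATA = "no_expression_data"
NO_FITTABLE_MODEL = "no_fittable_model"


def aicc(rss: float, K: int, n: int, *, variant: str = "published",
         rss_floor: float = RSS_FLOOR) -> float:
    """Small-sample corrected AIC of an OLS fit.

    ``variant="published"`` uses ln(RSS) + 2K + 2K(K+1)/(n-K-1);
    ``variant="standard"`` uses the textbook n·ln(RSS/n) + same penalty.
    RSS is floored at ``rss_floor`` to keep the logarithm finite on exact
    fits.  Requires n - K - 1 >= 1.
    """
    if n - K - 1 < 1:
        raise ValueError(f"AICc undefined for n={n}, K={K} (n-K-1 must be >= 1)")
    if rss < 0:
        raise ValueError("RSS must be non-negative")
    rss = max(rss, rss_floor)
    penalty = 2 * K + 2 * K * (K + 1) / (n - K - 1)
    if variant == "published":
        return math.log(rss) + penalty
    if variant == "standard":
        return n * math.log(rss / n) + penalty
    raise ValueError(f"unknown AICc variant {variant!r}")


class ModelSkipped(Exception):
    """A candidate model cannot be fitted on this data; carries the reason."""


@dataclass(frozen=True)
class RegressionFit:
    """One fitted candidate model."""

    model_id: str
    coefficients: tuple[float, ...]  # intercept first
    RSS: float
    K: int
    n: int
    R2: float
    F: float
    df1: int
    df2: int
    p: float
    AICc: float
    pattern: str

    def predict(self, x: np.ndarray) -> np.ndarray:
        builders = MODEL_SPECS[self.model_id][0]
        X = _design(np.asarray(x, dtype=float), builders)
        return X @ np.array(self.coefficients)


def _design(x: np.ndarray, builders: tuple) -> np.ndarray:
    cols = [np.ones_like(x)] + [b(x) for b in builders]
    return np.column_stack(cols)


def fit_model(x: Sequence[float], y: Sequence[float], model_id: str, *,
              aicc_variant: str = "published", rss_floor: float = RSS_FLOOR) -> RegressionFit:
    """OLS fit of one candidate model; raises ModelSkipped when not fittable.

    Requires n >= K + 2 (so the AICc denominator is positive) and a
    full-rank design (e.g. a cubic needs >=4 distinct x values).  A
    constant x is a caller error: such loci are fixed and must be
    pre-screened.
    """
    builders, K, pattern = MODEL_SPECS[model_id]
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("x and y must not contain missing values")
    n = len(x)
    if len(np.unique(x)) < 2:
        raise ValueError("x is constant; fixed loci must be excluded before fitting")
    if n < K + 2:
        raise ModelSkipped(f"{model_id}: n={n} < K+2={K + 2}")
    X = _design(x, builders)
    if np.linalg.matrix_rank(X) < K:
        raise ModelSkipped(f"{model_id}: rank-deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    df1, df2 = K - 1, n - K
    if tss <= 0:  # constant response: no signal by definition
        r2, F, p = 0.0, 0.0, 1.0
    else:
        r2 = min(1.0, max(0.0, 1.0 - rss / tss))
        if r2 >= 1.0:
            F, p = math.inf, 0.0
        else:
            F = (r2 / df1) / ((1.0 - r2) / df2)
            p = float(stats.f.sf(F, df1, df2))
    return RegressionFit(
        model_id=model_id, coefficients=tuple(float(b) for b in beta), RSS=rss,
        K=K, n=n, R2=r2, F=F, df1=df1, df2=df2, p=p,
        AICc=aicc(rss, K, n, variant=aicc_variant, rss_floor=rss_floor), pattern=pattern,
    )


class KnobRegression:
    """Model battery for one locus: expression (y) against NAL (x).

    Statsmodels-style entry point: construct from arrays or a DataFrame,
    call :meth:`fit` to obtain a :class:`KnobRegressionResults`.

    Parameters
    ----------
    nal, expression
        Paired, missing-free observations; NAL values must be >= 1 with at
        least two distinct values.
    models
        Candidate model ids (default: all seven).
    aicc
        "published" (default) or "standard"; see module docstring.
    """

    def __init__(self, nal: Sequence[float], expression: Sequence[float], *,
                 models: Iterable[str] = MODEL_ORDER, aicc: str = "published",
                 rss_floor: float = RSS_FLOOR):
        self.x = np.asarray(nal, dtype=float)
        self.y = np.asarray(expression, dtype=float)
        self.models = tuple(models)
        unknown = set(self.models) - set(MODEL_SPECS)
        if unknown:
            raise ValueError(f"unknown model ids: {sorted(unknown)}")
        self.aicc_variant = aicc
        self.rss_floor = rss_floor

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, x: str = "nal", y: str = "rpkm",
                       **kwargs) -> "KnobRegression":
        sub = data[[x, y]].dropna()
        return cls(sub[x].to_numpy(), sub[y].to_numpy(), **kwargs)

    def fit(self) -> "KnobRegressionResults":
        fits: dict[str, RegressionFit] = {}
        skipped: dict[str, str] = {}
        for mid in self.models:
            try:
                fits[mid] = fit_model(self.x, self.y, mid,
                                      aicc_variant=self.aicc_variant,
                                      rss_floor=self.rss_floor)
            except ModelSkipped as exc:
                skipped[mid] = str(exc)
        if not fits:
            raise ModelSkipped("no fittable model")
        # min AICc; exact ties broken by smaller K, then fixed model order
        order = {m: i for i, m in enumerate(MODEL_ORDER)}
        best_id = min(fits, key=lambda m: (fits[m].AICc, fits[m].K, order[m]))
        return KnobRegressionResults(model=self, fits=fits, skipped=skipped, best_id=best_id)


@dataclass
class KnobRegressionResults:
    """Fit results for one locus: all candidate fits plus the AICc winner."""

    model: KnobRegression
    fits: dict[str, RegressionFit]
    skipped: dict[str, str]
    best_id: str

    @property
    def best(self) -> RegressionFit:
        return self.fits[self.best_id]

    @property
    def pattern(self) -> str:
        return self.best.pattern

    @property
    def p(self) -> float:
        return self.best.p

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"model": m, "K": f.K, "n": f.n, "RSS": f.RSS, "R2": f.R2, "F": f.F,
             "p": f.p, "AICc": f.AICc, "best": m == self.best_id}
            for m, f in self.fits.items()
        ]
        return pd.DataFrame(rows).set_index("model")

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Knob regression battery (y = RPKM on x = NAL)",
            f"n = {self.best.n}   AICc variant: {self.model.aicc_variant}",
            df.to_string(float_format=lambda v: f"{v:.4g}"),
            f"best: {self.best_id} (pattern: {self.pattern}), "
            f"p = {self.best.p:.3g}, R2 = {self.best.R2:.3f}",
        ]
        if self.skipped:
            lines.append("skipped: " + "; ".join(f"{m}: {r}" for m, r in self.skipped.items()))
        return "\n".join(lines)


def select_best_model(x: Sequence[float], y: Sequence[float], *,
                      models: Iterable[str] = MODEL_ORDER,
                      aicc: str = "published") -> KnobRegressionResults:
    """Functional wrapper: fit the battery and return the results object."""
    return KnobRegression(x, y, models=models, aicc=aicc).fit()


@dataclass(frozen=True)
class KnobScanRow:
    """Outcome for one locus x grouping comparison."""

    locus_id: str
    gene_id: str
    grouping: str
    excluded: str | None = None
    best: RegressionFit | None = None
    significant_nominal: bool | None = None
    significant_bonferroni: bool | None = None

    @property
    def pattern(self) -> str | None:
        return self.best.pattern if self.best else None


class KnobScan:
    """Genome-scale knob scan: every TR locus under every grouping.

    Groupings are each population alone and both combined.  A comparison
    is excluded (not counted as a test) when the locus has fixed alleles
    within the grouping, or when the gene fails the expression rule.  The
    default expression rule excludes a grouping in which the gene has zero
    RPKM in at least one isolate (``unexpressed_rule="any_zero"``);
    ``"all_zero"`` requires every isolate at zero.

    Parameters
    ----------
    genotypes : GenotypeTable
    expression : DataFrame
        genes x isolates RPKM.
    locus_to_gene : mapping locus_id -> gene_id (e.g. from the TR catalog).
    """

    def __init__(self, genotypes: GenotypeTable, expression: pd.DataFrame,
                 locus_to_gene: Mapping[str, str], *, alpha_nominal: float = 0.01,
                 alpha_family: float = 0.05, unexpressed_rule: str = "any_zero",
                 aicc: str = "published", nal_per_population: bool = False):
        if unexpressed_rule not in ("any_zero", "all_zero"):
            raise ValueError(f"unknown unexpressed_rule {unexpressed_rule!r}")
        self.genotypes = genotypes
        self.expression = expression
        self.locus_to_gene = dict(locus_to_gene)
        self.alpha_nominal = alpha_nominal
        self.alpha_family = alpha_family
        self.unexpressed_rule = unexpressed_rule
        self.aicc = aicc
        self.nal = compute_nal(genotypes, per_population=nal_per_population)

    def _expression_excluded(self, gene: str, isolates: list[str]) -> str | None:
        if gene not in self.expression.index:
            return NO_EXPRESSION_DATA
        vals = self.expression.loc[gene, isolates]
        if vals.isna().any():
            return NO_EXPRESSION_DATA
        zero = vals.to_numpy(dtype=float) == 0.0
        if self.unexpressed_rule == "any_zero":
            return UNEXPRESSED if zero.any() else None
        return UNEXPRESSED if zero.all() else None

    def fit(self) -> "KnobScanResults":
        rows: list[KnobScanRow] = []
        fitted: list[tuple[int, KnobRegressionResults]] = []
        for locus in self.genotypes.lengths.index:
            if locus not in self.locus_to_gene:
                raise KeyError(f"locus {locus!r} missing from the TR catalog mapping")
            gene = self.locus_to_gene[locus]
            for grouping in GROUPINGS:
                isolates = self.genotypes.isolates_of(grouping)
                if is_fixed(self.genotypes, locus, grouping):
                    rows.append(KnobScanRow(locus, gene, grouping, excluded=FIXED_ALLELES))
                    continue
                reason = self._expression_excluded(gene, isolates)
                if reason:
                    rows.append(KnobScanRow(locus, gene, grouping, excluded=reason))
                    continue
                nal = self.nal.loc[locus, isolates]
                keep = nal.notna()
                x = nal[keep].to_numpy(dtype=float)
                y = self.expression.loc[gene, nal.index[keep]].to_numpy(dtype=float)
                try:
                    res = KnobRegression(x, y, aicc=self.aicc).fit()
                except ModelSkipped:
                    rows.append(KnobScanRow(locus, gene, grouping, excluded=NO_FITTABLE_MODEL))
                    continue
                fitted.append((len(rows), res))
                rows.append(KnobScanRow(locus, gene, grouping, best=res.best))
        n_tests = len(fitted)
        cutoff = self.alpha_family / n_tests if n_tests else math.nan
        final: list[KnobScanRow] = list(rows)
        for idx, res in fitted:
            r = rows[idx]
            final[idx] = KnobScanRow(
                r.locus_id, r.gene_id, r.grouping, best=r.best,
                significant_nominal=res.p < self.alpha_nominal,
                significant_bonferroni=res.p < cutoff,
            )
        return KnobScanResults(scan=self, rows=final, bonferroni_cutoff=cutoff)


@dataclass
class KnobScanResults:
    """All per-comparison rows plus the exclusion and significance tallies."""

    scan: KnobScan
    rows: list[KnobScanRow]
    bonferroni_cutoff: float

    @property
    def tests_run(self) -> int:
        return sum(1 for r in self.rows if r.excluded is None)

    @property
    def exclusions(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.rows:
            if r.excluded:
                out[r.excluded] = out.get(r.excluded, 0) + 1
        return out

    def summary_dict(self) -> dict:
        tested = [r for r in self.rows if r.excluded is None]
        patterns: dict[str, int] = {}
        for r in tested:
            patterns[r.pattern] = patterns.get(r.pattern, 0) + 1
        return {
            "comparisons": len(self.rows),
            "tests_run": self.tests_run,
            "exclusions": self.exclusions,
            "bonferroni_cutoff": self.bonferroni_cutoff,
            "significant_nominal": sum(bool(r.significant_nominal) for r in tested),
            "significant_bonferroni": sum(bool(r.significant_bonferroni) for r in tested),
            "best_model_patterns": patterns,
        }

    def summary(self) -> str:
        d = self.summary_dict()
        excl = ", ".join(f"{k}={v}" for k, v in sorted(d["exclusions"].items())) or "none"
        return "\n".join([
            "Knob scan over locus x grouping comparisons",
            f"comparisons: {d['comparisons']}   tests run: {d['tests_run']}   exclusions: {excl}",
            f"significant at p<{self.scan.alpha_nominal:g}: {d['significant_nominal']}   "
            f"at Bonferroni p<{d['bonferroni_cutoff']:.3g}: {d['significant_bonferroni']}",
            "patterns among winners: "
            + (", ".join(f"{k}={v}" for k, v in sorted(d["best_model_patterns"].items())) or "none"),
        ])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.rows:
            b = r.best
            rows.append({
                "locus_id": r.locus_id, "gene_id": r.gene_id, "grouping": r.grouping,
                "best_model": b.model_id if b else None,
                "K": b.K if b else None, "n": b.n if b else None,
                "R2": b.R2 if b else None, "F": b.F if b else None,
                "p": b.p if b else None, "AICc": b.AICc if b else None,
                "pattern": r.pattern,
                "sig_nominal": r.significant_nominal, "sig_bonferroni": r.significant_bonferroni,
                "excluded_reason": r.excluded,
            })
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def summary_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2)


def run_knob_scan(genotypes: GenotypeTable, expression: pd.DataFrame,
                  locus_to_gene: Mapping[str, str], **kwargs) -> KnobScanResults:
    """Functional wrapper around :class:`KnobScan`."""
    return KnobScan(genotypes, expression, locus_to_gene, **kwargs).fit()
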