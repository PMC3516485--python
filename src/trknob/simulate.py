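"""Synthetic study generator: genomes, genotypes and expression with known truth.

Emulates the study design the pipeline targets: two populations of eight
haploid isolates genotyped at 143 promoter tandem-repeat loci (72
microsatellite, 71 minisatellite), with population A carrying reduced
allelic variance at a subset of loci, a planted set of fixed-allele
locus-by-grouping comparisons (default 28), downstream gene expression
generated from the normalized allele length under the knob-model mean
shapes (volume / optimality / tuning / switch / null) at a controlled
generative R-squared, and a planted set of unexpressed gene-by-grouping
comparisons (default 9).  Everything is deterministic under the seed.

Expression noise is normal on the RPKM scale by default (matching the
OLS assumptions of the fitted battery), with a multiplicative lognormal
option.  The baseline RPKM (200) and structural SD (20) are chosen so
that, at the default generative R-squared, values sit many noise SDs
above zero: negative draws are clipped at zero, and an accidental zero
would masquerade as a planted unexpressed comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable, compute_nal
from .promoters import Gene

PATTERNS = ("volume", "optimality", "tuning", "switch", "null")
VOLUME_TRANSFORMS = ("identity", "log", "sqrt", "squared", "reciprocal")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults are the emulated study conditions."""

    n_isolates_per_pop: int = 8
    n_micro_loci: int = 72
    n_mini_loci: int = 71
    knob_mix: dict = field(default_factory=lambda: {
        "volume": 0.15, "optimality": 0.10, "tuning": 0.10, "switch": 0.10, "null": 0.55,
    })
    effect_size: float = 0.5          # generative R-squared of non-null loci
    noise_model: str = "normal"       # or "lognormal"
    noise_scale: float = 20.0         # residual SD (RPKM) for null loci
    baseline_rpkm: float = 200.0
    structure_sd: float = 20.0        # SD of the structural mean across isolates
    n_fixed_comparisons: int = 28
    n_unexpressed_comparisons: int = 9
    n_variance_reduced_loci: int = 25  # loci with reduced popA allelic variance
    allele_base_range: tuple[int, int] = (150, 400)
    n_background_genes: int = 300
    n_categories: int = 12
    pop_labels: tuple[str, str] = ("A. oryzae", "A. flavus")

    @property
    def n_loci(self) -> int:
        return self.n_micro_loci + self.n_mini_loci

    def __post_init__(self) -> None:
        total = sum(self.knob_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"knob_mix proportions must sum to 1, got {total}")
        if not 0 <= self.effect_size < 1:
            raise ValueError("effect_size must be in [0, 1)")
        if self.noise_model not in ("normal", "lognormal"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


def _fixed_decomposition(n: int) -> tuple[int, int, int]:
    """Split n fixed comparisons into (all-grouping loci, popA-only, popB-only).

    A locus fixed in both populations with the same allele is fixed in all
    three groupings (3 comparisons); a locus fixed in one population only
    contributes 1.
    """
    if n < 0:
        raise ValueError("n_fixed_comparisons must be >= 0")
    n_all = 2 if n >= 6 else 0
    rem = n - 3 * n_all
    n_a = (rem + 1) // 2
    n_b = rem - n_a
    return n_all, n_a, n_b


def _unexpressed_decomposition(n: int) -> tuple[int, int]:
    """Split n unexpressed comparisons into (fully zeroed genes, popA-zeroed genes).

    Zeroing one population also silences the combined grouping (2
    comparisons); zeroing everything silences all three.  n = 1 is
    therefore infeasible.
    """
    if n == 0:
        return 0, 0
    n3 = n % 2
    rest = n - 3 * n3
    if rest < 0 or rest % 2:
        raise ValueError(f"cannot plant exactly {n} unexpressed comparisons "
                         "(each zeroed gene silences 2 or 3 groupings)")
    return n3, rest // 2


def locus_ids(config: SimulationConfig) -> list[str]:
    return [f"L{i + 1:04d}" for i in range(config.n_loci)]


def gene_for_locus(locus: str) -> str:
    return "G" + locus[1:]


def simulate_genotypes(config: SimulationConfig | None = None, seed: int = 0
                       ) -> tuple[GenotypeTable, pd.DataFrame]:
    """Generate amplicon-length genotypes with planted structure.

    Returns the table and a truth frame indexed by locus with columns
    unit_length, repeat_class, fixed_in (none/popA/popB/all) and
    variance_reduced.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    loci = locus_ids(cfg)
    n_per = cfg.n_isolates_per_pop
    iso_a = [f"AO{i + 1:02d}" for i in range(n_per)]
    iso_b = [f"AF{i + 1:02d}" for i in range(n_per)]
    isolates = iso_a + iso_b

    n_all, n_a, n_b = _fixed_decomposition(cfg.n_fixed_comparisons)
    if n_all + n_a + n_b > cfg.n_loci:
        raise ValueError("more fixed loci requested than loci available")
    perm = rng.permutation(cfg.n_loci)
    fixed_all = set(perm[:n_all])
    fixed_a = set(perm[n_all:n_all + n_a])
    fixed_b = set(perm[n_all + n_a:n_all + n_a + n_b])
    free = [i for i in range(cfg.n_loci) if i not in fixed_all | fixed_a | fixed_b]
    if cfg.n_variance_reduced_loci > len(free):
        raise ValueError("not enough unconstrained loci for the variance-reduced subset")
    var_reduced = set(rng.choice(free, size=cfg.n_variance_reduced_loci, replace=False))

    lengths = np.zeros((cfg.n_loci, 2 * n_per))
    truth_rows = []
    for i, locus in enumerate(loci):
        unit = int(rng.integers(2, 10)) if i < cfg.n_micro_loci else int(rng.integers(10, 31))
        base = int(rng.integers(*cfg.allele_base_range))
        n_alleles = int(rng.integers(3, 7))
        offsets = np.sort(rng.choice(np.arange(10), size=n_alleles, replace=False))
        alleles = base + unit * offsets

        def draw(n: int, pool: np.ndarray) -> np.ndarray:
            picks = pool[rng.integers(0, len(pool), size=n)]
            # guarantee polymorphism within the sample
            picks[0], picks[1] = pool[0], pool[-1]
            return picks

        if i in fixed_all:
            allele = alleles[rng.integers(n_alleles)]
            row = np.full(2 * n_per, allele, dtype=float)
            fixed_in = "all"
        elif i in fixed_a:
            row = np.concatenate([
                np.full(n_per, alleles[rng.integers(n_alleles)], dtype=float),
                draw(n_per, alleles).astype(float),
            ])
            fixed_in = "popA"
        elif i in fixed_b:
            row = np.concatenate([
                draw(n_per, alleles).astype(float),
                np.full(n_per, alleles[rng.integers(n_alleles)], dtype=float),
            ])
            fixed_in = "popB"
        else:
            if i in var_reduced:  # popA restricted to two adjacent alleles
                pool_a = alleles[:2]
                a_part = draw(n_per, pool_a)
            else:
                a_part = draw(n_per, alleles)
            row = np.concatenate([a_part, draw(n_per, alleles)]).astype(float)
            fixed_in = "none"
        lengths[i] = row
        truth_rows.append({
            "locus_id": locus, "unit_length": unit,
            "repeat_class": "microsatellite" if unit <= 9 else "minisatellite",
            "fixed_in": fixed_in, "variance_reduced": i in var_reduced,
        })

    table = GenotypeTable(
        lengths=pd.DataFrame(lengths, index=loci, columns=isolates),
        population=pd.Series(
            {**{i: cfg.pop_labels[0] for i in iso_a}, **{i: cfg.pop_labels[1] for i in iso_b}}),
    )
    return table, pd.DataFrame(truth_rows).set_index("locus_id")


def _structural_mean(pattern: str, x: np.ndarray, cfg: SimulationConfig,
                     rng: np.random.Generator) -> tuple[np.ndarray, str | None]:
    """Mean RPKM across isolates for one locus; returns (mu, transform used)."""
    a = cfg.baseline_rpkm
    if pattern == "null" or len(np.unique(x)) < 2:
        return np.full_like(x, a), None
    transform = None
    if pattern == "volume":
        transform = VOLUME_TRANSFORMS[rng.integers(len(VOLUME_TRANSFORMS))]
        g = {"identity": lambda v: v, "log": np.log, "sqrt": np.sqrt,
             "squared": lambda v: v**2, "reciprocal": lambda v: 1.0 / v}[transform]
        raw = g(x) * (1.0 if rng.random() < 0.5 else -1.0)
    elif pattern == "optimality":
        x0 = (x.min() + x.max()) / 2.0
        raw = -((x - x0) ** 2)
    elif pattern == "tuning":
        lo, hi = x.min(), x.max()
        q = lo + np.array([0.25, 0.5, 0.75]) * (hi - lo)
        raw = (x - q[0]) * (x - q[1]) * (x - q[2])
    elif pattern == "switch":
        uniq = np.unique(x)
        thr = (uniq[len(uniq) // 2 - 1] + uniq[len(uniq) // 2]) / 2.0
        raw = (x >= thr).astype(float)
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    sd = raw.std()
    if sd == 0:
        return np.full_like(x, a), transform
    return a + cfg.structure_sd * (raw - raw.mean()) / sd, transform


def simulate_expression(
    genotypes: GenotypeTable,
    config: SimulationConfig | None = None,
    seed: int = 0,
    effect_size: float | None = None,
    knob_mix: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a genes x isolates RPKM matrix from the genotype table.

    One gene per locus plus ``n_background_genes`` null background genes.
    Returns (expression, truth) where truth is indexed by gene with
    columns locus_id, pattern, transform, noise_sd and zeroed
    (none/popA/all).  The noise SD of non-null loci is solved from the
    structural variance so the generative R-squared equals
    ``effect_size``; null loci use ``noise_scale``.
    """
    cfg = config or SimulationConfig()
    if effect_size is not None:
        cfg = replace(cfg, effect_size=effect_size)
    if knob_mix is not None:
        cfg = replace(cfg, knob_mix=knob_mix)
    rng = np.random.default_rng(seed)
    nal = compute_nal(genotypes)
    loci = list(genotypes.lengths.index)
    isolates = list(genotypes.lengths.columns)
    iso_a = genotypes.isolates_of("popA")

    mix_names = [p for p in PATTERNS if cfg.knob_mix.get(p, 0) > 0]
    mix_probs = np.array([cfg.knob_mix[p] for p in mix_names], dtype=float)
    mix_probs /= mix_probs.sum()
    patterns = rng.choice(mix_names, size=len(loci), p=mix_probs)

    n3, n2 = _unexpressed_decomposition(cfg.n_unexpressed_comparisons)
    # zeroed genes must come from loci polymorphic in every grouping, so the
    # planted exclusion is attributed to expression, never to fixed alleles
    polymorphic = [i for i, locus in enumerate(loci)
                   if genotypes.lengths.loc[locus].nunique() >= 2
                   and genotypes.lengths.loc[locus, iso_a].nunique() >= 2
                   and genotypes.lengths.loc[locus].drop(iso_a).nunique() >= 2]
    if n3 + n2 > len(polymorphic):
        raise ValueError("not enough fully polymorphic loci to plant unexpressed genes")
    chosen = rng.choice(polymorphic, size=n3 + n2, replace=False)
    zero_all = set(chosen[:n3])
    zero_a = set(chosen[n3:])

    rows = []
    truth_rows = []
    if cfg.effect_size > 0:
        signal_sd = cfg.structure_sd * math.sqrt((1 - cfg.effect_size) / cfg.effect_size)
    else:
        signal_sd = cfg.noise_scale
    for i, locus in enumerate(loci):
        x = nal.loc[locus].to_numpy(dtype=float)
        pattern = patterns[i] if cfg.effect_size > 0 else "null"
        mu, transform = _structural_mean(pattern, x, cfg, rng)
        sd = cfg.noise_scale if (pattern == "null" or np.ptp(mu) == 0) else signal_sd
        if cfg.noise_model == "normal":
            y = mu + rng.normal(0.0, sd, size=len(mu))
        else:  # multiplicative lognormal with matched variance
            cv = sd / mu
            slog = np.sqrt(np.log1p(cv**2))
            y = mu * rng.lognormal(-(slog**2) / 2.0, slog)
        y = np.maximum(y, 0.0)
        zeroed = "none"
        if i in zero_all:
            y[:] = 0.0
            zeroed = "all"
        elif i in zero_a:
            y[[isolates.index(j) for j in iso_a]] = 0.0
            zeroed = "popA"
        rows.append(y)
        truth_rows.append({"gene_id": gene_for_locus(locus), "locus_id": locus,
                           "pattern": pattern, "transform": transform,
                           "noise_sd": float(sd), "zeroed": zeroed})

    gene_index = [gene_for_locus(l) for l in loci]
    for k in range(cfg.n_background_genes):
        y = np.maximum(cfg.baseline_rpkm + rng.normal(0.0, cfg.noise_scale, len(isolates)), 0.0)
        rows.append(y)
        gene_index.append(f"B{k + 1:04d}")
        truth_rows.append({"gene_id": gene_index[-1], "locus_id": None, "pattern": "null",
                           "transform": None, "noise_sd": cfg.noise_scale, "zeroed": "none"})
    expression = pd.DataFrame(np.vstack(rows), index=gene_index, columns=isolates)
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return expression, truth


# ------------------------------------------------------------ full fixture

@dataclass
class FixtureBundle:
    """Everything one pipeline run needs, with generator truth attached."""

    config: SimulationConfig
    genotypes: GenotypeTable
    genotype_truth: pd.DataFrame
    expression: pd.DataFrame
    expression_truth: pd.DataFrame
    locus_to_gene: dict[str, str]
    categories: pd.Series          # gene -> functional category
    gene_order: dict[str, list[str]]
    strands: dict[str, str]

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.genotypes.to_tsv(out / "genotypes.tsv", out / "populations.tsv")
        self.expression.round(6).rename_axis("gene_id").to_csv(out / "rpkm.tsv", sep="\t")
        pd.Series(self.locus_to_gene, name="gene_id").rename_axis("locus_id").reset_index().to_csv(
            out / "catalog.tsv", sep="\t", index=False)
        self.categories.rename("category").rename_axis("gene_id").reset_index().to_csv(
            out / "categories.tsv", sep="\t", index=False)
        rows = []
        for chrom, genes in self.gene_order.items():
            for pos, g in enumerate(genes):
                rows.append((chrom, pos, g, self.strands[g]))
        pd.DataFrame(rows, columns=["chrom", "position", "gene_id", "strand"]).to_csv(
            out / "gene_order.tsv", sep="\t", index=False)


def study_scale_fixture(seed: int = 0, config: SimulationConfig | None = None) -> FixtureBundle:
    """One call producing the full study-scale synthetic dataset."""
    cfg = config or SimulationConfig()
    genotypes, gt_truth = simulate_genotypes(cfg, seed=seed)
    expression, ex_truth = simulate_expression(genotypes, cfg, seed=seed + 1)
    locus_to_gene = {l: gene_for_locus(l) for l in genotypes.lengths.index}
    rng = np.random.default_rng(seed + 2)
    genes = list(expression.index)
    cats = [f"FC{rng.integers(cfg.n_categories) + 1:02d}" for _ in genes]
    categories = pd.Series(cats, index=genes)
    order = rng.permutation(len(genes))
    n_chrom = 8
    gene_order: dict[str, list[str]] = {}
    for c in range(n_chrom):
        chrom_genes = [genes[j] for j in order[c::n_chrom]]
        gene_order[f"chr{c + 1}"] = chrom_genes
    strands = {g: ("+" if rng.random() < 0.5 else "-") for g in genes}
    return FixtureBundle(cfg, genotypes, gt_truth, expression, ex_truth,
                         locus_to_gene, categories, gene_order, strands)


# ----------------------------------------------------------- toy genome

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _mutate(seq: str, n_subs: int, rng: np.random.Generator,
            lo: int = 0, hi: int | None = None) -> str:
    """Substitute n_subs random positions within [lo, hi)."""
    hi = len(seq) if hi is None else hi
    chars = list(seq)
    for pos in rng.choice(np.arange(lo, hi), size=min(n_subs, hi - lo), replace=False):
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(3)]
    return "".join(chars)


def _impure_tract(unit: str, copies: int, per_column: int, rng: np.random.Generator) -> str:
    """Repeat tract with ``per_column`` substitutions in every unit position.

    Balanced placement guarantees every long-enough sub-window keeps enough
    mismatches to stay below a 90% consensus conservation, while the
    majority base of every column remains the original unit base.
    """
    u = len(unit)
    grid = np.array([list(unit)] * copies)
    for j in range(u):
        for i in rng.choice(copies, size=min(per_column, copies), replace=False):
            alternatives = [b for b in "ACGT" if b != unit[j]]
            grid[i, j] = alternatives[rng.integers(3)]
    return "".join("".join(row) for row in grid)


def _anti_flank(unit: str, n: int, phase_from: int, rng: np.random.Generator) -> str:
    """n bases, each differing from the periodic continuation of ``unit``."""
    u = len(unit)
    out = []
    for k in range(n):
        expect = unit[(phase_from + k) % u]
        alternatives = [b for b in "ACGT" if b != expect]
        out.append(alternatives[rng.integers(3)])
    return "".join(out)


def simulate_genome(
    n_genes: int = 12,
    seed: int = 0,
    promoter_length: int = 1000,
    gene_length: int = 900,
) -> tuple[dict[str, str], list[Gene], pd.DataFrame]:
    """Build a toy genome whose promoters contain planted tandem repeats.

    Per gene, the promoter gets one of: a clean repeat tract passing the
    detection thresholds, a mutated tract near the conservation limit, a
    negative control below the 24 bp minimum or below 90% conservation,
    or no repeat.  Returns (contigs, genes, truth catalog); the truth
    catalog records offset, unit, copies, planted conservation and the
    control type, with offsets in promoter coordinates (5'->3' toward the
    start codon).
    """
    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    genes: list[Gene] = []
    truth = []
    genes_per_contig = 4
    kinds = ["clean", "clean", "mutated", "short_control", "impure_control", "none"]
    for ci in range(math.ceil(n_genes / genes_per_contig)):
        chrom = f"ctg{ci + 1}"
        parts: list[str] = []
        pos = 0
        for gi in range(min(genes_per_contig, n_genes - ci * genes_per_contig)):
            gene_id = f"SG{ci * genes_per_contig + gi + 1:03d}"
            strand = "+" if rng.random() < 0.5 else "-"
            kind = kinds[rng.integers(len(kinds))]
            promoter = list(_random_seq(rng, promoter_length))
            rec = {"gene_id": gene_id, "control": kind, "offset": None,
                   "unit_length": None, "copy_count": None, "conservation": None}
            if kind != "none":
                if kind == "impure_control":
                    unit_len = int(rng.integers(2, 4))
                else:
                    unit_len = int(rng.integers(2, 7))
                unit = _random_seq(rng, unit_len)
                while len(set(unit)) == 1:  # avoid homopolymer units
                    unit = _random_seq(rng, unit_len)
                copies = math.ceil(24 / unit_len) + int(rng.integers(0, 4))
                if kind == "short_control":
                    # 2 units short of the 24 bp minimum, so no 24 bp window over
                    # the tract plus its anti-periodic flanks can reach 90%
                    copies = max(2, math.ceil(24 / unit_len) - 2)
                tract = unit * copies
                if kind == "mutated":  # ~95% conservation, interior substitutions only
                    tract = _mutate(tract, max(1, len(tract) // 20), rng,
                                    lo=unit_len, hi=len(tract) - unit_len)
                elif kind == "impure_control":  # provably below 90% in every window
                    copies = math.ceil(24 / unit_len) + 2
                    tract = _impure_tract(unit, copies, per_column=4 if unit_len == 2 else 3, rng=rng)
                # anti-periodic flanks (2 units each side) pin the tract boundary
                flank = 2 * unit_len
                offset = int(rng.integers(flank, promoter_length - len(tract) - flank))
                left = _anti_flank(unit, flank, phase_from=-flank % unit_len, rng=rng)
                right = _anti_flank(unit, flank, phase_from=0, rng=rng)
                promoter[offset - flank:offset + len(tract) + flank] = list(left + tract + right)
                cons = sum(1 for a, b in zip(tract, unit * copies) if a == b) / len(tract)
                rec.update(offset=offset, unit_length=unit_len, copy_count=copies,
                           conservation=round(cons, 6))
            prom_seq = "".join(promoter)
            body = _random_seq(rng, gene_length)
            spacer = _random_seq(rng, 200)
            if strand == "+":
                parts.append(spacer + prom_seq + body)
                start = pos + len(spacer) + promoter_length
                genes.append(Gene(gene_id, chrom, "+", start, start + gene_length))
            else:
                from Bio.Seq import Seq
                parts.append(spacer + body + str(Seq(prom_seq).reverse_complement()))
                start = pos + len(spacer)
                genes.append(Gene(gene_id, chrom, "-", start, start + gene_length))
            pos += len(parts[-1])
            truth.append(rec)
        parts.append(_random_seq(rng, 200))
        contigs[chrom] = "".join(parts)
    return contigs, genes, pd.DataFrame(truth).set_index("gene_id")


def write_genome(contigs: dict[str, str], genes: Iterable[Gene], fasta_path: str | Path,
                 gff_path: str | Path) -> None:
    """Write the toy genome as FASTA + GFF3 (1-based inclusive)."""
    with open(fasta_path, "w") as fh:
        for chrom, seq in contigs.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write("\t".join([g.chrom, "trknob_sim", "gene", str(g.start + 1), str(g.end),
                                ".", g.strand, ".", f"ID={g.gene_id}"]) + "\n")
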