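"""Promoter extraction: the noncoding window immediately upstream of each start codon.

Promoters are taken as up to 1000 bp upstream of the annotated translation
start, on the gene's strand, truncated wherever the window would run into a
neighbouring gene body (the window must stay noncoding) or off the contig.
Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class Gene:
    """A gene span from the annotation. start/end are 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: invalid span [{self.start},{self.end})")


@dataclass(frozen=True)
class PromoterRegion:
    """An extracted promoter window, oriented 5'->3' toward the start codon."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if not 1 <= self.end - self.start <= 1000:
            raise ValueError(f"promoter of {self.gene_id}: length {self.end - self.start} out of range")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(f"promoter of {self.gene_id}: sequence/coordinate length mismatch")
        if not set(self.sequence) <= VALID_BASES:
            bad = sorted(set(self.sequence) - VALID_BASES)
            raise ValueError(f"promoter of {self.gene_id}: invalid characters {bad}")


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Load a (small) genome FASTA into memory as uppercase strings."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_gene_annotation(path: str | Path) -> list[Gene]:
    """Read gene features from a GFF3 file (1-based inclusive -> half-open)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        if feat.strand not in ("+", "-"):
            raise ValueError(f"gene {feat.id} has no usable strand in annotation")
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(Gene(gene_id=gene_id, chrom=feat.seqid, strand=feat.strand,
                          start=feat.start - 1, end=feat.end))
    return genes


def extract_promoters(
    genome: Mapping[str, str],
    genes: Iterable[Gene],
    length: int = 1000,
    truncate_at_neighbors: bool = True,
) -> list[PromoterRegion]:
    """Extract one promoter window per gene.

    Parameters
    ----------
    genome
        Mapping of chromosome name to sequence.
    genes
        Gene spans with strand.  The start-codon-proximal boundary is
        ``start`` for plus-strand genes and ``end`` for minus-strand genes.
    length
        Maximum promoter length in bp (default 1000).
    truncate_at_neighbors
        If True (default) the window is clipped at any overlap with another
        gene's span, so only noncoding bases remain; if False the full
        window is kept except where it runs off the contig.

    Genes whose promoter window is fully covered by a neighbour or the
    contig edge are omitted with a warning.
    """
    genes = list(genes)
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    promoters: list[PromoterRegion] = []
    for gene in genes:
        if gene.chrom not in genome:
            raise KeyError(f"chromosome {gene.chrom!r} of gene {gene.gene_id} absent from FASTA")
        contig = genome[gene.chrom]
        if gene.strand == "+":
            a, b = max(0, gene.start - length), gene.start
        else:
            a, b = gene.end, min(len(contig), gene.end + length)
        if truncate_at_neighbors:
            for other in by_chrom[gene.chrom]:
                if other.gene_id == gene.gene_id:
                    continue
                if other.start < b and other.end > a:  # overlaps the window
                    if gene.strand == "+":
                        a = max(a, min(other.end, b))
                    else:
                        b = min(b, max(other.start, a))
        if b - a < 1:
            logger.warning("gene %s: no noncoding promoter bases remain; omitted", gene.gene_id)
            continue
        seq = contig[a:b]
        if gene.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        promoters.append(PromoterRegion(gene_id=gene.gene_id, chrom=gene.chrom,
                                        strand=gene.strand, start=a, end=b, sequence=seq))
    return promoters
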