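"""Tandem-repeat discovery in promoter sequences.

A tandem repeat is reported when consecutive copies of a unit of 2-100 bp
cover at least 24 bp and at least 90% of bases match a per-column majority
consensus built by stacking the copies.  Units of 2-9 bp are classed as
microsatellites, units of >=10 bp as minisatellites.  Homopolymers are
never reported.

The scan enumerates, for every unit length and phase, the conservation of
every (start, copy-count) window via prefix-summed one-hot base counts.
A window is reported when it meets the length and conservation thresholds
and is trimmed-maximal: no one-unit extension is both admissible (still
at or above the conservation threshold) and at least as well conserved,
and no one-unit shrink is strictly better conserved.  Trimming mirrors
how a mismatch-penalising repeat finder treats tract boundaries: a pure
tract does not absorb flanking junk units merely because the averaged
conservation would stay above threshold, and an imperfect terminal unit
is shed (which can drop a marginal tract below the 24 bp minimum).
Overlaps are then resolved: identical tracts callable at several unit
sizes collapse to the smallest unit, and among distinct overlapping
tracts the longer, then better-conserved, then leftmost one wins.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .promoters import PromoterRegion

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_BASES = "ACGT"

MICROSATELLITE = "microsatellite"
MINISATELLITE = "minisatellite"


@dataclass(frozen=True)
class RepeatFinderConfig:
    """Detection thresholds.

    min_total_length: minimum bp covered by the repeat tract (default 24,
    so dinucleotide repeats need >=12 copies and trinucleotides >=8).
    min_conservation: minimum fraction of bases matching the stacked-unit
    majority consensus (default 0.90).
    """

    min_total_length: int = 24
    min_conservation: float = 0.90
    min_unit: int = 2
    max_unit: int = 100

    def __post_init__(self) -> None:
        if self.min_unit < 2:
            raise ValueError("min_unit must be >= 2 (homopolymers are excluded)")
        if self.min_total_length < 2 * self.min_unit:
            raise ValueError("min_total_length must allow at least 2 copies of min_unit")
        if not 0 < self.min_conservation <= 1:
            raise ValueError("min_conservation must be in (0, 1]")
        if self.max_unit < self.min_unit:
            raise ValueError("max_unit must be >= min_unit")


@dataclass(frozen=True)
class TandemRepeat:
    """One detected repeat tract, anchored to a promoter by offset."""

    locus_id: str
    gene_id: str
    offset: int
    unit_length: int
    copy_count: int
    total_length: int
    consensus: str
    conservation: float
    repeat_class: str

    def __post_init__(self) -> None:
        if self.total_length != self.unit_length * self.copy_count:
            raise ValueError(f"{self.locus_id}: total_length != unit_length * copy_count")
        if self.copy_count < 2:
            raise ValueError(f"{self.locus_id}: copy_count must be >= 2")


def classify_repeat(unit_length: int) -> str:
    """Microsatellite for 2-9 bp units, minisatellite for >=10 bp."""
    if unit_length < 2:
        raise ValueError(f"unit_length must be >= 2, got {unit_length}")
    return MICROSATELLITE if unit_length <= 9 else MINISATELLITE


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    try:
        return np.array([_BASE_CODE[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence") from exc


def _primitive(unit: str) -> bool:
    """True unless the unit is an exact tiling of a shorter unit."""
    n = len(unit)
    for p in range(1, n):
        if n % p == 0 and unit == unit[:p] * (n // p):
            return False
    return True


def _consensus_and_score(counts: np.ndarray) -> tuple[str, int]:
    """Majority consensus per column (ties alphabetical; N never wins)."""
    # counts: (unit, 4) ACGT occupancy; argmax's lowest-index tie-break is
    # already alphabetical in ACGT order.
    idx = counts.argmax(axis=1)
    return "".join(_BASES[i] for i in idx), int(counts.max(axis=1).sum())


def find_tandem_repeats(sequence: str, config: RepeatFinderConfig | None = None) -> list[dict]:
    """Scan one sequence; returns raw repeat dicts sorted by (offset, unit).

    Each dict has keys offset, unit_length, copy_count, total_length,
    consensus, conservation, repeat_class.  Use
    :func:`find_repeats_in_promoters` to obtain :class:`TandemRepeat`
    records with locus ids.
    """
    cfg = config or RepeatFinderConfig()
    if not sequence:
        raise ValueError("sequence must be non-empty")
    codes = _encode(sequence)
    L = len(codes)
    onehot = np.zeros((L, 4), dtype=np.int32)
    valid = codes < 4
    onehot[np.arange(L)[valid], codes[valid]] = 1

    candidates: list[tuple[int, int, int, float, str]] = []  # start, unit, copies, cons, consensus
    tol = 1e-9
    for u in range(cfg.min_unit, min(cfg.max_unit, L // 2) + 1):
        for p in range(u):
            R = (L - p) // u  # stackable copies at this phase
            if R < 2:
                continue
            stack = onehot[p : p + R * u].reshape(R, u, 4)
            prefix = np.zeros((R + 1, u, 4), dtype=np.int64)
            np.cumsum(stack, axis=0, out=prefix[1:])
            cmin = max(2, -(-cfg.min_total_length // u))

            def window_scores(c: int) -> np.ndarray:
                cnt = prefix[c:] - prefix[:-c]  # (R-c+1, u, 4)
                return cnt.max(axis=2).sum(axis=1)

            def emit(c: int, sc: np.ndarray, prev: np.ndarray | None,
                     nxt: np.ndarray | None) -> None:
                """Report trimmed-maximal admissible windows with c copies.

                Conservation ratios S/(u*c) are compared by integer
                cross-multiplication, so ties are exact.  ``nxt`` is None
                when no window with c+1 copies can reach the threshold.
                """
                acc = sc >= cfg.min_conservation * u * c - tol
                if not acc.any():
                    return
                if nxt is not None:
                    adm = nxt >= cfg.min_conservation * u * (c + 1) - tol
                    # right extension of window a is (a, c+1); left is (a-1, c+1)
                    kill = np.zeros_like(acc)
                    kill[: nxt.size] = adm & (nxt * c >= sc[: nxt.size] * (c + 1))
                    acc &= ~kill
                    kill = np.zeros_like(acc)
                    kill[1 : nxt.size + 1] = adm & (nxt * c >= sc[1 : nxt.size + 1] * (c + 1))
                    acc &= ~kill
                if prev is not None and c - 1 >= 2:
                    # right shrink of window a is (a, c-1); left shrink is (a+1, c-1)
                    acc &= ~(prev[: sc.size] * c > sc * (c - 1))
                    acc &= ~(prev[1 : sc.size + 1] * c > sc * (c - 1))
                for a in np.flatnonzero(acc):
                    cnt = prefix[a + c] - prefix[a]
                    consensus, s = _consensus_and_score(cnt)
                    if not _primitive(consensus):
                        continue  # tract is governed by the smaller-unit analysis
                    candidates.append((p + a * u, u, c, s / (u * c), consensus))

            # scores grow by at most u per added copy while the threshold
            # requirement grows by min_conservation*u, so once the deficit
            # exceeds (R-c)*u*(1-min_conservation) no larger window -- and
            # hence no admissible extension -- can ever qualify.
            prev_sc: np.ndarray | None = None
            cur_sc: np.ndarray | None = None
            cur_c = 0
            for c in range(2, R + 1):
                sc = window_scores(c)
                if cur_sc is not None and cur_c >= cmin:
                    emit(cur_c, cur_sc, prev_sc, sc)
                prev_sc, cur_sc, cur_c = cur_sc, sc, c
                deficit = cfg.min_conservation * u * c - sc.max()
                if deficit > (R - c) * u * (1.0 - cfg.min_conservation) + tol:
                    cur_sc = None  # no window at any larger c can qualify
                    break
            if cur_sc is not None and cur_c >= cmin:
                emit(cur_c, cur_sc, prev_sc, None)

    return _resolve_overlaps(candidates, cfg)


def _resolve_overlaps(
    candidates: Sequence[tuple[int, int, int, float, str]], cfg: RepeatFinderConfig
) -> list[dict]:
    # same tract at several unit sizes -> smallest unit.  Same-tract means the
    # units divide one another and the spans share at least 80% of the shorter
    # one (a periodic tract read at a multiple of its true unit may pick up a
    # flanking base or two, so exact span equality is not required).
    cands = list(candidates)
    parent = list(range(len(cands)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(cands)):
        si, ui, ci = cands[i][0], cands[i][1], cands[i][2]
        for j in range(i + 1, len(cands)):
            sj, uj, cj = cands[j][0], cands[j][1], cands[j][2]
            if ui == uj or (ui % uj and uj % ui):
                continue
            li, lj = ui * ci, uj * cj
            overlap = min(si + li, sj + lj) - max(si, sj)
            if overlap >= 0.8 * min(li, lj):
                parent[find(i)] = find(j)
    groups: dict[int, list[tuple[int, int, int, float, str]]] = {}
    for i, cand in enumerate(cands):
        groups.setdefault(find(i), []).append(cand)
    reps = [min(g, key=lambda t: (t[1], -(t[1] * t[2]), -t[3], t[0])) for g in groups.values()]
    # distinct overlapping tracts -> longer, then better conserved, then leftmost
    ranked = sorted(reps, key=lambda t: (-(t[1] * t[2]), -t[3], t[0], t[1]))
    kept: list[tuple[int, int, int, float, str]] = []
    for cand in ranked:
        start, u, c, cons, consensus = cand
        end = start + u * c
        if all(end <= k[0] or start >= k[0] + k[1] * k[2] for k in kept):
            kept.append(cand)
    kept.sort(key=lambda t: (t[0], t[1]))
    return [
        {
            "offset": start,
            "unit_length": u,
            "copy_count": c,
            "total_length": u * c,
            "consensus": consensus,
            "conservation": cons,
            "repeat_class": classify_repeat(u),
        }
        for start, u, c, cons, consensus in kept
    ]


def find_repeats_in_promoters(
    promoters: Iterable[PromoterRegion], config: RepeatFinderConfig | None = None
) -> list[TandemRepeat]:
    """Run the repeat scan over promoter regions, assigning locus ids."""
    cfg = config or RepeatFinderConfig()
    out: list[TandemRepeat] = []
    for prom in promoters:
        for i, rep in enumerate(find_tandem_repeats(prom.sequence, cfg), start=1):
            out.append(
                TandemRepeat(
                    locus_id=f"{prom.gene_id}.TR{i}",
                    gene_id=prom.gene_id,
                    **rep,
                )
            )
    return out


CATALOG_COLUMNS = [
    "locus_id", "gene_id", "offset", "unit_length", "copy_count",
    "total_length", "consensus", "conservation", "repeat_class",
]


def write_catalog_tsv(repeats: Iterable[TandemRepeat], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CATALOG_COLUMNS)
        for r in repeats:
            w.writerow([r.locus_id, r.gene_id, r.offset, r.unit_length, r.copy_count,
                        r.total_length, r.consensus, f"{r.conservation:.6f}", r.repeat_class])


def read_catalog_tsv(path: str | Path) -> list[TandemRepeat]:
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(TandemRepeat(
                locus_id=row["locus_id"], gene_id=row["gene_id"], offset=int(row["offset"]),
                unit_length=int(row["unit_length"]), copy_count=int(row["copy_count"]),
                total_length=int(row["total_length"]), consensus=row["consensus"],
                conservation=float(row["conservation"]), repeat_class=row["repeat_class"]))
    return out


def write_catalog_gff3(
    repeats: Iterable[TandemRepeat], promoters: Iterable[PromoterRegion], path: str | Path
) -> None:
    """Write repeats in genomic coordinates (1-based inclusive GFF3)."""
    proms = {p.gene_id: p for p in promoters}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in repeats:
            p = proms[r.gene_id]
            if p.strand == "+":
                g0 = p.start + r.offset
            else:  # promoter sequence is reverse-complemented
                g0 = p.end - r.offset - r.total_length
            attrs = (f"ID={r.locus_id};gene={r.gene_id};unit={r.unit_length};"
                     f"copies={r.copy_count};conservation={r.conservation:.4f};"
                     f"class={r.repeat_class}")
            fh.write("\t".join([p.chrom, "trknob", "tandem_repeat", str(g0 + 1),
                                str(g0 + r.total_length), ".", p.strand, ".", attrs]) + "\n")
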