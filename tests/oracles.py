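"""Independent reference implementations used as test oracles.

These re-derive expected values by direct enumeration or closed-form
arithmetic, sharing no code with the package implementation.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
BASES = "ACGT"


def window_consensus(seq: str, start: int, unit: int, copies: int) -> tuple[str, int]:
    """Majority consensus and match count of one stacked window, scored directly."""
    counts = np.zeros((unit, 4), dtype=int)
    for c in range(copies):
        for j in range(unit):
            b = seq[start + c * unit + j]
            if b in BASE_INDEX:
                counts[j, BASE_INDEX[b]] += 1
    consensus = "".join(BASES[int(np.argmax(counts[j]))] for j in range(unit))
    return consensus, int(counts.max(axis=1).sum())


def _primitive_unit(unit_seq: str) -> bool:
    n = len(unit_seq)
    return not any(n % p == 0 and unit_seq == unit_seq[:p] * (n // p)
                   for p in range(1, n))


def _resolve(candidates: list[tuple]) -> list[dict]:
    """Apply the overlap-resolution rules to (s, u, c, cons, consensus) tuples.

    Same-tract collapse: candidates whose units divide one another and whose
    spans overlap by at least 80% of the shorter span are one tract; the
    smallest unit wins (then longest, best conserved, leftmost).  Remaining
    overlapping tracts resolve by longer, better conserved, leftmost.
    """
    import itertools

    n = len(candidates)
    adj = {i: set() for i in range(n)}
    for i, j in itertools.combinations(range(n), 2):
        si, ui, ci = candidates[i][:3]
        sj, uj, cj = candidates[j][:3]
        if ui == uj or (ui % uj != 0 and uj % ui != 0):
            continue
        li, lj = ui * ci, uj * cj
        if min(si + li, sj + lj) - max(si, sj) >= 0.8 * min(li, lj):
            adj[i].add(j)
            adj[j].add(i)
    seen: set[int] = set()
    reps = []
    for i in range(n):
        if i in seen:
            continue
        comp, stack = [], [i]
        while stack:
            k = stack.pop()
            if k in seen:
                continue
            seen.add(k)
            comp.append(k)
            stack.extend(adj[k] - seen)
        members = [candidates[k] for k in comp]
        reps.append(min(members, key=lambda t: (t[1], -(t[1] * t[2]), -t[3], t[0])))
    ranked = sorted(reps, key=lambda t: (-(t[1] * t[2]), -t[3], t[0], t[1]))
    kept = []
    for cand in ranked:
        s, u, c, cw, consensus = cand
        if all(s + u * c <= k[0] or s >= k[0] + k[1] * k[2] for k in kept):
            kept.append(cand)
    kept.sort(key=lambda t: (t[0], t[1]))
    return [{"offset": s, "unit_length": u, "copy_count": c,
             "conservation": float(cw), "consensus": consensus}
            for s, u, c, cw, consensus in kept]


def brute_force_repeats(seq: str, min_total: int = 24, min_cons: float = 0.90,
                        min_unit: int = 2, max_unit: int = 12) -> list[dict]:
    """Naive enumeration of every (start, unit, copies) window, pure Python.

    Reporting rules applied directly from their definitions: conservation
    is consensus matches over window length; a window is reported iff it
    meets the thresholds, has a primitive consensus, no one-unit
    extension is admissible (>= threshold) and at least as conserved, and
    no one-unit shrink (>=2 copies) is strictly better conserved.
    Conservation comparisons are exact (integer cross-multiplication with
    min_cons as an exact fraction).  Intended for short sequences.
    """
    L = len(seq)
    tau = Fraction(min_cons).limit_denominator(10**9)

    def score(s: int, u: int, c: int) -> int:
        counts = [[0] * 4 for _ in range(u)]
        for k in range(c):
            for j in range(u):
                b = seq[s + k * u + j]
                if b in BASE_INDEX:
                    counts[j][BASE_INDEX[b]] += 1
        return sum(max(col) for col in counts)

    def admissible(sc: int, u: int, c: int) -> bool:
        return sc * tau.denominator >= tau.numerator * u * c

    candidates = []
    for u in range(min_unit, min(max_unit, L // 2) + 1):
        for s in range(0, L - 2 * u + 1):
            cmax = (L - s) // u
            for c in range(max(2, math.ceil(min_total / u)), cmax + 1):
                sw = score(s, u, c)
                if not admissible(sw, u, c):
                    continue
                killed = False
                if s + (c + 1) * u <= L:  # right extension
                    se = score(s, u, c + 1)
                    killed = admissible(se, u, c + 1) and se * c >= sw * (c + 1)
                if not killed and s - u >= 0:  # left extension
                    se = score(s - u, u, c + 1)
                    killed = admissible(se, u, c + 1) and se * c >= sw * (c + 1)
                if not killed and c - 1 >= 2:  # shrinks
                    killed = (score(s, u, c - 1) * c > sw * (c - 1)
                              or score(s + u, u, c - 1) * c > sw * (c - 1))
                if killed:
                    continue
                consensus, _ = window_consensus(seq, s, u, c)
                if not _primitive_unit(consensus):
                    continue
                candidates.append((s, u, c, Fraction(sw, u * c), consensus))
    return _resolve(candidates)


def fast_reference_repeats(seq: str, min_total: int = 24, min_cons: float = 0.90,
                           min_unit: int = 2, max_unit: int = 12) -> list[dict]:
    """Vectorized reference scanner applying the same rules as brute_force_repeats.

    Validated against the naive enumeration on short sequences; used to
    check the production scanner on sequences where the naive oracle is
    impractically slow.  All conservation comparisons are exact integer
    cross-multiplications.
    """
    L = len(seq)
    tau = Fraction(min_cons).limit_denominator(10**9)
    tn, td = tau.numerator, tau.denominator
    onehot = np.zeros((L, 4), dtype=np.int64)
    for i, b in enumerate(seq):
        if b in BASE_INDEX:
            onehot[i, BASE_INDEX[b]] = 1

    candidates = []
    for u in range(min_unit, min(max_unit, L // 2) + 1):
        cmin = max(2, math.ceil(min_total / u))
        for phase in range(u):
            rows = (L - phase) // u
            if rows < cmin:
                continue
            cum = np.zeros((rows + 1, u, 4), dtype=np.int64)
            cum[1:] = onehot[phase:phase + rows * u].reshape(rows, u, 4).cumsum(axis=0)
            # S[c] holds scores of all windows with c copies (index by row a),
            # computed lazily: once the best score falls so far below the
            # threshold requirement that even +u per added copy cannot catch
            # up, no larger window (or extension) can qualify.
            S: dict[int, np.ndarray] = {}
            c_stop = rows
            for c in range(2, rows + 1):
                S[c] = (cum[c:] - cum[:-c]).max(axis=2).sum(axis=1)
                if tn * u * c - int(S[c].max()) * td > (rows - c) * u * (td - tn):
                    c_stop = c
                    break
            for c in range(cmin, c_stop + 1):
                sw = S[c]
                keep = sw * td >= tn * u * c
                if c + 1 in S:
                    nxt = S[c + 1]
                    adm = nxt * td >= tn * u * (c + 1)
                    ge_r = adm & (nxt * c >= sw[:-1] * (c + 1))
                    keep[:-1] &= ~ge_r                       # right extension
                    ge_l = adm & (nxt * c >= sw[1:] * (c + 1))
                    keep[1:] &= ~ge_l                        # left extension
                if c - 1 >= 2:
                    prv = S[c - 1]
                    keep &= ~(prv[:len(sw)] * c > sw * (c - 1))   # right shrink
                    keep &= ~(prv[1:len(sw) + 1] * c > sw * (c - 1))  # left shrink
                for a in np.flatnonzero(keep):
                    s = phase + int(a) * u
                    consensus, sc = window_consensus(seq, s, u, c)
                    if _primitive_unit(consensus):
                        candidates.append((s, u, c, Fraction(int(sc), u * c), consensus))
    return _resolve(candidates)


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> dict:
    """Explicit (X'X)^-1 X'y solve with R^2/F/p from their definitions."""
    from scipy import stats

    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    n, k = X.shape
    r2 = 1 - rss / tss
    df1, df2 = k - 1, n - k
    F = (r2 / df1) / ((1 - r2) / df2)
    p = float(stats.f.sf(F, df1, df2))
    return {"beta": beta, "RSS": rss, "R2": r2, "F": F, "p": p}


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing hypergeometric probabilities <= observed.

    Enumerates the full support of tables with the observed margins using
    exact rational arithmetic.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0

    def comb(n_: int, k_: int) -> int:
        return math.comb(n_, k_)

    total = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c), total)
    p_sum = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = Fraction(comb(r1, x) * comb(r2, c1 - x), total)
        if px <= p_obs:
            p_sum += px
    return float(min(p_sum, Fraction(1)))
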