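"""Independent brute-force oracles used to validate the fast implementations.

Each oracle is a separate, literal transcription of the underlying
definition — deliberately simple and quadratic where needed — and shares no
code path with the implementation it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMP.get(c, "N") for c in reversed(seq))


# ---------------------------------------------------------------------------
# SSRs: all-period exhaustive scan
# ---------------------------------------------------------------------------


def _unit_is_primitive(unit: str) -> bool:
    for d in range(1, len(unit)):
        if len(unit) % d == 0 and unit == unit[:d] * (len(unit) // d):
            return False
    return True


def brute_force_ssrs(seq: str, thresholds: dict[int, int]) -> set[tuple[int, int, int]]:
    """All maximal perfect SSRs as (start, unit_len, copies) triples."""
    n = len(seq)
    found: set[tuple[int, int, int]] = set()
    for p, min_copies in thresholds.items():
        i = 0
        while i + p <= n:
            if any(seq[i + t] not in "ACGT" for t in range(p)):
                i += 1
                continue
            # extend the periodic run starting at i
            j = i + p
            while j < n and seq[j] == seq[j - p] and seq[j] in "ACGT":
                j += 1
            run_len = j - i
            copies = run_len // p
            # maximal on the left?
            left_ok = i == 0 or seq[i - 1] not in "ACGT" or seq[i - 1] != seq[i - 1 + p]
            if copies >= min_copies and left_ok and _unit_is_primitive(seq[i : i + p]):
                found.add((i, p, copies))
            i += 1
    return found


# ---------------------------------------------------------------------------
# dispersed repeats: full-diagonal enumeration
# ---------------------------------------------------------------------------


def _diagonal_windows(a: str, b: str, i0: int, j0: int, k: int) -> list[tuple[int, int, int]]:
    """Maximal ≤k-mismatch windows along one diagonal, as (start_in_a,
    end_in_a, n_mismatches). Non-ACGT characters never match."""
    length = min(len(a) - i0, len(b) - j0)
    mism = [
        t
        for t in range(length)
        if a[i0 + t] != b[j0 + t] or a[i0 + t] not in "ACGT" or b[j0 + t] not in "ACGT"
    ]
    m = len(mism)
    if m <= k:
        return [(i0, i0 + length, m)]
    blockers = [-1] + mism + [length]
    wins = []
    for t in range(m - k + 1):
        start = blockers[t] + 1
        end = blockers[t + k + 1]
        wins.append((i0 + start, i0 + end, k))
    return wins


def brute_force_dispersed(
    seq: str, min_len: int, max_len: int, max_mismatch: int
) -> set[tuple[str, int, int, int]]:
    """All maximal dispersed repeat pairs with min_len <= length <= max_len,
    as (kind, pos1, pos2, length) with pos1 <= pos2."""
    n = len(seq)
    comp = "".join(COMP.get(c, "N") for c in seq)
    transforms = {"F": seq, "P": revcomp(seq), "R": seq[::-1], "C": comp}
    out: set[tuple[str, int, int, int]] = set()
    for kind, b in transforms.items():
        for d in range(-(n - 1), n):
            i0 = max(0, d)
            j0 = max(0, -d)
            for start, end, _ in _diagonal_windows(seq, b, i0, j0, max_mismatch):
                length = end - start
                if not (min_len <= length <= max_len):
                    continue
                jstart = start - d
                if kind in ("F", "C"):
                    p1, p2 = start, jstart
                    if p1 == p2:
                        continue
                else:
                    p1, p2 = start, n - jstart - length
                lo, hi = min(p1, p2), max(p1, p2)
                out.add((kind, lo, hi, length))
    return out


# ---------------------------------------------------------------------------
# nucleotide diversity: direct all-pairs recomputation
# ---------------------------------------------------------------------------


def direct_pi(rows: list[str], start: int, end: int) -> float:
    """Mean over sequence pairs of mismatches/compared in [start, end)."""
    vals = []
    for a, b in combinations(rows, 2):
        comp = mism = 0
        for x, y in zip(a[start:end], b[start:end]):
            if x in "ACGT" and y in "ACGT":
                comp += 1
                if x != y:
                    mism += 1
        if comp:
            vals.append(mism / comp)
    return sum(vals) / len(vals) if vals else math.nan


# ---------------------------------------------------------------------------
# Wright's ENC: second literal transcription
# ---------------------------------------------------------------------------

_CODE = {}
for _c1 in "TCAG":
    for _c2 in "TCAG":
        for _c3 in "TCAG":
            _CODE[_c1 + _c2 + _c3] = None
_TABLE = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _idx, _codon in enumerate(_CODE):
    _CODE[_codon] = _TABLE[_idx]


def literal_enc(counts: dict[str, int]) -> float:
    """Wright's Nc from raw codon counts (plastid code; stops excluded)."""
    families: dict[str, list[str]] = {}
    for codon, aa in _CODE.items():
        if aa == "*":
            continue
        families.setdefault(aa, []).append(codon)
    by_class: dict[int, list[float]] = {}
    for aa, fam in families.items():
        size = len(fam)
        if size == 1:
            continue
        ns = [counts.get(c, 0) for c in fam]
        n = sum(ns)
        if n < 2:
            continue
        f = (n * sum((x / n) ** 2 for x in ns) - 1) / (n - 1)
        if f > 0:
            by_class.setdefault(size, []).append(f)
    means = {k: sum(v) / len(v) for k, v in by_class.items()}
    if 3 not in means and 2 in means and 4 in means:
        means[3] = (means[2] + means[4]) / 2
    counts_per_class = {2: 9, 3: 1, 4: 5, 6: 3}
    if not means:
        return math.nan
    missing = [k for k in counts_per_class if k not in means]
    fallback = sum(means.values()) / len(means)
    for k in missing:
        means[k] = fallback
    nc = 2 + sum(counts_per_class[k] / means[k] for k in counts_per_class)
    return min(61.0, max(20.0, nc))


# ---------------------------------------------------------------------------
# NG86: exhaustive pathway enumeration (recursive)
# ---------------------------------------------------------------------------


def _aa(codon: str) -> str:
    return _CODE[codon]


def _codon_syn_sites(codon: str) -> float:
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if _aa(mut) == "*":
                continue
            tot += 1
            if _aa(mut) == _aa(codon):
                syn += 1
        if tot:
            s += syn / tot
    return s


def _enumerate_paths(c1: str, c2: str):
    """Yield (passes_through_stop, sd, nd) for every mutation ordering."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        yield (False, 0, 0)
        return

    def recurse(cur, remaining, via_stop, sd, nd):
        if not remaining:
            yield (via_stop, sd, nd)
            return
        for pos in remaining:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            stop_here = via_stop or (_aa(nxt) == "*" and len(remaining) > 1)
            if _aa(cur) == _aa(nxt):
                yield from recurse(nxt, [p for p in remaining if p != pos], stop_here, sd + 1, nd)
            else:
                yield from recurse(nxt, [p for p in remaining if p != pos], stop_here, sd, nd + 1)

    yield from recurse(c1, diff, False, 0, 0)


def ng86_oracle(seq1: str, seq2: str) -> dict[str, float]:
    cods1 = [seq1[i : i + 3] for i in range(0, len(seq1), 3)]
    cods2 = [seq2[i : i + 3] for i in range(0, len(seq2), 3)]
    pairs = [
        (a, b)
        for a, b in zip(cods1, cods2)
        if all(ch in "ACGT" for ch in a + b) and _aa(a) != "*" and _aa(b) != "*"
    ]
    S = (sum(_codon_syn_sites(a) for a, _ in pairs) + sum(_codon_syn_sites(b) for _, b in pairs)) / 2
    N = 3 * len(pairs) - S
    Sd = Nd = 0.0
    for a, b in pairs:
        paths = list(_enumerate_paths(a, b))
        ok = [(s, n) for via, s, n in paths if not via]
        if not ok:
            ok = [(s, n) for _, s, n in paths]
        Sd += sum(s for s, _ in ok) / len(ok)
        Nd += sum(n for _, n in ok) / len(ok)

    def jc(p):
        return -0.75 * math.log(1 - 4 * p / 3) if p < 0.75 else math.nan

    return {
        "S": S,
        "N": N,
        "Sd": Sd,
        "Nd": Nd,
        "ks": jc(Sd / S) if S else math.nan,
        "ka": jc(Nd / N) if N else math.nan,
    }


# ---------------------------------------------------------------------------
# Pearson correlation, textbook form
# ---------------------------------------------------------------------------


def pearson(x: list[float], y: list[float]) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den
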