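"""Microsatellite, dispersed-repeat, and tandem-repeat detection.

Three repeat classes are censused in plastome studies:

* **SSRs** (microsatellites): maximal perfect runs of a 1-6 bp unit, with
  MISA-style minimum copy numbers per unit length (10/5/4/3/3/3 by default).
* **Dispersed repeats**: maximal pairs of similar blocks in four orientations
  — forward (F), palindromic (P, reverse complement), reverse (R), and
  complement (C) — with a Hamming mismatch budget, REPuter style.
* **Tandem repeats**: arrays of a unit longer than 6 bp repeated in place,
  found by a period scan with gapless extension (a deliberately simple
  stand-in for score-model tandem finders).

All features can be localized to region (LSC/SSC/IRa/IRb) and genomic context
(CDS/intron/IGS) by the midpoint rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._genetics import complement, minimal_period, minimal_rotation, revcomp, seq_to_array
from .genome_io import GeneAnnotation, RegionPartition

DEFAULT_SSR_THRESHOLDS = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}
REPEAT_KINDS = ("F", "P", "R", "C")


@dataclass
class SSRRecord:
    motif: str  # canonical: lexicographically minimal rotation
    unit_len: int
    copies: int
    start: int
    end: int
    compound_id: str | None = None
    region: str | None = None
    context: str | None = None

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class DispersedRepeat:
    kind: str  # F, P, R, or C
    length: int
    pos1: int
    pos2: int
    mismatches: int
    region: str | None = None
    context: str | None = None

    @property
    def start(self) -> int:
        return self.pos1

    @property
    def end(self) -> int:
        return self.pos1 + self.length


@dataclass
class TandemRepeat:
    unit: str
    copies: float
    start: int
    end: int
    identity: float
    region: str | None = None
    context: str | None = None


# ---------------------------------------------------------------------------
# SSRs
# ---------------------------------------------------------------------------


def _valid_mask(arr: np.ndarray) -> np.ndarray:
    return (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) intervals of consecutive True values."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def find_ssrs(
    sequence: str,
    thresholds: dict[int, int] | None = None,
) -> list[SSRRecord]:
    """All maximal perfect microsatellites meeting per-unit-length thresholds.

    A run reportable at several unit lengths is reported only at its smallest
    period (a poly-A run is a mononucleotide SSR, never an AA dinucleotide).
    N (or any non-ACGT character) breaks runs. Motifs are canonicalized by
    minimal rotation; strandedness is preserved. Records are sorted by start.
    """
    thresholds = thresholds or DEFAULT_SSR_THRESHOLDS
    arr = seq_to_array(sequence)
    valid = _valid_mask(arr)
    out: list[SSRRecord] = []
    for p, min_copies in sorted(thresholds.items()):
        if len(sequence) <= p:
            continue
        eq = (arr[p:] == arr[:-p]) & valid[p:] & valid[:-p]
        for rs, re in _true_runs(eq):
            run_len = (re - rs) + p  # length of the periodic stretch
            copies = run_len // p
            if copies < min_copies:
                continue
            unit = sequence[rs : rs + p]
            if minimal_period(unit) != p:
                continue  # reported at its smaller period instead
            out.append(
                SSRRecord(
                    motif=minimal_rotation(unit),
                    unit_len=p,
                    copies=copies,
                    start=rs,
                    end=rs + copies * p,
                )
            )
    out.sort(key=lambda r: (r.start, r.unit_len))
    return out


def merge_compound(ssrs: Sequence[SSRRecord], max_gap: int = 100) -> list[SSRRecord]:
    """Assign a shared compound_id to SSRs separated by at most ``max_gap`` bp.

    Input must be sorted by start (same sequence); singletons keep
    ``compound_id=None``. Returns the same records, annotated.
    """
    starts = [r.start for r in ssrs]
    if starts != sorted(starts):
        raise ValueError("SSR records must be sorted by start")
    group: list[SSRRecord] = []
    n_compound = 0

    def flush():
        nonlocal n_compound
        if len(group) > 1:
            n_compound += 1
            for r in group:
                r.compound_id = f"c{n_compound}"

    for rec in ssrs:
        if group and rec.start - group[-1].end <= max_gap:
            group.append(rec)
        else:
            flush()
            group = [rec]
    flush()
    return list(ssrs)


# ---------------------------------------------------------------------------
# dispersed repeats
# ---------------------------------------------------------------------------


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all k-mers and a validity mask (no ambiguous base)."""
    lut = np.full(256, 4, dtype=np.int64)
    for v, b in enumerate("ACGT"):
        lut[ord(b)] = v
    codes = lut[arr]
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    km = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for t in range(k):
        km = km * 4 + codes[t : t + n]
        ok &= codes[t : t + n] < 4
    return km, ok

def _seed_pairs(km_a, ok_a, km_b, ok_b, cap: int = 20000) -> tuple[np.ndarray, np.ndarray]:
    """All (i, j) with identical valid k-mers in A and B."""
    ia = np.flatnonzero(ok_a)
    ib = np.flatnonzero(ok_b)
    if ia.size == 0 or ib.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    va, vb = km_a[ia], km_b[ib]
    order_a, order_b = np.argsort(va, kind="stable"), np.argsort(vb, kind="stable")
    sa, sb = va[order_a], vb[order_b]
    pa, pb = ia[order_a], ib[order_b]
    common = np.intersect1d(sa, sb)
    out_i, out_j = [], []
    for code in common:
        ga = pa[np.searchsorted(sa, code) : np.searchsorted(sa, code, side="right")]
        gb = pb[np.searchsorted(sb, code) : np.searchsorted(sb, code, side="right")]
        if ga.size * gb.size > cap:
            ga, gb = ga[: int(np.sqrt(cap))], gb[: int(np.sqrt(cap))]
        gi, gj = np.meshgrid(ga, gb, indexing="ij")
        out_i.append(gi.ravel())
        out_j.append(gj.ravel())
    if not out_i:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    return np.concatenate(out_i), np.concatenate(out_j)


def _filter_candidates(a: np.ndarray, b: np.ndarray, I: np.ndarray, J: np.ndarray,
                       k: int, min_len: int, max_mismatch: int) -> np.ndarray:
    """Keep seed pairs for which some window of ``min_len`` containing the
    seed has at most ``max_mismatch`` mismatches (vectorized prefilter)."""
    if I.size == 0:
        return np.zeros(0, dtype=bool)
    w = min_len
    pad_a = np.concatenate([np.full(w, 254, np.uint8), a, np.full(w, 254, np.uint8)])
    pad_b = np.concatenate([np.full(w, 255, np.uint8), b, np.full(w, 255, np.uint8)])
    offs = np.arange(-(w - k), w)
    keep = np.zeros(I.size, dtype=bool)
    chunk = 100_000
    for lo in range(0, I.size, chunk):
        ii = I[lo : lo + chunk, None] + w + offs
        jj = J[lo : lo + chunk, None] + w + offs
        mm = (pad_a[ii] != pad_b[jj]).astype(np.int32)
        cs = np.cumsum(mm, axis=1)
        win = cs[:, w - 1 :].copy()
        win[:, 1:] -= cs[:, : win.shape[1] - 1]
        keep[lo : lo + chunk] = win.min(axis=1) <= max_mismatch
    return keep


def _mismatch_blockers(a: str, b: str, i: int, j: int, step: int, budget: int) -> tuple[list[int], int]:
    """Scan from (i, j) in direction ``step`` collecting up to ``budget``+1
    mismatch positions (A coordinates); returns (positions, n_real) where a
    final wall entry is appended if a sequence end was reached first."""
    na, nb = len(a), len(b)
    pos: list[int] = []
    t, u = i, j
    while 0 <= t < na and 0 <= u < nb and len(pos) <= budget:
        if a[t] != b[u]:
            pos.append(t)
        t += step
        u += step
    n_real = len(pos)
    if n_real <= budget:  # ran into a wall before collecting budget+1 blockers
        pos.append(t)  # wall: first coordinate outside the sequence
        return pos, n_real
    return pos, n_real - 1  # last entry is the (budget+1)-th mismatch blocker


def _maximal_windows(a: str, b: str, i: int, j: int, k: int,
                     max_mismatch: int) -> list[tuple[int, int, int]]:
    """All maximal ≤max_mismatch windows on this diagonal containing the exact
    seed ``a[i:i+k] == b[j:j+k]``. Returns (start, end, mismatches) in A
    coordinates."""
    kk = max_mismatch
    left, nl = _mismatch_blockers(a, b, i - 1, j - 1, -1, kk)
    right, nr = _mismatch_blockers(a, b, i + k, j + k, +1, kk)
    wins = []
    for t in range(min(nl, kk) + 1):
        for u in range(min(nr, kk - t) + 1):
            ext_left = t < nl and t + u < kk
            ext_right = u < nr and t + u < kk
            if ext_left or ext_right:
                continue  # not maximal: could absorb another mismatch
            if t >= len(left) or u >= len(right):
                continue
            start = left[t] + 1
            end = right[u]
            wins.append((start, end, t + u))
    return wins


def find_dispersed(
    sequence: str,
    min_len: int = 30,
    max_mismatch: int = 3,
    ir_mask: tuple[tuple[int, int], tuple[int, int]] | None = None,
) -> list[DispersedRepeat]:
    """Maximal dispersed repeat pairs of the four orientations F/P/R/C.

    A pair is maximal when it cannot be extended on either side without
    exceeding the Hamming mismatch budget or running off the sequence. The
    genome's own IR duplication is excluded by passing the detected (IRb, IRa)
    intervals as ``ir_mask``: pairs with one copy inside each IR are artifacts
    of that duplication, not dispersed repeats.
    """
    n = len(sequence)
    if n < 2 * min_len:
        return []
    k = max(4, min_len // (max_mismatch + 1))
    # ambiguous bases must never match, not even each other: substitute
    # distinct sentinels on the two comparison strands
    a = "".join(c if c in "ACGT" else "!" for c in sequence)
    arr_a = seq_to_array(a)
    km_a, ok_a = _kmer_codes(arr_a, k)

    def sanitize_b(s: str) -> str:
        return "".join(c if c in "ACGT" else "?" for c in s)

    b_plain = sanitize_b(sequence)
    transforms = {
        "F": b_plain,
        "P": sanitize_b(revcomp(sequence)),
        "R": b_plain[::-1],
        "C": sanitize_b(complement(sequence)),
    }
    out: list[DispersedRepeat] = []
    seen: set[tuple] = set()
    for kind, b in transforms.items():
        arr_b = seq_to_array(b)
        if kind == "F":
            km_b, ok_b = km_a, ok_a
        else:
            km_b, ok_b = _kmer_codes(arr_b, k)
        I, J = _seed_pairs(km_a, ok_a, km_b, ok_b)
        if kind in ("F", "C"):
            mask = I < J if kind == "F" else I != J
            I, J = I[mask], J[mask]
        if I.size == 0:
            continue
        keep = _filter_candidates(arr_a, arr_b, I, J, k, min_len, max_mismatch)
        I, J = I[keep], J[keep]
        done_windows: set[tuple[int, int, int]] = set()
        # seeds inside one maximal exact stretch yield identical window sets
        # (every maximal window must span the whole stretch): compute once
        exact_stretches: dict[int, list[tuple[int, int]]] = {}
        nb = len(b)
        for i, j in zip(I.tolist(), J.tolist()):
            diag = i - j
            if any(s <= i and i + k <= e for s, e in exact_stretches.get(diag, ())):
                continue
            lo_i, lo_j = i, j
            while lo_i > 0 and lo_j > 0 and a[lo_i - 1] == b[lo_j - 1]:
                lo_i -= 1
                lo_j -= 1
            hi_i, hi_j = i + k, j + k
            while hi_i < n and hi_j < nb and a[hi_i] == b[hi_j]:
                hi_i += 1
                hi_j += 1
            exact_stretches.setdefault(diag, []).append((lo_i, hi_i))
            wins = _maximal_windows(a, b, i, j, k, max_mismatch)
            for start, end, mm in wins:
                if (diag, start, end) in done_windows:
                    continue
                done_windows.add((diag, start, end))
                length = end - start
                if length < min_len:
                    continue
                j0 = start - diag
                if kind in ("F", "C"):
                    p1, p2 = start, j0
                else:  # P and R map B coordinates back through the flip
                    p1, p2 = start, n - j0 - length
                if p1 == p2 and kind in ("F", "C"):
                    continue
                lo, hi = (p1, p2) if p1 <= p2 else (p2, p1)
                key = (kind, lo, hi, length)
                if key in seen:
                    continue
                seen.add(key)
                if ir_mask is not None and _is_ir_artifact((lo, hi, length), ir_mask, n):
                    continue
                out.append(DispersedRepeat(kind, length, lo, hi, mm))
    out.sort(key=lambda r: (r.pos1, r.pos2, r.kind))
    return out


def _overlap_frac(start: int, length: int, iv: tuple[int, int], n: int) -> float:
    """Fraction of [start, start+length) inside the (possibly origin-
    wrapping) interval ``iv``."""
    s, e = iv
    segs = [(s, e)] if e <= n else [(s, n), (0, e - n)]
    ov = 0
    for a, b in segs:
        ov += max(0, min(start + length, b) - max(start, a))
    return ov / length if length else 0.0


def _is_ir_artifact(pair: tuple[int, int, int], ir_mask, n: int) -> bool:
    """A repeat pair whose copies lie mostly inside the two IRs is a
    consequence of the IR duplication itself, not a dispersed repeat."""
    lo, hi, length = pair
    ivb, iva = ir_mask
    return (
        _overlap_frac(lo, length, ivb, n) >= 0.5 and _overlap_frac(hi, length, iva, n) >= 0.5
    ) or (
        _overlap_frac(lo, length, iva, n) >= 0.5 and _overlap_frac(hi, length, ivb, n) >= 0.5
    )


# ---------------------------------------------------------------------------
# tandem repeats
# ---------------------------------------------------------------------------


def find_tandem(
    sequence: str,
    min_unit: int = 7,
    min_copies: float = 2.0,
    min_identity: float = 0.9,
    min_span: int = 24,
    max_unit: int = 100,
    max_mismatch: int = 4,
) -> list[TandemRepeat]:
    """Near-exact tandem arrays with unit length above the SSR range.

    For each candidate period the self-offset match profile is scanned for
    maximal stretches containing at most ``max_mismatch`` substitutions; an
    array is kept when it clears all floors (copies, identity, span). Units
    that are themselves periodic with period ≤ 6 are left to the SSR scan.
    Overlapping candidate arrays are resolved by span x identity.
    """
    n = len(sequence)
    arr = seq_to_array(sequence)
    valid = _valid_mask(arr)
    # low-period (SSR-range) runs: tandem candidates mostly covering one are
    # left to the SSR scan, whatever period they were read at
    ssr_spans: list[tuple[int, int]] = []
    for p in range(1, 7):
        if n <= p:
            continue
        eq0 = (arr[p:] == arr[:-p]) & valid[p:] & valid[:-p]
        for rs, re in _true_runs(eq0):
            if (re - rs) + p >= 3 * p and (re - rs) + p >= 8:
                ssr_spans.append((rs, re + p))
    candidates: list[TandemRepeat] = []
    for u in range(min_unit, min(max_unit, n // 2) + 1):
        eq = (arr[u:] == arr[:-u]) & valid[u:] & valid[:-u]
        mism = np.flatnonzero(~eq)
        walls = np.concatenate(([-1], mism, [eq.size]))
        # maximal stretches with b mismatches sit between walls b+1 apart
        for b in range(0, max_mismatch + 1):
            if walls.size < b + 2:
                break
            starts = walls[: walls.size - b - 1] + 1
            ends = walls[b + 1 :]
            lens = ends - starts
            # cheap necessary conditions: span floor, copies floor, and the
            # identity floor (each consensus mismatch costs <= 2 offset
            # mismatches, so span * (1 - min_identity) >= b/2)
            ok = (
                (lens + u >= min_span)
                & (lens >= u * (min_copies - 1.0))
                & ((lens + u) * (1.0 - min_identity) * 2.0 >= b)
            )
            for idx in np.flatnonzero(ok):
                l, r = int(starts[idx]), int(ends[idx])
                span = (r - l) + u
                copies = span / u
                if copies < min_copies:
                    continue
                unit = _consensus_unit(sequence, l, span, u)
                if minimal_period(unit) < min_unit:
                    continue
                # identity is measured against the consensus unit over the
                # whole array (one substitution in k copies costs 1/(k*u))
                matches = sum(
                    1 for x in range(span) if sequence[l + x] == unit[x % u]
                )
                identity = matches / span
                if identity < min_identity:
                    continue
                ssr_ov = sum(
                    max(0, min(l + span, e) - max(l, s)) for s, e in ssr_spans
                )
                if ssr_ov * 2 >= span:
                    continue  # this locus is (mostly) a microsatellite
                candidates.append(TandemRepeat(unit, copies, l, l + span, identity))
    return _resolve_overlaps(candidates)


def _consensus_unit(seq: str, start: int, span: int, u: int) -> str:
    """Column-majority consensus over the full copies of the array."""
    cols = []
    n_full = span // u
    for c in range(u):
        col = [seq[start + r * u + c] for r in range(n_full) if start + r * u + c < start + span]
        cols.append(max(set(col), key=col.count))
    return "".join(cols)


def _tandem_score(t: TandemRepeat) -> float:
    """Alignment-style score: +1 per consensus match, −3 per mismatch, so an
    exact short-unit array beats a sloppier longer-period reading of the
    same locus."""
    span = t.end - t.start
    return span * (4.0 * t.identity - 3.0)


def _resolve_overlaps(cands: list[TandemRepeat]) -> list[TandemRepeat]:
    """Keep, among mutually overlapping arrays, the best-scoring one
    (ties: longer span, then smaller start)."""
    cands = sorted(
        cands,
        key=lambda t: (-_tandem_score(t), -(t.end - t.start), t.start),
    )
    chosen: list[TandemRepeat] = []
    for t in cands:
        if all(t.end <= c.start or c.end <= t.start for c in chosen):
            chosen.append(t)
    chosen.sort(key=lambda t: t.start)
    return chosen


# ---------------------------------------------------------------------------
# localization
# ---------------------------------------------------------------------------


def localize(
    features: Iterable,
    partition: RegionPartition,
    genes: Sequence[GeneAnnotation],
    genome_length: int | None = None,
) -> list:
    """Label features with region (by midpoint) and context (CDS/intron/IGS)."""
    feats = list(features)
    n = genome_length
    if n is None:
        n = max(e for _, (s, e) in partition.as_dict().items())
    for f in feats:
        start = f.start
        end = f.end if hasattr(f, "end") else f.start + f.length
        mid = ((start + end - 1) // 2) % n
        f.region = _region_of(mid, partition, n)
        f.context = _context_of(mid, genes, n)
    return feats


def _region_of(pos: int, partition: RegionPartition, n: int) -> str:
    for name, (s, e) in partition.as_dict().items():
        p = pos if pos >= s else pos + n
        if s <= p < e:
            return name
    return "?"


def _context_of(pos: int, genes: Sequence[GeneAnnotation], n: int) -> str:
    in_gene = False
    for g in genes:
        fs, fe = g.footprint()
        p = pos if pos >= fs else pos + n
        if not (fs <= p < fe):
            continue
        in_gene = True
        for s, e in g.parts:
            q = pos if pos >= s else pos + n
            if s <= q < e:
                return "CDS"
        return "intron"
    return "intron" if in_gene else "IGS"
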