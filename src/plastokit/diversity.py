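"""Sliding-window nucleotide diversity, variant calling, and genetic distances.

Nucleotide diversity (π) is the average pairwise per-site difference among
aligned sequences. Windows of high π mark mutational hotspots usable as DNA
barcodes; the tiers used for partitioning are high (π > 0.02), medium
(0.01 ≤ π ≤ 0.02), and low (π < 0.01), with windows above 0.06 flagged as
hotspots. SNVs and indel events are called against a designated reference
row, and pairwise distances are computed under the p or Kimura two-parameter
(K2P) model with pairwise deletion of gapped/ambiguous columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._genetics import seq_to_array

_GAP = ord("-")
_ACGT = tuple(ord(c) for c in "ACGT")
_TRANSITIONS = {(ord("A"), ord("G")), (ord("G"), ord("A")),
                (ord("C"), ord("T")), (ord("T"), ord("C"))}


@dataclass
class AlignmentMatrix:
    """A multiple sequence alignment over {A,C,G,T,N,-}."""

    accessions: list[str]
    matrix: np.ndarray  # (n_rows, n_cols) uint8 ASCII codes

    def __post_init__(self):
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.accessions):
            raise ValueError("matrix shape does not match accession list")
        if len(self.accessions) < 2:
            raise ValueError("an alignment needs at least two rows")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def row(self, accession: str) -> np.ndarray:
        return self.matrix[self.accessions.index(accession)]

    @classmethod
    def from_sequences(cls, named_seqs: Sequence[tuple[str, str]]) -> "AlignmentMatrix":
        names = [n for n, _ in named_seqs]
        seqs = [s.upper() for _, s in named_seqs]
        lens = {len(s) for s in seqs}
        if len(lens) != 1:
            raise ValueError(f"aligned rows have unequal lengths: {sorted(lens)}")
        # ambiguity codes other than N are treated as N
        cleaned = [
            "".join(c if c in "ACGTN-" else "N" for c in s) for s in seqs
        ]
        mat = np.vstack([seq_to_array(s) for s in cleaned])
        return cls(names, mat)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "AlignmentMatrix":
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise ValueError(f"{path}: no FASTA records")
        return cls.from_sequences(records)


@dataclass
class WindowDiversity:
    start: int
    end: int
    pi: float  # NaN when no comparable sites
    n_sites: int
    region: str | None = None
    var_class: str | None = None
    hotspot: bool = False


@dataclass
class HotspotInterval:
    start: int
    end: int
    mean_pi: float
    name: str


@dataclass
class VariantTable:
    reference: str
    bin_size: int
    bins: pd.DataFrame  # columns: bin_start, snv, indel
    per_row: pd.DataFrame  # columns: accession, snv, indel


@dataclass
class DistanceMatrix:
    accessions: list[str]
    values: np.ndarray
    model: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.accessions, columns=self.accessions)


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------


def _pair_pi(xa: np.ndarray, xb: np.ndarray) -> tuple[float, int]:
    """(mismatch fraction, compared sites) with pairwise gap/N deletion."""
    good = np.isin(xa, _ACGT) & np.isin(xb, _ACGT)
    comp = int(good.sum())
    if comp == 0:
        return math.nan, 0
    mism = int(((xa != xb) & good).sum())
    return mism / comp, comp


def sliding_window_pi(
    alignment: AlignmentMatrix,
    window: int = 600,
    step: int = 200,
    regions: Sequence[str] | None = None,
) -> list[WindowDiversity]:
    """π per sliding window: the mean over all sequence pairs of
    (mismatches / compared sites), columns with a gap or N in either member
    of a pair excluded pairwise.

    The final partial window is reported with its true span. ``regions`` may
    give a per-column region label; each window is tagged with the label of
    its first column. A window with no comparable sites gets ``pi = NaN``.
    """
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")
    mat = alignment.matrix
    n_cols = alignment.length
    out: list[WindowDiversity] = []
    starts = list(range(0, n_cols, step))
    for ws in starts:
        we = min(ws + window, n_cols)
        sub = mat[:, ws:we]
        vals = []
        for i, j in combinations(range(alignment.n_rows), 2):
            p, comp = _pair_pi(sub[i], sub[j])
            if comp > 0:
                vals.append(p)
        pi = float(np.mean(vals)) if vals else math.nan
        good_all = np.isin(sub, _ACGT).all(axis=0)
        region = regions[ws] if regions is not None else None
        out.append(
            WindowDiversity(ws, we, pi, int(good_all.sum()), region=region)
        )
        if we == n_cols:
            break
    return out


def classify_variability(
    windows: Sequence[WindowDiversity],
    hotspot: float = 0.06,
    high: float = 0.02,
    low: float = 0.01,
    annotations: Sequence[tuple[int, int, str]] | None = None,
) -> tuple[list[WindowDiversity], list[HotspotInterval]]:
    """Tag windows with variability tier and hotspot flag; merge contiguous
    hotspot windows into named intervals.

    Tiers: high (π > ``high``), medium (``low`` ≤ π ≤ ``high``), low
    (π < ``low``); hotspot iff π > ``hotspot``. Interval names come from the
    flanking/overlapping annotations (e.g. ``ndhF-rpl32``) when provided,
    otherwise coordinates are used.
    """
    for w in windows:
        if math.isnan(w.pi):
            w.var_class = None
            w.hotspot = False
        else:
            w.hotspot = w.pi > hotspot
            if w.pi > high:
                w.var_class = "high"
            elif w.pi >= low:
                w.var_class = "medium"
            else:
                w.var_class = "low"
    intervals: list[HotspotInterval] = []
    run: list[WindowDiversity] = []

    def flush():
        if not run:
            return
        start, end = run[0].start, run[-1].end
        mean_pi = float(np.mean([w.pi for w in run]))
        intervals.append(
            HotspotInterval(start, end, mean_pi, _interval_name(start, end, annotations))
        )

    for w in windows:
        if w.hotspot:
            if run and w.start <= run[-1].end:
                run.append(w)
            else:
                flush()
                run = [w]
        else:
            flush()
            run = []
    flush()
    return list(windows), intervals


def _interval_name(start: int, end: int, annotations) -> str:
    if not annotations:
        return f"{start + 1}-{end}"
    overlapping = [a for a in annotations if a[0] < end and start < a[1]]
    if overlapping:
        names = sorted({a[2] for a in overlapping})
        return "-".join(names)
    before = [a for a in annotations if a[1] <= start]
    after = [a for a in annotations if a[0] >= end]
    left = max(before, key=lambda a: a[1])[2] if before else "start"
    right = min(after, key=lambda a: a[0])[2] if after else "end"
    return f"{left}-{right}"


# ---------------------------------------------------------------------------
# SNV / indel calling
# ---------------------------------------------------------------------------


def call_variants(
    alignment: AlignmentMatrix, reference_accession: str, bin_size: int = 100
) -> VariantTable:
    """SNVs and indel events of every non-reference row against the reference.

    An SNV is a column where both rows carry (unambiguous) bases that differ.
    An indel event is a maximal run of gap columns present in exactly one of
    the two rows — one event per run regardless of length, assigned to the bin
    of its first column. Counts are aggregated per 100 bp bin (configurable)
    and per row.
    """
    if reference_accession not in alignment.accessions:
        raise KeyError(f"reference accession {reference_accession!r} not in alignment")
    ref = alignment.row(reference_accession)
    n_cols = alignment.length
    n_bins = (n_cols + bin_size - 1) // bin_size
    snv_bins = np.zeros(n_bins, dtype=int)
    indel_bins = np.zeros(n_bins, dtype=int)
    per_row = []
    ref_base = np.isin(ref, _ACGT)
    ref_gap = ref == _GAP
    for acc in alignment.accessions:
        if acc == reference_accession:
            continue
        row = alignment.row(acc)
        row_base = np.isin(row, _ACGT)
        snv_cols = np.flatnonzero(ref_base & row_base & (ref != row))
        np.add.at(snv_bins, snv_cols // bin_size, 1)
        # indel runs: gap in exactly one of the two rows, split by which row
        row_gap = row == _GAP
        n_indels = 0
        for gap_mask in (ref_gap & ~row_gap, row_gap & ~ref_gap):
            idx = np.flatnonzero(gap_mask)
            if idx.size:
                run_starts = idx[np.concatenate(([True], np.diff(idx) > 1))]
                np.add.at(indel_bins, run_starts // bin_size, 1)
                n_indels += len(run_starts)
        per_row.append({"accession": acc, "snv": int(snv_cols.size), "indel": n_indels})
    bins = pd.DataFrame(
        {
            "bin_start": np.arange(n_bins) * bin_size,
            "snv": snv_bins,
            "indel": indel_bins,
        }
    )
    return VariantTable(reference_accession, bin_size, bins, pd.DataFrame(per_row))


# ---------------------------------------------------------------------------
# genetic distances
# ---------------------------------------------------------------------------


def _pair_distance(xa: np.ndarray, xb: np.ndarray, model: str) -> float:
    good = np.isin(xa, _ACGT) & np.isin(xb, _ACGT)
    n = int(good.sum())
    if n == 0:
        return math.nan
    diff_mask = (xa != xb) & good
    n_diff = int(diff_mask.sum())
    if model == "p":
        return n_diff / n
    # K2P: split differences into transitions (P) and transversions (Q)
    pairs = zip(xa[diff_mask].tolist(), xb[diff_mask].tolist())
    ts = sum(1 for ab in pairs if ab in _TRANSITIONS)
    tv = n_diff - ts
    P, Q = ts / n, tv / n
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0 or arg2 <= 0:
        return math.nan
    return -0.5 * math.log(arg1 * math.sqrt(arg2))


def genetic_distance(alignment: AlignmentMatrix, model: str = "K2P") -> DistanceMatrix:
    """Pairwise distance matrix (p or K2P) with pairwise deletion.

    K2P: d = −½ ln((1 − 2P − Q)·sqrt(1 − 2Q)) with P/Q the transition and
    transversion fractions; a domain violation yields NaN for that pair.
    """
    if model not in ("p", "K2P"):
        raise ValueError(f"unknown model {model!r}")
    k = alignment.n_rows
    vals = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        d = _pair_distance(alignment.matrix[i], alignment.matrix[j], model)
        vals[i, j] = vals[j, i] = d
    return DistanceMatrix(list(alignment.accessions), vals, model)


# ---------------------------------------------------------------------------
# tier partition export
# ---------------------------------------------------------------------------


def export_tier_fastas(
    gene_alignments: dict[str, AlignmentMatrix],
    gene_pi: dict[str, float],
    out_dir: str | Path,
    high: float = 0.02,
    low: float = 0.01,
) -> dict[str, Path]:
    """Concatenate gene alignments into high/medium/low-π FASTA files.

    Genes are binned by their overall π using the same tier rule as
    :func:`classify_variability`; each tier file holds the concatenation of
    its member alignments (rows matched by accession).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tiers: dict[str, list[str]] = {"high": [], "medium": [], "low": []}
    for gene, pi in gene_pi.items():
        if math.isnan(pi):
            continue
        tier = "high" if pi > high else ("medium" if pi >= low else "low")
        tiers[tier].append(gene)
    paths: dict[str, Path] = {}
    for tier, genes in tiers.items():
        if not genes:
            continue
        accs: list[str] | None = None
        for g in genes:
            rows = gene_alignments[g].accessions
            accs = rows if accs is None else [a for a in accs if a in rows]
        if not accs:
            continue
        concat = {a: [] for a in accs}
        for g in sorted(genes):
            aln = gene_alignments[g]
            for a in accs:
                concat[a].append(aln.row(a).tobytes().decode("ascii"))
        path = out_dir / f"pi_tier_{tier}.fasta"
        with open(path, "w") as fh:
            for a in accs:
                fh.write(f">{a}\n{''.join(concat[a])}\n")
        paths[tier] = path
    return paths


def windows_table(windows: Iterable[WindowDiversity]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start": w.start + 1,
                "end": w.end,
                "pi": w.pi,
                "n_sites": w.n_sites,
                "region": w.region or "",
                "var_class": w.var_class or "",
                "hotspot": int(w.hotspot),
            }
            for w in windows
        ]
    )
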