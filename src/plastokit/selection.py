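"""Nei–Gojobori (NG86) Ka/Ks estimation and selection classification.

The NG86 counting method partitions each codon's three positions into
synonymous and nonsynonymous site fractions (mutations to stop codons are
excluded from the possible-change count), tallies observed differences by
equal-weight averaging over all minimal mutational pathways between the two
codons (pathways through stop codons excluded), and applies the Jukes–Cantor
multiple-hit correction d = −¾·ln(1 − 4p/3) to the proportions pS and pN.
ω = Ka/Ks classifies genes: ω > 1 positive, ω < 1 purifying, ω ≈ 1 neutral;
ω is undefined when Ks is zero or incalculable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._genetics import BASES, CODON_TO_AA, SENSE_CODONS, STOP_CODONS, codons_of

logger = logging.getLogger(__name__)

_FUNCTION_PREFIXES = {
    "photosynthesis": ("psa", "psb", "pet", "atp", "ndh", "rbc"),
    "self-replication": ("rps", "rpl", "rpo", "inf", "mat"),
}


def gene_functional_class(gene: str, table: Mapping[str, str] | None = None) -> str:
    """Functional class of a plastid gene: photosynthesis, self-replication,
    or other. An explicit gene→class table overrides the prefix heuristic."""
    if table and gene in table:
        return table[gene]
    g = gene.lower()
    for cls, prefixes in _FUNCTION_PREFIXES.items():
        if g.startswith(prefixes):
            return cls
    return "other"


# ---------------------------------------------------------------------------
# per-codon site fractions (precomputed)
# ---------------------------------------------------------------------------


def _site_fractions() -> dict[str, float]:
    """Synonymous site count per sense codon (out of 3), NG86 definition."""
    out: dict[str, float] = {}
    for codon in SENSE_CODONS:
        aa = CODON_TO_AA[codon]
        s = 0.0
        for pos in range(3):
            syn = 0
            possible = 0
            for b in BASES:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1 :]
                if mut in STOP_CODONS:
                    continue  # mutations to stops are not counted
                possible += 1
                if CODON_TO_AA[mut] == aa:
                    syn += 1
            s += syn / possible if possible else 0.0
        out[codon] = s
    return out


_SYN_SITES = _site_fractions()


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair: equal-weight average over all minimal
    mutational pathways; pathways passing through a stop codon are excluded
    (unless every pathway does, in which case all are used)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0
        via_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != c2:
                via_stop = True
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((via_stop, sd, nd))
    valid = [(sd, nd) for via, sd, nd in paths if not via]
    if not valid:
        valid = [(sd, nd) for _, sd, nd in paths]
    sd = sum(s for s, _ in valid) / len(valid)
    nd = sum(n for _, n in valid) / len(valid)
    return sd, nd


_USABLE = frozenset(SENSE_CODONS)


def _usable_codon_pairs(seq1: str, seq2: str) -> list[tuple[str, str]]:
    c1, c2 = codons_of(seq1.upper()), codons_of(seq2.upper())
    if len(c1) != len(c2):
        raise ValueError(f"sequences differ in codon length: {len(c1)} vs {len(c2)}")
    return [
        (a, b) for a, b in zip(c1, c2) if a in _USABLE and b in _USABLE
    ]


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_pair(seq1: str, seq2: str) -> dict[str, float]:
    """NG86 Ka/Ks for a pair of aligned coding sequences.

    Codon columns containing gaps, ambiguous bases, or stop codons in either
    sequence are deleted pairwise. Returns S, N (site counts averaged over
    the two sequences), Sd, Nd (pathway-averaged differences), and the
    Jukes–Cantor corrected ka and ks (NaN when p ≥ 3/4 or no sites).
    """
    pairs = _usable_codon_pairs(seq1, seq2)
    if not pairs:
        raise ValueError("no usable codon pairs after filtering")
    s1 = sum(_SYN_SITES[a] for a, _ in pairs)
    s2 = sum(_SYN_SITES[b] for _, b in pairs)
    S = (s1 + s2) / 2.0
    N = 3.0 * len(pairs) - S
    Sd = Nd = 0.0
    for a, b in pairs:
        sd, nd = _pathway_counts(a, b)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else math.nan
    pn = Nd / N if N > 0 else math.nan
    return {
        "S": S,
        "N": N,
        "Sd": Sd,
        "Nd": Nd,
        "ks": _jukes_cantor(ps) if not math.isnan(ps) else math.nan,
        "ka": _jukes_cantor(pn) if not math.isnan(pn) else math.nan,
    }


# ---------------------------------------------------------------------------
# group aggregation
# ---------------------------------------------------------------------------


@dataclass
class CodonAlignment:
    """One gene's aligned coding sequences keyed by accession."""

    gene: str
    rows: dict[str, str]

    def __post_init__(self):
        lens = {len(s) for s in self.rows.values()}
        if len(lens) > 1:
            raise ValueError(f"{self.gene}: rows of unequal length")
        if lens and next(iter(lens)) % 3 != 0:
            raise ValueError(f"{self.gene}: alignment length not divisible by 3")


@dataclass
class KaKsRecord:
    gene: str
    group: str
    level: str  # pair | tribe | clade | function
    ka: float
    ks: float
    omega: float
    selection_class: str
    n_pairs: int = 1


def classify_selection(ka: float, ks: float, eps: float = 1e-9) -> str:
    """positive (ω > 1), purifying (ω < 1), neutral (|ω − 1| ≤ eps), or
    undefined (Ks zero or incalculable)."""
    if math.isnan(ks) or ks <= 0 or math.isnan(ka):
        return "undefined"
    omega = ka / ks
    if abs(omega - 1.0) <= eps:
        return "neutral"
    return "positive" if omega > 1.0 else "purifying"


def _mean_record(gene: str, group: str, level: str, pair_vals: list[dict]) -> KaKsRecord | None:
    kas = [v["ka"] for v in pair_vals if not math.isnan(v["ka"])]
    kss = [v["ks"] for v in pair_vals if not math.isnan(v["ks"])]
    if not kas or not kss:
        return None
    ka, ks = float(np.mean(kas)), float(np.mean(kss))
    omega = ka / ks if ks > 0 else math.nan
    return KaKsRecord(
        gene, group, level, ka, ks, omega, classify_selection(ka, ks), len(pair_vals)
    )


def group_kaks(
    alignments: Iterable[CodonAlignment],
    grouping: Mapping[str, Mapping[str, str]],
    outgroup_accession: str,
    gene_classes: Mapping[str, str] | None = None,
) -> list[KaKsRecord]:
    """Per-gene Ka/Ks of every accession against the outgroup, aggregated by
    tribe, clade, and functional class.

    Each member-vs-outgroup pair yields one ``pair``-level record; group
    records carry the arithmetic mean of the member pair estimates. Genes
    missing the outgroup, or groups with no members in an alignment, are
    skipped with a log entry.
    """
    records: list[KaKsRecord] = []
    by_function: dict[str, list[dict]] = {}
    for aln in alignments:
        if outgroup_accession not in aln.rows:
            logger.warning("%s: outgroup %s absent, gene skipped", aln.gene, outgroup_accession)
            continue
        out_seq = aln.rows[outgroup_accession]
        pair_vals: dict[str, dict] = {}
        for acc, seq in aln.rows.items():
            if acc == outgroup_accession:
                continue
            try:
                res = ng86_pair(seq, out_seq)
            except ValueError as exc:
                logger.warning("%s:%s vs outgroup: %s", aln.gene, acc, exc)
                continue
            pair_vals[acc] = res
            omega = res["ka"] / res["ks"] if res["ks"] and not math.isnan(res["ks"]) else math.nan
            records.append(
                KaKsRecord(
                    aln.gene, acc, "pair", res["ka"], res["ks"], omega,
                    classify_selection(res["ka"], res["ks"]),
                )
            )
        for level in ("tribe", "clade"):
            groups: dict[str, list[dict]] = {}
            for acc, vals in pair_vals.items():
                label = grouping.get(acc, {}).get(level)
                if label:
                    groups.setdefault(label, []).append(vals)
            for label, vals in groups.items():
                rec = _mean_record(aln.gene, label, level, vals)
                if rec is not None:
                    records.append(rec)
                else:
                    logger.info("%s %s=%s: no defined pairs", aln.gene, level, label)
        fclass = gene_functional_class(aln.gene, gene_classes)
        by_function.setdefault(fclass, []).extend(pair_vals.values())
    for fclass, vals in by_function.items():
        rec = _mean_record("(all)", fclass, "function", vals)
        if rec is not None:
            records.append(rec)
    return records


def ks_summary(
    records: Sequence[KaKsRecord], by_group: bool = True, bin_width: float = 0.005
) -> pd.DataFrame:
    """Ks distribution per group: fixed-width histogram bins plus mean and
    median; undefined records are excluded but counted."""
    defined = [r for r in records if not math.isnan(r.ks)]
    if not defined:
        raise ValueError("no defined Ks values")
    rows = []
    keys = sorted({r.group for r in defined}) if by_group else ["(all)"]
    for key in keys:
        sub = [r.ks for r in defined if (not by_group or r.group == key)]
        n_undef = sum(
            1 for r in records if (not by_group or r.group == key) and math.isnan(r.ks)
        )
        if not sub:
            logger.info("group %s: no defined Ks, skipped", key)
            continue
        arr = np.asarray(sub)
        n_bins = int(arr.max() / bin_width) + 1
        hist, edges = np.histogram(arr, bins=n_bins, range=(0, n_bins * bin_width))
        for b, c in enumerate(hist):
            if c:
                rows.append(
                    {
                        "group": key,
                        "bin_start": edges[b],
                        "count": int(c),
                        "mean_ks": arr.mean(),
                        "median_ks": float(np.median(arr)),
                        "n_undefined": n_undef,
                    }
                )
    return pd.DataFrame(rows)


def selection_heatmap(records: Sequence[KaKsRecord], level: str = "tribe") -> pd.DataFrame:
    """Gene × group ω matrix (the per-tribe selection landscape)."""
    sub = [r for r in records if r.level == level]
    if not sub:
        return pd.DataFrame()
    df = pd.DataFrame([{"gene": r.gene, "group": r.group, "omega": r.omega} for r in sub])
    return df.pivot_table(index="gene", columns="group", values="omega", aggfunc="mean")
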