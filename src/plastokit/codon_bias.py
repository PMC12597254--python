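"""Codon-usage-bias statistics for plastid protein-coding genes.

Implements the classical index set used in plastome comparative studies:

* **RSCU** — relative synonymous codon usage, the observed count of a codon
  divided by the mean count over its synonymous family (1 = no bias).
* **ENC** (Nc) — Wright's effective number of codons, from 20 (one codon per
  amino acid, maximal bias) to 61 (uniform usage of all synonymous codons),
  via family homozygosities averaged within degeneracy classes.
* **Expected ENC** — Wright's null curve as a function of GC3s:
  ``Nc = 2 + s + 29 / (s**2 + (1-s)**2)``; genes below the curve by more than
  a threshold fraction are candidates for selection on codon usage.
* **CAI / CBI / Fop** — reference-set-dependent adaptation indices.
* **PR2** — parity-rule-2 coordinates ``A3/(A3+T3)`` vs ``G3/(G3+C3)`` at the
  third positions of four-fold degenerate families.
* **ΔRSCU optimal codons** — codons over-used in putatively highly expressed
  (lowest-ENC) genes relative to the least expressed (highest-ENC) ones.

The plastid genetic code (translation table 11) is used throughout; stop
codons are excluded from ENC/CAI/CBI/Fop but can be included in RSCU reports.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._genetics import (
    AA_TO_CODONS,
    ALL_CODONS,
    CODON_TO_AA,
    DEGENERACY_CLASSES,
    FOURFOLD_AAS,
    SINGLE_CODON_AAS,
    STOP_CODONS,
    codons_of,
)
from .genome_io import GenomeRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


@dataclass
class CodonCounts:
    """Codon counts for one gene (or a pooled gene set)."""

    gene: str
    accession: str
    counts: dict[str, int]
    has_internal_stop: bool = False

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    @property
    def aa_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for codon, c in self.counts.items():
            aa = CODON_TO_AA[codon]
            out[aa] = out.get(aa, 0) + c
        return out

    @classmethod
    def from_sequence(cls, gene: str, accession: str, seq: str) -> "CodonCounts":
        counts: dict[str, int] = {}
        cods = codons_of(seq.upper())
        internal_stop = False
        for idx, codon in enumerate(cods):
            if any(b not in "ACGT" for b in codon):
                continue  # ambiguous codon: uncounted
            if codon in STOP_CODONS and idx < len(cods) - 1:
                internal_stop = True
            counts[codon] = counts.get(codon, 0) + 1
        return cls(gene, accession, counts, internal_stop)


def pooled_counts(items: Iterable[CodonCounts], label: str = "pooled") -> CodonCounts:
    total: dict[str, int] = {}
    accs = set()
    for it in items:
        accs.add(it.accession)
        for codon, c in it.counts.items():
            total[codon] = total.get(codon, 0) + c
    return CodonCounts(label, "+".join(sorted(accs)) if accs else "", total)


def extract_cds_set(
    records: Iterable[GenomeRecord],
    min_len: int = 300,
    require_frame: bool = True,
    dedup: bool = True,
) -> list[CodonCounts]:
    """Spliced CDS codon counts after the standard filters.

    Genes shorter than ``min_len`` nucleotides or (optionally) not divisible
    by three are dropped with a logged reason; IR-duplicated genes are kept
    once (copy A). The terminal stop codon is retained in the counts; stops
    are excluded later by the individual statistics.
    """
    out: list[CodonCounts] = []
    for rec in records:
        for g in rec.genes:
            if g.kind != "CDS":
                continue
            if dedup and g.copy_tag not in (None, "A"):
                continue
            seq = rec.gene_sequence(g)
            if len(seq) < min_len:
                logger.info("%s:%s excluded: %d bp < %d", rec.accession, g.name, len(seq), min_len)
                continue
            if require_frame and len(seq) % 3 != 0:
                logger.info("%s:%s excluded: length %d not divisible by 3", rec.accession, g.name, len(seq))
                continue
            cc = CodonCounts.from_sequence(g.name, rec.accession, seq)
            if cc.has_internal_stop:
                logger.info("%s:%s carries an internal stop codon", rec.accession, g.name)
            out.append(cc)
    return out


# ---------------------------------------------------------------------------
# RSCU
# ---------------------------------------------------------------------------


def rscu(counts: CodonCounts, include_stops: bool = False) -> dict[str, float]:
    """RSCU(c) = count(c) / mean count over c's synonymous family.

    An entirely unused family yields zeros; single-codon families (Met, Trp)
    have RSCU 1 when used. Stops form their own three-codon family when
    ``include_stops`` is set (they are reported separately by convention).
    """
    if counts.n_codons == 0:
        raise ValueError("no codons counted")
    out: dict[str, float] = {}
    for aa, family in AA_TO_CODONS.items():
        if aa == "*" and not include_stops:
            continue
        total = sum(counts.counts.get(c, 0) for c in family)
        if total == 0:
            for c in family:
                out[c] = 0.0
            continue
        mean = total / len(family)
        for c in family:
            out[c] = counts.counts.get(c, 0) / mean
    return out


# ---------------------------------------------------------------------------
# ENC
# ---------------------------------------------------------------------------


def _family_homozygosity(counts: CodonCounts, family: Sequence[str]) -> float | None:
    """Wright's F-hat = (n*sum(p^2) - 1)/(n - 1); None when n < 2."""
    ns = [counts.counts.get(c, 0) for c in family]
    n = sum(ns)
    if n < 2:
        return None
    s = sum((x / n) ** 2 for x in ns)
    return (n * s - 1.0) / (n - 1.0)


def enc(counts: CodonCounts) -> float:
    """Wright's effective number of codons, clamped to [20, 61].

    Degeneracy-class means of the family homozygosities enter as
    ``Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6``. Families with fewer than two
    codons observed, or zero homozygosity, are skipped; a missing three-fold
    class (Ile absent) is imputed as the average of the two- and four-fold
    means, Wright's rule. Stop codons are excluded. Returns NaN when no
    family is scorable.
    """
    class_means: dict[int, float] = {}
    for k, aas in DEGENERACY_CLASSES.items():
        fs = []
        for aa in aas:
            f = _family_homozygosity(counts, AA_TO_CODONS[aa])
            if f is not None and f > 0:
                fs.append(f)
        if fs:
            class_means[k] = float(np.mean(fs))
    if 3 not in class_means and 2 in class_means and 4 in class_means:
        class_means[3] = (class_means[2] + class_means[4]) / 2.0
    n_families = {2: 9, 3: 1, 4: 5, 6: 3}
    missing = [k for k in n_families if k not in class_means]
    if len(missing) == len(n_families):
        return math.nan
    if missing:
        # generic fallback: impute remaining absent classes with the mean of
        # the observed class means
        fallback = float(np.mean(list(class_means.values())))
        for k in missing:
            class_means[k] = fallback
    nc = 2.0 + sum(n_families[k] / class_means[k] for k in n_families)
    return float(min(61.0, max(20.0, nc)))


def expected_enc(gc3s: float) -> float:
    """Wright's null ENC as a function of synonymous third-position GC."""
    s = float(gc3s)
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def enc_deviation(enc_observed: float, gc3s: float, threshold: float = 0.15) -> dict:
    """Relative deviation (expected − observed)/expected and its class.

    ``selection_high`` (observed far below the curve) and ``selection_low``
    flag genes whose codon usage departs from the mutation-only expectation
    by more than ``threshold``; everything else is classed ``mutation``.
    """
    exp = expected_enc(gc3s)
    value = (exp - enc_observed) / exp
    if value > threshold:
        cls = "selection_high"
    elif value < -threshold:
        cls = "selection_low"
    else:
        cls = "mutation"
    return {"value": value, "class": cls, "expected": exp}


# ---------------------------------------------------------------------------
# third-position composition and PR2
# ---------------------------------------------------------------------------


def third_position_composition(counts: CodonCounts) -> dict[str, float]:
    """Base composition at synonymous third positions, plus PR2 coordinates.

    Single-codon families and stops are excluded throughout; the PR2
    coordinates use four-fold degenerate families only. A zero denominator
    yields NaN.
    """
    tallies = {b: 0 for b in "ACGT"}
    four = {b: 0 for b in "ACGT"}
    n_syn = 0
    for codon, c in counts.counts.items():
        aa = CODON_TO_AA[codon]
        if aa == "*" or aa in SINGLE_CODON_AAS:
            continue
        tallies[codon[2]] += c
        n_syn += c
        if aa in FOURFOLD_AAS:
            four[codon[2]] += c
    if n_syn == 0:
        nan = math.nan
        return {k: nan for k in ("t3s", "c3s", "a3s", "g3s", "gc3s", "pr2_x", "pr2_y")}
    at4 = four["A"] + four["T"]
    gc4 = four["G"] + four["C"]
    return {
        "t3s": tallies["T"] / n_syn,
        "c3s": tallies["C"] / n_syn,
        "a3s": tallies["A"] / n_syn,
        "g3s": tallies["G"] / n_syn,
        "gc3s": (tallies["G"] + tallies["C"]) / n_syn,
        "pr2_x": four["A"] / at4 if at4 else math.nan,
        "pr2_y": four["G"] / gc4 if gc4 else math.nan,
    }


# ---------------------------------------------------------------------------
# CAI / CBI / Fop
# ---------------------------------------------------------------------------


@dataclass
class ReferenceWeights:
    """Per-codon relative adaptiveness w ∈ (0, 1] plus the optimal-codon set."""

    w: dict[str, float]
    optimal: frozenset[str]

    @classmethod
    def from_counts(cls, reference: CodonCounts, floor: float = 0.01) -> "ReferenceWeights":
        """Derive weights from a reference gene set: within each family
        w = count / max count; zero counts in a used family get ``floor``;
        entirely unused families are uninformative (w = 1)."""
        w: dict[str, float] = {}
        optimal: set[str] = set()
        for aa, family in AA_TO_CODONS.items():
            if aa == "*":
                continue
            ns = {c: reference.counts.get(c, 0) for c in family}
            peak = max(ns.values())
            if peak == 0:
                for c in family:
                    w[c] = 1.0
                continue
            for c in family:
                w[c] = max(ns[c] / peak, floor)
            if len(family) > 1:
                optimal.update(c for c in family if ns[c] == peak)
        return cls(w, frozenset(optimal))


def cai_cbi_fop(counts: CodonCounts, reference_weights: ReferenceWeights) -> dict[str, float]:
    """Codon adaptation index, codon bias index, and frequency of optimal codons.

    CAI is the geometric mean of the reference weights over the gene's codons
    (single-codon families and stops excluded). Fop is the fraction of codons
    drawn from the optimal set. CBI contrasts the optimal-codon count with its
    expectation under uniform family usage: (Nopt − Nrand)/(Ntot − Nrand).
    """
    log_sum = 0.0
    n_cai = 0
    n_tot = 0
    n_opt = 0
    n_rand = 0.0
    for aa, family in AA_TO_CODONS.items():
        if aa == "*" or aa in SINGLE_CODON_AAS:
            continue
        fam_opt = [c for c in family if c in reference_weights.optimal]
        fam_total = 0
        for c in family:
            k = counts.counts.get(c, 0)
            if k == 0:
                continue
            if c not in reference_weights.w:
                raise KeyError(f"no reference weight for used codon {c}")
            log_sum += k * math.log(reference_weights.w[c])
            n_cai += k
            fam_total += k
            if c in reference_weights.optimal:
                n_opt += k
        n_tot += fam_total
        n_rand += fam_total * (len(fam_opt) / len(family))
    cai = math.exp(log_sum / n_cai) if n_cai else math.nan
    fop = n_opt / n_tot if n_tot else math.nan
    cbi = (n_opt - n_rand) / (n_tot - n_rand) if n_tot - n_rand else math.nan
    return {"cai": cai, "cbi": cbi, "fop": fop}


# ---------------------------------------------------------------------------
# per-gene index set
# ---------------------------------------------------------------------------


@dataclass
class CodonIndexSet:
    gene: str
    accession: str
    n_codons: int
    rscu: dict[str, float]
    enc: float
    indices: dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "accession": self.accession,
            "gene": self.gene,
            "n_codons": self.n_codons,
            "enc": self.enc,
        }
        row.update(self.indices)
        return row


def compute_indices(
    counts: CodonCounts, weights: ReferenceWeights | None = None
) -> CodonIndexSet:
    """Full index set for one gene: RSCU, ENC, compositions, and (when a
    reference is given) CAI/CBI/Fop."""
    idx = third_position_composition(counts)
    e = enc(counts)
    if not (math.isnan(idx["gc3s"]) or math.isnan(e)):
        dev = enc_deviation(e, idx["gc3s"])
        idx["enc_expected"] = dev["expected"]
        idx["enc_deviation"] = dev["value"]
        idx["enc_class"] = dev["class"]
    if weights is not None:
        idx.update(cai_cbi_fop(counts, weights))
    return CodonIndexSet(
        gene=counts.gene,
        accession=counts.accession,
        n_codons=counts.n_codons,
        rscu=rscu(counts),
        enc=e,
        indices=idx,
    )


# ---------------------------------------------------------------------------
# optimal codons
# ---------------------------------------------------------------------------


@dataclass
class OptimalCodonTable:
    table: pd.DataFrame  # codon, aa, rscu_high, rscu_low, delta_rscu, optimal
    high_set: list[str]
    low_set: list[str]

    @property
    def optimal(self) -> list[str]:
        return self.table.loc[self.table["optimal"], "codon"].tolist()


def optimal_codons(
    gene_table: Sequence[tuple[CodonCounts, float]],
    top_frac: float = 0.05,
    delta_min: float = 0.08,
    rule: str = "standard",
    include_stops: bool = False,
) -> OptimalCodonTable:
    """ΔRSCU screen for optimal codons using ENC as an expression proxy.

    Genes are ranked by ENC ascending; the lowest ⌈``top_frac``⌉ fraction is
    the putative high-expression set and the highest the low-expression set.
    RSCU is computed on the pooled counts of each set. Under the ``standard``
    rule a codon is optimal iff ΔRSCU ≥ ``delta_min`` and RSCU_high > 1; the
    ``literal`` rule instead requires ΔRSCU ≥ ``delta_min`` and ΔRSCU > 1.
    """
    usable = [(cc, e) for cc, e in gene_table if not math.isnan(e)]
    n = len(usable)
    k = math.ceil(top_frac * n)
    if n < 20 or k == 0 or 2 * k > n:
        raise ValueError(f"need at least 20 ENC-ranked genes, got {n}")
    ranked = sorted(usable, key=lambda t: (t[1], t[0].gene))

    def extend_ties(idx_last: int, direction: int) -> int:
        # entries identical in (ENC, name) to the boundary entry are taken
        # together, so duplicating the whole table cannot change the screen
        key = (ranked[idx_last][1], ranked[idx_last][0].gene)
        j = idx_last + direction
        while 0 <= j < n and (ranked[j][1], ranked[j][0].gene) == key:
            j += direction
        return j - direction

    hi_end = extend_ties(k - 1, +1)
    lo_start = extend_ties(n - k, -1)
    high = [cc for cc, _ in ranked[: hi_end + 1]]
    low = [cc for cc, _ in ranked[lo_start:]]
    r_high = rscu(pooled_counts(high, "high"), include_stops=include_stops)
    r_low = rscu(pooled_counts(low, "low"), include_stops=include_stops)
    rows = []
    for codon in ALL_CODONS:
        if codon not in r_high:
            continue
        rh, rl = r_high[codon], r_low.get(codon, 0.0)
        delta = rh - rl
        if rule == "standard":
            opt = delta >= delta_min and rh > 1.0
        elif rule == "literal":
            opt = delta >= delta_min and delta > 1.0
        else:
            raise ValueError(f"unknown rule {rule!r}")
        rows.append(
            {
                "codon": codon,
                "aa": CODON_TO_AA[codon],
                "rscu_high": rh,
                "rscu_low": rl,
                "delta_rscu": delta,
                "optimal": bool(opt),
            }
        )
    return OptimalCodonTable(
        pd.DataFrame(rows),
        high_set=[cc.gene for cc in high],
        low_set=[cc.gene for cc in low],
    )


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

_BANDS = ((0.8, "high"), (0.5, "moderate"), (0.3, "low-mid"), (0.0, "low"))


def index_correlation(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix of per-gene indices plus |r| band labels.

    Bands: low (<0.3), low-mid (0.3–0.5), moderate (0.5–0.8), high (≥0.8).
    Zero-variance columns yield NaN / 'undefined'.
    """
    num = table.select_dtypes(include=[np.number])
    if len(num) < 3:
        raise ValueError("need at least 3 genes")
    corr = num.corr(method="pearson", min_periods=3)
    const = num.std(ddof=0) == 0
    corr.loc[const, :] = np.nan
    corr.loc[:, const] = np.nan

    def band(r: float) -> str:
        if pd.isna(r):
            return "undefined"
        a = abs(r)
        for cut, name in _BANDS:
            if a >= cut:
                return name
        return "low"

    bands = corr.map(band) if hasattr(corr, "map") else corr.applymap(band)
    return corr, bands
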