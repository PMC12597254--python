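"""Synthetic annotated plastomes with a machine-readable truth manifest.

Every analysis stage in the package can be exercised without downloading
data: this module emits quadripartite genomes (LSC + IRb + SSC + IRa with
IRa the exact reverse complement of IRb) with planted genes, junction
spans, microsatellites, dispersed and tandem repeats; star-phylogeny
diverged genome sets with region-specific substitution rates; and
codon-evolved gene pairs with a chosen dN/dS.

Default dimensions follow typical Moraceae-like plastomes: ~160 kb total,
LSC ≈ 89 kb, IR ≈ 25.7 kb, SSC ≈ 19.5 kb, with GC highest in the IR and
lowest in the SSC. Background sequence is i.i.d. at the region GC target and
is *repeat-sanitized*: chance microsatellites or tandem arrays above the
detection floors are broken by point substitutions, so that planted features
are exactly the detectable ones. All randomness flows from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._genetics import SENSE_CODONS, STOP_CODONS, CODON_TO_AA, minimal_period, revcomp, complement
from .genome_io import GeneAnnotation, GenomeRecord, RegionPartition
from .diversity import AlignmentMatrix
from .repeat_scan import DEFAULT_SSR_THRESHOLDS, find_ssrs, find_tandem


class PlanError(ValueError):
    """Infeasible simulation plan (e.g., colliding planted features)."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class GenePlan:
    name: str
    region: str  # lsc | irb | ssc
    length: int  # nucleotides (multiple of 3 for CDS)
    strand: str = "+"
    kind: str = "CDS"
    junction: tuple[str, int] | None = None  # (boundary, spanning bp)


@dataclass
class SSRPlan:
    motif: str
    copies: int
    region: str = "lsc"


@dataclass
class DispersedPlan:
    kind: str  # F | P | R | C
    length: int
    region1: str = "lsc"
    region2: str = "lsc"


@dataclass
class TandemPlan:
    unit_len: int
    copies: int
    region: str = "lsc"
    substitutions: int = 0


@dataclass
class DivergenceConfig:
    rates: dict = field(default_factory=lambda: {"lsc": 0.010, "ssc": 0.015, "ir": 0.002})
    indel_rate: float = 0.0005
    indel_mean_len: float = 3.0


def default_gene_plan() -> list[GenePlan]:
    return [
        GenePlan("psbA", "lsc", 1062, "-"),
        GenePlan("matK", "lsc", 1530, "-"),
        GenePlan("atpA", "lsc", 1524, "-"),
        GenePlan("rpoB", "lsc", 3213, "-"),
        GenePlan("psbD", "lsc", 1062, "+"),
        GenePlan("rbcL", "lsc", 1428, "+"),
        GenePlan("clpP", "lsc", 591, "-"),
        GenePlan("rps2", "lsc", 711, "-"),
        GenePlan("rps4", "lsc", 606, "-"),
        GenePlan("petA", "lsc", 963, "+"),
        GenePlan("rps19", "lsc", 279, "-", junction=("JLB", 45)),
        GenePlan("rpl2", "irb", 825, "-"),
        # ndhF pokes 60 bp into IRb; its spanning length at JSB (bases in the
        # downstream region, the SSC) is therefore length - 60
        GenePlan("ndhF", "ssc", 2235, "-", junction=("JSB", 2175)),
        GenePlan("rpl32", "ssc", 171, "+"),
        GenePlan("ccsA", "ssc", 966, "+"),
        GenePlan("ndhD", "ssc", 1503, "-"),
        GenePlan("rps15", "ssc", 273, "-"),
        GenePlan("ycf1", "ssc", 5301, "+", junction=("JSA", 1200)),
        GenePlan("trnN-GUU", "ssc", 72, "-", kind="tRNA"),
    ]


def default_ssr_plan() -> list[SSRPlan]:
    return [
        SSRPlan("A", 12, "lsc"),
        SSRPlan("T", 10, "lsc"),
        SSRPlan("AT", 6, "lsc"),
        SSRPlan("TA", 5, "ssc"),
        SSRPlan("AAG", 4, "lsc"),
        SSRPlan("AATT", 3, "lsc"),
        SSRPlan("AATAT", 3, "ssc"),
        SSRPlan("AATCAT", 3, "lsc"),
    ]


def default_dispersed_plan() -> list[DispersedPlan]:
    return [
        DispersedPlan("F", 40, "lsc", "lsc"),
        DispersedPlan("P", 35, "lsc", "ssc"),
        DispersedPlan("R", 32, "lsc", "lsc"),
        DispersedPlan("C", 31, "ssc", "ssc"),
    ]


def default_tandem_plan() -> list[TandemPlan]:
    return [
        TandemPlan(12, 3, "lsc"),
        TandemPlan(15, 3, "ssc", substitutions=1),
        TandemPlan(8, 4, "lsc"),
    ]


@dataclass
class SimConfig:
    seed: int = 0
    region_lengths: dict = field(
        default_factory=lambda: {"lsc": 89000, "irb": 25700, "ssc": 19500}
    )
    region_gc: dict = field(
        default_factory=lambda: {"lsc": 0.33, "irb": 0.43, "ssc": 0.28}
    )
    gene_plan: list[GenePlan] = field(default_factory=default_gene_plan)
    ssr_plan: list[SSRPlan] = field(default_factory=default_ssr_plan)
    dispersed_plan: list[DispersedPlan] = field(default_factory=default_dispersed_plan)
    tandem_plan: list[TandemPlan] = field(default_factory=default_tandem_plan)
    divergence: DivergenceConfig = field(default_factory=DivergenceConfig)
    accession: str = "SIM000001"
    taxon: str = "Simulatus plastomae"

    def validate(self) -> None:
        for key in ("lsc", "irb", "ssc"):
            if self.region_lengths.get(key, 0) <= 0:
                raise PlanError(f"region length {key} must be positive")
        for r in self.divergence.rates.values():
            if not 0 <= r <= 0.5:
                raise PlanError(f"divergence rate {r} outside [0, 0.5]")
        for p in self.ssr_plan:
            if minimal_period(p.motif) != len(p.motif):
                raise PlanError(f"SSR motif {p.motif} is itself periodic")
            if p.copies < DEFAULT_SSR_THRESHOLDS.get(len(p.motif), 3):
                raise PlanError(f"SSR {p.motif}x{p.copies} below detection floor")

    def scaled(self, factor: float) -> "SimConfig":
        """A smaller copy of this config (same plans) for fast tests."""
        cfg = SimConfig(
            seed=self.seed,
            region_lengths={k: int(v * factor) for k, v in self.region_lengths.items()},
            region_gc=dict(self.region_gc),
            gene_plan=list(self.gene_plan),
            ssr_plan=list(self.ssr_plan),
            dispersed_plan=list(self.dispersed_plan),
            tandem_plan=list(self.tandem_plan),
            divergence=self.divergence,
            accession=self.accession,
            taxon=self.taxon,
        )
        return cfg


# ---------------------------------------------------------------------------
# plastome assembly
# ---------------------------------------------------------------------------


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=probs)


def _random_cds(rng: np.random.Generator, length: int) -> str:
    n_codons = length // 3
    body = rng.choice(len(SENSE_CODONS), size=max(n_codons - 2, 0))
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + "TAA"


def _clean_cds(rng: np.random.Generator, length: int, tries: int = 30) -> str:
    """A random CDS free of chance repeats above the detection floors, so
    that planted repeats are the only detectable ones."""
    for _ in range(tries):
        seq = _random_cds(rng, length)
        if not find_ssrs(seq) and not find_tandem(seq):
            return seq
    return seq  # exceedingly unlikely; caller logs leftovers as coincidences


class _Occupancy:
    """Non-overlapping interval bookkeeping over the physical buffer."""

    def __init__(self):
        self.intervals: list[tuple[int, int, str]] = []

    def claim(self, start: int, end: int, label: str) -> None:
        for s, e, lab in self.intervals:
            if start < e and s < end:
                raise PlanError(f"planted feature {label} [{start},{end}) collides with {lab} [{s},{e})")
        self.intervals.append((start, end, label))

    def is_free(self, start: int, end: int) -> bool:
        return all(end <= s or e <= start for s, e, _ in self.intervals)

    def covers(self, pos: int) -> bool:
        return any(s <= pos < e for s, e, _ in self.intervals)


def _place(rng: np.random.Generator, occ: _Occupancy, lo: int, hi: int, length: int,
           label: str, margin: int = 8, tries: int = 500) -> int:
    for _ in range(tries):
        start = int(rng.integers(lo, hi - length))
        if occ.is_free(start - margin, start + length + margin):
            occ.claim(start - margin, start + length + margin, label)
            return start
    raise PlanError(f"could not place {label} in [{lo},{hi}) without collision")


def simulate_plastome(config: SimConfig | None = None) -> tuple[GenomeRecord, dict]:
    """Emit an annotated quadripartite genome and its truth manifest.

    Deterministic for a fixed seed. Raises :class:`PlanError` for infeasible
    plans (colliding or unplaceable features).
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.region_lengths["lsc"]
    I = config.region_lengths["irb"]
    S = config.region_lengths["ssc"]
    n = L + 2 * I + S
    # physical buffer: LSC + IRb + SSC (IRa derived)
    buf = np.concatenate(
        [
            _random_bases(rng, L, config.region_gc["lsc"]),
            _random_bases(rng, I, config.region_gc["irb"]),
            _random_bases(rng, S, config.region_gc["ssc"]),
        ]
    )
    occ = _Occupancy()
    region_bounds = {"lsc": (0, L), "irb": (L, L + I), "ssc": (L + I, L + I + S)}
    boundary = {"JLB": L, "JSB": L + I, "JSA": L + I + S, "JLA": 0}
    manifest: dict = {
        "seed": config.seed,
        "length": n,
        "regions": {"LSC": [0, L], "IRb": [L, L + I], "SSC": [L + I, L + I + S], "IRa": [L + I + S, n]},
        "genes": [],
        "junction_spans": {},
        "ssrs": [],
        "dispersed": [],
        "tandem": [],
    }

    def write(start: int, seq: str, label: str, claim: bool = True) -> None:
        # a tail extending past the physical buffer falls in IRa, whose
        # content is derived from IRb at assembly time: such a tail inherits
        # the IR sequence (as real junction-spanning genes do) and is not
        # written
        end = start + len(seq)
        phys_end = L + I + S
        if claim:
            occ.claim(max(start - 2, 0), min(end + 2, phys_end), label)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        direct = min(end, phys_end) - start
        buf[start : start + direct] = arr[:direct]

    genes: list[GeneAnnotation] = []
    # junction-anchored genes claim fixed coordinates; plant them before any
    # randomly placed feature so placements cannot collide with them
    ordered = sorted(config.gene_plan, key=lambda g: g.junction is None)
    for gp in ordered:
        if gp.kind == "CDS" and gp.length % 3 != 0:
            raise PlanError(f"{gp.name}: CDS length {gp.length} not divisible by 3")
        seq = _clean_cds(rng, gp.length) if gp.kind == "CDS" else "".join(
            chr(b) for b in _random_bases(rng, gp.length, 0.5)
        )
        if gp.junction is not None:
            bname, span = gp.junction
            b = boundary[bname]
            if not 0 < span < gp.length:
                raise PlanError(f"{gp.name}: junction span {span} outside (0, {gp.length})")
            start = b - (gp.length - span)
            occ_claimed = False
            manifest["junction_spans"][bname] = {"gene": gp.name, "span": span}
        else:
            lo, hi = region_bounds[gp.region]
            start = _place(rng, occ, lo, hi, gp.length, gp.name)
            occ_claimed = True
        phys = revcomp(seq) if gp.strand == "-" else seq
        write(start, phys, gp.name, claim=not occ_claimed)
        genes.append(GeneAnnotation(gp.name, gp.kind, gp.strand, [(start, start + gp.length)]))
        manifest["genes"].append(
            {"name": gp.name, "kind": gp.kind, "strand": gp.strand, "start": start, "end": start + gp.length}
        )

    for sp in config.ssr_plan:
        p = len(sp.motif)
        span = p * sp.copies
        lo, hi = region_bounds[sp.region]
        start = _place(rng, occ, lo, hi, span, f"SSR:{sp.motif}", margin=max(8, p + 2))
        write(start, sp.motif * sp.copies, f"SSR:{sp.motif}", claim=False)
        # break periodic extension into the flanks
        left = start - 1
        if buf[left] == ord(sp.motif[p - 1]):
            buf[left] = ord(_other_base(chr(buf[left]), rng))
        right = start + span
        if buf[right] == ord(sp.motif[0]):
            buf[right] = ord(_other_base(chr(buf[right]), rng))
        manifest["ssrs"].append(
            {"motif": sp.motif, "copies": sp.copies, "start": start, "end": start + span, "region": sp.region}
        )

    for dp in config.dispersed_plan:
        block = "".join(chr(b) for b in _random_bases(rng, dp.length, 0.40))
        lo1, hi1 = region_bounds[dp.region1]
        lo2, hi2 = region_bounds[dp.region2]
        pos1 = _place(rng, occ, lo1, hi1, dp.length, f"DR:{dp.kind}")
        pos2 = _place(rng, occ, lo2, hi2, dp.length, f"DR:{dp.kind}")
        copy2 = {"F": block, "P": revcomp(block), "R": block[::-1], "C": complement(block)}[dp.kind]
        write(pos1, block, f"DR:{dp.kind}:1", claim=False)
        write(pos2, copy2, f"DR:{dp.kind}:2", claim=False)
        lo, hi = sorted((pos1, pos2))
        manifest["dispersed"].append(
            {"kind": dp.kind, "length": dp.length, "pos1": lo, "pos2": hi}
        )

    for tp in config.tandem_plan:
        unit = _aperiodic_unit(rng, tp.unit_len)
        arr_seq = list(unit * tp.copies)
        for _ in range(tp.substitutions):
            # substitute inside an interior copy, away from the array edges
            pos = int(rng.integers(tp.unit_len, len(arr_seq) - tp.unit_len))
            arr_seq[pos] = _other_base(arr_seq[pos], rng)
        lo, hi = region_bounds[tp.region]
        start = _place(rng, occ, lo, hi, len(arr_seq), f"TR:{unit[:4]}", margin=tp.unit_len + 4)
        write(start, "".join(arr_seq), f"TR:{unit[:4]}", claim=False)
        left, right = start - 1, start + len(arr_seq)
        if buf[left] == ord(unit[-1]):
            buf[left] = ord(_other_base(chr(buf[left]), rng))
        if buf[right] == ord(unit[0]):
            buf[right] = ord(_other_base(chr(buf[right]), rng))
        manifest["tandem"].append(
            {"unit": unit, "copies": tp.copies, "start": start, "end": start + len(arr_seq),
             "substitutions": tp.substitutions}
        )

    _pin_ir_boundaries(buf, rng, L, I, S)
    protected = (
        [(g["start"], g["end"]) for g in manifest["genes"]]
        + [(p["start"], p["end"]) for p in manifest["ssrs"]]
        + [(p["start"], p["end"]) for p in manifest["tandem"]]
        + [(p["pos1"], p["pos1"] + p["length"]) for p in manifest["dispersed"]]
        + [(p["pos2"], p["pos2"] + p["length"]) for p in manifest["dispersed"]]
    )
    planted_ssr = {(p["start"], p["end"]) for p in manifest["ssrs"]}
    planted_tandem = [(p["start"], p["end"]) for p in manifest["tandem"]]
    manifest["coincidences"] = _sanitize_background(
        buf, rng, L, I, S, protected, planted_ssr, planted_tandem
    )

    physical = buf.tobytes().decode("ascii")
    genome = physical + revcomp(physical[L : L + I])
    record = GenomeRecord(config.accession, config.taxon, genome, genes)
    record.validate()
    return record, manifest


def _pin_ir_boundaries(buf: np.ndarray, rng: np.random.Generator, L: int, I: int, S: int) -> None:
    """Force three consecutive non-complementary flank pairs at both IR ends
    so the maximal reverse-complement repeat stops exactly at the planned
    boundaries (IR detection tolerates mismatch runs of up to two)."""
    comp_of = {ord(a): ord(b) for a, b in zip("ACGT", "TGCA")}
    for t in range(3):
        # left IRb flank pairs with the wrap past IRa: genome[t] vs buf[L-1-t]
        for a, b in ((t, L - 1 - t), (L + I + t, L + I + S - 1 - t)):
            if buf[a] == comp_of[buf[b]]:
                options = [ord(c) for c in "ACGT" if ord(c) not in (buf[a], comp_of[buf[b]])]
                buf[a] = options[int(rng.integers(0, len(options)))]


def _other_base(base: str, rng: np.random.Generator) -> str:
    options = [b for b in "ACGT" if b != base]
    return options[int(rng.integers(0, 3))]


def _aperiodic_unit(rng: np.random.Generator, length: int) -> str:
    while True:
        unit = "".join(chr(b) for b in _random_bases(rng, length, 0.45))
        if minimal_period(unit) == length:
            return unit


def _sanitize_background(buf: np.ndarray, rng: np.random.Generator,
                         L: int, I: int, S: int,
                         protected: list[tuple[int, int]],
                         planted_ssr: set[tuple[int, int]],
                         planted_tandem: list[tuple[int, int]],
                         max_rounds: int = 25) -> list[dict]:
    """Break chance SSRs/tandem arrays so planted repeats are exactly the
    detectable ones. Any detected feature that is not a planted one is broken
    by a point substitution outside the protected (planted/gene) intervals;
    mutations inside IRb are implicitly mirrored because IRa is rebuilt from
    IRb afterwards. Returns features that could not be broken (logged
    coincidences)."""
    phys_end = L + I + S

    def is_protected(pos: int) -> bool:
        return any(s <= pos < e for s, e in protected)

    leftovers: list[dict] = []
    for _ in range(max_rounds):
        physical = buf.tobytes().decode("ascii")
        genome = physical + revcomp(physical[L:L+I])
        chance = []
        for ssr in find_ssrs(genome):
            if (ssr.start, ssr.end) not in planted_ssr:
                chance.append((ssr.start, ssr.end))
        for tr in find_tandem(genome):
            if not any(tr.start < e and s < tr.end for s, e in planted_tandem):
                chance.append((tr.start, tr.end))
        if not chance:
            return []
        leftovers = []
        for start, end in chance:
            candidates = []
            for p in range(start, end):
                q = p
                if q >= phys_end:  # position in IRa: edit its IRb image
                    q = L + I - 1 - (q - phys_end)
                if not is_protected(q):
                    candidates.append(q)
            if not candidates:
                leftovers.append({"start": start, "end": end})
                continue
            # re-roll the whole unprotected span: spot substitutions are not
            # enough in quasi-periodic AT-rich background, where the array
            # simply re-phases around them
            for q in candidates:
                buf[q] = ord("ACGT"[int(rng.integers(0, 4))])
    return leftovers


# ---------------------------------------------------------------------------
# divergence simulation
# ---------------------------------------------------------------------------


def simulate_divergence(
    ancestor: GenomeRecord,
    config: DivergenceConfig | None = None,
    n_taxa: int = 5,
    seed: int = 0,
    partition: RegionPartition | None = None,
) -> tuple[AlignmentMatrix, list[str], dict]:
    """Star-phylogeny divergence of ``n_taxa`` from a common ancestor.

    Each taxon receives independent Poisson-distributed substitutions at the
    per-region rates, plus indels (insertions and deletions, geometric
    lengths). Returns the true alignment, a per-column region label list, and
    a manifest of realized per-region substitution counts.
    """
    config = config or DivergenceConfig()
    rng = np.random.default_rng(seed)
    n = ancestor.length
    region_of = np.empty(n, dtype="U3")
    if partition is None:
        from .genome_io import detect_quadripartite

        partition = detect_quadripartite(ancestor)
    for name, (s, e) in partition.as_dict().items():
        key = "ir" if name in ("IRa", "IRb") else name.lower()
        for a, b in (((s, min(e, n))), ) if e <= n else ((s, n), (0, e - n)):
            region_of[a:b] = key

    anc = np.frombuffer(ancestor.sequence.encode(), dtype=np.uint8)
    taxa: list[dict] = []
    manifest = {"seed": seed, "n_taxa": n_taxa, "substitutions": [], "indels": []}
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    for t in range(n_taxa):
        seq = anc.copy()
        sub_counts: dict[str, int] = {}
        for key in set(region_of.tolist()):
            idx = np.flatnonzero(region_of == key)
            rate = config.rates.get(key, config.rates.get("ir", 0.0))
            k = rng.poisson(rate * idx.size)
            k = min(k, idx.size)
            positions = rng.choice(idx, size=k, replace=False)
            for pos in positions:
                old = seq[pos]
                choices = base_codes[base_codes != old]
                seq[pos] = choices[int(rng.integers(0, len(choices)))]
            sub_counts[key] = int(k)
        deleted = np.zeros(n, dtype=bool)
        insertions: dict[int, str] = {}
        n_indels = int(rng.poisson(config.indel_rate * n))
        indel_events = []
        for _ in range(n_indels):
            pos = int(rng.integers(0, n))
            length = int(rng.geometric(1.0 / config.indel_mean_len))
            if rng.random() < 0.5:
                deleted[pos : pos + length] = True
                indel_events.append({"type": "del", "pos": pos, "len": length})
            else:
                ins = "".join(chr(b) for b in _random_bases(rng, length, 0.35))
                insertions[pos] = insertions.get(pos, "") + ins
                indel_events.append({"type": "ins", "pos": pos, "len": length})
        taxa.append({"seq": seq, "deleted": deleted, "insertions": insertions})
        manifest["substitutions"].append(sub_counts)
        manifest["indels"].append(indel_events)

    # build the true alignment column by column
    names = [f"{ancestor.accession}_t{t}" for t in range(n_taxa)]
    cols: list[list[str]] = [[] for _ in range(n_taxa)]
    col_regions: list[str] = []
    for pos in range(n):
        for t, tx in enumerate(taxa):
            cols[t].append("-" if tx["deleted"][pos] else chr(tx["seq"][pos]))
        col_regions.append(region_of[pos])
        for t, tx in enumerate(taxa):
            ins = tx["insertions"].get(pos)
            if ins:
                for t2 in range(n_taxa):
                    cols[t2].extend(ins if t2 == t else "-" * len(ins))
                col_regions.extend(region_of[pos] for _ in ins)
    aln = AlignmentMatrix.from_sequences([(names[t], "".join(cols[t])) for t in range(n_taxa)])
    return aln, col_regions, manifest


# ---------------------------------------------------------------------------
# codon evolution
# ---------------------------------------------------------------------------


def simulate_codon_evolution(
    gene_length_codons: int,
    omega: float,
    divergence: float,
    rscu_profile: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[str, str, dict]:
    """Evolve one descendant from a sampled ancestor at a chosen dN/dS.

    Substitutions are proposed uniformly over nucleotide sites at an expected
    ``divergence`` proposals per site and accepted with probability 1 for
    synonymous and min(1, ω) for nonsynonymous changes (ω > 1 instead
    down-weights synonymous acceptance by 1/ω); proposals creating stop
    codons are rejected. Returns (ancestor CDS, descendant CDS, realized
    counts of accepted synonymous/nonsynonymous changes).
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    if not 0 < divergence < 1:
        raise ValueError("divergence must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    codon_pool = list(SENSE_CODONS)
    if rscu_profile:
        weights = np.array([rscu_profile.get(c, 0.0) for c in codon_pool], dtype=float)
        if weights.sum() <= 0:
            raise ValueError("rscu_profile assigns no mass to sense codons")
        probs = weights / weights.sum()
    else:
        probs = np.full(len(codon_pool), 1.0 / len(codon_pool))
    idx = rng.choice(len(codon_pool), size=gene_length_codons, p=probs)
    ancestor = [codon_pool[i] for i in idx]
    descendant = list(ancestor)

    p_syn = min(1.0, 1.0 / omega)
    p_non = min(1.0, omega)
    n_prop = int(rng.poisson(divergence * 3 * gene_length_codons))
    realized = {"Sd": 0, "Nd": 0, "proposals": n_prop}
    for _ in range(n_prop):
        ci = int(rng.integers(0, gene_length_codons))
        pos = int(rng.integers(0, 3))
        cur = descendant[ci]
        new_base = _other_base(cur[pos], rng)
        mut = cur[:pos] + new_base + cur[pos + 1 :]
        if mut in STOP_CODONS:
            continue
        synonymous = CODON_TO_AA[mut] == CODON_TO_AA[cur]
        p_accept = p_syn if synonymous else p_non
        if rng.random() < p_accept:
            descendant[ci] = mut
            realized["Sd" if synonymous else "Nd"] += 1
    return "".join(ancestor), "".join(descendant), realized


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_outputs(record: GenomeRecord, manifest: dict, out_dir) -> dict:
    """Write GenBank, FASTA, and manifest JSON for a simulated genome."""
    from pathlib import Path

    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rec = SeqRecord(
        Seq(record.sequence),
        id=record.accession,
        name=record.accession,
        description=record.taxon,
        annotations={"molecule_type": "DNA", "topology": "circular", "organism": record.taxon},
    )
    for g in record.genes:
        for s, e in g.parts:
            loc = FeatureLocation(s, min(e, record.length), strand=1 if g.strand == "+" else -1)
            ftype = g.kind if g.kind in ("CDS", "tRNA", "rRNA") else "CDS"
            quals = {"gene": [g.name]}
            if g.kind == "pseudogene":
                quals["pseudo"] = [""]
            rec.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    from Bio import SeqIO

    gb = out_dir / f"{record.accession}.gb"
    fa = out_dir / f"{record.accession}.fasta"
    SeqIO.write([rec], str(gb), "genbank")
    SeqIO.write([rec], str(fa), "fasta")
    mpath = out_dir / f"{record.accession}.manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return {"genbank": gb, "fasta": fa, "manifest": mpath}
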