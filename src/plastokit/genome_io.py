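"""Annotated plastome input, quadripartite partition detection, and junction analysis.

A chloroplast genome is a circular molecule with a quadripartite layout: a
large single-copy region (LSC), a small single-copy region (SSC), and two
identical reverse-complementary inverted repeats (IRb, IRa) separating them.
This module reads annotated genomes (GenBank flat files, or FASTA plus a gene
coordinate table), locates the IR pair, computes GC content per region, and
reports the genes at the four single-copy/IR junctions (JLB, JSB, JSA, JLA).

Coordinates are 0-based half-open internally; GenBank 1-based inclusive
coordinates are converted on read. A circular interval is a pair ``(start,
end)`` with ``0 <= start < n`` and ``start < end <= start + n`` — ``end > n``
denotes wrap past the origin.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from ._genetics import gc_fraction, revcomp

GENE_KINDS = ("CDS", "tRNA", "rRNA", "pseudogene")
BOUNDARIES = ("JLB", "JSB", "JSA", "JLA")

_IUPAC_TO_N = str.maketrans("RYSWKMBDHVU", "NNNNNNNNNNN")


class ValidationError(ValueError):
    """Input that parses but violates a structural constraint."""


class ParseError(ValueError):
    """Input that cannot be parsed at all."""


class NoIRDetectedError(ValueError):
    """No reverse-complementary repeat pair long enough to be an IR."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneAnnotation:
    """One annotated gene: exons as ordered half-open intervals.

    ``parts`` may use ``end > genome_length`` to represent wrap past the
    circular origin. ``copy_tag`` disambiguates IR-duplicated genes (A/B).
    """

    name: str
    kind: str
    strand: str
    parts: list[tuple[int, int]]
    copy_tag: str | None = None

    def footprint(self) -> tuple[int, int]:
        """Genomic footprint (introns included): (min start, max end)."""
        return min(s for s, _ in self.parts), max(e for _, e in self.parts)

    @property
    def span_length(self) -> int:
        fs, fe = self.footprint()
        return fe - fs

    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.parts)


@dataclass
class GenomeRecord:
    """A circular annotated plastome."""

    accession: str
    taxon: str
    sequence: str
    genes: list[GeneAnnotation] = field(default_factory=list)
    group_labels: dict[str, str] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        if not self.sequence:
            raise ValidationError(f"{self.accession}: empty sequence")
        n = self.length
        for g in self.genes:
            if not g.parts:
                raise ValidationError(f"{self.accession}:{g.name}: no exon parts")
            for s, e in g.parts:
                if not (0 <= s < n and s < e <= s + n and e <= 2 * n):
                    raise ValidationError(
                        f"{self.accession}:{g.name}: interval [{s},{e}) out of "
                        f"bounds for length {n}"
                    )
            if g.kind == "CDS" and g.spliced_length() < 3:
                raise ValidationError(f"{self.accession}:{g.name}: CDS shorter than one codon")

    def region_sequence(self, interval: tuple[int, int]) -> str:
        """Sequence of a circular interval (handles wrap)."""
        s, e = interval
        n = self.length
        if e <= n:
            return self.sequence[s:e]
        return self.sequence[s:] + self.sequence[: e - n]

    def gene_sequence(self, gene: GeneAnnotation) -> str:
        """Spliced coding-strand sequence (parts joined, revcomp for '-')."""
        parts = sorted(gene.parts)
        seq = "".join(self.region_sequence(p) for p in parts)
        return revcomp(seq) if gene.strand == "-" else seq


@dataclass
class RegionPartition:
    """The quadripartite tiling: LSC, IRb, SSC, IRa as circular intervals."""

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {"LSC": self.lsc, "IRb": self.irb, "SSC": self.ssc, "IRa": self.ira}

    def lengths(self) -> dict[str, int]:
        return {k: e - s for k, (s, e) in self.as_dict().items()}

    def boundaries(self, n: int) -> dict[str, int]:
        """Junction positions: JLB = LSC|IRb, JSB = IRb|SSC, JSA = SSC|IRa,
        JLA = IRa|LSC (position of the first base of the downstream region)."""
        return {
            "JLB": self.irb[0] % n,
            "JSB": self.ssc[0] % n,
            "JSA": self.ira[0] % n,
            "JLA": self.lsc[0] % n,
        }


@dataclass
class JunctionGene:
    boundary: str
    position: int
    gene: str | None
    spanning_bp: int
    distance_bp: int | None


@dataclass
class JunctionReport:
    accession: str
    entries: dict[str, JunctionGene]


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _normalize_sequence(seq: str) -> str:
    seq = seq.upper().translate(_IUPAC_TO_N)
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ParseError(f"sequence contains non-nucleotide characters: {sorted(bad)}")
    return seq


def _tag_duplicates(genes: list[GeneAnnotation]) -> None:
    """Assign copy tags A/B/... to genes sharing a name (IR duplicates)."""
    by_name: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_name.setdefault((g.name, g.kind), []).append(g)
    for copies in by_name.values():
        if len(copies) > 1:
            copies.sort(key=lambda g: g.footprint()[0])
            for tag, g in zip("ABCDEFGH", copies):
                g.copy_tag = tag


def _genes_from_seqrecord(rec, n: int) -> list[GeneAnnotation]:
    genes: list[GeneAnnotation] = []
    for feat in rec.features:
        if feat.type not in ("CDS", "tRNA", "rRNA"):
            continue
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("locus_tag") or ["?"])[0]
        kind = "pseudogene" if "pseudo" in quals or "pseudogene" in quals else feat.type
        strand = "-" if feat.location.strand == -1 else "+"
        parts = [(int(p.start), int(p.end)) for p in feat.location.parts]
        # an origin-crossing compound location arrives as (x, n) + (0, y)
        parts.sort()
        if len(parts) >= 2 and parts[-1][1] == n and parts[0][0] == 0:
            first, last = parts[0], parts[-1]
            merged = (last[0], n + first[1])
            parts = parts[1:-1] + [merged]
        genes.append(GeneAnnotation(name=name, kind=kind, strand=strand, parts=parts))
    _tag_duplicates(genes)
    return genes


def read_gene_table(path: str | Path) -> dict[str, list[GeneAnnotation]]:
    """Read a gene-coordinate TSV (accession, gene, kind, strand, start, end,
    part_index); start/end are 1-based inclusive, GenBank style."""
    rows: dict[str, dict[tuple[str, str, str], list[tuple[int, int, int]]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"accession", "gene", "kind", "strand", "start", "end"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(f"gene table {path}: missing columns {required}")
        for lineno, row in enumerate(reader, start=2):
            try:
                start = int(row["start"]) - 1
                end = int(row["end"])
                part = int(row.get("part_index") or 0)
            except ValueError as exc:
                raise ParseError(f"gene table {path} line {lineno}: {exc}") from None
            key = (row["gene"], row["kind"], row["strand"])
            rows.setdefault(row["accession"], {}).setdefault(key, []).append(
                (part, start, end)
            )
    out: dict[str, list[GeneAnnotation]] = {}
    for acc, by_gene in rows.items():
        genes = []
        for (name, kind, strand), triplets in by_gene.items():
            triplets.sort()
            genes.append(
                GeneAnnotation(
                    name=name,
                    kind=kind,
                    strand=strand,
                    parts=[(s, e) for _, s, e in triplets],
                )
            )
        _tag_duplicates(genes)
        out[acc] = genes
    return out


def read_group_table(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a grouping TSV (accession, tribe, clade, outgroup)."""
    out: dict[str, dict[str, str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            acc = row.pop("accession")
            out[acc] = {k: v for k, v in row.items() if v}
    return out


def read_annotated_genome(
    source: str | Path,
    gene_table: str | Path | None = None,
    group_table: str | Path | None = None,
    accession: str | None = None,
) -> GenomeRecord:
    """Read one annotated plastome from GenBank, or FASTA plus a gene table.

    Sequences are uppercased and ambiguity codes other than N collapsed to N;
    coordinates are converted to 0-based half-open. Raises :class:`ParseError`
    on malformed input and :class:`ValidationError` on out-of-bounds genes.
    """
    source = Path(source)
    fmt = "genbank" if source.suffix.lower() in (".gb", ".gbk", ".gbff") else "fasta"
    try:
        records = list(SeqIO.parse(str(source), fmt))
    except Exception as exc:  # Biopython raises assorted types
        raise ParseError(f"{source}: {exc}") from exc
    if not records:
        raise ParseError(f"{source}: no records")
    if accession is not None:
        matches = [r for r in records if accession in (r.id, r.name, r.id.split(".")[0])]
        if not matches:
            raise ParseError(f"{source}: accession {accession} not found")
        rec = matches[0]
    else:
        rec = records[0]

    seq = _normalize_sequence(str(rec.seq))
    acc = rec.id.split(".")[0] if rec.id else rec.name
    taxon = ""
    if fmt == "genbank":
        taxon = rec.annotations.get("organism", "") or rec.description
        genes = _genes_from_seqrecord(rec, len(seq))
    else:
        taxon = rec.description
        genes = []
        if gene_table is not None:
            table = read_gene_table(gene_table)
            genes = table.get(acc) or table.get(rec.id, [])

    groups: dict[str, str] = {}
    if group_table is not None:
        groups = read_group_table(group_table).get(acc, {})

    record = GenomeRecord(
        accession=acc, taxon=taxon, sequence=seq, genes=genes, group_labels=groups
    )
    record.validate()
    return record


# ---------------------------------------------------------------------------
# quadripartite detection
# ---------------------------------------------------------------------------

_SEED_K = 32


def _extend_match(d: str, rcd: str, i: int, j: int, k: int, max_len: int,
                  max_gap_mm: int = 2) -> tuple[int, int, int]:
    """Extend an exact seed ``d[i:i+k] == rcd[j:j+k]`` in both directions,
    crossing runs of at most ``max_gap_mm`` mismatches when an exact match
    resumes. Returns (i0, j0, length)."""
    nd, nr = len(d), len(rcd)
    # right
    ir, jr = i + k, j + k
    while ir < nd and jr < nr and (ir - i) < max_len:
        if d[ir] == rcd[jr]:
            ir += 1
            jr += 1
            continue
        # try to cross a short mismatch run
        for gap in range(1, max_gap_mm + 1):
            if ir + gap < nd and jr + gap < nr and d[ir + gap] == rcd[jr + gap]:
                ir += gap + 1
                jr += gap + 1
                break
        else:
            break
    # left
    il, jl = i, j
    while il > 0 and jl > 0 and (ir - il) < max_len:
        if d[il - 1] == rcd[jl - 1]:
            il -= 1
            jl -= 1
            continue
        for gap in range(1, max_gap_mm + 1):
            if il - gap - 1 >= 0 and jl - gap - 1 >= 0 and d[il - gap - 1] == rcd[jl - gap - 1]:
                il -= gap + 1
                jl -= gap + 1
                break
        else:
            break
    return il, jl, ir - il


def _circ_disjoint(a: tuple[int, int], b: tuple[int, int], n: int) -> bool:
    """True if two circular intervals (end may exceed n) do not overlap."""
    def segs(iv):
        s, e = iv
        return [(s, min(e, n))] + ([(0, e - n)] if e > n else [])

    for s1, e1 in segs(a):
        for s2, e2 in segs(b):
            if s1 < e2 and s2 < e1:
                return False
    return True


def detect_quadripartite(record: GenomeRecord, min_ir_len: int = 1000) -> RegionPartition:
    """Locate the inverted-repeat pair and derive the LSC/IRb/SSC/IRa tiling.

    The IR pair is the longest pair of disjoint maximal reverse-complementary
    repeats of at least ``min_ir_len`` bases; isolated mismatches (runs of at
    most two) inside otherwise exact IRs are tolerated. Detection is
    rotation-invariant: region lengths do not depend on where the circular
    sequence was linearized. Raises :class:`NoIRDetectedError` when no
    qualifying repeat pair exists.
    """
    s = record.sequence
    n = len(s)
    if n < 4 * min_ir_len:
        raise NoIRDetectedError(
            f"{record.accession}: genome of {n} bp cannot hold two IRs of {min_ir_len} bp"
        )
    d = s + s
    rcd = revcomp(d)
    k = min(_SEED_K, min_ir_len)

    index: dict[str, list[int]] = {}
    for i in range(0, n, 1):
        index.setdefault(d[i : i + k], []).append(i)

    best: tuple[int, tuple[int, int], tuple[int, int]] | None = None
    covered: dict[int, list[tuple[int, int]]] = {}
    stride = max(1, k // 2)
    for j in range(0, 2 * n - k + 1, stride):
        hits = index.get(rcd[j : j + k])
        if not hits:
            continue
        for i in hits:
            diag = i - j
            done = False
            for a, b in covered.get(diag, ()):
                if a <= i and i + k <= b:
                    done = True
                    break
            if done:
                continue
            i0, j0, length = _extend_match(d, rcd, i, j, k, max_len=n)
            covered.setdefault(diag, []).append((i0, i0 + length))
            if length < min_ir_len:
                continue
            a_start = i0 % n
            b_start = (2 * n - j0 - length) % n
            iv_a = (a_start, a_start + length)
            iv_b = (b_start, b_start + length)
            if not _circ_disjoint(iv_a, iv_b, n):
                continue
            if best is None or length > best[0]:
                best = (length, iv_a, iv_b)

    if best is None:
        raise NoIRDetectedError(
            f"{record.accession}: no reverse-complementary repeat ≥ {min_ir_len} bp"
        )
    length, iv_a, iv_b = best
    # order the two copies around the circle and measure the two gaps
    a, b = sorted([iv_a, iv_b])
    gap_ab = (b[0] - a[1]) % n  # single-copy stretch after copy a
    gap_ba = (a[0] + n - b[1]) % n  # single-copy stretch after copy b
    if gap_ab == 0 or gap_ba == 0:
        raise NoIRDetectedError(f"{record.accession}: IR copies are adjacent; no single-copy regions")
    if gap_ab >= gap_ba:
        # LSC follows copy b (wraps to copy a): order LSC, IRb=a? No:
        # larger gap = LSC lies between a.end and b.start? gap_ab is between
        # a and b, so LSC = (a_end, b_start) and IRb is the copy after LSC = b.
        lsc = (a[1] % n, a[1] % n + gap_ab)
        irb = (b[0], b[0] + length)
        ssc = (b[1] % n, b[1] % n + gap_ba)
        ira = (a[0], a[0] + length)
    else:
        lsc = (b[1] % n, b[1] % n + gap_ba)
        irb = (a[0], a[0] + length)
        ssc = (a[1] % n, a[1] % n + gap_ab)
        ira = (b[0], b[0] + length)
    part = RegionPartition(lsc=lsc, irb=irb, ssc=ssc, ira=ira)
    assert sum(part.lengths().values()) == n
    return part


def rotate_record(record: GenomeRecord, k: int) -> GenomeRecord:
    """Rotate the circular genome so original position ``k`` becomes 0."""
    n = record.length
    k %= n
    seq = record.sequence[k:] + record.sequence[:k]
    genes = []
    for g in record.genes:
        parts = []
        for s, e in g.parts:
            s2 = (s - k) % n
            parts.append((s2, s2 + (e - s)))
        genes.append(GeneAnnotation(g.name, g.kind, g.strand, parts, g.copy_tag))
    return GenomeRecord(record.accession, record.taxon, seq, genes, dict(record.group_labels))


def canonicalize(record: GenomeRecord, partition: RegionPartition) -> tuple[GenomeRecord, RegionPartition]:
    """Rotate genome and partition so the LSC starts at position 0."""
    k = partition.lsc[0]
    n = record.length
    rec2 = rotate_record(record, k)

    def shift(iv):
        s, e = iv
        s2 = (s - k) % n
        return (s2, s2 + (e - s))

    part2 = RegionPartition(
        lsc=shift(partition.lsc),
        irb=shift(partition.irb),
        ssc=shift(partition.ssc),
        ira=shift(partition.ira),
    )
    return rec2, part2


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------


def gc_content_by_region(record: GenomeRecord, partition: RegionPartition) -> dict[str, float]:
    """GC fraction for the whole genome, each region, and the CDS set.

    N bases are excluded from numerator and denominator; an empty region
    yields NaN (undefined), never 0.
    """
    out = {"total": gc_fraction(record.sequence)}
    for name, iv in partition.as_dict().items():
        seq = record.region_sequence(iv)
        out[name] = gc_fraction(seq) if seq else float("nan")
    cds = "".join(
        record.gene_sequence(g)
        for g in record.genes
        if g.kind == "CDS" and g.copy_tag in (None, "A")
    )
    out["CDS"] = gc_fraction(cds) if cds else float("nan")
    return out


# ---------------------------------------------------------------------------
# junction analysis
# ---------------------------------------------------------------------------

_DOWNSTREAM = {"JLB": "irb", "JSB": "ssc", "JSA": "ira", "JLA": "lsc"}


def analyze_junctions(record: GenomeRecord, partition: RegionPartition) -> JunctionReport:
    """Report the gene at each of the four region junctions.

    A gene *spans* a junction when its genomic footprint (introns included)
    covers the boundary; the spanning length is the number of its bases lying
    in the downstream region. When no gene spans, the nearest gene (either
    side) is reported with its distance. Ties break toward the smaller start
    coordinate.
    """
    n = record.length
    entries: dict[str, JunctionGene] = {}
    for bname, pos in partition.boundaries(n).items():
        down_iv = getattr(partition, _DOWNSTREAM[bname])
        down_len = down_iv[1] - down_iv[0]
        spanning: list[tuple[int, int, str]] = []  # (start, span_bp, name)
        nearest: list[tuple[int, int, str]] = []  # (distance, start, name)
        for g in record.genes:
            fs, fe = g.footprint()
            b = pos if pos >= fs else pos + n
            if fs < b < fe:
                span = min(fe - b, down_len)
                spanning.append((fs, span, g.name))
            else:
                # circular distance from footprint to the boundary
                d_up = (pos - fe) % n
                d_down = (fs - pos) % n
                nearest.append((min(d_up, d_down), fs, g.name))
        if spanning:
            spanning.sort(key=lambda t: (t[0], t[2]))
            fs, span, name = spanning[0]
            entries[bname] = JunctionGene(bname, pos, name, span, None)
        elif nearest:
            nearest.sort()
            dist, _, name = nearest[0]
            entries[bname] = JunctionGene(bname, pos, name, 0, dist)
        else:
            entries[bname] = JunctionGene(bname, pos, None, 0, None)
    return JunctionReport(accession=record.accession, entries=entries)


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------


def regions_table(records_partitions: Iterable[tuple[GenomeRecord, RegionPartition]]) -> "list[dict]":
    rows = []
    for rec, part in records_partitions:
        gc = gc_content_by_region(rec, part)
        for name, (s, e) in part.as_dict().items():
            rows.append(
                {
                    "accession": rec.accession,
                    "region": name,
                    "start": s + 1,  # 1-based inclusive for human-facing output
                    "end": e if e <= rec.length else e - rec.length,
                    "length": e - s,
                    "gc": gc[name],
                }
            )
    return rows


def junctions_table(reports: Iterable[JunctionReport]) -> "list[dict]":
    rows = []
    for rep in reports:
        for bname in BOUNDARIES:
            j = rep.entries[bname]
            rows.append(
                {
                    "accession": rep.accession,
                    "boundary": bname,
                    "position": j.position + 1,
                    "gene": j.gene or "",
                    "spanning_bp": j.spanning_bp,
                    "distance_bp": "" if j.distance_bp is None else j.distance_bp,
                }
            )
    return rows
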