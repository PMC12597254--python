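"""Shared sequence and genetic-code helpers.

The plastid genetic code (NCBI translation table 11) drives every codon-level
statistic in the package. Synonymous families and degeneracy classes are built
once at import time from Biopython's codon tables.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: transition partner of each base (A<->G, C<->T)
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

PLASTID_TABLE_ID = 11
_table = CodonTable.unambiguous_dna_by_id[PLASTID_TABLE_ID]

#: codon (DNA alphabet) -> one-letter amino acid; stops map to '*'
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)
for _stop in _table.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(_table.stop_codons)
ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

#: amino acid -> tuple of synonymous codons (stops under '*')
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon in ALL_CODONS:
    AA_TO_CODONS.setdefault(CODON_TO_AA[_codon], ())
AA_TO_CODONS = {
    aa: tuple(c for c in ALL_CODONS if CODON_TO_AA[c] == aa) for aa in AA_TO_CODONS
}

#: amino acids whose family has a single codon (Met, Trp under table 11)
SINGLE_CODON_AAS = frozenset(
    aa for aa, cods in AA_TO_CODONS.items() if aa != "*" and len(cods) == 1
)

#: degeneracy class (2, 3, 4, 6) -> amino acids in that class
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {}
for _aa, _cods in AA_TO_CODONS.items():
    if _aa == "*" or len(_cods) == 1:
        continue
    DEGENERACY_CLASSES.setdefault(len(_cods), ())
DEGENERACY_CLASSES = {
    k: tuple(aa for aa, cods in AA_TO_CODONS.items() if aa != "*" and len(cods) == k)
    for k in DEGENERACY_CLASSES
}

#: four-fold degenerate amino acids (used for PR2 coordinates)
FOURFOLD_AAS = frozenset(DEGENERACY_CLASSES.get(4, ()))


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def seq_to_array(seq: str) -> np.ndarray:
    """Sequence as a uint8 array of ASCII codes (vector comparisons)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def gc_fraction(seq: str) -> float:
    """GC fraction with N excluded from numerator and denominator.

    Returns NaN for a sequence without countable bases.
    """
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    total = gc + at
    return gc / total if total else float("nan")


@lru_cache(maxsize=None)
def minimal_rotation(motif: str) -> str:
    """Lexicographically minimal rotation (canonical SSR motif)."""
    doubled = motif + motif
    return min(doubled[i : i + len(motif)] for i in range(len(motif)))


@lru_cache(maxsize=None)
def minimal_period(unit: str) -> int:
    """Smallest p such that unit is a whole number of repetitions of unit[:p]."""
    n = len(unit)
    for p in range(1, n + 1):
        if n % p == 0 and unit == unit[:p] * (n // p):
            return p
    return n


def codons_of(seq: str) -> list[str]:
    """Split a nucleotide string into codons, discarding a trailing partial."""
    return [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]


def translate(seq: str) -> str:
    return "".join(CODON_TO_AA.get(c, "X") for c in codons_of(seq))
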