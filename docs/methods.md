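# Methods

This note documents the models, statistics, and numerical choices behind
`plastokit`, and what the synthetic-data generator does and does not emulate.

## Quadripartite structure and junctions

A plastome is modeled as a circular string with a quadripartite tiling
LSC + IRb + SSC + IRa, where IRa is the reverse complement of IRb.
Coordinates are 0-based half-open internally (GenBank 1-based inclusive is
converted on read and restored in human-facing tables); a circular interval
`(start, end)` with `end > n` denotes wrap past the origin.

**IR detection.** The IR pair is found as the longest pair of disjoint
maximal reverse-complementary repeats of at least `min_ir_len` (default
1,000 bp, the shortest value that excludes incidental palindromes in a
~160 kb genome while accepting even strongly contracted IRs). Seeds are
exact 32-mers between the doubled sequence and its reverse complement,
extended in both directions; runs of up to two mismatches are crossed when
an exact match resumes, which tolerates isolated sequencing errors inside
otherwise identical IRs. Detection operates on the doubled sequence, so the
result is invariant under rotation of the circular origin; `canonicalize`
rotates the genome so the LSC starts at position 0, making junction
coordinates comparable across accessions.

**Junctions.** The four boundaries JLB (LSC|IRb), JSB (IRb|SSC), JSA
(SSC|IRa), and JLA (IRa|LSC) are positioned at the first base of the
downstream region. A gene *spans* a boundary when its genomic footprint —
introns included, measured on the genomic interval from first to last exon
— covers it; the spanning length is the number of its bases in the
downstream region. This footprint convention can differ from display tools
that draw exon boxes only; it is stated here because the choice is not
forced by anything upstream. When no gene spans a boundary, the nearest
gene on either side is reported with its distance; ties break toward the
smaller start coordinate.

**GC content** is computed with N excluded from numerator and denominator;
an empty region reports NaN, never 0, so downstream averaging cannot be
silently biased.

## Repeat census

**SSRs** are maximal perfect runs of a 1–6 bp unit with MISA-style minimum
copy numbers 10/5/4/3/3/3 for unit lengths 1–6. A run reportable at several
periods is reported only at its smallest one (a poly-A run is never an AA
dinucleotide repeat); unit primitiveness is checked explicitly. Motifs are
canonicalized by lexicographically minimal rotation without folding in the
reverse complement, since plastome strand orientation is fixed; strand
symmetry therefore holds only after mapping motifs through the reverse
complement, which is how the property is tested. SSRs within 100 bp of each
other share a compound identifier; the compound is a grouping only and
members are counted individually.

**Dispersed repeats** follow the REPuter four-orientation scheme — forward
(F), palindromic (P), reverse (R), complement (C) — with floors
`min_len = 30` and Hamming budget `max_mismatch = 3` (common REPuter
practice; both configurable). A reported pair is a *maximal* window on its
alignment diagonal: extending it on either side would exceed the mismatch
budget or leave the sequence. Exact k-mer seeds (k = ⌊min_len/(budget+1)⌋,
the pigeonhole guarantee) are verified by a vectorized window filter before
exact maximal-window enumeration; seeds inside one maximal exact stretch
yield identical window sets and are computed once, which keeps the IR-sized
self-match cheap. The genome's own IR duplication is excluded by masking
pairs whose copies lie ≥ 50% inside the two IRs — these pairs are
consequences of the duplication, not dispersed repeats. Ambiguous bases
never match, not even each other.

**Tandem repeats** (unit > 6 bp, so they never overlap the SSR range) are
found by scanning each candidate period's self-offset match profile for
maximal stretches with a small substitution budget, then scoring arrays
against their column-majority consensus: identity = consensus matches /
span, so one substitution in a k-copy array costs 1/(k·unit). Arrays mostly
covering a low-period run are left to the SSR scan regardless of the period
they were read at. Overlapping readings of one locus are resolved by an
alignment-style score (+1 match, −3 mismatch), which prefers an exact
short-unit reading over a sloppier long-period one. This is a deliberately
simple near-exact array finder, not a reimplementation of stochastic
score-model tools, so absolute tandem counts from such tools are not
comparable.

Feature localization uses the midpoint rule: region = the partition
interval containing the feature midpoint; context = CDS if the midpoint
falls in any exon, intron if inside a gene but not an exon, IGS otherwise.

## Nucleotide diversity and variants

π per window is the average over all sequence pairs of (mismatches /
compared sites), with columns containing a gap or N in either pair member
excluded pairwise; ambiguity codes other than N are treated as N. Window
and step default to 600/200, recorded in output headers. The final partial
window is reported with its true span. Variability tiers are high
(π > 0.02), medium (0.01 ≤ π ≤ 0.02), low (π < 0.01); windows with π > 0.06
are flagged as barcode-candidate hotspots and contiguous flagged windows
merge into intervals named by the flanking or overlapping annotations.

SNVs are columns where both the row and the reference carry unambiguous
bases that differ. An indel is one event per maximal gap run present in
exactly one of the two rows, assigned to the 100 bp bin of its first
column; a run where the gapped row switches counts as two events.

Distances use pairwise deletion and either the p model or Kimura's
two-parameter model, d = −½·ln((1 − 2P − Q)·√(1 − 2Q)); a domain violation
(argument ≤ 0) reports NaN for that pair rather than a clamped value.

## Codon usage

All codon statistics use the plastid/bacterial genetic code (translation
table 11). CDS enter the analysis after the standard filters: spliced
length ≥ 300 bp, divisible by three, IR duplicates kept once (copy A);
internal stops are flagged but retained, the terminal stop stays in the raw
counts and is excluded by each statistic that should not see it.

* **RSCU**(c) = count(c) / mean count over c's synonymous family; unused
  families report zeros, and the family means equal 1 exactly whenever the
  family is used (tested to 1e−12). Stops can be included as their own
  three-codon block for reports that list them.
* **ENC** is Wright's estimator: per-family homozygosity
  F̂ = (nΣp̂² − 1)/(n − 1), degeneracy-class means, and
  Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, clamped to [20, 61]. Families with
  n < 2 or F̂ ≤ 0 are skipped from their class mean; a missing three-fold
  class (isoleucine absent) is imputed as the mean of the two- and
  four-fold classes, and any other missing class falls back to the mean of
  the observed class means.
* **Expected ENC** is Wright's null curve 2 + s + 29/(s² + (1−s)²) in
  GC3s. The flattened typesetting of this equation sometimes seen in print
  drops the grouping of the denominator; the standard curve is what is
  computed here, giving the familiar 60.5 at s = 0.5 and 31 at s = 0.
  Deviation (expected − observed)/expected classifies genes at ±0.15 into
  selection-shaped versus mutation-shaped codon usage.
* **Third-position compositions** are tallied over synonymous third
  positions (Met, Trp, stops excluded); PR2 coordinates A3/(A3+T3) and
  G3/(G3+C3) use four-fold degenerate families only, so (0.5, 0.5) is the
  no-asymmetry parity point.
* **CAI/CBI/Fop** need a reference set, which the source analyses do not
  name; by default the reference is the pooled counts of the lowest-ENC 5%
  of genes (the same expression proxy the optimal-codon screen uses), with
  w = count/max within each family, floor 0.01 for unused codons of used
  families, and the optimal set = the per-family maxima. Absolute values
  of these three indices are therefore reference-dependent and comparable
  only within one run, or under a user-supplied weight file.
* **Optimal codons**: genes ranked by ENC ascending; high- and
  low-expression sets are the bottom/top ⌈5%⌉ with ties in (ENC, name)
  taken together — the tie rule makes the screen invariant to duplicating
  the gene table, which ⌈·⌉ alone is not. A codon is optimal iff
  ΔRSCU = RSCU_high − RSCU_low ≥ 0.08 and RSCU_high > 1. The printed form
  of the second clause ("ΔRSCU > 1") is selectable via `rule="literal"`,
  but makes the first clause vacuous and is not the default.

## Ka/Ks

The NG86 counting method with Jukes–Cantor correction, the classic
estimator behind DnaSP's Ka/Ks, with these stated conventions: codon
columns containing gaps, Ns, or stops in either sequence are deleted
pairwise; synonymous site fractions per position exclude mutations to stop
codons from the possible-change count, so S + N = 3 × usable codons
exactly; observed differences average equally over all minimal mutational
pathways, excluding pathways through stop codons unless every pathway
passes through one (then all are used); p ≥ 3/4 leaves the corrected rate
undefined (NaN). Group values (tribe, clade, functional class) are
arithmetic means of member-versus-outgroup pair estimates, with ω taken as
the ratio of the averaged rates; the functional class of a gene defaults
to a prefix rule (psa/psb/pet/atp/ndh/rbc → photosynthesis,
rps/rpl/rpo/inf/mat → self-replication, else other) and a gene→class table
overrides it. Ks distributions are histogrammed at a fixed 0.005 bin width.

## Synthetic data

The generator emits what the analyses need to be verifiable end to end,
with a truth manifest recording every planted feature.

* **Plastome**: LSC + IRb + SSC + IRa with IRa built as the exact reverse
  complement of IRb. Default dimensions 89,000 + 25,700 + 19,500 (+ IRa) =
  159,900 bp and GC targets 0.33/0.43/0.28 for LSC/IR/SSC match typical
  Moraceae-like plastomes. Genes are random CDS (ATG … TAA, no internal
  stops) placed per plan; junction-anchored genes (an rps19 analog spanning
  JLB by 45 bp, an ndhF analog poking 60 bp into IRb, a ycf1 analog
  extending 1,200 bp into IRa) claim their fixed coordinates first. A gene
  tail that crosses into IRa inherits the IR content rather than writing
  it, exactly as real junction-spanning genes coexist with the IR copy of
  their own 3′ end; such tails may contain internal stops, which the CDS
  extractor flags. Three consecutive non-complementary base pairs are
  forced at each IR flank so the maximal repeat ends exactly at the planned
  boundaries.
* **Background sanitation**: background sequence is i.i.d. at the region
  GC target and is then scanned with the package's own SSR and tandem
  detectors; any chance feature above the detection floors that is not a
  planted one is destroyed by re-rolling its unprotected bases (quasi-
  periodic AT-rich stretches resist single substitutions by re-phasing).
  Gene bodies are resampled at generation until repeat-free. Anything that
  survives 25 sanitation rounds is recorded in the manifest as a logged
  coincidence; planted-recovery checks treat those windows as excluded.
  Chance *dispersed* repeats (≥ 30 bp at ≤ 3 mismatches) are improbable
  enough (~10⁻⁴ per genome) not to be sanitized. A planted tandem array is
  legitimately also visible as a self-offset forward repeat pair; feature
  accounting matches detections against all planted features.
* **Divergence** is a star phylogeny: each taxon mutates independently
  from the ancestor with Poisson substitution counts at per-region rates
  (defaults 0.010/0.015/0.002 per site for LSC/SSC/IR, i.e. the
  1 : 1.5 : 0.2 conservation ordering of real plastomes) and geometric-
  length indels; the true alignment is emitted directly, and the two IR
  copies mutate independently (no concerted-evolution model). No tree
  structure, recombination, rearrangement, or IR expansion process is
  simulated — detection floors and estimators, not realism, are under
  test, so passing these checks says nothing about alignment quality or
  annotation error in real data.
* **Codon evolution** samples ancestor codons from an RSCU profile and
  proposes uniform single-base changes at an expected `divergence`
  proposals per site, accepting synonymous changes with probability 1 and
  nonsynonymous with min(1, ω) (for ω > 1 the synonymous acceptance is
  down-weighted by 1/ω instead); stops are never introduced. Realized
  accepted counts are recorded, so estimator bias can be measured against
  the truth.

## Problem sizes used in tests and the acceptance script

Unit and acceptance tests run on a compact 53 kb plastome
(30,000 + 8,000 + 7,000 + IRa) carrying the full planted feature set, plus
one full-size 159,900 bp genome for structure/junction/repeat recovery;
divergence checks use 10–20 replicates of 3–4 taxa; selection recovery uses
100 replicates of 300-codon genes at divergence 0.3; the oracle
equivalences run on 100 × 5 kb (SSRs), 1.2–1.5 kb (dispersed, quadratic
oracle), and 500 random codon pairs (NG86). These sizes were chosen so the
whole suite completes in about a minute while every check retains enough
events to be informative.

## Known limitations

* IR detection assumes a single dominant IR pair; genomes with grossly
  degraded or lost IRs report "no IR detected" and are treated as
  non-quadripartite rather than being force-partitioned.
* The tandem finder's scores are not TRF's; only presence/coordinates of
  near-exact arrays are comparable, not counts from score-model tools.
* CAI/CBI/Fop absolute values depend on the derived reference set (see
  above).
* Reported genetic distances use pairwise deletion; alignments with very
  uneven gap structure can make pairs incomparable in different column
  sets.
* Group ω is a mean of pairwise NG86 estimates, not a likelihood model;
  no significance testing is attached.
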