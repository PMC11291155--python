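# Methods

This note documents the models behind each pipeline stage, the defaults
that matter, what the synthetic data does and does not emulate, and the
design choices made where more than one reasonable convention exists.

## Coordinates and alphabet

All positions are 1-based and inclusive on the mature reference sequence:
"C12" is the 12th nucleotide. Canonical (Sprinzl) tRNA numbering is
deliberately not implemented — synthetic references are constructed so that
the acetylation site falls at mature position 12, and every downstream
table reports mature coordinates. Sequences are stored as DNA (U→T on
input) so pileups and codon tables share one alphabet; codons may be
written with U in prose but comparisons are always on DNA. Alignments are
single-end and forward-strand; a SAM subset (M/=/X/D, plus I and S which
consume no reference) or an equivalent four-column TSV is accepted, and
soft clips are ignored for pileup purposes.

## Probing chemistry model and site calling

A modified site is described by three numbers: the stoichiometry *s*
(fraction of molecules modified) and, conditional on modification, the
probability of an RT stop *p*<sub>stop</sub> and of a C→T
misincorporation *p*<sub>mis</sub> (*p*<sub>stop</sub> + *p*<sub>mis</sub>
≤ 1; the remainder reads through silently). A stop emits a read whose
leftmost aligned position is site − 1: the physical geometry of a
truncated cDNA is ambiguous, but the measured coordinate — read starts one
base 5′ of the site — is not, so the simulator encodes the measurement
convention directly. The untreated control carries the same uniform
per-base error rate but no modification channels, since mock treatment
leaves sequencing error as the only first-order artifact. Expected
misincorporation rate at the site is therefore
*s* · *p*<sub>mis</sub> / (1 − *s* · *p*<sub>stop</sub>) — the denominator
because stopped molecules never present a base at the site. The defaults
*p*<sub>mis</sub> = 0.5, *p*<sub>stop</sub> = 0.2 are test placeholders on
the order of observed RT behaviour, not measured constants; every test that
depends on them sets them explicitly.

Calling conventions:

- Misincorporation denominator is total base-presenting coverage, not
  C+T only: this reads "C→T misincorporation rate" as a mismatch rate and
  is robust to stray non-T errors.
- Significance is a two-sided Fisher exact test of T vs non-T counts,
  treated against control. Counts at tRNA scale are small enough for an
  exact test, and Fisher has a trivial enumeration oracle used in the test
  suite. Whether the comparison should instead be against a global
  background error model is an open choice; treated-vs-control is
  implemented.
- Multiple testing is Benjamini–Hochberg across all tested C positions in
  the run.
- p-values are floored at the smallest representable positive double
  (≈ 4.9e−324) instead of being reported as 0.
- Fold RT stop normalises start counts by total library depth (not local
  coverage). Control starts = 0 with treated starts > 0 returns the
  sentinel 100 exactly; both zero returns 1 (no evidence in either
  direction).
- Filters: coverage strictly greater than 100 in both libraries (a
  position below that is not tested at all), misincorporation ≥ 2%,
  q ≤ 0.05, and treated rate strictly above control. The CCG-context flag
  is annotation only and not a filter, because sites outside the consensus
  are informative as likely artifacts.

## tRNA quantification

Assignment is ungapped: each read is slid along each reference, the
Hamming distance at the best offset is taken, and mismatches at masked
(modified) positions cost 0. Ungapped matching keeps the model honest for
mature tRNAs (short references, near-full-length reads) and admits an
exhaustive brute-force oracle over every (read, reference, offset) triple,
which the test suite uses. Ties split the read equally among co-minimal
references; distance beyond the budget (default 2) discards it. The
quantification unit is the isodecoder (distinct mature sequence); an
anticodon-family rollup is provided for reporting. Differential abundance
uses pseudocount 0.5 for proportions and fold changes only — the test
statistic (two-proportion z on raw counts) never sees pseudocounts. With
one isodecoder depleted 4-fold among 20, the proportion-based log₂ fold
change is −2 plus a small renormalisation term (≈ +0.05 at these sizes),
which is why recovery is asserted as −2 ± 0.3.

## Footprint occupancy

A-site offsets default to {28: 12, 29: 12, 30: 13} nt for monosomes and 45
nt for 59–63 nt disome footprints (the leading, stalled ribosome of the
collided pair). These follow common ribosome-profiling practice; they are
config-overridable and any unlisted length is rejected with a counter.
A-site codon = ⌊(start − 1 + offset)/3⌋ + 1; P and E are the two codons
5′ of it; footprints whose E index < 1 or A index beyond the last codon
are rejected.

Occupancy excludes the first 15 and last 5 codons (initiation/termination
artifacts, standard practice) and transcripts with fewer than 64 reads in
the included region. Per transcript, density at codon *i* is reads over
the mean reads per included codon, so included densities average exactly
1; occupancy per codon identity is the **unweighted** mean over
occurrences (not read-weighted), which keeps the hand oracle unambiguous.
Occupancies are pure footprint densities, not normalised against an
RNA-seq library. Meta-codon profiles average the same density vectors over
every occurrence of the centre codon whose full ±30-codon window (units:
codons) fits in the included region.

The footprint simulator draws a transcript proportional to length
(a uniform per-codon baseline — expression weighting can be layered by
duplicating records), a length from the configured weights, and an A-site
codon proportional to the dwell multiplier among positions eligible for
that length; the 5′ end is then placed so the offset table recovers the
A-site exactly. It does not simulate nuclease raggedness, ligation bias,
or sub-codon periodicity noise, so offset learning cannot be tested
against it — only occupancy statistics given correct offsets.

Translation efficiency is footprint proportion over mRNA proportion with
pseudocount 0.5, classified at |Δlog₂ TE| ≥ 1. Because TEs are built from
proportions, a shift concentrated in a large fraction of the library moves
every other transcript's TE; classification accuracy claims hold for
perturbations that are small relative to the library.

## Codon bias

Codon fractions are per-transcript-averaged by default (each transcript
contributes equally); pooled fractions over concatenated coding sequence
are available separately. Both the all-sense-codon and the
within-family denominator are exposed for group content, since "combined
codon content" is ambiguous between them. Group comparisons use the
classical pooled-variance two-tailed Student's *t* (the stricter reading
of "Student's t test"), with the usual star convention. Dipeptides are
counted with overlap. The background set is unweighted by expression.
Wobble decoding applies Watson–Crick pairing at anticodon positions 35–36
and, at position 34, Watson–Crick plus G:U and U:G wobble plus inosine
pairing with U/C/A. Note that with U:G wobble admitted, an anticodon with
U34 formally decodes any codon ending in G — e.g. both CAU and UAU decode
AUG under the bare pairing table; biological restriction of such pairings
involves position-34 modification states that this table intentionally
does not model. The table is validated against brute-force enumeration of
all 5³ anticodons.

## Cross statistics

Independent assortment is assumed (the two loci of interest lie on
different chromosomes in the motivating system; linkage is not modelled).
Expectations are products of per-locus transmission probabilities;
goodness of fit is Pearson chi-square over categories with positive
expectation, with a warning recommending an exact test when any expected
count falls below 1. Cross-background comparison of a target genotype is a
Fisher exact test for two backgrounds and chi-square for 2×k. The cross
simulator draws gametes independently per locus and applies per-genotype
viability to each conceptus, returning both surviving and conception
counts.

## Problem sizes and tolerances in the test suite

Simulation scales were chosen so that expected sampling error is several
times smaller than the asserted tolerance: probing recovery at 10,000×
coverage (binomial SE ≈ 0.005 against a ±0.02 band); false-positive
calibration on 1,000 null C sites at 300× with 1% error; dwell recovery at
200,000 footprints over 40 × 300-codon transcripts (±15% on the shifted
codon, ±10% elsewhere); the uniform-dwell null at 10⁶ footprints (±0.05);
isodecoder depletion at 50,000 reads over 20 isodecoders; chi-square
calibration over 1,000 crosses of 160 offspring (rejection rate 5% ± 2%).
Deterministic identities (normalisation to 1, partition identities, exact
sentinels) are asserted at 1e−9 or tighter. All stochastic tests are
seeded and deterministic.

## Known limitations

- No raw-read alignment: both probing and footprint stages consume
  pre-aligned input (SAM subset or TSV).
- No modelling of 5-formylcytidine cross-reactivity, rRNA acetylation,
  paired-end or reverse-strand data, or pre-tRNA genomic coordinates.
- The isodecoder quantifier is deliberately simpler than full
  EM-based tRNA quantification tools: no indels, no cluster remapping,
  no stop-aware modelling, no charging-state estimation.
- Synthetic data covers the measurement conventions, not library
  artefacts (UMIs, adapters, structure-dependent RT behaviour), so green
  tests certify the statistics, not robustness to real library noise.
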