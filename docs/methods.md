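# Methods

This note documents the models and numerical choices behind `sasiseq`: what
each component assumes, which parameters matter and why their defaults are
what they are, what the synthetic-data generator does and does not emulate,
and where the design was genuinely open.

## Barcode code design

Barcodes are words of length L over {A,C,G,T}. The design goal is a set of
n words whose minimum pairwise Hamming distance is at least d; with
bounded-radius decoding at radius r = ⌊(d−1)/2⌋ the correction balls of
distinct codewords are disjoint, so decoding is unambiguous and a read
needs at least d − r substitutions in the index before it can be assigned
to a different barcode. The production profiles are `384x11_d5` (r = 1
correction, 3-error detection, 4 errors to misassign), `384x9_d4` and
`96x8_d4`.

**Search.** The designer enumerates all 4^L candidates (L ≤ 12), filters
them by composition constraints, permutes them with a seeded RNG, and
accepts greedily every word at distance ≥ d from all words accepted so far
(a lexicode over a shuffled order). Distance checks are vectorized through
one-hot encoding and a matrix product (distance = L − matches), with a
chunked prefilter so the Python-level loop only compares candidates against
words accepted within the current chunk. The search stops at the target
count, making the output a deterministic function of (L, d, target,
constraints, seed); exhaustion below target raises an error that carries
the partial set rather than silently truncating. At (11, 5) the greedy
search reaches 384 words within the first ~1% of the permuted space, in
roughly a second.

**Composition constraints.** GC fraction in [0.25, 0.75] and homopolymer
runs ≤ 3 by default — ordinary synthesizability/sequencer-friendliness
conventions of this package, not claims about any published set; they are
fully configurable and disabled (`DesignConstraints.none()`) for
code-theoretic work, including the shipped acceptance computations.
Fixed-suffix conventions (e.g. reserving the base adjacent to the adapter)
are expressible through forbidden prefixes/suffixes.

**Decoding.** An observed index word is `perfect` if it equals a codeword,
`corrected` if exactly one codeword lies within the correction radius,
`unassigned` if none does, and `ambiguous` only when the set itself
violates d ≥ 2r + 1. Non-ACGT characters (N) count as a mismatch to every
base — uncertainty is never converted into a confident call. The batch
decoder uses the same one-hot matrix product as the designer; a
brute-force nearest-codeword scan serves as its oracle in the tests.

**Misassignment probability.** Under an iid substitution channel with
per-base rate p (uniform over the three alternatives), the probability
that the channel output of codeword c lands inside the correction ball of a
*different* codeword is computed exactly: the balls of all competitors are
enumerated, deduplicated (so overlapping balls in malformed sets are not
double counted), and each word's channel probability (p/3)^k (1−p)^(L−k)
is summed by its distance k from c; the result is averaged uniformly over
true codewords. For the 384 × 11-mer d = 5 set at p = 0.01 this gives
6.9 × 10⁻⁹. An exhaustive enumeration over all ≤ 3-substitution
perturbations of every codeword (1,913,472 words) confirms that none
decodes to a wrong barcode — the geometric floor of 4 errors is not just a
pairwise-distance consequence but holds word-by-word.

## Spike-in construction

The three amplicons derive from primers against the PhiX174 control genome
(a sequence deliberately absent from real samples): three forward primers
share one reverse primer, giving nested products of 214, 397 and 568 bp.
In-silico PCR is exact-match only — the primers match their reference
perfectly, and published primer coordinates are treated as derived outputs
rather than inputs (printed positions in the source material are mutually
inconsistent by one base, so the sequence is authoritative). Zero or
multiple matches and mis-oriented sites raise named errors.

Tagging prepends the barcode to the amplicon 5′ end (`forward_only`, the
default, matching the multiplexed-experiment design) or additionally
appends its reverse complement at the 3′ end (`both_ends`). Nextera flanks
add the fixed 33/34 bp transposase adapter sequences so fragments amplify
in Nextera-style PCR. The three same-barcode fragments form a set mixed
equimolar (1:1:1 molecules); mass-based dosing is converted to molecule
counts in the simulator using molar weight proportional to length.

**Dosing arithmetic.** At fixed lane yield, expected spike-in reads per
sample = reads_per_lane / plex × mass_fraction; holding that constant makes
the dose scale linearly with plex (0.1% at 96-plex ↔ 0.4% at 384-plex).
The default 0.1% dose at ~10⁶ reads/sample puts ~1000 spike-in reads in
each dataset — the operating point at which 1% relative contamination is
reliably detectable (below).

## Library simulation

The generator emulates, at desk scale, the path of a spiked sample through
library preparation:

* **Material.** One genome molecule (default synthetic, 1 Mb in the shipped
  computations) plus spike-in fragments at the dosed mass fraction. Each
  spike-in fragment is materialized `sasi_copies` (default 100) times with
  weights scaled down accordingly, so shearing and size-selection outcomes
  are ensemble-averaged instead of hinging on a single stochastic
  realization of a sub-molecule weight. Read sampling is proportional to
  molecule weight (molar), as on a flow cell.
* **Shearing.** Breakpoints are placed by a Gamma renewal process: cut
  spacings iid Gamma with mean equal to the target size and coefficient of
  variation `dispersion` (default 0.5, a typical spread for focused
  acoustic shearing). This yields fragment lengths unimodal around the
  dialed mean — the defining behaviour of acoustic shearing — rather than
  the size-zero mode of a uniform-breakage (Poisson process) model, which
  we found under-retains genomic fragments in a 200–600 bp window and
  consequently inflates the simulated spike-in read share ~1.7-fold over
  the dose. Short molecules rarely receive a cut; long ones are cut into
  ~length/mean pieces; children partition the parent exactly, so bases are
  conserved to the base. The longer spike-in amplicons are therefore more
  susceptible to breakage (at mean 300: ~45% of the 225 bp tagged fragment
  survives intact vs ~2% of the 579 bp one), and survival increases with
  the shear mean.
* **Size selection.** A hard window (lower ≤ length ≤ upper) or a logistic
  retention roll-off of scale `edge_steepness` bp at each edge.
* **Sequencing.** Reads sample fragments with replacement ∝ weight; read 1
  is the fragment 5′ prefix, read 2 the reverse complement of the 3′
  suffix, both truncated at the fragment end; the index read is the library
  barcode. Every emitted base passes independently through the substitution
  channel (default 1%). Qualities are constant (the screen ignores them).
  Output is 4-line phred+33 FASTQ (R1/R2/I1), byte-identical across reruns
  with the same seed; per-stage seeds are spawned from the experiment seed.
* **Events.** Contamination mixes the source sample's material — genome and
  its spike-ins — into the recipient at the stated relative fraction before
  shearing. Swaps transpose two tubes *after* spiking: spike-in tags follow
  the sample material, library barcodes follow the tube, which is exactly
  what makes swaps detectable downstream. A truth table records every
  read's tube, material sample, molecule origin and event provenance.

**What the generator does not emulate:** quality-score structure, indels,
PCR amplification bias and chimeras, GC bias, optical duplicates, adapter
read-through, and enrichment capture. Passing tests therefore demonstrate
the method's logic and its statistical operating points under
substitution-only error, not robustness to those artifacts on real data.

**Count-level mode.** For power studies, spike-in read counts are drawn
directly: own-barcode counts ~ Binomial(reads, dose) and foreign counts ~
Binomial(reads, dose × relative_fraction), skipping base-level simulation.

## Screening

Reads are matched to the amplicon bodies with exact 21-mer seeds (tried
every 7 bases along the read, in both orientations) and Hamming extension
along the seed diagonal, accepting alignments with mismatch fraction ≤ 0.1
— sufficient under substitution-only error and free of aligner
dependencies. The similarity threshold is a package choice (no published
value exists) and is exposed in `ScreenConfig`. Terminal barcodes are
extracted at their expected offset upstream of the amplicon start and
decoded with single-error correction. A read pair is **intact** evidence
when the tagged 5′ terminus (with a decodable barcode) and the opposite
terminus are both observed within 2 bp slop; **broken** with exactly one
tagged terminus (the shearing signature); **internal_only** otherwise.
Reverse-terminus hits carry no barcode in `forward_only` mode and are
tabulated under matrix column 0, which the identity verdicts ignore but
conservation checks include (so each row margin equals that sample's total
spike-in reads). On simulated data at 1% error, ≥ 95% of reads from intact
spike-in molecules are recovered with the correct barcode, and no hit
carries a wrong barcode id in the shipped tests.

## Verdicts, swaps, contamination

* **Identity.** A sample is `confirmed` when its registered barcode(s) hold
  the row maximum of the assurance matrix and the attributed row margin is
  ≥ `min_reads` (default 10 — at the ~1000-read operating point this
  suppresses singleton noise without costing sensitivity); `low_evidence`
  below that floor; `swapped` when the maximum belongs to another sample's
  barcode; `unidentified` when it belongs to no registered barcode;
  `contaminated` when the expected barcode dominates but foreign registered
  barcodes carry ≥ 0.5% of the row. The contamination trigger is a
  fraction, not a count, so verdicts are invariant to row scaling.
* **Swaps.** Each sample maps to the sample that registered its
  row-maximum barcode; the non-trivial cycles of this best-match mapping
  are reported — 2-cycles for simple transpositions, longer cycles for
  multi-sample permutations.
* **Contamination.** For each foreign barcode with a non-zero count,
  estimated relative contamination = foreign / (own + foreign) over the
  attributed row, rescaled by the recipient/source dose ratio when doses
  differ (the estimator assumes equal dosing otherwise). A call is above
  background when the count reaches `min_foreign_reads` (default 3) and
  exceeds the 99.9% quantile of a Poisson background whose rate is pooled
  as the **median** of the same barcode's counts across the other rows
  where it is foreign — the median rather than the mean so that rows
  carrying genuine contamination do not inflate the noise floor and mask
  smaller events. Multiple testing across foreign cells is handled by the
  fixed count floor rather than FDR: decisions are per-cell with strong
  priors, and the floor is configurable. At ~1000 own reads/sample this
  flags 10% and 1% relative contamination in every replicate while 0.1%
  (expected count ≈ 1) is not reliably flagged — the detection floor is 1%,
  and scales with dose.
* **Oligo contamination vs drift.** Reads attributed to an absent barcode
  are classed `contamination` when perfect matches outnumber one-mismatch
  (corrected) hits, `drift` in the opposite case, `inconclusive` on ties or
  totals below `min_total` (default 10): physical contamination introduces
  the true sequence, sequencing drift arrives via single errors from
  neighbouring codewords.
* **Combinatorial registration.** Dosing two spike-in sets per sample gives
  C(n, 2) registrations (4560 at n = 96; 73,536 at n = 384); only an exact
  registered pair identifies a sample, and subset/superset/unknown
  detections fail loudly with the offending ids.

## Numerical and scale choices

The shipped computations use a 1 Mb synthetic genome, 10⁵ read pairs per
library and 10 seeds for the dose-conservation measurement, and 10⁶
count-level reads per sample for the titration — sizes at which the
measured quantities are stable to a few percent while the whole acceptance
run completes in well under a minute. Degenerate inputs fail loudly:
empty pools, zero-length windows, contradictory constraints, unknown event
references and malformed FASTQ records all raise typed errors naming the
offender. All randomness flows through explicit integer seeds
(numpy `default_rng`; per-stage seeds spawned via `SeedSequence`), and
identical seeds give byte-identical artifacts.

## Known limitations

* The in-silico PCR is exact-match; primer mismatches/degeneracy are out of
  scope. The shipped worked example uses a synthetic reference carrying the
  canonical primer sites (the true PhiX coordinates require downloading
  accession NC_001422.1).
* Quantitative intact-fragment percentages depend on acoustic-shearing
  physics that no public parameterization captures; the package asserts
  only their ordering (longer amplicons break more; gentler shearing leaves
  more intact), which is robust to the shear model's dispersion parameter.
* Hamming distance throughout: indels in the index read are not corrected
  and will generally unassign the read.
* The contamination estimator assumes spike-in reads scale linearly with
  dose and material fraction; strong enrichment or extreme size selection
  can bias it low (spike-in representation after tight selection drops
  below the dose while remaining detectable).
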