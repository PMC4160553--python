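# Methods

## Scope and model

`estssr` quantifies simple sequence repeat (SSR) content in transcript
(EST) collections, separately for the 5′UTR, ORF and 3′UTR of each
sequence, and compares it across genera. The unit of counting is the
*event*: either one perfect repeat locus or a compound chain of loci
whose neighbours lie closer than the compound spacer. All coordinates
are 0-based half-open internally; rendered reports are the only place a
1-based convention could appear, and they keep half-open spans with a
`start0` column to avoid ambiguity.

## Repeat detection

A perfect SSR locus is a tandem array of complete copies of a primitive
unit of length 2–10 bp reaching the class minimum (dimer 10, trimer 7,
tetramer 5, pentamer 4, hexamer 4, heptamer 3, octamer 3, nonamer 3,
decamer 2). Two consequences of this parameterization are load-bearing:

* every admissible locus spans at least 20 bp (class I repeats); the
  bound is attained by dimers, tetramers, pentamers and decamers;
* mononucleotide repeats can never surface, because homopolymer units —
  and any other unit that is itself a repetition of a shorter word, such
  as "ATAT" read as a tetramer — are non-primitive and rejected. This
  makes a separate mononucleotide filter redundant, though the flag
  exists for configurations that relax primitivity.

**Run semantics.** "Maximal tandem array" underdetermines the output
when a periodic region supports complete-copy runs in several phases:
`CATATATAG` contains both `[AT]₃` at 1–7 and `[TA]₃` at 2–8, equal in
copy number, neither extendable. The scanner therefore pins the
semantics to the *leftmost-greedy tiling*: per unit length, scanning
left to right, the first position (at or past the end of the previous
run) where two or more complete copies of an admissible unit begin opens
a run, which takes as many complete copies as the sequence supports.
Runs of one unit length then never overlap, the output is unique, and
partial trailing units extend neither span nor count — consistent with
the `[TA]n` notation in which repeat counts are conventionally reported.
The production scanner implements this with vectorised period-k match
arrays (`s[i] == s[i+k]`) whose maximal true stretches are exactly the
periodic regions; an independent oracle (`brute_force_oracle_scan`)
implements the same semantics by naive substring comparison, and the
test suite requires exact agreement on randomized and adversarial
inputs.

**Overlap resolution across unit lengths.** A locus whose span is fully
contained in another reported locus is suppressed (longer span wins;
span ties go to the smaller unit, then leftmost). Partially overlapping
loci of different unit lengths are both reported. Under the default
class minima, Fine–Wilf periodicity arguments make genuine containment
between primitive-unit loci essentially impossible, so the rule mostly
matters for permissive configurations — it is still implemented and
tested so the output stays well defined for any configuration.

**N handling.** Sequences are uppercased on ingest; N terminates every
run; any character outside A/C/G/T/N rejects the record (the pipeline
logs the id and continues).

**Compound events.** Consecutive loci with an inter-locus gap strictly
below 100 bp are chained transitively into one compound event. The
bound is exclusive: a 99 bp gap merges, a 100 bp gap does not. Compound
events count once in event densities; each member locus contributes to
the motif-size and motif-class composition tables, whose totals are
therefore member-level. Both tallies appear in the JSON summary
(`counts_per_mbp` vs `member_counts_per_mbp`) because the counting unit
of published per-motif tables is not always stated.

## Canonical motif classes

Units that are cyclic rotations of one another, or rotations of the
reverse complement, denote the same repeat array read in a different
phase or from the other strand; they form one canonical class named by
the lexicographically smallest member. Exhaustive enumeration gives 4
dimer classes (AC, AG, AT, CG) and 10 trimer classes. Note that plain
*reversal* is not an equivalence move: GCA is a rotation of AGC, not of
ACG, and merging the ACG and AGC classes (as informal equality chains
sometimes do) would leave only 9 trimer classes, inconsistent with the
10 rows of standard trimer composition tables.

## ORF calling and partitioning

Each EST is scanned in all six frames for ATG→stop spans (stop
included); the longest one at or above `min_orf_bp` (default 90 bp) is
taken as the coding region, ties resolved toward the forward strand and
then the leftmost start. Reverse-strand winners flip the sequence, so
all downstream coordinates are forward-coding. The flanks become 5′UTR
and 3′UTR; repeats are scanned per fraction sub-sequence, so a repeat
straddling a boundary is truncated at it by construction. Sequences
with no qualifying ORF are labelled UNPARTITIONED: they are scanned and
reported at the locus level but excluded from fraction-wise densities,
and counted in the run log. The 90 bp default (30 codons) is a common
floor for distinguishing genuine coding regions from chance ORFs in
short reads; full gene-prediction models are out of scope, and external
GFF3/BED CDS annotations are accepted as a drop-in replacement for the
heuristic (longest span per sequence wins, mirroring the same rule).

## Redundancy clustering

An optional pre-stage approximates the standard greedy-incremental
clustering used to de-duplicate EST sets: sequences are visited longest
first and join the first representative with identity ≥ 0.90, else
found a new cluster. Identity is the matched-column fraction of a
semi-global alignment of the shorter sequence within the longer
(edit-distance alignment; match 1, mismatch 0, unit gap cost), after an
8-mer prescreen that reports unrelated pairs as below-cutoff without
aligning. This deliberately follows the shorter-sequence identity
convention so a contained fragment clusters with its container; it does
not replicate short-word statistics of specialised tools, and it is off
by default for inputs that are already non-redundant.

## Statistics

* **Heterogeneity across fractions:** Pearson χ² (no continuity
  correction) on a 2×3 table of bp inside SSR loci vs bp outside, per
  fraction, df = 2. Basing rows on base pairs rather than event counts
  makes both rows well-defined counts with fraction sizes as margins;
  the statistic is 0 exactly when the three repeat-bp proportions are
  equal, and invariant to column order.
* **Length comparison:** Tukey's HSD between fraction length samples.
  By default observations are replaced by global midranks first, which
  makes the comparison non-parametric in the same sense as rank-based
  ANOVA; the classic test on raw lengths is available via
  `use_ranks=False`. Pairwise adjusted p-values come from the
  studentized-range distribution (statsmodels); tests cross-check them
  against scipy's independent implementation to 4 decimals.
* **Genome-size association:** Pearson r between genome size (1C, pg)
  and a per-genus metric (mean repeat length or density) in a chosen
  fraction; two-sided p via the t transform with n−2 df. Degenerate
  inputs (constant metric, fewer than 3 genera) raise rather than
  returning NaN.
* Length dispersion is the sample SD (n−1); with fewer than two member
  loci it is reported as not available rather than zero.

## The simulator

The generator emulates the statistical structure the analysis assumes,
not transcriptome realism. Each synthetic EST is assembled as
5′UTR + ORF + 3′UTR in forward-coding orientation:

* **Backgrounds** are i.i.d. bases at the spec's GC content,
  rejection-resampled until the scanner finds no threshold-passing
  locus. Precision/recall against the manifest are therefore exact
  quantities, not probabilistic ones. ORF backgrounds are uniform
  stop-free codons (GC ≈ 0.51 regardless of the spec's GC — coding
  regions are not GC-tunable in this generator).
* **The ORF** is ATG + stop-free codons + stop. A 12 bp triple-frame
  stop barrier (`CTAACTAACTAA`, no G, no ATG) ends the 5′UTR so no
  upstream start can read through; with UTRs shorter than the ORF this
  makes the planted ORF the unique longest ORF, which the generator
  verifies by running the ORF caller on every sequence (and again on
  the flipped sequence for antisense records), regenerating on the rare
  failure.
* **Events** are planted per fraction at Poisson counts matching the
  target density (events/Mbp of fraction length), mutually separated by
  more than 100 bp so planted events never merge with each other.
  Compound events carry two members of distinct canonical classes with
  a spacer drawn below 100 bp. Guard characters at block junctions
  prevent the background from extending a planted array by a unit or a
  phase shift. Event plans are drawn once per sequence, independent of
  assembly retries, so verification failures cannot select against
  event-rich sequences (unmitigated, that selection biases recovered
  densities low by 1–3%). In the ORF, planting is codon-aligned with
  unit lengths divisible by 3 and a repeat phase whose in-frame codons
  are stop-free — the frame constraint that shapes real coding-region
  repeats — so the ORF class composition is the spec's weight map
  conditioned on trimer/hexamer/nonamer classes.
* **Orientation stress:** a configurable share of sequences (default
  0.3) is emitted reverse-complemented; ground truth stays in
  forward-coding coordinates and the pipeline must re-orient.
* Every fraction is verified after assembly: the scanner must report
  exactly the planted loci. Assembly is retried with fresh backgrounds
  (bounded attempts) on failure; an infeasible density/separation
  combination raises instead.

The presets sketch two regimes seen in plant EST studies — an
"angiosperm-like" profile (GC 0.50, UTR-dense: 900/400/600 events per
Mbp across 5′UTR/ORF/3′UTR, AG-rich dimers, genome 0.6 pg) and a
"gymnosperm-like" one (GC 0.42, 3′UTR-dominant: 280/200/380, AT-rich
dimers, genome 15 pg). They are demonstration profiles, not reproductions
of any published table. Repeat counts are class minimum + Geometric(0.6)
− 1, capped at minimum + 10, giving mean locus lengths around 22–28 bp.

What passing simulator-based tests does **not** show: robustness to
sequencing error, interrupted (imperfect) repeats, chimeric reads,
expression-level effects, or UTR/ORF misannotation in real data — none
of which the generator models.

**Recovery matching** uses ≥ 50% reciprocal span overlap on the
oriented sequence; with exact recovery the convention questions (best
overlap ties, one-to-many matches) never bind. With zero detections
precision is reported as 1 with an explicit flag.

## Problem sizes in bundled checks

The test suite and acceptance script size their simulations to keep the
statistical claims meaningful at desk scale: oracle equivalence on
~1,200 randomized sequences of 20–500 bp; the 20 bp length bound over
10,000 short oracle-scanned sequences; exact recovery over 3 seeds × 2
presets × 40 sequences; density estimation on one genus of 12,500
sequences (~37 Mbp, ≥ 10 Mbp per fraction), where planted densities of
500/300/450 events per Mbp are recovered within 5% relative error; and
byte-level determinism on two identical pipeline runs.

## Known limitations

* Only perfect repeats are modelled; interrupted single-motif repeats
  are out of scope (a compound event is the only representation of
  near-adjacent repeats).
* The longest-ORF heuristic can mislabel UTRs on transcripts whose true
  coding region is not the longest ORF; external annotations are the
  faithful alternative.
* The clustering stage approximates, but is not, CD-HIT; identity
  values near the cutoff can differ from specialised tools.
* Densities in fractions with very little sequence are noisy; the JSON
  bundle reports raw totals so consumers can apply their own floors.
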