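# Methods

## Scope and data model

The package analyses adaptor-trimmed small-RNA reads against consensus-level
references: TE family consensuses, protein-coding transcripts, a miRNA set
and an rRNA set. All coordinates in the public data model are 1-based and
inclusive on the consensus plus strand; for a minus-strand alignment the
read's 5′ end is the `end` coordinate. piRNA species are alignments
collapsed by (strand, 5′, 3′) with multi-mapper-apportioned weights summed.

## Reference handling

Redundant TE consensuses are collapsed into family groups by global pairwise
alignment (match +1, mismatch −1, gap −2, terminal gaps free). Identity is
matches over aligned columns excluding terminal-gap columns; coverage is the
fraction of the shorter sequence inside the non-terminal-gap core. Two
consensuses join one family when identity > 0.90 and coverage > 0.90 (strict
inequalities), and groups are single-linkage connected components, which
makes the partition order-independent; the representative id is the
lexicographically smallest member. Columns containing N count against
identity — a conservative, deterministic choice. Whether the original
redundancy screen used local or global alignment is not documented anywhere
we know of; free-end-gap global alignment was chosen because it matches the
"identical across most of their length" notion while remaining checkable
against a plain dynamic-programming oracle.

## Alignment

Reads are placed ungapped and end-to-end on both strands with at most
`max_mm` (default 2) Hamming mismatches; N never matches. All qualifying
placements are reported by default, because apportioning divides a read over
every place it *can* align; `best_stratum=True` restricts to
minimum-mismatch placements for users who want Bowtie-best-like behaviour.
The search is pigeonhole seed-and-verify: any placement with ≤ m mismatches
contains an exact k-mer block with k = ⌊L/(m+1)⌋, so looking up the m+1
disjoint blocks in an exact k-mer index enumerates every candidate offset,
each verified by a vectorised Hamming count. This is complete, not
heuristic; reads containing N fall back to a full scan. A palindromic
double-hit at one locus on both strands would count as two alignments
(deterministic, and vanishingly rare at 23–30 nt). SAM import/export uses
pysam with NM for mismatches and XW for apportioned weights.

## Quantification

Size classes are inclusive: 23–30 nt piRNA candidates, 18–22 nt miRNA
candidates. rRNA-matching reads are removed at the piRNA mismatch
allowance. The miRNA total counts each matching read once regardless of
multi-mapping and defaults to 0 mismatches (miRNA references are near-exact;
a nonzero allowance would absorb degradation products); it is configurable.
Family counting applies the once-only rule: a read whose placements all fall
in one family group contributes one count, assigned to the strand holding
the majority of its alignment weight (a tie splits 0.5/0.5, preserving the
conservation identity counted + discarded + unaligned = input reads); reads
spanning two or more groups are discarded. A weighted mode that sums
apportioned weights per (group, strand) is available behind a flag.
Normalized counts are raw / miRNA-total × 10⁶ — the fixed per-million scale
changes no ratio but keeps magnitudes readable. The low-count filter drops a
family unless its mean raw count reaches 50 in at least one genotype
(mean = 50 is retained; "below 50" is read strictly). Fold-change classes
use strict thresholds (2-fold TE, 1.5-fold gene); with the default
pseudocount of 0, x/0 is +∞ ("up") and 0/0 is NA.

## Signatures

ppf, d1 and u1 are defined in the README. Numerical notes:

* The ping-pong partner window is o ∈ [1, 30] — an offset beyond the
  maximal piRNA length cannot be a 5′ overlap; configurable
  (`pp_max_offset`).
* The ppf denominator includes every species of the family on both strands,
  including species with no partners (their f = 0).
* d1 pair weighting is the product wᵢ·wⱼ over ordered same-strand pairs at
  distances 1–22; computed on species-level weight arrays indexed by
  coordinate, which is algebraically identical to enumerating read pairs
  and far faster. An alternative per-focal normalization is not offered at
  species level because the product form is the one that matches read-level
  sampling frequency.
* u1 excludes species whose +1 position falls off the consensus or is N.
* A family with zero supporting weight reports NaN for the affected
  signature, and NaN pairs are dropped from paired tests (pairwise
  deletion).

Genotype contrasts average replicates within genotype per family, then run
the paired two-sided Wilcoxon signed-rank test: zero differences dropped,
tied magnitudes mid-ranked, exact null for n ≤ 25 without ties, otherwise
the tie-corrected normal approximation with continuity correction.

## Statistics

Sign and binomial tests are exact and two-sided by tail doubling,
p = min(1, 2·min(P(X ≤ k), P(X ≥ k))); implementations differ on this
convention, so the minlike (point-probability summation) alternative is
exposed via `method="minlike"`. The 2×2 chi-square applies the Yates
continuity correction by default (`yates=False` available) and requires
positive margins. The auto-immunity analysis takes per-gene
rescue-vs-mutant log2 fold-changes for two transgenes, calls down/up at
>1.5-fold, and reports per-transgene binomial tests, a 2×2 chi-square of
down-counts between transgenes, down-set overlaps, and sign tests on the
between-rescue expression and genic piRNA fold-change directions, the
latter restricted to genes whose mean antisense piRNA count exceeds 50
(strictly) in at least one genotype. Significance-filtered gene calls from
an external differential-expression tool can be reproduced by pre-filtering
the input tables; the package itself classifies by fold change only.

## Synthetic data generator

The generator emulates the features the signatures detect, with exact
ground truth:

* **Background**: reads with uniform 5′ placement, strand antisense with
  probability `antisense_frac` (default 0.7 — TE piRNAs are predominantly
  antisense), lengths uniform on 23–30 nt.
* **Ping-pong**: an antisense read acquires a sense partner whose 5′ end
  sits at the 10-nt overlap register with probability `pp_rho`.
* **Phasing**: with probability `phase_frac` an event emits a trail of
  `trail_len` head-to-tail reads (1-nt spacing) along the family's
  *cleavage lattice* — an ordered set of cut positions fixed at
  reference-construction time, in which the next cut is chosen among the
  23–30 nt-spaced candidates preferentially (probability `u1_bias`,
  default 0.9) at positions whose base is already U in read orientation.
  This mirrors Zucchini's preference for cleaving before uridines and, as a
  property of the *reference*, keeps phasing and +1-U structure consistent
  across every library simulated against the same reference bundle; the
  consensus sequence itself is never modified, so with `mut_rate` 0 every
  read is an exact copy of the shared consensus. (An earlier design that
  edited the consensus per pool was abandoned: each library's effective
  reference diverged, which broke multi-library runs against one FASTA.)
* **Noise and nuisance structure**: iid per-base substitution at
  `mut_rate`; `n_redundant_pairs` duplicate consensuses at 95% identity to
  exercise family collapsing; optional rRNA contamination reads; a miRNA
  pool of exact reference copies for normalization.

Randomness uses per-family substreams keyed by (seed, family, stream tag)
with a fixed per-event draw order, so raising `pp_rho` only *adds* partner
reads without moving anything else — ping-pong recovery is therefore
monotone in `pp_rho` under a shared seed, which the tests assert. Identical
(params, seed) reproduce byte-identical FASTQ. `reads_per_family` counts
generative events (a trail or pair is one event emitting several reads);
ground truth records realized per-kind and per-strand read counts, which
sum exactly to the pool size. `min_spacing` places event anchors on a fixed
grid instead of uniformly, giving isolated ping-pong pairs for which the
pipeline recovers ppf = 1.0 exactly.

What the generator does **not** model: genomic piRNA clusters and hotspot
placement (placement is uniform), transcriptional silencing feedback, TE
copy-number variation, ligation/PCR bias, and quality-score structure
(FASTQ quality is constant). Passing tests therefore demonstrate
correctness of the measurement pipeline under known generative structure,
not robustness to every bias of real libraries.

Presets bundle the study conditions: `mutant-like` (pp_rho 0, phase_frac
0), `rescue-like` (0.6, 0.3) and `weak-rescue` (0.45, 0.22), emulating a
mutant whose ping-pong/phasing collapse and rescues that restore them with
different efficiency.

## Problem sizes and expectations used in validation

Brute-force oracle equivalence runs 50 random profiles of up to 500
species at 1e-9 tolerance. Null pools (no planted structure) are checked at
50 000 reads per family: d1 → 1/22 ± 0.01 and u1 → 0.25 ± 0.02. Because u1
of a null pool tracks the realized T frequency of its consensus, these
checks use 4 000-nt consensuses over several families so that composition
fluctuation (sd ∝ 1/√(total consensus length)) is small against the band.
The mutant-vs-rescue contrast uses 20 families at 800 events per family.
The noise-recovery property (≥ 99% of reads realign to their true locus
within 2 mismatches) is checked at `mut_rate` 0.01; at 0.02 an iid model
puts ≥ 3 substitutions in ~1.5–2% of 23–30 nt reads, so 99% recovery is not
attainable there and the default `mut_rate` is 0.

## Known limitations

Pairwise identity may differ from other tools when co-optimal alignments
exist (a fixed scoring scheme and deterministic traceback are used).
The aligner is for consensus-sized references, not genomes — the k-mer
index is rebuilt in memory per run and there is no FM-index. Signature
computation keys species by coordinates within a family group; for groups
with several redundant members the members' coordinate systems are assumed
near-collinear (they are, at >90% identity), and apportioned weights from
within-group multi-mapping merge onto the shared coordinates.
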