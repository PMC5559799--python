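# Methods

This note documents the models and procedures `asmeval` implements,
the parameter choices that matter, what the synthetic-data generator
does and does not emulate, and the numerical conventions that make
results reproducible. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Quality trimming

Reads are trimmed with the modified-Mott rule: with per-base error
probability `p_i = 10^(-q_i/10)` and limit `L = 10^(-cutoff/10)`
(default cutoff Phred 20), the retained subread is the contiguous
segment maximising `Σ (L − p_i)`. A read whose best segment scores
≤ 0 trims to empty. Ties — possible only when bases sit exactly at the
cutoff — resolve to the earliest-ending segment free of zero-score
padding, so the result is a deterministic function of the qualities.
Adapter trimming is out of scope (no adapter list is modelled).

## Length metrics

N50 (N90) is the length of the contig at which the cumulative length
of contigs sorted in descending order first reaches ≥ 50% (90%) of
total assembly bases; the boundary is inclusive. Mean length is
reported to 0.01 bp, percentages to 0.01. The 300 bp minimum-length
filter is applied with an inclusive ≥ comparison.

## Read-mapping metrics

A placement parsed from SAM is accepted when
`aligned_len / read_len ≥ 0.75` and `identity ≥ 0.90`, both inclusive.
`aligned_len` sums CIGAR M/=/X, `read_len` additionally I and S, and
identity is the edit-distance proxy `1 − NM/aligned_len`. The NM tag
counts indels as well as substitutions; the aligner-internal
"similarity" the thresholds originate from is unpublished, so this
proxy is a documented decision, not a reproduction. A record without
NM has unknown identity: it is rejected and counted separately.

All three percentages use total reads (mapped or not) as the
denominator. A read is *mapped* when it has ≥ 1 accepted placement
(multi-mapped reads count once, at the highest-identity, then longest,
placement); *in pairs* when both mates' best placements share a
contig; *broken* when they are on different contigs. Mapped singletons
count toward the mapped percentage only, so
`pct_in_pairs + pct_broken + pct_singletons = pct_mapped` exactly.
Orientation and insert size are not checked — co-placement on one
contig is the pairing criterion.

## Ortholog metrics

Hit tables are the 12-column tabular dialect; parsing is strict
(exactly 12 columns, fail-loud with line numbers). Minus-strand
nucleotide queries (qstart > qend) are normalised by swapping and
recording strand, so span arithmetic can assume qstart ≤ qend.

Best hits keep, per query, the hit with maximum bitscore; ties resolve
by minimum e-value, then longest subject span, then lexicographically
smallest subject id. Because this chain is a total order, the result
is invariant to input row order and idempotent. The e-value cutoff
(default 1e-5) applies to both search directions equally.

RBH pairs are mutual best hits; the result is a matching (each contig
and each protein at most once). OHR divides the best hit's span on the
ortholog (`send − sstart + 1`, amino acids) by the ortholog length.
The span-based numerator — rather than contig length / 3 — is the
deliberate reading: a UTR-bearing full-length contig then scores
exactly 1 instead of systematically exceeding it. Multiple HSPs per
pair are not merged; the single best HSP is used (conservative and
deterministic). OHR is computed for RBH pairs only, and ≥ 0.8 counts
as near-full-length. Histogram bins are right-open except the last,
which absorbs values ≥ 1.

Core completeness: a core protein is *complete* when one hit covers
≥ 70% of its length (inclusive), *partial* when it has any accepted
hit; partial therefore includes complete, and percentages are over the
core-set size.

## Merge pipeline

Pooled multi-k assemblies are clustered greedily: sequences sorted
longest-first (ties keep input order) either join the first cluster
whose representative they match at ≥ the identity threshold (default
0.99, both strands) or found a new cluster. Identity is exact — the
best ungapped end-gap-free placement of the shorter sequence along the
longer, matched columns over the shorter length — rather than a
word-filter heuristic; at desk scale the exact comparison is
affordable and is what such heuristics approximate.

Meta-assembly repeatedly merges the pair with the longest suffix–prefix
overlap ≥ 40 bp at ≥ 90% ungapped identity (both strands), resolving
overlap disagreements with the base from the longer parent, until no
qualifying overlap remains; unmerged inputs become singletons. This
greedy longest-overlap order is a deterministic simplification of full
overlap–layout–consensus scoring and is not claimed to be equivalent
to it in general. Contigs and singletons are pooled and the 300 bp
filter applied last.

## SSR markers

Only perfect (uninterrupted) tandem repeats of primitive 2–6 bp motifs
are detected, at minimum repeat counts {2: 6, 3: 5, 4: 5, 5: 5, 6: 5};
mononucleotide runs are excluded. Runs are reported at the smallest
primitive unit (an (AT)×8 run is dinucleotide, never ATAT) and
phase-shifted reports of one run collapse to the leftmost start.
Coordinates are 0-based half-open in memory, 1-based inclusive in TSV.

The canonical motif class pairs a motif with its reverse complement
(lexicographically smaller first, e.g. GA/TC); rotations are *not*
merged, so AG/CT is a distinct class — matching how transcriptome SSR
surveys conventionally tabulate them.

Primer design is a rule system, not a thermodynamic model: length
18–24 nt, GC 40–60%, Tm 50–65 °C by the salt-free approximation
`Tm = 64.9 + 41·(GC_count − 16.4)/len`, inter-primer Tm difference
≤ 5 °C, product 100–300 bp. Windows are scanned from the locus
outward, and a locus without sufficient flanking sequence yields no
pair. Virtual PCR searches both strands of every contig exhaustively,
with 0 mismatches by default and an always-exact 3′-terminal base, and
a 3 kb product ceiling; the strictest setting makes the single-amplicon
(putative single-locus) classification conservative. Mismatch
tolerance and product window are exposed as parameters because the
original tools' settings are not published.

## Expression

The Pfaffl model: `ratio = E_t^ΔCt_t / E_ref^ΔCt_ref` with
`ΔCt = mean Ct(control) − mean Ct(treated)` over replicates, so
ratio > 1 means up-regulation under treatment. Efficiencies default to
2.0 (perfect doubling) and are configurable per gene in (1, 2].
Replicates are aggregated by arithmetic Ct mean before the formula —
the common usage — rather than averaging per-replicate ratios. Signed
fold change is ratio when ≥ 1, else −1/ratio (a bijection between
(0, ∞) and (−∞, −1] ∪ [1, ∞)).

Significance comes from a randomization test: condition labels are
permuted jointly for target and reference (each replicate keeps its
target/reference Ct pair), the statistic is |log ratio|, and
`p = (1 + #extreme) / (n_permutations + 1)`. This is a documented
stand-in for the proprietary fixed-reallocation scheme of REST-style
software, whose internals are not published. With 3 + 3 replicates
there are only C(6,3) = 20 distinct splits, so p-values are discrete
and conservative; the calibration property tested is super-uniformity
(type-I error ≤ nominal), which is the correct guarantee for a
permutation test, not agreement with a continuous uniform. P-values
are reported raw, without multiple-testing correction across genes.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of their arguments; the same seed gives
identical bytes. Fractions convert to whole pair counts by
round-half-away-from-zero so contracts are exact counts.

- *Reference genes*: ATG…stop CDSs free of internal stops (standard
  code), uniform-random UTRs of 50–250 bp, CDS lengths 300–1200 bp by
  default — typical plant mRNA scales. There is no codon-usage bias,
  paralogy, alternative splicing or expression-level structure.
- *Corrupted assemblies*: one contig per gene, a contiguous window
  retaining a `fragmentation` fraction of the transcript at a uniform
  position, optionally reverse-complemented; chimeras concatenate two
  half-windows from two genes; duplicates are exact copies. No
  sequencing-error or SNP corruption — identity-threshold behaviour is
  tested with explicitly constructed mismatches instead.
- *Alignments*: exact planted fractions of unmapped and broken pairs;
  every mapped record is fully aligned at identity 1, so acceptance
  thresholds are passed by construction. Coverage, insert-size and
  error structure are not modelled.
- *Hit tables*: coordinates are derived arithmetically from
  provenance (which codons of the source CDS a contig covers), with
  e-values strictly decreasing and bitscores increasing in covered
  length. This replaces running an aligner and makes ortholog-metric
  tests exact rather than aligner-dependent — but it also means
  homology noise (spurious hits, divergence) is absent.
- *Planted SSRs*: one locus per selected contig with flanking bases
  forced to differ from the motif's adjacent bases (guaranteeing
  maximality); accidental repeats elsewhere are broken by single-base
  edits so a scan recovers exactly the planted truth.
- *Ct tables*: `Ct = base − log_E(expression) + N(0, sd)` with control
  expression 1 and treated expression equal to the true ratio; at
  sd = 0 the Pfaffl pipeline recovers ratios to machine precision.

Consequently, passing tests demonstrate correctness of the metrics and
algorithms on inputs satisfying their stated contracts; they do not
demonstrate robustness to aligner idiosyncrasies, sequencing error or
biological confounders, which real data add on top.

## Problem sizes and tolerances

The test suite and acceptance script run at desk scale, chosen so each
oracle comparison is exhaustive or statistically well-powered:
500 random assemblies for the length-metric oracle; 1000 pairs for the
mapping contract; 20 × 200-gene assemblies for RBH truth recovery and
4 × 500 genes for fragmentation–OHR recovery (tolerance ± 0.05);
1000 random 2 kb sequences for the SSR regex-oracle equivalence;
50 designed primer pairs for the virtual-PCR exhaustive scan; 500 null
simulations at 200 permutations for test calibration. Closed-form
Pfaffl cases are asserted to 1e-12; noise-free recoveries to relative
1e-12; the noisy-recovery calibration bound (median |log2 error| < 0.5
at sd = 0.2, 3 replicates) is a property of this artifact's generator,
not an external claim.

## Known limitations

- The identity definition (ungapped, shorter-sequence denominator)
  matches the clustering use-case but underestimates identity for
  indel-divergent pairs.
- The meta-assembler handles suffix–prefix overlaps only; containment
  cases are expected to have been removed by clustering first.
- Primer Tm is a GC-count approximation; designed primers are
  self-consistent against the stated rules, not validated against
  nearest-neighbor thermodynamics.
- SAM parsing covers the minimal text subset the metrics need (FLAG,
  RNAME, CIGAR, RNEXT, NM); BAM/CRAM and full-spec features are out of
  scope.
- The randomization test is not the proprietary REST scheme; with few
  replicates its p-values are discrete and conservative.
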