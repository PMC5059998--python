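# Methods

## Read classification and proportional counting

The counting model treats a read's reported alignments as its set of
plausible origins. With k reported positions the read is:

* **UM** (k = 1) — accepted; attributed to the overlapped TE copy if any,
  otherwise UNANNOTATED;
* **SMM** (k ≥ 2, ≥ 2 TE-overlapping positions, all in one family) — kept;
* **NMM** (positions in ≥ 2 families) — discarded as uninformative;
* **UNANNOTATED** (no TE overlap).

Each retained read contributes weight 1/k to each TE copy it overlaps. When
some of a read's positions fall outside annotated TEs, those positions absorb
their share: the read's total contributed weight is n_TE_hits/k ≤ 1. An
alternative that renormalizes over TE positions only would inflate family
totals whenever annotation is incomplete, so it is not offered.

Two situations the classification rules leave genuinely open are resolved as
explicit, configurable policies:

* a multi-mapper with exactly **one** TE-overlapping position is discarded by
  default (`single_te_hit_policy="discard"`, class NMM): a single TE hit among
  several equally good non-TE origins is weak evidence the read is TE-derived
  at all. `"keep"` classifies it SMM with weight 1/k.
* one alignment overlapping **two** TE features (nested or adjacent
  annotations) is attributed to the feature with the larger overlap; ties go
  to the lexicographically smaller identifier, making attribution
  deterministic.

Multiplicity k is the number of alignment records (primary + secondary) a
read has after flag/MAPQ filtering; secondary alignments must therefore be
present in the input. Counting is unstranded, matching strand-non-specific
library protocols. Mates of paired-end data are treated as independent
reads; a fragment-level mode is deliberately out of scope.

Coordinates are GFF (1-based inclusive) everywhere in the annotation layer;
the single SAM→GFF conversion happens in `collect_mappings`, which prevents
off-by-one drift between modules.

### Normalization and filtering

RPKM = count / (length/10³) / (library_size/10⁶). The library size is the
number of distinct mapped reads by default (`all_mapped_reads`); since only a
small fraction of a transcriptome maps to TEs, the retained-TE-read
alternative (`retained_te_reads`) changes scale drastically and is opt-in.
Family-level RPKM uses the summed bp of member copies as the family length.
A row counts as expressed when it reaches `rpkm_threshold` (default 0.55) in
at least one sample; the retained row set is monotone non-increasing in the
threshold. Export for count-based differential testing integerizes
fractional counts with round-half-to-even (an unbiased choice for the
half-integers that proportional weights produce) and always writes the raw
fractional matrix alongside.

Reported percentages (significantly regulated features out of totals) are
rounded half-up to one decimal, matching the convention of the summaries
they reproduce.

## HRE scanning

A module is any 5-mer nGAAn or nTTCn (n ∈ {A,C,G,T}; N never matches; case
and soft-masking are ignored). Overlapping matches are resolved greedily
left-to-right by default — keep the earlier module, rescan after its end —
because a base cannot belong to two bound modules; `overlap_policy="all"`
reports every match. Note the greedy rule is direction-dependent for
overlapping pairs, so the strand-mirror symmetry of scanning holds exactly
under report-all (the invariance test uses that mode).

Modules ≤ `max_adjacent_gap` (default 5) bp apart share a cluster. The
adjacency threshold is ≤ 5 bp; the rule is exposed in `HREConfig` because
both "≤ 5" and "< 5" appear in the literature describing basal HREs.

Cluster classification, precedence P4 > P3 > GAP > STEP > PROTO > NONE:

| type | rule |
|------|------|
| P4 | longest head-to-tail run (0-bp gaps) ≥ 4 modules |
| P3 | longest head-to-tail run = 3 |
| GAP | ≥ 3 modules, longest run ≤ 2, ≥ 1 gap of exactly 5 bp, both orientations present |
| STEP | ≥ 3 modules, every gap exactly 5 bp, uniform orientation |
| PROTO | exactly 2 head-to-tail modules oriented (TTC, GAA), i.e. nTTCnnGAAn |

The GAP/STEP boundary is one consistent reading of criteria that are usually
summarized rather than stated operationally; the whole table lives in
`classify_cluster` so an alternative reading is a one-line change. Both
orientations count toward all types by default (published HRE arrays alternate
nGAAn/nTTCn); `require_alternation=True` restricts P-types to strictly
alternating runs.

## Conservation shadowing

Windows cover `window` (default 20) consecutive **ungapped query** positions
and are anchored at their left end; subject insertions relative to the query
carry no query coordinate and are skipped, subject gaps and N count as
mismatches, and matching is exact base equality after case-folding
(`ambiguity_matches=True` additionally accepts subject IUPAC codes
compatible with the query base). Identity is the raw per-window percentage;
no smoothing is applied. Trailing windows shorter than `window` are not
emitted, so a profile has L − window + 1 anchors.

Segment calling: maximal anchor runs ≥ `identity_cutoff` (default 70 %)
spanning ≥ `min_consensus_len` (default 7) bp are extended to
[a, b + window) — every base the qualifying windows cover — clipped to the
query length; extensions that overlap are merged with anchor-weighted mean
identity so segments are sorted and disjoint. Raising the cutoff can split
one long run into two reportable runs, so monotonicity holds for the
*covered position set* (it only shrinks), not for the segment count.

Consensus building emits, per column: a gap iff gaps are the strict
majority; else the most frequent base if its frequency among non-gap
characters exceeds `majority_threshold` (default 0.5, i.e. strict majority);
else the IUPAC code covering all observed bases. The threshold is
configurable because interactive alignment editors differ here.

## The simulator

`SimSpec` defaults describe the emulated study conditions: 100-bp single-end
error-free reads from a small multi-family TE genome (3 families × 4 copies
of 400 bp, 300-bp random intergenic spacers, 50 reads per family, 5 %
per-base copy divergence). Family consensus sequences are rejection-sampled
to < 60 % mutual identity so cross-family exact multi-mapping can only be
engineered (via `shared_segment_bp`), never accidental. A read's "mapped
positions" are **all** exact occurrences of its sequence on the forward
strand, enumerated by exhaustive substring search — an aligner-independent
definition of multiplicity. `family_weights` switches from fixed per-family
depth to multinomial read allocation, making planted expression ratios
properly stochastic.

The truth table (expected class, family, and per-copy 1/k weights per read)
is produced by a separate straight-line implementation of the counting rules
(linear feature scans, inline logic) that shares no code with the pipeline,
so test agreement is evidence rather than tautology.

What the simulator does **not** model: sequencing errors and quality
variation, reverse-strand reads, splicing, paired ends, expression
stochasticity beyond uniform within-family sampling, and incomplete or
nested annotation (tests construct those cases directly). Passing tests
therefore demonstrate the correctness of classification, weighting, and
arithmetic under idealized alignments — not robustness to alignment error,
which lives upstream of this toolkit.

HRE fixtures plant canonical module arrangements into backgrounds built
base-by-base to exclude GAA/TTC trigrams entirely; planting validates that
exactly the intended modules exist near the planted offset and rejects
backgrounds whose junction bases would create artefacts.

## Problem sizes and numerics

Test and verification runs use small instances chosen to exercise every code
path with comfortable margins: 20 simulated datasets (~1200 reads) for the
counting-vs-oracle comparison at 1e-9 absolute tolerance (counts are sums of
exact binary fractions plus thirds, so agreement is effectively exact); 600
reads for the 5:1 ratio recovery, judged at 3 binomial standard deviations;
200 random 500-bp sequences against the exhaustive HRE oracle; 200 seeded
planting trials (40 per type); 25 random gapped pairs for the shadowing
recount. All randomness flows through explicitly seeded NumPy generators
(default seed 1729), and outputs are byte-identical across reruns.

## Known limitations

* The upstream "mapping error removal" of the emulated workflow is
  approximated by the flag/MAPQ filter; its exact behaviour is not public.
* Whether RPKM should use total mapped reads or retained TE reads as library
  size is ambiguous in the emulated workflow; both are offered, default
  total.
* The GAP/STEP rule table is one defensible operationalization (see above).
* Alignment construction for shadowing is consumed, not produced; global
  aligners are out of scope.
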