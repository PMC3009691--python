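# Methods

This note records the model assumptions, the tunable parameters, the
numerical choices and the known limitations of the implementation, in the
spirit of the methods documentation of packages like statsmodels or
msprime.

## Database model

An entry is an accession, a free-text description, a residue string over
the 20-letter alphabet (plus `X`), and a set of EC numbers extracted from
`EC x.x.x.x` tokens in the description. EC numbers are four-level
classifiers in which a specified level may never follow an unspecified
one (`1.2.-.-` is valid, `1.-.3.4` is not) and the class level is always
specified.

Grouping is keyword-first: any description containing a configured
keyword (default, case-insensitive: *putative, hypothetical, fragment,
probable, by similarity*) makes the entry PUTATIVE regardless of EC
annotation, because an uncertain annotation must not generate
false-positive evidence later. EC-bearing entries outside the 100–7000
residue bounds are also routed to PUTATIVE rather than discarded: their
sequences then contribute neutral (NA) rather than FP evidence during
verification. The length floor reflects that essentially no complete
enzyme is shorter than 100 residues; the ceiling excludes the handful of
giant ORFs that would dominate alignment cost.

Redundancy removal retains, among identical sequences, the record with
the largest EC set first (descending |ec|, then lexicographic id), so the
EC superset survives subset-annotated duplicates. This retention order is
a deliberate choice to maximize retained annotation; any order satisfying
the pairwise rule would yield a non-redundant set.

EC transfers are dereferenced through chains up to depth 5 (configurable);
a longer chain is treated as a cycle and is an error. Deletions remove
the EC from the record; a record with no ECs left leaves the enzyme
group. The update map is an input file because the IUBMB list changes
over time; no snapshot is bundled.

## Similarity and E-values

Low-complexity masking is a windowed Shannon-entropy filter: every
12-residue window with entropy below 2.2 bits is masked to `X`. This is a
simplified, documented masker in the spirit of SEG-style filters, not a
re-implementation of any particular one; pipelines that require a
specific filter can supply pre-masked sequences instead (`window=None`
makes the masker the identity). Masking affects the similarity search
only; patterns are always built from the unmasked sequences.

The built-in pairwise step is optimal local alignment (Smith–Waterman,
via biotite's C kernels) with BLOSUM62, gap open 11 / extend 1, mapped to
an E-value by Karlin–Altschul statistics `E = K·m·n·exp(−λS)` with the
published gapped BLOSUM62(11,1) constants λ = 0.267, K = 0.041. A
moment-matching calibration routine (Gumbel moments of shuffled-pair
scores) is provided for modified scoring schemes. Because the optimal
score is symmetric, each unordered pair is aligned once and reported in
both directions; genuinely asymmetric E-value pairs arise only from
imported heuristic search results (BLAST outfmt-6), for which the
symmetrification rule — keep the *higher* of the two directed E-values —
is implemented as stated. The sequences this protocol clusters are
closely related family members, so a rigorous local aligner with a
calibrated E-value scale is an adequate engine at this scale; a banded
implementation would change speed, not results.

Hits under 50 alignment columns or with E > 10⁻³ are discarded, boundary
values retained. A pair with a hit in only one direction gets no
distance: the missing direction's E-value exceeded the reporting
threshold, and max(reported, >10⁻³) would exceed the clustering cutoff
anyway. Multiple HSPs in one direction collapse to the best (minimum)
E-value before symmetrification. E-values of exactly 0 from external
tools are clamped to 10⁻¹⁸⁰ so ordering and max() stay well defined.

## Clustering

Complete linkage with inter-cluster distance = max over cross pairs,
absent pairs = +∞, cut at 10⁻³ (inclusive). The production code uses the
Lance–Williams max-update recurrence; the test suite holds it to exact
agreement (partition, topology and merge heights) with a brute-force
oracle that recomputes every maximum from the original matrix. Ties on
the merge distance are broken by the lexicographically smallest sorted
pair of the clusters' smallest member ids, making the forest a pure
function of the distance set. Merge trees are strictly binary; equal-
height merges are not collapsed into multifurcations. Heights are
compared as exact floats, never log-rounded.

The max-linkage rule is what keeps clusters clean under multidomain
confounders: a two-domain protein A–B has finite distances to both family
A and family B members, but once it merges into one family, the distance
of that cluster to the other family is +∞ (some cross pair has no hit),
so the two families can never fuse. The synthetic benchmark asserts
exactly this behavior.

## Patterns

Conservation follows ClustalW's published markup conventions, recomputed
from the residues rather than trusted from any printed markup line:
*star* columns (one residue, no gap) become literals; *colon* columns (no
gap, residue set within one strong group — STA, NEQK, NHQK, NDEQ, QHRK,
MILV, MILF, HY, FYW) become residue classes. Weak ("period") groups are
not used. A class element records the *observed* residue set, not the
whole strong group: tighter patterns serve the specificity goal. Runs of
unconserved columns become `x(min,max)` where min/max are the
fewest/most residues any single row places in the run; all-gap runs
contribute nothing. The pattern is trimmed to the first/last conserved
column, and fewer than eight conserved positions reject it.

Qualified nodes are the root and every node whose EC-set cardinality is
strictly below its parent's (node EC sets are member unions), processed
breadth-first, skipping nodes with ≥ 1000 members. The %pce coverage
loop (threshold 0.9 by default; configurable) then tries pattern-less
internal nodes in batches of equal, currently-worst merge E-value, never
retrying a node. Single leaves are not patterned inside multi-leaf trees;
unclustered enzymes get exact-sequence (all-literal) patterns so that a
database sequence resubmitted as a query is always recognized.

The built-in multiple aligner is deterministic center-star: the center is
the sequence with the highest summed pairwise semi-global score (free
terminal gaps; above 60 sequences a cheap length-medoid stands in for
the quadratic scan), others are merged by "once a gap, always a gap".
Center-star is entirely adequate for the high-identity clusters this
protocol aligns; ClustalW `.aln` files can be imported for fidelity runs,
in which case conservation is still recomputed.

Every kept pattern must re-match all of its source sequences
(self-recognition); a failure indicates a non-homologous conserved column
and rejects the pattern.

## Verification and set selection

Matching translates the element list to a regular expression
(`x(n,m)` → `[A-Z]{n,m}`), unanchored, first occurrence only; the test
suite pins it to a recursive enumeration oracle. The EC calculus is
asymmetric: TP iff the target agrees at every level the pattern
specifies and is specified wherever the pattern is; FP iff a co-specified
level differs; NA otherwise. Across multi-EC sets the cross product is
aggregated with precedence TP > FP > NA. Non-enzyme matches are FP,
putative matches NA.

Specificity is TP/(TP+FP), defined as 1.0 when TP+FP = 0 — a pattern with
only neutral evidence has no counterevidence. Set A requires specificity
1.0, all ECs in one sub-subclass, and excludes patterns whose EC set is
exactly one unresolved EC; a multi-EC set containing an unresolved EC
alongside resolved same-sub-subclass ECs stays eligible. Set B is set A
plus every pattern with specificity ≥ 0.75, regardless of EC structure.
No NA-based filtering is applied to either set. False negatives are not
computed: one EC can legitimately live in several unrelated families,
each with its own patterns, so FN counts against the training database
would not measure pattern quality.

## Annotation harness

Query proteins are searched with a pattern set; each match predicts the
pattern's ECs. Against a standard of truth, a predicted EC that
TP-matches a SOT EC (prediction in the pattern role) claims that SOT EC
once; remaining predictions that agree with a SOT EC on levels 1–3 claim
that sub-subclass once, skipping sub-subclasses already represented among
the claimed ECs, so the combined count never double-credits one SOT
entry. Unresolved predictions are handled by the same level-3 channel.
The contribution split of two prediction sets is computed over the union
of SOT ECs either set claimed.

## Synthetic data generator

The generator emulates exactly what the protocol needs to be tested
against: families of similar sequences with controlled divergence, decoy
entries exercising the NA channel, background non-enzymes, and
multidomain concatenations exercising the clustering confounder. Each
family draws a uniform-random ancestor and n independent descendants with
i.i.d. per-site substitution (uniform over the 19 alternatives — no
substitution-matrix bias, so pairwise identity has the closed form
`(1−r)² + r²/19` that the tests check) and geometric(½)-length indels at
a per-site rate. Putative decoys alternate between verbatim member copies
(which the family patterns must match, so the neutral NA channel is
actually exercised) and further-mutated relatives (which long, strict
patterns essentially never match). Integer-seeded numpy generators make
every output byte-reproducible.

The canonical benchmark is five families (distinct fully resolved ECs
from five different classes), eight members each, 300-residue ancestors,
substitution rate 0.08, indel rate 0.01, twenty decoys, fifty
non-enzymes, two multidomain concatenations — about 112 entries, which
runs the full pipeline in seconds on one CPU. What passing on this data
shows: correct group routing, clean family recovery under multidomain
confounders, conserved-column extraction, self-recognition and the whole
verification calculus. What it does not show: behavior under real
substitution processes, rate heterogeneity, shared domains between
genuinely different enzymes, alignment-quality limits on distant
homologs, or database-scale performance.

## Defaults at a glance

| Parameter | Default | Meaning |
|---|---|---|
| length bounds | 100–7000 aa | enzyme group admission |
| masking window / entropy | 12 / 2.2 bits | low-complexity filter |
| min alignment columns | 50 | hit filter |
| max E-value | 10⁻³ | hit filter and clustering cutoff |
| gap open / extend | 11 / 1 | local aligner |
| λ, K | 0.267, 0.041 | E-value surrogate (gapped BLOSUM62) |
| min conserved positions | 8 | pattern rejection threshold |
| node size cap | 1000 members | pattern attempt cutoff |
| %pce threshold | 0.9 | coverage loop target |
| set B specificity | ≥ 0.75 | loose-set admission |

All of these are overridable through `PipelineConfig` or the CLI
`--config` file.

## Known limitations

* The E-value surrogate is calibrated statistics, not a bit-for-bit
  reproduction of any particular search tool; imported BLAST tabular
  output should be used when exact E-values matter.
* Center-star alignment can produce shorter patterns than a full
  progressive aligner on gappy clusters; the `.aln` importer exists for
  that case.
* No domain detection is performed; the protocol relies on the strictness
  of complete linkage to keep domain compositions clean.
* Deterministic patterns trade sensitivity for specificity by design: a
  single substitution at a literal position hides a true family member.
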