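# Methods

This note records the models, conventions and numerical choices behind
`evani`, and what the simulation-based tests can and cannot show.

## Simulation model

**Tree.** Species trees are sampled from a birth–death process
(default birth 0.01, death 0.001 per unit time; dendropy's sampler)
conditioned on the number of extant tips. The sampler stops at the
final birth event, which would leave the youngest cherry at depth
zero; we therefore extend all pendant edges by a single exponential
waiting time with rate n·(birth+death) — the expected time to the next
event among n lineages — so every pair has positive distance. The tree
is then rescaled linearly so the root-to-leaf depth equals
`mutation_rate` PAM. 100 PAM corresponds to one *accepted* substitution
per site on average; the calibration test verifies 1.0 ± 0.02 events
per site over a 100-PAM path on 100-kb genomes.

**Substitutions.** On a branch of b PAM each site receives
Poisson(b/100) substitution events; each event moves the base to a
uniformly chosen different base (Jukes–Cantor). Events are applied as
additive shifts in Z₄, which composes exactly under multiple hits, so
back-mutations arise naturally; the observed pairwise difference
fraction follows the JC saturation curve ¾(1 − e^(−4d/300)) (property
test, 3 Monte-Carlo standard errors).

**Indels.** Independent of substitutions, indel events arrive at
`indel_rate` (default 10⁻⁴) per site per PAM. Lengths are
Zipf-distributed; the exponent (1.8) and truncation (50 bp) are
package defaults chosen as a common Zipfian indel parameterization at
desk scale — heavy-tailed but bounded — since no canonical values
exist. Insertions get random content; gene intervals are shifted,
grown, shrunk or dropped (if fully deleted) accordingly. Insertions at
a gene boundary fall between genes, so intergenic material can
accumulate even though the root genome is a seamless concatenation of
genes.

**Duplication and LGT.** Both are per-gene, per-PAM Poisson processes
(the unit choice is a package decision; "per gene per branch" is the
alternative reading). A duplication copies a uniformly chosen gene of
the same lineage into a uniformly chosen inter-gene slot at the event
time, after which the copy evolves like any other sequence. An LGT
copies a gene from a donor lineage alive at the event time; lineages
are advanced through a global chronological event queue, so the donor
sequence is its true state at the transfer time, and the donor is
recorded per gene (a donor alive at time t is never an ancestor of the
recipient — checked by a test). Event intensities use the gene count
at branch activation / segment start rather than the instantaneous
count; at the studied rates (≤ 0.002) the gene count changes by a few
percent per branch, so this is a second-order approximation.

**Compositional drift (`gc_drift`, default 0).** When enabled, each
lineage carries a target-GC offset performing a Brownian walk (standard
deviation `gc_drift` per 100 PAM); substitution targets are then drawn
A/T vs C/G according to the lineage's current target GC instead of
uniformly. This makes base composition itself a heritable,
tree-structured signal — the mechanism behind the two-signal scenario
used for the bi-k analysis (below). With drift enabled, multiple hits
at one site within a branch segment resolve last-event-wins rather
than as an exact chain; the event *count* (used for calibration) is
unaffected. With drift at 0 the exact additive-shift path is used.

**Provenance.** Every gene carries its root family id and an event
path; `HomologyMap` exposes per-leaf vertically inherited families and
the vertical intersection of leaf pairs. This is the truth layer for
ortholog-restricted estimators; it plays the role that orthology
inference plays on real data, without its errors.

## Distance estimators

**K-mer sets.** K-mers are strand-canonicalized (lexicographic minimum
of the k-mer and its reverse complement) because assemblies have
arbitrary strand; windows containing non-ACGT characters are skipped.
K-mers are 2-bit packed (k ≤ 32) and hashed with a seeded SplitMix64
finalizer whose constants are fixed in the source — sketches are
reproducible across runs and platforms, and the hash seed is part of
every sketch's identity.

**Jaccard and sketches.** Exact Jaccard uses distinct canonical
k-mers, ignoring multiplicity. The bottom-s MinHash estimator follows
the Mash convention by default: pool the two sketches, keep the s
smallest values X, and return |X ∩ S_a ∩ S_b|/|X|; the literal ratio
|S_a ∩ S_b|/|S_a ∪ S_b| (whose denominator can exceed s) is available
as `mode="literal"`. The two coincide for saturated sketches. Averaged
over 200 hash seeds, the s=256 estimate sits within 3 standard errors
of the exact Jaccard on 10-kb pairs (test).

**Mash similarity.** 1 + (1/k)·ln(2j/(1+j)), from the Poisson model in
which a k-mer survives point divergence d with probability e^(−kd). At
j=0 the similarity is reported as 0 and the distance saturates at 1 —
pairs sharing nothing are maximally, not infinitely, distant. This
mirrors how alignment tools "report an ANI of zero" for unalignable
pairs and keeps such pairs usable as ties in rank analyses.

**Fragment ANI (ANIb-style).** The query is cut into consecutive
1020-bp fragments (trailing short fragment kept, coverage measured
against its own length). Each fragment's best local hit on either
strand of the reference comes from a seed-and-extend banded aligner:
shared 11-mers vote for a diagonal band, and a banded affine
Smith–Waterman (match +1, mismatch −1, gap open −5, gap extend −2,
x-drop 150, band half-width 75) scores it. Hits with identity > 0.30
over > 0.70 of the fragment are kept; ANI is Σmatches/Σcolumns
(per-fragment mean available). The banded aligner stays within 0.01
identity of an unconstrained Smith–Waterman oracle on 1020-bp
fragments (test). A published scoring recipe for this step reports a
mismatch "penalty" of 21 alongside reward 1; treating that as the
typographical artifact it appears to be, we use the symmetric ±1
scheme above.

**Reciprocal fragment ANI (OrthoANI-style).** Both genomes are
fragmented; pair (i, j) counts when i's best hit lands in fragment j
with ≥ 50% interval overlap and j's best hit lands back in i likewise
(the exact published rule is not specified; the 50% back-mapping rule
is this package's definition). ANI is the mean of the per-pair mean
identities, over pairs passing the ANIb filters.

**MEM/MUM ANI (ANIm-style).** Maximal exact matches ≥ `min_len`
(8–32; seeds are packed words) are found on both strands by merging
diagonal-consecutive shared seeds — a maximal run of consecutive
matching seeds *is* a maximal match. MUM mode keeps matches whose
substring occurs exactly once in the forward strand of each genome
(uniqueness is checked against the literal sequence, with a
seed-multiplicity fast path); maxmatch mode keeps all. Anchors are
chained per strand by a heaviest-collinear-chain DP (non-overlapping,
inter-anchor gaps ≤ 5 kb), chains below 65 anchor-bases are discarded
as seed noise, and `one_to_one` filtering keeps chains greedily by
weight subject to ≥ 50% novel coverage in both genomes *and* order
consistency with previously kept same-strand chains (crossing chains
lose). Intra-chain gaps shorter than 1 kb are closed by unit-cost
global alignment (edlib) and contribute matches/columns; larger gaps
stay unaligned and count only in the AF denominator. ANI =
Σmatches/Σcolumns over retained blocks; AF is reported per genome;
when no anchor survives the result is flagged undefined and serialized
downstream as 0 with `defined_flag=0`. `find_mems` agrees exactly with
an O(n²) brute-force oracle on ≤ 500-bp pairs over 50 seeds (test).

**AF weighting and DDH distances.** AF-weighted ANI multiplies ANI by
the mean of the two per-genome alignment fractions (no convention
fixes which genome's length is the denominator, so we average). The
three digital-DDH style formulas use both comparison directions:
d₁ = 1 − alignment-length/(len_a+len_b), d₂ = 1 − identities/alignment
length, d₃ = 1 − identities/(len_a+len_b).

## Evaluation

Spearman rho is Pearson on mid-ranks (ties averaged). The two-sided
p-value uses the t approximation with the survival function in log
space; where scipy's `t.logsf` underflows to −inf, a power-law tail
expansion with first-order correction takes over, so log₁₀p stays
finite for every |rho| < 1. Against the exact permutation null
(n ≤ 7) the approximation agrees within 0.15 log₁₀ units for moderate
correlations; near |rho| = 1 the discrete null has large atoms and no
continuous approximation tracks it, so tests probe |rho| ≤ 0.83.
P-values on genome pairs are nominal in any case — the n(n−1)/2 pairs
share branches and are not independent; they are used as a
comparative score, never as inference.

Similarities are negated before correlation so the reported `rho` is
positive for a good estimator; `rho_signed` preserves the raw sign
(negative for a good similarity). Undefined pairs are included as ties
at the maximal distance by default (`drop_undefined` excludes them);
this choice materially affects rankings when many pairs fail to align,
which is precisely one of the phenomena under study.

`merge_ranks` rank-transforms each input matrix (similarities ranked
descending), averages the two ranks per pair, and returns the averaged
ranks as a new distance. Spearman against any reference is invariant
to whether one re-ranks after averaging, which a test verifies
indirectly via monotone-transform invariance.

## Benchmark scenarios and their scale

All scenario tests use 15 genomes of 100 genes × 1 kb (≈ 100 kb per
genome — 50× smaller than the 100 × 50 kb genomes the full-scale
protocol calls for), 5 replicates with pinned seeds, and medians
across replicates. Scenario placements on the mutation axis are
package choices made so the mechanism under study is in its informative
regime at this genome size:

* **Sketch-size sweep** (s = 64, 256, 1024, saturated; k=15) at
  mutation 100: median rho increases with sketch size.
* **LGT contrast** at mutation 20: exact Jaccard's rho drop under LGT
  0.002 exceeds Mash-s1000's. The direction holds where baseline
  correlations are strong; at higher divergence Mash's saturation ties
  interact with LGT and the ordering inverts at this genome size.
* **AF weighting** at mutation 100 (MUM anchors, min length 21):
  AF-weighted ANIm ≥ plain ANIm in median rho. The margin is modest at
  100-kb scale because most distant pairs are undefined in both
  variants.
* **Duplication** (0.002) at mutation 10, where ANIm is defined for
  essentially all pairs: MUM-mode alignment fraction falls below
  maxmatch-mode AF (uniqueness filtering discards duplicated regions),
  while AF-weighting barely changes maxmatch-mode ANIm.
* **Ortholog restriction** under LGT 0.002 (mutation 20): Jaccard on
  vertically inherited genes only ≥ whole-genome Jaccard.
* **Bi-k merged ranking** on the two-signal scenario (mutation 150,
  `gc_drift` 0.15): under uniform composition, small-k sharing between
  diverged genomes is collision noise, and a single large k dominates
  at every divergence — plain single-rate simulations cannot produce
  complementary k scales. With inherited compositional drift, k=10
  sharing tracks composition (informative for pairs beyond k=19's
  homology horizon) while k=19 tracks homology for closer pairs;
  averaging the two rankings beats either alone.

**What passing these tests does not show.** The simulator draws i.i.d.
root sequences, has no repeats beyond what duplication creates, no
rearrangements or inversions, no rate heterogeneity across sites, no
codon structure, and length-0 intergenic spacers at the root. Real
genomes violate all of these; results here quantify the estimators'
response to the modelled forces (divergence, indels, duplication, LGT,
composition drift), not their absolute accuracy on real assemblies.

## Numerical and interface conventions

* All coordinates 0-based half-open; minus-strand hits reported in
  plus coordinates with a strand flag.
* Determinism: every sampled quantity derives from the config seed
  (tree sampling and sequence evolution use independent streams);
  identical configs give byte-identical FASTA/Newick/TSV outputs.
* Writers are atomic (temp file + rename); matrices round-trip at 12
  significant digits; undefined entries serialize as value 0 with
  `defined_flag=0`.
* One genome = concatenation of the records in its FASTA file;
  normalization uppercases, maps U→T and other IUPAC codes→N (logged).
* Degenerate inputs: empty k-mer sets give NaN Jaccard ("undefined"),
  constant rank vectors give NaN rho; both propagate as undefined
  rather than raising mid-pipeline.
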