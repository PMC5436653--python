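# Methods

## Alignment model and core positions

The unit of analysis is a fixed multiple sequence alignment; the
package never realigns. Columns whose gap fraction (counting `-` and
`X`) is at most `max_gap_frac` (default 0.3) form the *core* and are
numbered 1..K in column order. This is a sequence-only surrogate for
structure-based core definitions, in which structurally variable
(loop) regions are excluded by superposition; without structures, gap
fraction is the observable proxy, and the threshold is exposed because
no single value suits every family. Raising the threshold only ever
adds columns, so cores are nested across thresholds.

Residue numbering is 1-based after a per-sequence integer offset
(default 0), emulating species-specific numbering; the mapping between
a protein's residue numbers and core position numbers is exact and
invertible on non-gap cells. The alphabet is strict: the 20 standard
amino acids plus `-` and `X` (`X` treated as gap everywhere;
`B`, `Z`, `U`, `O` are rejected at parse time so downstream statistics
stay on a clean 20-letter alphabet).

## Pairwise correlated-mutation scores

Both scorers operate on the joint residue counts of a column pair,
restricted to sequences non-gapped at *both* columns
(pairwise-complete deletion; this keeps the marginals of a pair
internally consistent and, unlike listwise deletion, does not discard
most of a ragged family). Pairs with fewer than `min_pairs` (default
20) complete sequences are *undefined* — reported as NaN and excluded
from networks — never coerced to 0, so sparse data cannot create or
suppress edges silently.

**Statistical coupling (`sca`, default).** For residue *a* at column i
with count n_a ≥ `min_subset` (default 5), the perturbation is the
total-variation distance between the conditional distribution at j
given *a* and the marginal at j:

    d_a = ½ Σ_b | f_{j|a}(b) − f_j(b) |

The directed score D(i→j) is the n_a-weighted mean of d_a over
qualifying residues (weights renormalised over those residues), and
the reported score is ½(D(i→j) + D(j→i)) ∈ [0, 1]. A conserved column
perturbs nothing and scores exactly 0 with every partner. If no
residue reaches `min_subset`, the pair scores 0 and is flagged
`low_support`.

**Normalised mutual information (`nmi`).** Plug-in MI in bits divided
by min(H_i, H_j); 0 when the smaller entropy is 0. NMI equals 1
exactly when the lower-entropy column is a deterministic function of
the other (mutual determinism when the entropies tie) — verified by
enumeration against an independent MI implementation.

Neither scorer applies a small-sample bias correction. The MI bias is
≈ (|A|−1)(|B|−1)/(2·n·ln 2) bits; the TV perturbation has an analogous
positive bias of order √(categories/class size) — measured at ≈ 0.08
for two uniform 20-letter columns at n = 10 000 and ≈ 0.05 for
realistic skewed profiles. Both biases shrink as n grows and sit well
below the coupled-pair scores at the alignment sizes the package
targets (hundreds to thousands of sequences); they are the reason the
calibration below is relative rather than an absolute threshold. No
sequence-redundancy weighting is applied (no weighting scheme is
defined for this score; the hook would be a per-sequence weight vector
in the joint counts).

## Networks and cutoff calibration

Edges are pairs with a defined score ≥ cutoff (inclusive — strictness
is a convention; inclusive was chosen and is stated in every export).
Nodes are edge endpoints only, so an isolated position is *not* part
of any network and network sizes count genuinely co-evolving positions.
Components are ordered by decreasing size, ties by smallest member;
the hub is the highest-degree node, ties to the lowest position
number. Sub-networks are components of a component re-thresholded at a
stricter cutoff.

When no cutoff is given, one is calibrated as the midpoint between the
median and the maximum of the defined scores. Rationale: in a family
with genuine co-evolving groups the score distribution is strongly
bimodal — a large near-background bulk (median) and a small coupled
tail (maximum) — and the midpoint lands between the modes without any
ground truth. On simulated families the bulk sits near 0.07 (`sca`,
n = 5000) while planted pairs score ≈ 0.73, so the calibrated cutoff
≈ 0.4 is robust to either mode moving moderately. The calibration is
deliberately per-matrix: conditioned sub-alignments have their own
score scale. Its failure mode — no coupled tail at all — yields a
cutoff just above half the background maximum and hence a small
spurious network; the robustness scan and permutation p-values are the
guards against over-reading such networks.

## Annotation mining and enrichment

Sentences are the co-occurrence unit; the splitter is a deterministic
regex split on sentence-final punctuation followed by an uppercase
letter, with a short abbreviation guard (e.g., i.e., et al., Fig.).
Three mention dialects are recognised: compact (S127P), three-letter
(Glu422Lys, case-insensitive), and phrase ("Trp58 was
mutated/substituted/replaced/changed to/by/with/into Ala"). Mentions
are validated against the stated sequence — the wild-type letter must
match the residue at that (offset-corrected) position — then mapped to
a core position; mismatches, out-of-range positions and non-core
columns are rejected with typed reasons. Silent mentions (S127S) are
flagged and excluded by default. Keyword expressions are
case-insensitive word-prefix stems ("increase" matches "increased")
or conjunctions "a AND b" requiring every stem; prefix matching stands
in for stemming, which the short functional vocabulary does not need.
An annotation (position, keyword) is accepted when at least `n_mut`
(default 2) *distinct* article ids support it; repeated mentions
within one article count once. Because validation maps through the
family numbering, mentions made in different homologs pool at the
same position — that pooling is the point of the shared numbering.

Enrichment of a keyword on a network node set is
Escore = (Kn/Kt)·(Nt/Nn). Nt counts *all* core positions (not only
annotated ones), and the network position set defaults to the union of
all components at the cutoff, with per-component scoring available.
Undefined situations are kept distinct from zero: an empty network and
a keyword with no annotated positions produce status markers, not 0.
Under random placement of Kt annotated positions, Kn is
hypergeometric and E[Escore] = 1, which anchors the interpretation:
values near 1 are noise-level. Significance is a permutation test over
uniformly drawn position sets of the network's size,
p = (1 + #{Escore_perm ≥ Escore_obs}) / (n_perm + 1); since Escore is
monotone in Kn at fixed sizes, this null is exactly the
hypergeometric tail, and the implementation is tested against it.

## Sub-alignments and robustness

Residue-conditioned subsets keep all columns and the original core
numbering (numbering must stay comparable across layers — an
intentional divergence from re-deriving cores per subset). The
conditioned column is conserved in the subset, scores 0 with every
partner, and leaves the network; with hierarchically structured
families this promotes the next layer of co-evolution to the main
network. Subsets smaller than 50 sequences trigger a warning, not an
error: small subsets are legitimate but their networks are noisy.

Random subsampling is uniform without replacement, size
round(fraction·N) with a floor of 2, reproducible per (seed, fraction,
replicate). The robustness scan recomputes scores and the network for
each subset *at the full-alignment cutoff* and reports the F-measure
of node sets against the full-alignment network
(F = 2PR/(P+R); two empty sets compare as 1, exactly one empty as 0 —
needed for degenerate runs at tiny fractions).

## Library design

Targets default to the k = 4 most frequent residues at a position
(ties alphabetical). The designer enumerates all 15³ degenerate
codons, keeps those whose expansion is stop-free and within the
target, deduplicates by encoded set (keeping the lexicographically
smallest codon per set), and searches exact covers of increasing size
up to `max_codons` (default 3), returning the lexicographically
smallest minimal solution — an arbitrary but deterministic tie-break;
codon-usage preferences among equal-size solutions are out of scope. A
relaxed mode allowing off-target amino acids exists behind a flag and
minimises the off-target load first. The wild-type residue is not
forced into the target (a frequent design choice is to drop it); a
warning is emitted when the design does not encode it. Library size is
the product of encoded-set sizes over the jointly randomised block
plus the sum over independently randomised positions — wild-type-like
combinations included, matching how combinatorial libraries are
counted.

## Synthetic families

The generator emulates subgroup-driven covariation: sequences get a
top-level subgroup (and optionally an independent nested subgroup
label); at each planted network position every subgroup has its own
consensus residue (drawn without replacement across subgroups, so
consensus residues are distinct — this is what makes
residue-conditioning select a subgroup cleanly), carried with
probability `p_cons`, otherwise replaced by a uniform random other
residue (maximum-entropy noise). Background positions draw iid from
per-column profiles sampled from a symmetric Dirichlet (concentration
0.5) for realistic column heterogeneity; gaps are injected iid at
`gap_rate`; optional high-gap columns (gap fraction 0.7) can be
spliced in to exercise core derivation. Level-1 networks are keyed on
the top-level subgroup; level-2 networks on the independent nested
label, so in the full alignment they form a separate, smaller
component, and after conditioning a level-1 position to one residue
the level-1 network collapses (conserved) while the level-2 network
becomes the main one — the layered behaviour of sub-alignment
analyses.

Defaults (5000 sequences, 150 core positions, 8 equal subgroups, one
12-position network, p_cons 0.9, 5% gaps) represent a large diverse
super-family with a strong functional signal. The corpus generator
writes article texts whose mentions use wild-type letters read off the
emitted sequences, each planted position mentioned with its network's
keyword in 2 articles by default, plus Poisson-distributed noise
sentences pairing random positions with neutral keywords; it also
emits the expected annotation table so the mining pipeline can be
checked end to end.

What the generator does *not* model: phylogenetic correlation between
sequences (each sequence is drawn independently given its group),
indels and alignment errors, substitution-matrix structure, shared
positions between networks, or anaphora and protein-name ambiguity in
text. Tests passing on this generator therefore demonstrate that the
estimators and the pipeline behave correctly under the stated
statistical model, not that any particular real family will yield
networks of a given quality; on real alignments the background score
level is higher (tree-induced correlation) and cutoffs deserve
inspection of the score distribution.

## Problem sizes and determinism

The test suite and the acceptance script use 2000–5000 sequences and
60–150 core positions — large enough that sampling noise sits far
below the planted signal (separation measured at ≈ 0.07 vs ≈ 0.73 for
`sca` at n = 5000) while a full run stays in the tens of seconds.
Every stochastic step (simulation, subsampling, permutation) takes an
explicit seed and is bit-reproducible given it; the pipeline writes
only text outputs so reruns diff cleanly.
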