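# Methods

This note documents the models, the defaults and the numerical choices
behind `probmsa`, and what its synthetic-data tests do and do not show.

## Pair hidden Markov model (stage I)

The pair-HMM has three states — match M and two insert states X, Y — with
no X↔Y transitions and no end state: a complete path covers both
sequences, and its weight is the start probability times transition and
emission products. Defaults: gap-open probability δ = 0.0119, gap-extend
ε = 0.33, start distribution (1−2δ, δ, δ); these magnitudes follow the
classic consistency-aligner lineage. Match emissions are a Boltzmann
transform of BLOSUM62 over Robinson–Robinson background frequencies,
p(a,b) ∝ π_a π_b·exp(0.32·s(a,b)), symmetrized and normalized; insert
emissions are the background. Ambiguity codes B/Z/X are kept in the
sequence text and scored as the wildcard: the background-weighted
expectation over the alphabet (on the probability scale for emissions, on
the score scale for substitution matrices).

Forward and backward recursions are accumulated in log space with
`numpy.logaddexp` (numba-compiled kernels). Double precision in log space
keeps per-cell error around 1e-15 on the enumeration oracles, far inside
the 1e-10 contract, and is overflow-safe at any length.

## Partition function (stage I)

The second posterior comes from a Boltzmann ensemble over global
affine-gap alignments: an alignment with substitution-score sum *s* and
gap runs of lengths *k₁, k₂, …* has weight
exp((s − Σ(open + (kᵢ−1)·ext)) / T). Adjacent X/Y runs are distinct runs,
each paying the opening penalty. Pairing probabilities are obtained from
a forward pass and a second forward pass over the reversed sequences.

Defaults: GONNET1992 (as distributed with Biopython) with open 2.2,
extend 0.1, temperature 0.5 — the classic partition-function calibration
expressed on this matrix's scale. The matrix is configurable by name or
by a plain-text residue-labelled file, so an externally obtained VTML200
(or any other matrix) can be substituted; VTML200 is not shipped because
no source of its numeric values is bundled with the package's
dependencies. HMM and partition posteriors are combined by the cellwise
arithmetic mean (root-mean-square available), and sparsified at cutoff
0.01 by default; cutoff 0 keeps all nonzero cells exactly.

The MEA objective is the plain match-sum: unpaired residues cost nothing
and the dynamic program maximizes the summed posterior over matched
cells. Traceback ties prefer match, then a gap in the first profile,
then in the second — fixed for determinism.

## Guide tree (stage II)

Distances are d = 1 − score/min(|x|,|y|), clamped to [0,1]; because every
downstream consumer (rank normalization, UPGMA) is order-isomorphic, any
monotone transform of the MEA score would give the same tree. "Weighted
UPGMA" is implemented as the WPGMA update (plain mean of the merged
clusters' distances); the size-weighted update is available behind a
flag. Merge ties break to the lowest cluster-index pair in input order.
Heights are ultrametric (d/2 at each merge); sequence weights follow the
ClustalW rule (each branch length divided equally over the leaves below
it), normalized to sum 1, with a uniform fallback for all-zero branch
lengths. The tree distance used by selective consistency is the node
count of the minimal subtree containing both leaves (d(x,x) = 1).

## Selective consistency (stage III)

One transformation relaxes every matrix over its accepted third
sequences using the pre-transformation matrices (double-buffered, so the
result is independent of pair order and the reverse orientation is an
exact transpose). The relaxation formula weights the original matrix by
h₍xy₎(w_x+w_y) and each product S₍xz₎S₍zy₎ by w_z, dividing by the total
weight; with an empty accepted set the identity is returned exactly
(no floating-point round trip). Products are computed sparsely and
re-thresholded at the configured cutoff.

Defaults: deterministic selectivity with aggregation max and
T = ⌈2√N⌉ on the node-count tree distance — a documented package choice,
since no canonical threshold value is available; the per-pair acceptance
list is capped at 200 (closest-first by α). h = 3 in selective modes and
1 (off) in full mode; h₍xy₎ is applied in every iteration. The stochastic
filter inequality is implemented as accept-iff p ≤ F(α₀), making F an
acceptance probability — the direction consistent with the 10% calibrated
triangle presets; a flag restores the inverted reading. Triangle presets
(low/mid/high-pass, rate r, default 0.10): the low-pass filter is
max(0, 1 − α/(2r)), the high-pass its mirror, the mid-pass the unit
triangle of half-width r centred at 0.5; each has expected acceptance
exactly r over uniform α.

The number of transformations follows the family-size rule (2 for
N < 50, else 1).

## Progressive alignment and refinement (stage IV)

The profile DP score for a column pair is the sum over cross-sequence
pairs of w_x·w_y·S₍xy₎ at the columns' residue indices; gap positions
contribute nothing, and there are no explicit gap penalties — posterior
mass is the only signal. Scores are normalized by the summed weight
products so node size does not change their scale (switchable off;
scale does not affect the argmax).

Refinement realigns with the same consistency-transformed matrices used
by the progressive stage. Column-oriented splitting draws uniformly from
the columns containing at least one gap and one residue; the optional
balance bias sorts candidates by |g − N/2| (g = gap count) and keeps the
first or last p%. Candidates are accepted under the configured rule;
the default is non-increasing column count. The trident acceptance rule
scores each column as (1−t)(1−r)(1−g) with t the residue entropy over
log 20, r the entropy over an 8-class stereochemical partition
(aliphatic AVLIM, aromatic FWY, polar STNQ, positive KRH, negative DE,
and C, G, P as singletons) over log 8, and g the gap fraction; exponents
are configurable. Refinement runs 30 iterations when two consistency
transformations were applied, 200 otherwise. Every iteration re-checks
the alignment invariants (degap identity, no all-gap columns); a gapless
incumbent makes a column iteration a counted no-op.

Because a candidate realignment can always reproduce the incumbent's
cross-profile matching, accepted candidates never decrease the weighted
posterior mass: refinement is a hill-climb on that objective, constrained
by the acceptance rule.

## Synthetic families and what the tests show

The generator evolves an ancestral sequence (drawn from the background
frequencies) down a binary tree (balanced, caterpillar or random shape;
unit branch lengths): each branch substitutes every site with probability
0.05 and triggers indel events at rate 0.01 per site (insertion or
deletion with equal chance, geometric lengths with continuation 0.3,
inserted residues from the background). Sites are tracked through a
global column registry, so the true multiple alignment is exact by
construction and every output is bit-reproducible from the seed. The
defaults give families around 65–75% mean pairwise identity with a few
dozen indel events — moderately conserved, ultrametric, with no rate
heterogeneity across sites, no domain shuffling and no long terminal
extensions.

Consequently the synthetic tests validate the machinery (oracle
equivalence, algebraic identities, determinism, scaling) and the
direction of the pipeline's advantage over naive baselines, but they are
not a substitute for structure-based benchmarks: in this conserved
regime the progressive alignment already recovers ~97% of true residue
pairs, and the refinement hill-climb — verified monotone in its own
objective and in alignment length — has little headroom; its measured
mean effect on SP here is slightly negative, whereas its benefit is
expected on harder, more divergent families where progressive errors
dominate. The refinement acceptance test reports this comparison as
specified and currently documents that gap.

## Numerical and degenerate-input choices

- Posterior cells are clipped to [0,1]; stored sparse values must lie in
  (0,1] and row/column sums stay ≤ 1 + 1e-9 through combination and
  consistency (the transform is a convex combination of row-stochastic-
  bounded terms).
- Probability normalization is validated at parameter construction with
  tolerance 1e-12 (transitions, start distribution) and 1e-9 (emissions).
- MEA/profile traceback uses a 1e-13 slack when re-deriving the path
  from the filled table.
- The RAM fit walks the cutoff grid {0.01, 0.02, 0.05, 0.1, 0.2, 0.3,
  0.5} and bounds each matrix's cells by min(dense, rows·⌊1/cutoff⌋,
  cols·⌊1/cutoff⌋) at 16 bytes per cell — each posterior row sums to at
  most 1, so at most ⌊1/cutoff⌋ cells per row can reach the cutoff. An
  infeasible budget at the 0.5 floor raises an error rather than degrade
  silently.
- Problem sizes in the test suite (families up to N=20, L=100 for
  behavioural checks; N∈{20,40,80} for the selectivity-scaling check;
  sequences ≤5–7 residues for enumeration oracles) were chosen so the
  exhaustive oracles stay exact and the whole suite completes in a couple
  of minutes on one CPU.

## Known limitations

- Protein only; the nucleotide flag errors by design.
- No banding, anchoring or long-sequence memory engineering: posterior
  computation is O(L²) per pair and all-pairs storage is the memory
  bottleneck, mitigated only by the sparsity cutoff.
- The guide tree is built once (no iteration on a preliminary
  alignment).
- Benchmark corpora are not bundled; supervised evaluation expects a
  reference alignment in aligned FASTA with identical sequence content.
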