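# Methods

This note documents the models, parameter choices and numerical
conventions behind pnpalign, and what the test suite does and does not
demonstrate.

## Percent identity and its conventions

PID drives every adaptive decision, so its definition matters.  We define
the PID of a pair as the identity fraction of one optimal global
(Needleman–Wunsch) alignment under a fixed classical scheme — BLOSUM62
substitution scores, gap open −10, gap extend −1 (a gap of length k costs
10 + (k − 1)) — computed with Biopython's `PairwiseAligner`.  Using a
fixed classical scheme keeps PID independent of the posterior stage,
which PID itself selects.

The denominator is the number of columns in which *both* sequences carry
a residue (configurable alternatives: shorter-sequence length, full
alignment length).  This makes PID of identical sequences exactly 1.
Identity counts can differ between co-optimal alignments; we accept the
first optimal alignment Biopython enumerates, which is deterministic.
The brute-force oracle test therefore accepts the identity fraction of
*any* co-optimal alignment.

σ(PID) is the **population** standard deviation over the N(N−1)/2 pair
PIDs: a family's pairs are a complete population, not a sample, and with
all-equal PIDs both conventions give 0.

**Consequence for the thresholds.**  The 18 % and 11.5 % routing
thresholds were calibrated by the method's authors against their own
implementation's PID convention.  An optimal-alignment PID is upward
biased for unrelated sequences (the aligner maximizes scoring matches):
under our default convention, families of fully random protein sequences
realize avg(PID) ≈ 0.20–0.25.  Absolute routing behaviour near the
thresholds therefore differs between PID conventions, which is why every
threshold is configurable and the CLI offers `--force-strategy` for
controlled experiments.  Tests assert that routing follows the rules
*applied to the realized statistics*, not that a particular generator
setting lands in a particular branch.

## Pair-HMM models and parameters

Two model families, both with explicit start/end distributions so every
path has a well-defined probability:

* **global3** — Match, InsertX, InsertY.  Gap open δ = 0.02, extension
  ε = 0.4, end probability τ_end = 0.02 per state; start distribution
  (0.96, 0.02, 0.02).
* **local5a/local5b** — Match plus two insert tiers per sequence.
  Tier 1 (ordinary indels): δ₁ = 0.012, ε₁ = 0.4.  Tier 2 (long
  divergent stretches): δ₂ = 0.01, ε₂ = 0.9 (local5a) or 0.95 (local5b).
  The start distribution (0.4, 0.05, 0.05, 0.25, 0.25) places half its
  mass on tier-2 inserts, so alignments can begin and end inside
  unalignable flanks nearly free of charge — local alignment semantics
  for homologs that share only domains or motifs.  The two variants'
  posteriors are averaged with equal weight; how many local models the
  ancestor tools combine is not published, so two is this package's
  documented default.

The model set is chosen per family: global3 when avg(PID) ≥ 0.40 (the
boundary takes the global branch), the local set otherwise.

**Emissions.**  Match emissions are derived from BLOSUM62 by inverting
its log-odds construction.  BLOSUM62 scores are rounded half-bit
log-odds, s_ab = 2·log₂(p_ab / f_a f_b), hence p_ab ∝ f_a f_b K_ab with
K = 2^(S/2).  Requiring the marginals of p to equal f forces Σ_b K_ab f_b
to be constant in a, i.e. f ∝ K⁻¹·1 — a single linear solve.  For
BLOSUM62 the solution is strictly positive and reproduces the familiar
background frequencies (A ≈ 8.2 %, L ≈ 9.0 %, W ≈ 1.2 %).  The marginal
doubles as the insert-state emission distribution.  Letters outside the
20 standard amino acids emit uniformly (1/20), pair as if independent,
and never count as identical in PID.  Nucleotide input is accepted
mechanically (A/C/G/T are BLOSUM row letters) but the scoring model is a
protein model; treat nucleotide results accordingly.

All transition and emission parameters can be exported to and loaded from
a versioned flat `key = value` text file (`pnpalign.hmm.save_params` /
`load_params`, CLI `--hmm-params`).

**Numerics.**  Forward and backward run in log space with log-sum-exp;
results are finite for arbitrary lengths.  The unit suite checks
posteriors against exhaustive path enumeration to 1e−8 for all three
models.  Posterior entries below the sparsity cutoff 0.01 are zeroed
after forward–backward (once, after model averaging) and after each
consistency round; the same cutoff bounds the annealing candidate list.

## Consistency transformation

P′_xy = (1/N) Σ_z P_xz P_zy with P_xx = I, applied twice by default (the
established default in posterior-decoding aligners; the transformation is
idempotent in spirit but not in value, and more rounds over-smooth).
Matrices are dense numpy arrays; the z = x and z = y relay terms each
contribute P_xy itself.

## Distances and guide trees

Pair distance is 1 − expected accuracy, where expected accuracy is the
posterior mass collected by the best posterior-decoding monotone
alignment of the pair, normalized by the shorter sequence length (1 − PID
is the documented alternative; the config records which was used).
Agglomeration is implemented directly (O(N³), exact): UPGMA weights the
merged clusters' distances by cluster size, WPGMA averages them equally;
merge heights are half the merge distance.  Ties between equally close
cluster pairs resolve toward the lexicographically smallest (min leaf
index, max leaf index), making trees reproducible across platforms.
scipy's `linkage` ("average"/"weighted") serves as an independent oracle
in tests, never as the implementation.

WPGMA is selected iff σ(PID) < τ (strict; default τ = 0.115), UPGMA
otherwise.  Whenever every merge joins equal-size clusters the two
updates coincide, so the choice only matters for unbalanced merge
histories — precisely where treating a low-discrepancy cluster as one
meta-sequence (WPGMA) diverges from size-weighting (UPGMA).

## Profile–profile alignment

Column pairing (i, j) scores the *mean* posterior over cross-sequence
pairs with residues in both columns; the mean keeps a large profile from
dominating a small one, and no explicit gap penalty exists — skipping a
column forgoes posterior mass, as is standard in maximum-expected-
accuracy alignment.  Cross-pair posteriors are unweighted (sequence
weighting is not described for this stage in the ancestor tools).  DP
ties prefer match, then consuming the first profile's column, then the
second's.  All-gap columns created by a merge are deleted.

## Sequence annealing

Every residue starts as its own column node; chain edges encode
within-sequence order.  Candidate pairs (posterior ≥ cutoff) are
processed in descending probability, ties broken by (sequence, position)
keys.  An insertion merges two nodes and is accepted iff the merged set
keeps at most one residue per sequence and neither node currently
reaches the other (reachability by DFS; merging mutually unreachable
nodes cannot create a cycle, and a pre-existing path is exactly a
violated column-order constraint).  Checks run before mutation, so
rejected insertions need no rollback.  The three update cases usually
described — new set, join existing set, merge two sets — are all
instances of node merge under this representation.

The final alignment is one column per node in topological order (Kahn's
algorithm, priority queue keyed by smallest (sequence, position) member).
Residues never merged each occupy their own column, so zero posterior
support yields a fully staggered but valid alignment.  Annealed output
passes through the same refinement stage as progressive output
(configurable off): the refinement step follows the strategy branch
unconditionally in the pipeline definition.

## Refinement

Objective: total posterior mass realized by the alignment (sum of
Pr(x_i, y_j) over residue pairs sharing a column).  Each iteration draws
a uniform random bipartition (numpy `default_rng(seed)`; degenerate
splits with an empty side are redrawn without consuming an iteration),
re-aligns the two group profiles and accepts iff the objective strictly
increases.  Stopping: 2N consecutive non-improving iterations, or 4N
total.  Identical seeds give bit-identical output.

## Scoring

SP and TC follow the standard benchmark definitions: SP is the fraction
of reference residue pairs co-columned in the test alignment; TC the
fraction of scored reference columns whose residue set is reproduced
exactly as a test column.  Scored reference columns are those with
residues from at least two sequences by default (`full_columns=True`
restricts to all-sequence columns, the analogue of annotated-core
scoring).  The accumulated-difference curve sums per-σ-bin mean score
differences between two methods; it rises at a bin exactly when the
first method wins there, and its peak locates the natural threshold
between the methods — the calibration methodology behind both default
thresholds.

## Synthetic families

The generator plants `n_conserved_regions` evenly spaced regions of
`region_length` copied identically from a consensus into every sequence;
all other positions are i.i.d. uniform over the 20 amino acids (with
optional probability `background_identity` of copying the consensus).
Sequences share one length and no indels are planted, so the ground
truth is the gapless column alignment.  Defaults (8 sequences × 120
residues, two regions of 20) put conserved coverage at one third —
families in the 20–40 % identity band with low discrepancy, the regime
the WPGMA rule targets.

What the generator does *not* emulate: indels (so gap placement is never
tested against truth), phylogenetic correlation between sequences,
compositional bias, and conservation gradients.  Passing recovery tests
on these families shows the pipeline machinery is sound, not that it
matches benchmark accuracy on real protein families.

Problem sizes in the tests and the acceptance script (families of 3–8
sequences, 30–120 residues) were chosen as the smallest instances that
exercise every branch with comfortable statistical margins.

## Known limitations

* Pair-HMM transition parameters are package defaults, not re-estimated
  or copied from a published fit; accuracy on real benchmarks would need
  calibration.
* PID from one optimal alignment is tie-dependent in principle
  (deterministic in practice); thresholds interact with the PID
  convention as described above.
* Annealing emits one column per same-column set; columns of unmerged
  residues are not packed together even when order-compatible, so
  annealed alignments can be wider than strictly necessary.
* Single-threaded by design.
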