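# Methods

## Model

`csln` scores candidate protein targets for a query molecule that has no
interactions of its own ("cold start"). The working assumption is
ligand-based: molecules binding the same target tend to be structurally
similar, so a target is represented entirely by the chemistry of its
known ligands. Two representations are used side by side:

1. the **profile** F_t, the elementwise sum of the 167-bit MACCS
   fingerprints of the target's interacting drugs — a count vector whose
   cosine against the query fingerprint rewards sharing the cluster's
   *characteristic* bits; and
2. the **local network**, the ligand set itself — S1 is the mean
   pairwise Tanimoto among the x ligands (x(x−1)/2 pairs), S2 the mean
   after merging the query (x(x+1)/2 pairs), and S2/S1 rewards a query
   that tightens rather than dilutes the cluster.

The binding score is Score = w1·S_cos + (1−w1)·S2/S1 with one global
weight w1. The two channels are deliberately combined on their raw
scales even though S2/S1 can exceed 1; an optional `normalize_ratio`
flag (min–max over the screened target set) exists but is off by
default, because the score formula is defined on the raw values.

### Cosine variants

The package implements two denominators for S_cos. The default,
`"standard"`, is the ordinary cosine ‖F_t‖₂‖F_q‖₂, bounded by 1. The
alternative `"paper_literal"` divides by √(ΣF_t)·√(ΣF_q) — the L1 masses
under square roots. For a binary query the two coincide only when the
profile is also binary; for count-valued profiles the literal form is
unbounded (the tests construct cases above 1) and dimensionally
inconsistent, so the standard form is presumed intended and used by
default. The variant is stored in the model for provenance, and both
remain selectable for fidelity experiments.

## Conventions and degenerate inputs

* Tanimoto of two all-zero fingerprints is defined as 0.0: a featureless
  vector should match nothing. This matches common toolkit behaviour.
* MACCS bit 0 is a placeholder and must be 0; fingerprints are validated
  on construction and on load.
* A target needs at least two ligands to be scoreable (S1 averages over
  member pairs), hence the hard floor θ ≥ 2 on the degree threshold.
* S1 = 0 (all ligand pairs share no bits) makes S2/S1 undefined; such
  targets are skipped and reported as degenerate rather than given an
  infinite ratio.
* Ranking ties are broken by target id ascending so output is
  deterministic.
* Removing a drug to simulate a fresh molecule also removes targets left
  with no interactions; targets orphaned by *degree filtering* are kept,
  since their drugs may still serve as training queries.
* The MACCS bit dialect is pinned to one reference toolkit (RDKit); the
  frozen ethanol/caffeine bit sets in the tests document it. Other
  toolkits may differ in a few bits.

## Training

**w1.** "Feedback learning" is realised as an exhaustive grid search
(default grid 0.00–1.00, step 0.01) minimising Error = Σ|yᵢ − ŷᵢ| over
training pairs. The objective is piecewise linear in w1, so the grid
search is exact at grid granularity, reproducible, and needs no
optimiser state. Ties go to the larger w1. Predictions enter the
objective raw (they may exceed 1); no clipping.

**Training pairs.** Every observed edge is a positive; negatives are
non-edges sampled uniformly without replacement, `neg_ratio` per
positive (default 1.0), from a seeded generator. For each pair the drug
is excluded from the target's profile *and* from the S1/S2 member set —
without this leave-one-out contract every positive pair would partially
score itself. A positives-only objective (`neg_ratio=0`) is allowed but
not default: with no negatives the objective simply favours the
larger-valued channel.

**θ selection.** For each candidate threshold, w1 is first fitted on the
θ-filtered network, then every drug is held out in turn (its edges
removed, degrees recomputed so filtering reflects only the information
actually available), scored against the retained targets, and the
pooled (score, label) pairs give one AUROC (or AUPR) per candidate. The
best candidate wins, ties to the smaller θ, and the full (θ, metric)
curve is returned as a diagnostic. Fitting w1 per candidate (rather
than once globally) was a genuinely open choice; it keeps each
candidate's evaluation self-consistent, and at the package's scale the
extra grid searches are cheap.

## Evaluation

Cross-validation splits *drugs* into k folds (sizes differing by at most
one, seeded). Per fold the test drugs' rows are removed from the
training network entirely — equivalent to deleting their edges, since an
edge-free drug contributes to no profile — and θ and w1 are fitted on
what remains. Test drugs are scored against the targets retained at θ;
labels come from the original adjacency. Pairs are pooled within a fold
before computing AUROC/AUPR (per-drug averaging is available via
`per_drug_average`); pooling uses every pair and matches how
matrix-factorisation baselines are scored.

AUROC is the Mann–Whitney statistic with ties counted ½ (computed via
scikit-learn, which implements exactly that). AUPR is average precision
with equal-score groups ordered **pessimistically** — negatives ahead of
positives within a tie — so the reported value is deterministic and
never flattered by arbitrary tie order; it is hand-implemented because
standard step-wise average precision does not pin down tie order this
way.

## Synthetic data

The generator emulates the statistical structure the method assumes:
each target has a seed fingerprint (each of bits 1–166 set with
probability `bit_density`, default 0.2, roughly the set-bit density of
drug-like molecules under MACCS); members are copies with independent
per-bit flip probability `flip_rate`; decoys are independent draws;
`overlap_rate` lets a member join one extra target, creating
cross-cluster edges. Defaults for the cold-start experiments are 8
targets × 10 members with flip rate 0.02 — small, clean clusters on
which the method should and does succeed nearly perfectly.

What the generator does **not** emulate: real MACCS bit correlations
(bits are dependent in real molecules, independent here), heavy-tailed
degree distributions, promiscuous ligands, and target families sharing
chemistry. Passing tests therefore demonstrate correctness of the
computation and recoverability under the method's own assumptions, not
screening accuracy on real pharmacological data. The exact-count
builder (`network_with_counts`) reproduces published dataset *shapes*
(counts and sparsity only); edge placement is random and no fingerprints
are attached.

Problem sizes in the test-suite and the acceptance script (networks of
tens of drugs, 20 replicates, 101-point w1 grids) were chosen so that
each statistical check has clear headroom over its threshold while the
whole suite stays interactive to run.

## Known limitations

* The cosine and ratio channels live on different scales; w1 is fitted
  on the combined raw objective and is therefore not comparable across
  cosine variants.
* Grid-search w1 resolution is 0.01 by default; a finer optimum between
  grid points is not found (the piecewise-linear objective makes the
  loss difference bounded and small).
* All-pairs S1 computation is O(x²) per target; fine at benchmark scale
  (≤ a few hundred ligands per target), not tuned for targets with tens
  of thousands of ligands.
* Negative sampling treats all non-edges as true negatives; unobserved
  true interactions in sparse networks bias Error upward.
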