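# Methods

This document describes the model implemented by `mutblot`, the choices
made where the method leaves freedom, and the package's numerical and
statistical conventions. No empirical claims are made here beyond what
the test suite and `scripts/acceptance.py` compute.

## Problem setting

Somatic single-base substitutions (SBSs) are usually summarized by their
substitution type and immediate trinucleotide context. `mutblot` instead
treats each SBS together with 50 reference bases on each side as a
201-base "mutation sequence" and clusters these sequences without
supervision. The resulting clusters ("mutation blots", MBs) give every
patient a composition vector — the fraction of their SBSs in each MB —
which feeds downstream clinical analyses: patient clustering, group
comparisons of clinical variables, and survival tests.

## Encoding

Each base maps to a 2-bit code: A=[0,0], T=[0,1], C=[1,0], G=[1,1];
an unknown base N maps to [-1,-1]. A flank base `b` contributes the row
`[b | b]`; the mutated position contributes `[alt | ref]`. A sequence
with flank length F therefore becomes a (2F+1) x 4 integer matrix in
which the mutation site is the unique row whose halves can disagree.
The worked example CATTG>CACTG (flanks CA/TG, T>C) encodes to

```
[[1 0 1 0]   C
 [0 0 0 0]   A
 [1 0 0 1]   site: alt C | ref T
 [0 1 0 1]   T
 [1 1 1 1]]  G
```

For spectrum summaries, substitutions are collapsed onto the pyrimidine
strand (reverse-complementing the context when the reference base is a
purine), yielding the canonical 6 types C>A, C>G, C>T, T>A, T>C, T>G.

## Feature extractor

A two-layer LSTM (hidden size 64) reads the encoded matrix from both
ends toward the mutation site with shared weights: the 5' read in
natural order and the 3' read reversed, each ending at the site row.
The two final hidden states are concatenated and mapped by an affine
layer to an 8-dimensional feature vector. Reading toward the site makes
the bases nearest the mutation the most recent inputs, so they dominate
the representation (verified empirically in the test suite over 100
random initializations).

The LSTM, backpropagation through time, and the Adam optimizer
(learning rate 0.001) are implemented directly in NumPy; gradients are
verified against central finite differences in the test suite.

## Clustering layer

The competition layer is a set of 200 unit vectors living directly in
the 8-dimensional feature space (no lattice; all distances Euclidean).
For an input x:

- the winner `w_min` is the nearest unit;
- the threshold S is the distance from `w_min` to the unit at rank
  `ceil(q * n_units)` (1-based, winner = rank 1). The default
  q = 0.2 puts the gate at rank 40 of 200 units. The rank computation
  guards against binary floating-point excess (0.2 x 200 evaluates to
  slightly over 40 in floating point; the guard keeps the rank at 40);
- every unit receives a Gaussian decay in its distance to the winner,
  D(w_j) = exp(-d_j(w_min)^2 / (2 pi sigma^2)). The 2 pi factor in the
  denominator is kept exactly in this form; at d = 1, sigma = 1 the
  decay is exp(-1/(2 pi)) = 0.852864...;
- the per-unit update is Delta(w_j) = +/- L * D(w_j) * (w_j - x), with
  the positive sign for units inside the gate (d_j <= S) and negative
  outside. Units move by -Delta: gated units approach x, the rest
  recede. The default learning rate L is 0.005.

Updates run in frozen-layer batches of 100: every input in a batch is
scored against the layer state at batch start, unit motions are summed
and applied once at batch end. Each input also receives the opposite
aggregate feedback, x(new) = x + sum_j Delta(w_j), which pulls similar
inputs together and dissimilar inputs apart.

## Alternating training and the round

One *round* of training repeats, on random batches of 100 sequences:

1. extract feature vectors with the current LSTM;
2. one frozen-layer batch update of the competition layer, producing the
   fed-back vectors x(new);
3. fit the LSTM to the x(new) vectors by mean squared error for exactly
   2 Adam passes.

The round stops when the feature vectors of a fixed probe subset
(default 256 samples) move less than `stability_tol` (default 2e-4) per
epoch on average, or at `max_epochs` (default 100). The final feature
vectors of all samples are then read out into exactly two groups.

### Sigma calibration

The Gaussian decay only shapes the update when sigma is commensurate
with the distances between feature vectors. Randomly initialized LSTM
features occupy a data-dependent scale (typically far below 1), so a
fixed sigma either flattens the decay to ~1 everywhere (sigma too
large, which lets the update dynamics collapse all features toward
their mean) or kills it (sigma too small). By default the trainer
therefore sets sigma at layer initialization to
`auto_sigma_scale = 0.1` times the mean distance of the first batch's
feature vectors to their centroid. The value 0.1 was chosen by a
grid comparison of planted-class recovery on synthetic validation data
(scales 0.05-0.5; small scales are uniformly stable, 0.5 destroys the
clustering on some seeds). Setting `auto_sigma_scale=None` uses the
configured sigma verbatim.

### Binary readout

The method requires each round to end in exactly two groups but does
not prescribe how to cut the final feature cloud. The default readout
is 2-group Ward-linkage agglomerative clustering of the final feature
vectors: Ward merges whole point clouds bottom-up, so it cuts between
clouds rather than bisecting one, which matters when a leaf still
contains several latent classes. Two alternatives are available behind
`readout=`: "kmeans" (2-means on the features) and "units" (2-means on
the competition units, samples assigned through their nearest unit).
In a comparison on synthetic fixtures with planted classes, Ward
dominated 2-means at every neighborhood scale tried; the package's own
acceptance script reports the recovery numbers it achieves. Group 0 is
canonically the larger group, making labelings comparable across runs.

## Recursive schedule

The full procedure applies rounds recursively: 3 rounds of independent
binary splits produce 8 leaves (each leaf trains a fresh extractor and
fresh competition layer, with seeds derived from the root seed and the
leaf's tree path via SHA-256), after which the 2 largest leaves are
split once more, giving 10 MB classes. Classes are numbered MB 1..10
by decreasing size. Leaves smaller than 4 samples, or splits that
return an empty side, leave the leaf intact with a warning. All
randomness flows from one root seed, so a labeling is exactly
reproducible.

## Downstream analyses

- **Composition**: per-patient MB proportions (rows sum to 1); patient
  identity is the first three fields of the sample barcode, so aliquots
  merge.
- **Patient clustering**: K-means on composition rows; K defaults to 7,
  or `K="auto"` selects K by the elbow of the within-cluster
  sum-of-squares curve (largest second difference over `k_range`).
- **Group comparisons**: numeric variables use a t-test for 2 groups
  and one-way ANOVA for more; categorical variables use a chi-square
  test with Yates continuity correction on 2x2 tables (the worked
  example [[10,20],[20,10]] gives 5.4). Missing values are dropped and
  counted.
- **Survival**: multivariate log-rank tests via `lifelines`, validated
  in the test suite against an explicit risk-set tabulation, with
  Monte-Carlo checks of type-I error and power; Kaplan-Meier curves for
  plotting. Gene-level survival groups place each patient in the group
  of every MB observed in their mutations of that gene (`mode="all"`),
  or only patients with a unique MB (`mode="exclusive"`).

## Synthetic data generator

The generator exists to make planted-truth fixtures that flow through
the *same* readers and extraction code as real data:

- a reference FASTA is simulated at a target GC content;
- each planted class is a context profile: one canonical substitution
  type plus per-position base probabilities that are strongly enriched
  for a dominant base adjacent to the site (probability 0.9 at distance
  1) and decay exponentially toward uniform with distance (scale 8);
- class flanks are written into a scratch copy of the genome at spaced
  sites, so ordinary flank extraction reproduces the planted context
  exactly;
- patients are archetypes with mixture weights over classes,
  exponential survival times with archetype-specific hazards, and
  uniform censoring;
- hidden truth (per-SBS class, per-patient archetype) is written to
  separate files, never into the MAF;
- profiles must differ by a minimum total-variation separation, and
  everything is byte-reproducible from one seed.

## Numerical conventions

- All floating-point state is float64.
- Derived seeds are SHA-256 digests of the root seed and a tag path,
  reduced modulo 2^31.
- The SOM batch update is asserted (in tests) to match a scalar
  brute-force oracle to 1e-12 and to conserve feedback
  (x(new) - x = sum of deltas) to 1e-15.
- LSTM gradients are exact BPTT gradients, not approximations.

## Limitations

- The clustering is stochastic; planted-class recovery is a median
  statement over seeds, not a per-seed guarantee.
- With 10 leaves for 10 planted classes the schedule has no slack: a
  single impure split caps the achievable agreement, which is why
  recovery on the 10-class fixture is noticeably below the 2-class
  fixture.
- The NumPy LSTM runs on one CPU; corpus-scale runs (millions of SBSs)
  are out of scope.
- The synthetic generator does not imitate real mutation burdens,
  chromosome structure, or signature etiologies; it only provides
  recoverable planted structure.
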