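# mutblot

Unsupervised clustering of somatic single-base substitutions (SBSs) by
their long flanking sequence context, with downstream per-patient
clinical analyses.

## The problem

Mutational signature analysis usually reduces an SBS to its substitution
type plus one base of context on each side (96 trinucleotide channels).
That discards almost all of the surrounding sequence. `mutblot`
implements an alternative: each SBS is represented together with 50
reference bases on each side, and these 101-base "mutation sequences"
are clustered without supervision into *mutation blots* (MBs) — classes
of SBSs that share extended sequence context. Every patient then gets a
composition vector (the fraction of their SBSs in each MB) that can be
clustered, compared across clinical groups, and tested for survival
differences.

## The model

1. **Encoding.** Bases map to 2-bit codes (A=[0,0], T=[0,1], C=[1,0],
   G=[1,1]); a flank base `b` becomes the row `[b|b]`, the mutated
   position becomes `[alt|ref]`, so an SBS with flank length F is a
   (2F+1) x 4 matrix.
2. **Feature extraction.** A two-layer LSTM (hidden size 64, pure
   NumPy) reads the matrix from both ends toward the mutation site with
   shared weights; the concatenated final states map to an
   8-dimensional feature vector, so bases near the mutation dominate.
3. **Clustering layer.** 200 competition units live directly in the
   feature space. For each input, units within a rank-based threshold
   of the winner (rank 40 of 200 by default) are attracted toward it
   and all others repelled, with Gaussian decay
   `exp(-d^2 / (2 pi sigma^2))`. Updates run in frozen-layer batches of
   100, and each input receives the opposite aggregate feedback
   `x(new) = x + sum(Delta)`, which pulls similar inputs together.
4. **Alternation.** The LSTM is refit to the fed-back vectors (2 Adam
   passes, MSE) and the loop repeats until the features stop moving;
   the final features are cut into two groups by Ward linkage.
5. **Recursion.** Three rounds of independent binary splits (fresh
   models per leaf) give 8 leaves; the 2 largest are split once more,
   yielding 10 MB classes numbered by decreasing size.

See `docs/methods.md` for the full description and the rationale behind
every default.

## Worked example

Encoding the substitution CATTG>CACTG (a T>C with flanks CA and TG),
from `examples/01_encode_a_mutation.py`:

```
encoded matrix (one row per base, mutation row = [alt | ref]):
[[1 0 1 0]
 [0 0 0 0]
 [1 0 0 1]
 [0 1 0 1]
 [1 1 1 1]]
mutation site row index: 2
```

Training one binary round on a synthetic cohort with two planted
context classes and scoring against the hidden truth, from
`examples/03_train_and_cluster.py`:

```
trained for 12 epochs, converged=True
group sizes: [1202  798]
adjusted Rand index vs planted classes: 0.992
```

The other examples cover synthetic-cohort generation
(`02_generate_synthetic_cohort.py`) and the downstream per-patient
pipeline — MB composition, patient clustering, and log-rank survival
comparison (`04_patient_analysis.py`).

## Library tour

- `mutblot.sbs_io` — MAF and clinical readers, indexed FASTA access,
  flank extraction with reference-mismatch policies.
- `mutblot.encoding` — sequence encoding, bidirectional reads,
  pyrimidine collapse to the 6 canonical substitution types.
- `mutblot.feature_extractor` — the NumPy LSTM (BPTT + Adam),
  checkpointing.
- `mutblot.som` — the threshold-gated attract/repel competition layer.
- `mutblot.trainer` — alternating rounds, the recursive schedule,
  MB labelings, seed derivation, run manifests.
- `mutblot.downstream` — compositions, spectra, patient clustering with
  elbow selection, group tests (t-test/ANOVA/chi-square), log-rank and
  Kaplan-Meier survival, gene-level MB survival groups.
- `mutblot.synthetic_data` — planted-truth cohort generator used by the
  tests and the acceptance script.

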