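# Methods

This note describes what `parascope` computes, the parameters it defaults
to, and the reasoning behind the main design decisions.

## 1. Ground-truth paratope and epitope labels

A residue of the antibody Fv region is labeled a paratope residue if any of
its non-hydrogen atoms lies within 4.5 Å (inclusive) of any non-hydrogen
atom of the antigen. Epitope labels are the same criterion with the roles of
antibody and antigen swapped; the implementation is one role-symmetric
routine.

Parsing details (`parascope.structure`):

- PDB and mmCIF files are read with gemmi; the first model is used.
- Hydrogens and deuteriums are excluded by element, with an atom-name
  fallback (leading H/D after stripping digits) for files without element
  columns.
- Alternate locations are resolved to the highest-occupancy conformer
  (ties broken by altloc identifier) before any distance is measured, so a
  residue never counts contacts from two mutually exclusive conformers.
- Waters and non-amino-acid heteroatoms are dropped; nonstandard amino
  acids are kept, sequence-coded as `X`, and logged.
- Residue identity is the triple (chain, residue number, insertion code),
  ordered by number then insertion code.
- Contact queries use a k-d tree (`scipy.spatial.cKDTree`) over the
  opposite molecule's heavy atoms; the boundary is inclusive (d ≤ 4.5
  labels positive). An exhaustive all-pairs scan is kept in the test suite
  as an independent oracle.

## 2. Paratope asymmetry

An antibody's two arms are chemically identical, so any difference between
their observed paratopes is conformational or crystallographic, not
sequence-driven. For arm paratope sets P₁, P₂ of (amino-acid, position)
pairs:

- asymmetry = |P₁ △ P₂| (symmetric difference count);
- normalized asymmetry = |P₁ △ P₂| / |P₁ ∪ P₂|, which is the Jaccard
  distance; undefined (raises) when both sets are empty.

Example: {L63, Q64, G66} vs {L63, Q64, A67} → asymmetry 2, normalized 0.5.

Dataset curation applies four filters at the complex level, in order:
(1) protein or peptide antigen; (2) both heavy and light chain present
(excludes nanobodies); (3) exactly two arms; (4) identical arm sequences,
relaxable to a Levenshtein distance ≤ N (computed with edlib). The stage
counts after each filter are reported for auditability.

`arm_upper_bound` scores arm 2's labels as if they were predictions of
arm 1's labels (F1 and MCC). Since no sequence-based predictor can
distinguish the arms, this is an empirical ceiling on per-complex
performance.

## 3. Embedding layer

`EmbeddingBackend` is a protocol: given the heavy/light chain sequences it
returns one vector per residue. Multiple backends are concatenated
column-wise in alphabetical order of backend name, and the resulting
`FeatureMatrix` records a block index mapping each backend name to its
column range — the interpretability layer depends on this.

The bundled `SyntheticBackend` is a deterministic stand-in for a pretrained
protein language model. Each residue's vector is generated by hashing
(backend name, seed, chain tag, ±2-residue sequence context) with BLAKE2b
and drawing standard normals from a PCG64 generator seeded by the hash.
Consequences that the tests rely on:

- identical (name, seed, context) → identical vector; changing any of them
  decorrelates the output;
- windows never cross the heavy/light boundary ("paired-aware" mode), so
  paired-mode features for the heavy chain equal single-mode features — a
  "single-sequence" variant that embeds the concatenated chains is provided
  to exercise the other behavior;
- `X` (unknown residue) embeds as the mean over the 20 standard
  substitutions at that position.

`PlantedSignal` adds a constant shift (effect size β) to designated
dimensions at designated positions. This is what makes supervised-learning
behavior checkable: a classifier should find the planted dimensions, and
with β = 0 it should find nothing.

What the synthetic backend does NOT emulate: long-range sequence context,
residue biochemistry, inter-residue correlation structure, or any learned
representation. Results on synthetic fixtures validate the machinery
(shapes, determinism, training dynamics, attribution bookkeeping), not
biological predictive power.

## 4. Paratope model

A per-residue feed-forward network in pure NumPy: input d → 2000 → 1000 →
500 → 1, ReLU activations, logistic output. For d = 24 the parameter count
is (24+1)·2000 + (2000+1)·1000 + (1000+1)·500 + (500+1)·1 = 2,552,001.

Training protocol and defaults (`TrainConfig`):

- loss: mean binary cross-entropy, probabilities clamped to
  [1e-7, 1 − 1e-7];
- optimizer: Adam (β₁ = 0.9, β₂ = 0.999) with bias correction,
  learning rate 1e-5, decoupled weight decay 1e-5 applied to weight
  matrices only (not biases);
- regularization: dropout 0.4 on hidden layers (inverted scaling), plus
  input masking — each input coordinate is independently zeroed with
  probability 0.4 during training only;
- batches of 16 sequences, loss averaged over the residues in the batch;
- early stopping: per-protein validation PR AUC, patience 10 epochs,
  maximum 300 epochs, strict improvement required; the best-epoch
  parameters are restored at the end;
- initialization: He-scaled normals from a seeded generator, so runs are
  bit-reproducible for a given seed.

The defaults are the recommended full-scale settings. They are
intentionally not what the test suite uses: at the test suite's synthetic
scale (d ≤ 64, dozens of sequences) the full widths and learning rate
would be slow and undertrained, so tests use reduced widths (e.g.
128/64/32) and learning rate 1e-3, while the full architecture is still
constructed, run forward, and checked against its closed-form parameter
count.

Single-class validation proteins cannot produce a PR AUC and are skipped;
training refuses to start if no validation protein is scorable.

## 5. Evaluation

Four metrics per complex — PR AUC (average precision, step-function
summation), ROC AUC, F1 and MCC at threshold 0.5 (binarization is p ≥ 0.5)
— averaged unweighted across complexes. Complexes whose labels are all one
class have undefined AUCs: they are excluded from the AUC means and their
count is reported. Degenerate F1/MCC denominators return 0 with a warning
rather than raising, since all-negative predictions are a meaningful model
output. sklearn provides the AUC implementations; exhaustive concordance
counting and enumerated confusion tables serve as oracles in the tests.

Per-protein averaging is deliberate: pooling residues across complexes
would weight long sequences more and can produce a different ranking (the
test suite carries a counterexample).

## 6. Interpretability

Shapley values apportion a prediction among input dimensions. `exact_shapley`
enumerates all 2ⁿ coalitions (features not in the coalition take their
baseline value) and is limited to n ≤ 12 — 2¹² evaluations is the practical
desk-scale bound, and the error message points to the estimator beyond it.
`approx_shapley` samples permutations and averages marginal contributions;
the baseline is the mean of a background sample, and per-permutation
telescoping makes the estimator satisfy efficiency exactly at any sample
size.

Backend importance sums |φᵢ| over each backend's column block ("raw" mode)
or divides the sum by block width ("mean" mode, controlling for embedding
dimensionality), then normalizes to sum to 1. Absolute values are the
default so the normalization is well defined; signed aggregation is
available. Profiles can be averaged across residues or keyed by position
(averaging only over sequences where the position exists).

## 7. Downstream quantities

- Paratope size proxy: Σᵢ pᵢ over residues — continuous, so it does not
  need a threshold; a binarized variant counts pᵢ ≥ t.
- Pooled embedding: unweighted mean, or the paratope-weighted form
  Σᵢ wᵢ eᵢ with wᵢ = pᵢ / Σⱼ pⱼ. Weights are scale-invariant; a zero
  probability sum raises rather than silently degrading to the mean.
- Track combiner: given a full-length probability track, a region mask,
  and region-restricted probabilities (compact or full-length), the region
  values replace the full track's values at masked positions — raw
  substitution, no renormalization, idempotent by construction.

## 8. Synthetic fixtures

- Toy complex: antibody Cα atoms on an 8 Å-spaced lattice; each position
  gets one antigen atom at 4.4 Å (contact) or 4.6 Å (decoy), straddling the
  4.5 Å cutoff so the labeler's boundary handling is directly observable.
  Optional hydrogen decoys sit 1.0 Å from non-contact positions and must be
  ignored.
- Two-arm complex: the arm is duplicated into two chain pairs offset in z;
  asymmetry k is planted by adding contacts to arm 2 where possible
  (keeping the union at |P₁| + k) and dropping otherwise, so the planted k
  is exactly recoverable.
- Training set: paired random sequences; labels are drawn inside three
  CDR-like windows covering ~30 % of each chain, with within-window
  probability chosen to hit a target prevalence (default 0.12); the planted
  signal shifts designated feature dimensions at positive residues;
  60/20/20 split by seeded permutation.

## 9. Numerical and engineering choices

- Everything is seeded; the acceptance script derives all seeds from a
  single `--seed` via `numpy.random.SeedSequence`.
- Probability clamping at 1e-7 bounds a single BCE term at ~16.1 and keeps
  gradients finite.
- The MLP, Adam, dropout and Shapley computations are implemented in NumPy
  rather than a deep-learning framework: the models are small, the
  algorithms are the package's own subject matter, and this keeps the
  dependency set importable offline.
- Errors are typed (`parascope.errors`): undefined mathematical inputs
  raise (`UndefinedInputError`, `UndefinedMetricError`,
  `NormalizationError`), contract violations by embedding backends raise
  `ContractViolationError`, and misaligned tracks raise `AlignmentError`,
  so silent shape coercion cannot corrupt results.

## 10. Limitations

- No pretrained language-model weights ship with the package; headline
  benchmark numbers from the antibody literature are not reproducible here
  and are not claimed.
- The structure annotation assumes the first model of a file and one
  conformer per residue after altloc resolution; NMR ensembles are not
  averaged.
- Exact Shapley is exponential in feature count by design; for realistic
  embedding widths only the sampling estimator is practical.
- The curation filters operate on a metadata table (one row per arm); they
  do not re-derive arm pairing from structure.
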