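# Methods

## Problem and model

The package classifies (drug, nuclear receptor) pairs as interactive or
non-interactive. A pair is represented by the orthogonal sum of two
fixed-length encodings:

* **Drug, 256 components.** A 2-D molecular fingerprint vector. The
  canonical source is a precomputed table (one row per drug id, 256
  values); values are treated as reals throughout, so binary and counted
  fingerprints are both accepted. For drugs without a table entry a
  structure-based fallback is provided (hashed linear-path fingerprint
  folded to 256 bits, computed with RDKit on the canonicalized molecular
  graph); its output is flagged `source="fallback"` because it is a
  standard topological fingerprint, not the specific fingerprint the
  precomputed tables were built with — mixing the two in one dataset is
  possible but should be done knowingly.

* **Receptor, 500 components (PseAAC).** Four groups: amino acid
  composition (20), ordered dipeptide composition (400, divisor L−1),
  sigmoid-scaled PSSM column means (20), and grey-model features (60).
  All residue-indexed quantities use the full alphabetical order
  A C D E F G H I K L M N P Q R S T V W Y. PSI-BLAST ASCII matrices print
  their columns in a different fixed order (A R N D C Q E G H I L K M F P
  S T W Y V); the reader remaps them on input, and only the first 20
  (log-odds) columns are used.

The 756-component pair vector is standardized componentwise,
y = (x − mean)/SD with mean and SD from the training vectors, and
classified by a soft-margin RBF-kernel SVM.

## Grey-model features

For each scaled-PSSM column e = (e₁ … e_L) the model solves the
least-squares problem B θ = U with

    U_k = e_{k+1} − e_k                      (k = 1 … L−1)
    B_k = [ −e_{k+1},  −(Σ_{i≤k} e_i + ½ e_{k+1}),  1 ]

and keeps θ = (a1, a2, b). This is the parameter fit of a
first-order grey system model: the first differences are regressed on the
signal level and its accumulated (background) sum, capturing the trend of
the evolutionary conservation signal for one residue type along the
sequence. The three coefficients are weighted by the residue type's
composition frequency (weights w₁ = w₂ = w₃ = 1 by default, configurable).

**Numerical choice.** θ is computed by minimum-norm least squares
(`lstsq`), not the literal normal-equation inverse (BᵀB)⁻¹BᵀU: for a
constant column, U = 0 and columns 1 and 3 of B are proportional, so BᵀB is
singular and the literal formula is undefined. Minimum-norm least squares
agrees with the normal equations whenever B has full column rank (verified
in tests against an independent 3×3 solve on random full-rank columns,
condition number < 10⁸) and returns the natural (0, 0, 0) solution when
U = 0.

**Minimum length.** The full encoding requires L ≥ 4 so the grey design has
at least 3 rows; shorter sequences are rejected rather than zero-filled,
which would silently produce meaningless grey features.

## Validation, standardization and degenerate inputs

* Sequences are validated against the 20-letter alphabet. Non-standard
  codes (B J O U X Z) are rejected by default; an opt-in mode drops those
  positions and records them so the matching PSSM rows are dropped too.
  Composition denominators then refer to the cleaned length, keeping the
  composition blocks proper probability vectors.
* Standard deviation uses divisor n (population form; divisor n−1
  available). Features with SD = 0 standardize to 0 — an information-free
  feature has no meaningful z-score, and 0 is the neutral value.
* The decision threshold is 0 with exact zero mapped to +1; the tie has
  negligible probability but determinism requires a rule.
* Sigmoid-scaled PSSM entries are clipped into the open interval (0, 1) at
  machine precision so extreme log-odds cannot produce exact 0/1 and break
  the scaled-matrix invariant.
* Metrics are defined only when both classes are present. The Matthews
  coefficient is reported as *undefined* (not 0) when a predicted class is
  empty — the zero-factor cases of the misprediction-count form coincide
  exactly with the zero-denominator cases of the textbook form.

## Cross-validation protocol

Evaluation is leave-one-out ("jackknife"): each pair is predicted by a
model trained on the remaining n−1. By default the standardizer is refit on
each training fold, so no information from the held-out pair leaks into the
scaling; a `global` mode fits it once on the full dataset first, which
matches evaluation protocols that scale the whole dataset before
cross-validation and can change results slightly. Negative training pairs
are constructed by re-coupling the drugs and receptors of the positive set
and sampling uniformly without replacement (default ratio 1:2,
seed-recorded). No class weighting is applied by default despite the 1:2
imbalance; it is exposed as an option. The (C, γ) operating point defaults
to (2³, 2⁻⁹); `grid_search` scans power-of-two grids
C ∈ {2⁻⁵ … 2¹⁵}, γ ∈ {2⁻¹⁵ … 2³} by jackknife accuracy, breaking ties
toward smaller C then smaller γ.

## Synthetic benchmark

The generator emulates all three external inputs with no downloads. Each
drug carries a latent type u ∈ {±1} expressed in 32 fingerprint bits whose
set-probability is shifted by min(0.45, 0.1·s)·u (s = `signal_strength`);
each protein carries a latent class v ∈ {±1} expressed as a raw-score
offset 0.5·s·v on 8 PSSM columns, which propagates into the scaled column
means and grey features. Pair affinity is s·u·v plus unit Gaussian noise
and the top `n_positive` pairs are labeled interactive; negatives are drawn
by the same re-coupling procedure as for real data, over all generated
entities.

Defaults (12 drugs × 6 proteins, 20 positives, ratio 2, s = 4, unit PSSM
noise, fingerprint density 0.15, lengths 50–120) give a 60-pair benchmark.
The entity-type counts are chosen so the aligned block (u·v = +1) has
exactly 20 members; with s = 4 the affinity gap between aligned and
anti-aligned pairs (≈ 8 vs. unit noise) means the planted labels are a
noise-free XOR of the entity types, so a correctly wired pipeline can in
principle classify every pair. When a spec admits no exact block partition
the generator falls back to balanced types, and labels near the
top-`n_positive` cut then carry irreducible ranking noise — accuracy
guarantees apply only to exact-block specs. At the default operating point
the jackknife accuracy on the default benchmark is ≈ 0.92–1.00 across
seeds, against a label-permutation baseline of ≈ 0.6.

What the generator does **not** emulate: real fingerprint bit correlations
(bits are independent Bernoulli), true alignment statistics (PSSM noise is
i.i.d. Gaussian around a diagonal signal; an integer-rounding flag exists
for file round-trip realism), homologous sequence structure, and the
many-entity sparsity of real interaction networks (6 receptors appear in
~10 pairs each). Consequently, passing the synthetic learning check shows
the feature wiring, standardization and classifier are correct and that the
pipeline can recover a planted bilinear interaction rule; it says nothing
about accuracy on curated interaction data, which depends on the real
fingerprints and evolutionary profiles.

Two limitations of the planted design are worth knowing. First, with only
six receptors the composition blocks identify each protein, so ablating the
PSSM block alone does not reduce accuracy (the classifier recovers the
protein class from per-protein label patterns); PSSM wiring is instead
verified by checking the class signal appears in, and only in, the
scaled-column-mean segment. Second, the label-permutation null of the
jackknife MCC at n = 60 has standard deviation ≈ 0.14 — close to the
1/√(n−1) floor of a correlation coefficient under fixed margins — so
individual permutation replicates land outside ±0.25 in roughly one case in
ten; the permutation check is therefore most informative as a comparison of
means (planted-signal accuracy vs. permuted-label accuracy), which differs
by ≈ 30 percentage points.

## Problem sizes

The test suite and acceptance checks run on the 60-pair default benchmark
(full jackknife ≈ 0.2 s), a 30-pair variant for model unit tests, and a
20-replicate permutation null (≈ 4 s); the metric-equivalence check
enumerates all 8100 confusion matrices with class totals up to 12. These
sizes exercise every code path at full feature dimensionality (756).
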