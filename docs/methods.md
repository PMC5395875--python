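# Methods

This note records the modeling decisions behind `seqloop`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and known limitations.

## Oligomer distance histograms

For alphabet Σ = {A,C,G,T}, oligomer length K and maximum separation D,
the transform Φ(s) counts ordered K-mer occurrence pairs at start
positions p₁ ≤ p₂ with separation d = p₂ − p₁ ≤ D. Conventions:

- **d = 0 is the self-pair diagonal.** Every occurrence is paired once
  with itself, so only (i, i, 0) coordinates occur at separation zero, and
  the total count of a length-L sequence without ambiguity codes is
  P(P+1)/2 with P = L − K + 1 occurrence positions.
- **Separations beyond D are dropped** (truncated histogram). Loci are
  kilobases long while D defaults to 100 bp, so the histogram captures
  local co-occurrence structure, not global composition.
- **Ambiguity codes:** N is retained in stored sequences, but any K-mer
  window touching a non-ACGT character contributes nothing. This is the
  conservative standard treatment.
- **Strand:** sequences are used exactly as supplied (reference forward
  strand); there is no reverse-complement augmentation.
- **Coordinates** are 0-based half-open internally (BED); readers accept a
  `one-based` dialect flag for coordinate strings printed 1-based
  inclusive.

Feature vectors are stored as sorted flat integer keys
(i·M + j)·(D+1) + d with counts, which keeps the K = 5 space (≈1.06·10⁸
coordinates) tractable; Gram matrices are computed by sparse
matrix–matrix products.

**Normalization.** By default feature vectors are raw counts and the
kernel is the literal inner product **X**ᵀ**X**. An `l2_normalize` flag
rescales each Φ(s) to unit norm. Raw counts make kernel magnitudes grow
quadratically with locus length (self-similarities ~10⁴–10⁶ for kilobase
loci), which has a practical consequence for SVM training: the dual
variables then never reach the cost bound anywhere on the 10⁻³…10³ grid,
so every fit degenerates to a hard-margin SVM and cost selection becomes
vacuous. For single-locus problems with hundreds of samples this is
usually harmless (the hard-margin solution already separates well), but
for the product-kernel multitask setting it is actively harmful (see
below). The multitask benchmark therefore runs on unit-norm vectors; the
single-task default remains raw counts.

## Training protocol

- Outer 5-fold stratified cross-validation on the full labeled set
  produces the reported per-fold test AUCs and five primal weight
  vectors, whose elementwise mean is the representative weight vector
  used for interpretation. An optional stratified 80/20 hold-out split
  (`stratified_split`) supports final-model evaluation on untouched data.
- Within each outer training split, an inner 5-fold CV picks the cost
  from 10^{−3..3} by mean inner AUC; ties go to the smallest cost
  (determinism, preference for stronger regularization). Inner folds that
  end up single-class (possible for very small classes) are skipped.
- Class imbalance: the minority class's misclassification cost is
  multiplied by (majority count / minority count); no flooring.
- A degenerate outer fold (one class absent) triggers exactly one refold
  with a shifted seed, then an error.
- Primal recovery: w = Σ_s (α_s y_s) Φ(s) over support vectors, valid
  because the kernel is linear in Φ; decision values computed in primal
  and kernel form agree to better than 10⁻⁶ relative (asserted per fold
  in the test suite).
- AUC is the rank-based area under the ROC curve with ties counting 1/2
  (scikit-learn's `roc_auc_score`); one-class inputs are an error.

## Multitask learning

Samples from T tasks are pooled under
K_MTL((s_A,t_A),(s_B,t_B)) = K_S(s_A,s_B) · K_T(t_A,t_B), with K_T the
ODH inner products of the model-defining locus sequences at the same K
and D as the sample kernel. The product of PSD kernels is PSD (Schur).
Samples appearing in several tasks are distinct (sample, task) tuples.
Per-task AUC is computed from pooled out-of-fold decision values, so each
sample is scored exactly once by a model that never saw it.

Two numerical facts matter in practice:

1. **Task-kernel scale.** Raw K_T entries for kilobase model loci are
   ~10⁶–10⁷ and multiply into every kernel entry; the
   `cosine_task_kernel` flag rescales K_T to unit diagonal so the product
   kernel keeps the sample kernel's scale. The raw form remains the
   default for fidelity to the kernel definition.
2. **Within-task emphasis and anti-learning.** Any excess of K_T's
   diagonal over its off-diagonal multiplies within-task similarities
   relative to cross-task ones. With few samples per task and
   near-orthogonal high-dimensional features, emphasizing a sample's own
   task block makes the pooled SVM memorize per-task training sets and
   generalize *worse than chance* on held-out task members — the known
   anti-learning regime of diagonal-dominant kernels. Multitask transfer
   therefore helps precisely when tasks are genuinely similar (K_T close
   to uniform), and the benchmark below constructs that situation
   explicitly rather than hiding the effect.

## Contact labeling

- **5C side:** positives are loci called a peak in all replicates,
  negatives in none; partially-called loci are excluded from training.
  FDR levels (1/10/15%) are attributes of the consumed label table, with
  10% as the working default; the upstream peak caller is out of scope.
- **Hi-C side:** counts are balanced as count/(norm_i · norm_j); entries
  touching NaN or zero factors are dropped. The expected value at bin
  distance d is the mean normalized count over *all* bin pairs at that
  distance within the span of bins present, structural zeros included, no
  smoothing — the simplest defensible distance-stratified expected model.
  A partner bin is significant when O/E ≥ 2.5 (inclusive) at 5 kb and in
  the containing coarser bin at 10 kb or 25 kb; a model locus spanning
  several bins qualifies a partner through any of its bins. The 1 Mb
  exclusion band keeps only partners whose nearest edge lies strictly
  beyond the band.

## Synthetic data

The generator emulates the pipeline's three inputs with known truth:

- **Sequences:** i.i.d. background (uniform base composition by default;
  a composition parameter exists because real loci are GC-biased) with,
  in positives, planted signals: a K-mer pair written at exact separation
  d\*, and/or a tandem-repeat tract of a 1–3 bp unit. The default signal
  is a 5-mer pair (ACGTT…GGATC, d\* = 20, two copies per positive) plus a
  GT-dinucleotide tract of 8–14 units — chosen so that the default
  dataset (60 positives, 200 negatives, 500–1500 bp loci) is cleanly
  separable, mirroring the tandem-repeat-like signals this kind of model
  is expected to exploit in real data. Default lengths (0.5–1.5 kb) keep
  the diverse-length property of restriction fragments at a size that
  transforms quickly. Label noise, when requested, flips labels after
  planting.
- **Peak tables:** with probability `agreement_rate` all replicates agree
  with the truth; otherwise the pair is called in a random non-empty
  proper subset of replicates and lands in the uncalled partition.
- **Hi-C:** balanced-signal mean base_count·(1+|i−j|)^−γ at 5 kb
  (γ = 0.8, base 400 by default), multiplied by the requested fold for
  enriched cells, scaled by per-bin factors near 1 and Poisson-sampled;
  10 kb and 25 kb raw matrices are exact sums of their constituent
  unordered 5 kb cells.

What the generator does **not** emulate: genomic repeat families and
compositional heterogeneity of real chromatin, restriction-site-aware
fragment boundaries, trans contacts, and the correlated noise structure
of real Hi-C. Passing tests on this generator demonstrate correctness of
the machinery and recoverability of planted signals, not real-data
performance.

### Benchmark conditions used by the test suite

- **Discrimination:** default generator conditions (60/200), K = 3,
  D = 100; nested CV on true labels and on a label permutation.
- **Interpretation recovery:** a pair-only 3-mer signal (ACG…TTG,
  d\* = 12, three copies) in 30/100 datasets of 0.5–1 kb loci, ten
  generator seeds. The tract signal is omitted here so the planted pair
  is itself a single feature-space coordinate rather than being spread
  over frame-shifted keys.
- **Multitask:** ten tasks, eight samples each (2 positives, 6 negatives,
  0.3–0.6 kb), sharing the standard signal at one planted copy with
  probability 0.7 — individually data-starved, collectively well
  determined. Model-defining loci are 5 kb sequences derived from one
  template at 2% point mutation, giving high task similarity (cosine
  ≈ 0.95), the regime where product-kernel transfer is expected to work;
  unit-norm features and the cosine task kernel are used for the scale
  reasons above. Single-task baselines use 2-fold nested CV (the largest
  stratified protocol the two positives admit), the multitask model
  5-fold. Reported quantities are means over ten generator seeds of the
  per-task mean AUC and of the across-task standard deviation.

## Numerical choices and edge cases

- Ties in AMPD and TopN break to the lexicographically first adjoined
  2K-mer (equivalently the smallest pair index under A<C<G<T base-4
  encoding), then to the smaller distance; an all-zero weight vector
  reports weight 0 with the first pair at every distance.
- TopN selects by signed value per polarity (separate positive and
  negative panels), not by absolute value pooled.
- PWWM columns are exact probabilities (each column sums to 1 by
  construction since every motif contributes its magnitude at every
  position); logo letter heights are the column entries directly, not
  information content.
- Kernel PSD tolerance: smallest eigenvalue ≥ −10⁻⁸ × largest.
- Figures are written deterministically (fixed metadata, fixed SVG hash
  salt), so re-rendering identical inputs is byte-identical.

## Limitations

- The pipeline consumes peak-call labels and balancing vectors; it does
  not re-derive them (no z-score peak calling, no Knight–Ruiz solver —
  the synthetic generator simply draws factors near 1).
- Only text triplet Hi-C inputs are supported (no .hic/.cool containers),
  and only cis contacts are labeled.
- Probability calibration, non-linear kernels, and learned task
  similarity are out of scope.
- Primal weight interpretation is only meaningful for the linear ODH
  kernel; the multitask model is interpreted per task through its kernel
  form, not through a single primal vector.
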