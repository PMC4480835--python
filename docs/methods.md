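# Methods

## Model and assumptions

`varfx` treats variant-effect prediction as binary classification of single
amino-acid substitutions into *effect* (any change of molecular function)
and *neutral*. The classifier is an ensemble of ten feed-forward networks,
one per cross-validation rotation, each with one sigmoid hidden layer and
exactly two sigmoid output units (neutral, effect). The final score for a
variant is the difference of the per-class output averages over all ten
members, scaled to −100 … +100; the binary decision compares the raw
difference against a threshold, and the reliability index
`RI = floor(10·|out_eff − out_neu|)` (capped at 10, displayed 0–9) exposes
prediction confidence.

Assumptions worth stating explicitly:

* effect and neutral are exhaustive and mutually exclusive; gain and loss
  of function are not distinguished;
* homology is transitive for the purpose of train/test separation
  (single-linkage clustering deliberately over-merges rather than risking
  leakage);
* the features available at prediction time are the same as at training
  time — descriptors backed by missing external profiles cause row
  exclusion, never silent imputation.

## Training protocol

Each network trains by mini-batch SGD with momentum on squared-error-style
sigmoid outputs using the cross-entropy gradient (no output-saturation
factor). Batch gradients are summed, which is equivalent to sequential
per-pattern updates at the configured learning rate up to within-batch
weight staleness. The anti-overfitting loop is:

* **S1** every repetition draws a fresh class-balanced training sample
  (majority class down-sampled to the minority count);
* **S2** after each repetition the AUC on the cross-training fold is
  recorded and the best-scoring weight snapshot is kept;
* **S3** training continues at least ten repetitions beyond the current
  best (configurable, never fewer than ten) before stopping, bounded by a
  repetition cap.

The returned model is always the snapshot with the maximal cross-train AUC,
so the reported model can never be worse (on cross-train) than any earlier
snapshot. Hyperparameters are searched per rotation on that rotation's own
cross-training fold within the ranges: hidden units 10–100, learning rate
0.005–0.1, momentum 0.01–0.3; ties prefer fewer hidden units, then the
lower learning rate.

## Cross-validation construction

Pairwise similarity evidence below an E-value threshold (default 10⁻³, in
either search direction) yields graph edges; connected components are the
clusters; clusters are packed whole onto ten folds greedily, largest first
(ties in seeded random order) onto the currently smallest fold. The packing
is deterministic per seed. Rotation *t* tests on fold *t*, cross-trains on
fold *(t+1) mod 10* (a fixed convention — the cross-train fold only needs
to be disjoint and consistent) and trains on the rest. A dominant cluster
can make one fold much larger than the others; this imbalance is accepted
because splitting a cluster would leak homology.

The built-in pairwise scorer computes global-alignment percent identity
(match +1, mismatch −1, gap open −2, extend −0.5) and treats
identity ≥ 30% over ≥ 50 aligned columns as a hit, mapped to a
pseudo-E-value far below any threshold. It exists so the module runs
without an external search binary; tabular output of a real all-vs-all
search can be loaded instead (`load_edge_list`). The HSSP-style curve used
by the enzyme-pair neutral miner is `480·L^(−0.32)` for alignment length
L ≤ 450 and 19.5% beyond, exposed as a replaceable function.

## Feature space

Windowed per-residue features use w ∈ {1, 5, 9, 13, 17, 21}; out-of-sequence
cells are zero-filled with an explicit per-cell padding flag, so every
windowed block has fixed length w·(k+1). Terminus information is carried by
a separate scaled depth feature, `min(pos, L−pos+1) / ((L+1)/2)`, rather
than by inventing residues. Delta features are native-minus-variant
differences and are antisymmetric by construction.

Shipped scales: Kyte–Doolittle hydropathy, integer formal charge (His
+0.1), residue volumes (Å³), Grantham polarity and Chou–Fasman helix
propensity as the curated index subset. The 20×20 contact potential is a
documented one-term hydrophobicity approximation, `e(i,j) = −(h_i+h_j)/9`,
which reproduces the dominant additive structure of statistical
contact-energy matrices; it is symmetric by construction and any
user-supplied symmetric table can replace it. Per-column z-scoring is
fitted on each rotation's training rows only and reused unchanged on
cross-train and test rows.

The alignment-free descriptor profile consists of amino-acid composition,
scaled protein length, one-hot wt/var encoding, contact-potential
wt/var/delta profiles, windowed biophysical properties and their deltas,
the polarity scale and delta, terminus depth, and (when available) the
effect-probability matrix feature.

## Feature selection

Greedy forward selection per rotation adds the (descriptor, window)
candidate with maximal cross-train AUC, requiring improvement beyond a
tolerance of 10⁻³ AUC, with a default budget of 25 accepted steps; ties
break to the lowest candidate index and seeds are derived per
(step, candidate), making runs deterministic. One fold per network is held
out of the entire procedure and an assertion rejects rotations that touch
it. Per-network selections merge by order-preserving union (the same
provider at two windows stays twice); backward elimination then removes any
descriptor whose removal does not lower the mean test-rotation Q2 by more
than a tolerance (default 10⁻³), sweeping in fixed order until stable.
Candidate evaluations use fresh seeded initialisation per step rather than
warm starts.

## Alignment-free mode

Saturation mutagenesis enumerates all 19 substitutions at every position
(position-major, variant alphabetical — deterministic). The derived 20×20
matrix stores, per ordered (wt, var) pair, the fraction of predictions
classified effect at the decision threshold, plus a support count; cells
without support are undefined, not zero, and propagate the missing-feature
policy. The source protein set is a parameter: the synthetic set in tests,
any user FASTA in production.

## Evaluation

Effect is the positive class. Per-class accuracy (precision), coverage
(recall), F-measures, Q2 and MCC follow their standard confusion-table
definitions; any zero denominator yields an explicit undefined marker
(`None`), never a silent zero. ROC/AUC uses a threshold sweep with
trapezoid integration, equal to the tie-corrected Mann–Whitney statistic
(ties count ½); the test suite checks this against an O(n²) pairwise
oracle. Bootstrap errors use n = 1000 sets, each a random 50% subsample
drawn without replacement; SD is the root mean squared deviation from the
bootstrap mean and SE = SD/√(n−1); subsamples on which a metric is
undefined are skipped and counted. The difficulty triage labels a variant
*easy* when all methods agree and are correct, *unsolvable* when all agree
and are wrong, and *difficult* otherwise; the random baseline predicts
effect with a fixed background probability, giving the closed-form expected
Q2 `p_bg·f_eff + (1−p_bg)·(1−f_eff)`.

## Synthetic benchmark: what it does and does not show

The generator emulates three structural properties of curated variant
training data: homologous families (founders mutated at a per-family rate
of 10–30%, so within-family identity stays far above the 30% edge threshold
and cross-family identity far below), a 60:40 effect:neutral class balance,
and label noise (default 5% independent flips). The planted rule — effect
iff the position is non-terminal (scaled depth above 0.5) **and** the
absolute hydropathy change exceeds 2.0 Kyte–Doolittle units — is expressed
exclusively through quantities the shipped feature providers compute, so
the recovery tests demonstrate that the implemented encoder, trainer and
ensemble machinery work end to end.

What passing does **not** show: real variant effects are not governed by a
two-term rule; real homology is not block-structured; real label noise is
not independent; evolutionary-profile features are absent entirely. The
synthetic AUC (~0.92 at the default sizes) therefore says nothing about
accuracy on biological data — it is a correctness check, not a benchmark
claim. Default sizes (10 families × 3 proteins, lengths 80–150, 2,000
variants) keep a full generate→cluster→fold→featurize→train→evaluate run in
seconds on one CPU.

## Numerical choices and degenerate inputs

* Weight init: uniform ±1/√n_in for input→hidden, ±0.5 for hidden→output,
  from the config seed; all randomness flows from explicit seeds and every
  training run is bit-reproducible.
* Constant feature columns get unit scale in the z-scorer (they pass
  through as zeros after centring).
* Non-finite training loss aborts with diagnostics rather than continuing.
* A score of exactly 0 classifies as effect at the default threshold
  (0 > −0.05); RI 10 is reachable only at a saturated |difference| of 1,
  so averaged-sigmoid ensembles in practice top out at display digit 9.
* The PMD-style annotation mapper accepts either a single grade or a set;
  any set containing more than the `'='` grade maps to effect. Aggregation
  of multiple assay entries for one substitution is the caller's decision.
* Non-canonical residues (B, Z, X, U, O) are rejected in strict mode;
  lenient mode maps them to X, and X positions are never valid variant
  sites.

## Known limitations

* No profile-search or structure-prediction tools are bundled; evolutionary
  and structural features enter only as precomputed per-residue TSV files.
* The contact potential is an analytic approximation, not a fitted
  statistical table (any symmetric 20×20 replacement is accepted).
* The backward-elimination tolerance compares retrained models whose seeded
  initialisation changes with the input dimension, so run-to-run Q2 jitter
  (~0.01 at the synthetic sizes) sets a practical floor on meaningful
  tolerances; the duplicated-descriptor tests use 0.02 for this reason.
* Calibration beyond the reliability index (e.g. probabilistic outputs) is
  out of scope, as are codon-level variants and web-service deployment.
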