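# Methods

## Problem setting

Given assembled contigs from a mixed (cellular-fraction) metagenome, the
task is to rank and call the contigs that derive from prokaryotic
viruses rather than their hosts, using only nucleotide composition. The
classifier is trained on fragments cut from labeled reference genomes
and applied to query contigs of arbitrary length.

## Sequence signatures

A sequence is represented by its canonical *k*-mer frequency vector.
Every *k*-mer is identified with its reverse complement and the pair is
represented by the lexicographically smaller member, giving
(4^k + 4^{k/2})/2 features for even *k* (palindromic words are their own
partner and occupy a single slot counted once per window) and 4^k/2 for
odd *k*: 136 words at *k* = 4, 32,896 at *k* = 8. Counting slides a
width-*k* window one base at a time over the given strand only;
collapsing handles the complementary strand, and scanning both strands
would merely double every non-palindromic count and cancel under
normalization. Windows containing an N are skipped rather than imputed,
to avoid biasing frequencies with an arbitrary fill; a sequence with no
valid window (shorter than *k*, or entirely N) has no signature and is
reported unscored rather than given a default. Counts are normalized to
sum to one, so the signature is a composition, not a length-dependent
count vector.

Signatures are strand-symmetric by construction:
featurize(S) = featurize(revcomp(S)) exactly, and every downstream score
inherits this invariance bit-for-bit.

## Training protocol

For one length class *L*:

1. every virus genome is tiled into non-overlapping length-*L*
   fragments starting at position 0 (the trailing remainder is
   discarded);
2. a fraction (default 20%) of host **genomes** — never fragments — is
   reserved before training; their fragments later supply the null
   score distribution. Holding out whole genomes prevents fragments of
   one genome from appearing on both sides;
3. an equal number of host fragments is subsampled uniformly, without
   replacement, from the *L*-aligned grid slots pooled across the
   remaining host genomes (so genomes contribute in proportion to their
   length). If the host pool is smaller than the virus pool, the virus
   fragments are subsampled instead, keeping the classes balanced;
4. fragments with more than 10% N are excluded from both pools —
   their signatures rest on too few windows to be informative;
5. the model is fit on the balanced signature matrix (below).

The bundle repeats this for L ∈ {500, 1000, 3000} bp and routes query
contigs by length: <1 kb to the 500 bp model, 1–3 kb to the 1 kb model,
≥3 kb to the 3 kb model. Contigs under 500 bp are scored by the 500 bp
model but flagged, since no model was trained at their scale.

## The classifier

Logistic regression with an L1 penalty on the mean-log-likelihood
scale:

    minimize  -(1/n) Σ log l(Y_i | V_i, β, β0)  +  λ Σ_w |β(w)|

with the intercept unpenalized. Before fitting, a pooled-variance
two-sample *t* statistic compares each word's mean frequency between
classes, and exactly one word — the one with the largest p-value — is
removed. This breaks the exact collinearity induced by the unit-sum
constraint Σ V(w) = 1 (the intercept column otherwise lies in the span
of the features). A word with zero pooled variance is assigned t = 0,
p = 1, making a constant column the natural removal candidate. The
pooled-variance (Student) variant is the classical default for the
equal group sizes the balanced protocol guarantees.

Features are **not** standardized: all features live on the common
frequency scale, and penalizing raw frequencies keeps β(w) directly
interpretable as the log-odds effect of word w's frequency share.

### Penalty selection

λ is selected over a log-spaced grid of 100 values from λ_max — the
smallest penalty that zeroes every coefficient, computed from the KKT
condition λ_max = max_w |x_w · (y − ȳ)| / n — down to λ_max · 10⁻⁴.
Stratified 10-fold cross-validation (fold assignment fixed by the
training seed) scores each grid point by mean out-of-fold AUROC; ties
are broken toward the larger λ, i.e. the sparser model, and the winner
is refit on all data. The per-λ CV table is stored in the model
metadata.

### Numerical choices

The optimizer is scikit-learn's liblinear coordinate-descent solver.
Raw frequency features are tiny (mean 1/p per column), which conditions
the solver poorly, so the fit is run through an exact reparametrization:
columns are centered (the unpenalized intercept absorbs the shift
without affecting the penalized optimum) and the whole matrix is
multiplied by one global constant, with the penalty scaled by the same
constant and the coefficients divided by it on the way out. No
per-column scaling is applied anywhere, so the returned model is the
exact optimum of the stated objective on raw frequencies. liblinear
formally L1-penalizes its intercept term; with `intercept_scaling = 10`
against unit-order features the distortion is negligible (and the
λ ≥ λ_max ⇒ β ≡ 0 identity holds exactly in practice, which the tests
assert). The solver's internal tie-breaking seed is pinned, making
training bit-reproducible: the same corpus, configuration and seed
serialize to byte-identical model files. A grid point whose fit does not
converge is flagged, excluded from selection, and logged; training fails
only if every grid point fails.

Solver tolerance defaults to 1e-5 (5000 iteration cap). The benchmark
harness (`pipeline.run_benchmark`) coarsens this to a 30-point grid with
floor λ_max · 10⁻² and tolerance 1e-4: near the production floor the
nearly unregularized fits are by far the most expensive part of
training, and cross-validation never selects them — the harness choice
trades unused grid tail for a much faster experiment loop.

## Scores, p-values, q-values

A contig's score is logistic(β0 + Σ β(w) V(w)) ∈ (0, 1), higher meaning
more virus-like. Scores are a property of the contig and model alone —
they do not depend on what else is in the batch.

Because scores from different length-class models are not comparable,
each is referred to its model's **null distribution**: the sorted scores
of the held-out host genomes' fragments. The empirical p-value is the
fraction of null scores **strictly greater** than the query score
(computed by binary search). Strictly-greater is the literal reading of
the definition; it yields p = 0 for a query above every null score,
which is informative for ranking but awkward for FDR estimation, so an
optional smoothed variant (#greater + 1)/(n + 1) is available behind a
flag (`--null-smoothing`). A null below ~100 fragments triggers a
resolution warning.

q-values are positive-FDR estimates over the pooled batch of p-values
(pooling across models is what makes cross-model calls comparable):
π₀ is estimated by the smoother method — π₀(t) = #{p > t}/(m(1 − t))
over t = 0.05, 0.10, …, 0.95, cubic smoothing spline evaluated at
0.95, clamped into (0, 1] with a warning if the spline misbehaves —
then q_(i) = min_{j ≥ i} π₀ m p_(j)/j on the sorted p-values, mapped
back to input order. Calibration is a tested property: p-values of
held-out host fragments drawn from the same generator as the null are
approximately Uniform(0, 1) (Kolmogorov–Smirnov distance < 0.1 at
n = 1000).

## Evaluation harness

- **AUROC** is computed exactly as the Mann–Whitney rank statistic
  U/(n₊ n₋) with ties counting ½ — identical to trapezoidal ROC area
  but free of curve-integration choices; the full ROC sweep (no
  intermediate-point dropping) is returned for plotting and for the
  matched-FPR lookup.
- **AUPRC** uses the step-wise, non-interpolated area (average
  precision), the standard PR convention.
- **TPR at matched FPR** returns the largest TPR at the most permissive
  threshold whose FPR does not exceed the target — the fair way to read
  one classifier's sensitivity at another's operating point.
- **Bootstrap** (default B = 30) resamples with replacement within each
  class, preserving the evaluation mixture. Replicate vectors are
  returned so two conditions bootstrapped with the same seed and label
  vector share resample indices, enabling paired (Wilcoxon) tests.
- **bayes_precision(tpr, fpr, ρ) = tpr·ρ / (tpr·ρ + fpr·(1 − ρ))** is
  the expected precision at viral fraction ρ; it equals precision from
  confusion counts in the large-sample limit (tested at n = 10⁵ within
  1%).

## Synthetic corpus generator

Real virus/host discrimination rests on the two classes occupying
different regions of composition space, with the discriminating words
empirically AT-enriched on the viral side. The generator reproduces
exactly this structure and nothing else: a host composition model is an
order-*m* Markov chain (default m = 2 — enough context to create word
structure a k = 4..8 model can exploit, without memorizing genomes)
with Dirichlet(5)-distributed transition rows; the virus class uses a
perturbed copy in which each row is resampled from
Dirichlet(row · 50/divergence) and its A/T mass inflated by
(1 + divergence). One scalar `divergence` therefore controls
separability: 0 makes the classes identical in distribution (no
classifier can beat chance — a property the tests assert), and the
default 0.3 puts the 500 bp, k = 4 pipeline in the cleanly separable
regime. Genomes default to 10 kb; chains start from a burn-in-estimated
stationary context; everything is seeded.

What the generator does **not** emulate: genes and codon structure,
repeats and mobile elements, proviruses embedded in host chromosomes,
assembly chimeras, real taxonomic heterogeneity (every synthetic genome
of a class is one draw from a single composition model, where real
classes are mixtures of thousands of distinct compositions), and
sequencing error beyond uniform point substitutions. Passing benchmarks
on this corpus therefore demonstrates that the machinery — signatures,
screening, penalized fit, calibration, FDR — behaves correctly, not
that any particular accuracy will be achieved on real metagenomes.

## Study conditions and problem sizes

The benchmark protocol used by the tests and by
`scripts/acceptance.py`: 200 virus + 200 host genomes of 10 kb, 30% of
genomes (per class) held out for evaluation, L = 500, k = 4, 10-fold
CV on the harness grid above. This yields ~2240 balanced training
fragments per class, a ~560-fragment null, and 1200 + 1200 evaluation
fragments. Robustness experiments reuse the same trained model:
mutation rates {0, 0.001, 0.01} substitutions/site applied to the
evaluation fragments, and viral fractions {10%, 50%, 90%} obtained by
subsampling only the minority class so that mixtures share scores and
differences reflect composition, not resampling noise.

## Known limitations

- The mutation model is substitutions-only (uniform over the three
  alternatives, N positions untouched); no indels.
- Host fragment subsampling uses the L-aligned grid (starts 0, L,
  2L, …) pooled over genomes; random-offset sampling would differ
  negligibly for the fragment counts used here but is not implemented.
- π₀ smoothing uses a generic cubic smoothing spline rather than a
  fixed-degrees-of-freedom smoother; on small batches (tens of
  p-values) the estimate is noisy and is clamped to 1 when it leaves
  (0, 1].
- Provirus boundary detection inside long host contigs is out of
  scope: a contig is scored as a whole.
- The three length classes are fixed at 500/1000/3000 bp; contigs
  below 500 bp are scored but flagged as outside the evaluated range.
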