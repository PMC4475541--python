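# Methods

This note records the models, conventions and numerical choices behind
`ringdim`, and what the synthetic study does and does not emulate.

## The synthetic ring-trial generator

### Latent design

A study is built on a shared latent design over the samples:

* a **group contrast** column (two-valued, balanced, unit variance after
  centering) — present for `contrast="high"`/`"low"`, absent for
  `contrast="none"`, where the group labels remain (from the native/spiked
  pairing, or a balanced split) but carry no planted effect;
* **metabotype** columns — one orthonormal direction per free individual
  degree of freedom, constant within a native/spiked pair, representing
  each individual's characteristic profile;
* **outlier** columns — one scaled indicator per planted outlier
  individual, exactly zero off that individual's samples.

Construction order: the group column is fixed by the labels; outlier
indicators are raw indicators normalized to unit variance; metabotype
columns are drawn from per-individual Gaussians and orthonormalized (QR)
against the centered group and outlier columns and each other. After
centering, all factor pairs are exactly orthogonal with two unavoidable
exceptions, each O(1/n): between two outlier indicators (centered disjoint
indicators have inner product −ab/n), and between the group column and an
outlier indicator in *unpaired* designs. Keeping the indicators exactly
zero off their support was judged more important than exact orthogonality
in those two cells; property tests assert exactness everywhere else and
bound the residual. A consequence is that a paired design with `m` planted
outliers has `n_individuals − 1 − m` metabotype columns: the outlier
directions consume part of the between-individual subspace.

Per-sample **dilution factors** are lognormal with a configurable CV
(shared within a native/spiked pair — the spike is reconstituted in the
same urine), and **specific gravity** is generated as
`1 + (SG_ref − 1)·dilution`, clipped to (1.000, 1.050], so that
specific-gravity correction at the reference removes the planted dilution
exactly (up to clipping, which is negligible at the default CV).

### Rendering a block

Each platform profile renders the design as a noisy factor model
`x_j = Σ_f l_jf z_f + e_j`, with `e_j ~ N(0, noise_fraction)` and loading
columns drawn i.i.d. standard normal, then rescaled so factor `f` carries
exactly `variance_shares[f]` of the block's expected total variance.
Share keys may name factor classes (`group`, `metabotype`, `outlier`),
which are split equally over the class's columns; naming a class absent
from the design is a configuration error.

In a paired spiking design the group contrast is realized entirely through
the spike: the group factor's loadings are nonzero only on the
spike-carrying feature subset (`responds_to_spike` of the features). Since
the group score is constant within each group, the spike acts as a
constant additive effect across all spiked samples, and the
spiked-minus-native difference of a noise-free pair is nonzero exactly on
the carriers.

The rendered matrix is shifted so its minimum is zero *before* row-wise
multiplication by the dilution factors. The offset is thus on the
concentration scale — real intensities are nonnegative analyte levels
scaled by the sample's dilution — and dilution correction followed by
column centering removes it exactly. (Applying the offset after dilution
instead would leave a rank-one offset/dilution artifact once rows are
rescaled, which in early end-to-end runs dominated the first common
component.)

One master seed spawns one child seed for the design and one per platform
(via `numpy.random.SeedSequence.spawn`), so appending a platform to a
roster never changes the existing blocks, and the whole study is
reproducible bit-for-bit.

### What the generator does and does not emulate

It reproduces the *statistical* structure downstream methods consume:
shared latent sample geometry seen through platform-specific feature
spaces, feature counts spanning two orders of magnitude, platform-specific
variance allocation (NMR-like lenses emphasizing the group contrast,
LC-MS-like lenses the metabotypes), instrument noise, dilution variation,
and planted outliers. It does **not** simulate raw spectra, retention-time
or m/z structure, peak-picking artifacts, batch or run-order drift,
missing values, or heteroscedastic (intensity-dependent) noise. Passing
tests therefore demonstrate correctness of the statistics under a
homoscedastic factor model with exactly orthogonal planted structure —
they do not certify behaviour under real instrument pathologies.

### Bundled study conditions

`configs/test1_like.yaml` encodes a high-contrast paired urine study:
14 individuals (28 samples), 2 outlier individuals, dilution CV 0.25,
5 NMR-like profiles (group share ≈ 0.7, except one atypical NMR at 0.35
that behaves like the LC-MS group) and 9 LC-MS-like profiles (group share
0.22–0.35), feature counts 233–9,699 following a real ring-trial roster.
`configs/test2_like.yaml` encodes a low-contrast unpaired plasma study
(n = 18, group shares 0.03–0.07, no dilution variation, feature counts
120–9,550); there a few dominant metabotype directions carry most of the
biological variance, so the first two common components describe
individuals rather than groups and the weak group effect surfaces only in
a minor component. Salience allocations mirror the reported pattern that NMR
concentrates ~70% of its variance on the contrast while LC-MS spreads
20–50% on the contrast and 20–30% on metabotypes; outlier shares are free
parameters (the magnitude of a real biological outlier is not a published
quantity) set so the outlier dimensions appear around the third/fourth
common component.

## RV statistics

`rv_coefficient` evaluates the trace formula through the n × n Gram
matrices (n ≪ p), after column centering (idempotent if the caller already
centered). A zero Gram norm (constant table) is a domain error.

`modified_rv` zeroes the Gram diagonals and uses the tables **as given**,
without internal centering. This is deliberate: exact per-feature centering
forces each Gram's off-diagonal entries to sum to −trace, so the
off-diagonals of two *centered* independent tables share a deterministic
negative mean and their diagonal-zeroed RV is biased upward (≈0.5 at
n = 50, p in the thousands — verified numerically), whereas on tables
whose Gram off-diagonals are zero-mean the statistic is ≈0 as intended.
The docstring flags this sensitivity; the block-matrix variant computes
the modified values from the stored block matrices unchanged.

The permutation null permutes rows of the second table only (the minimal
scheme that breaks sample correspondence while holding the first table's
geometry fixed); since row permutation commutes with centering it is
implemented as symmetric reindexing of the second Gram. At least 100
permutations are required (quantile stability); the pipeline default is
199 per pair with independently spawned child seeds. Within/between
technology link averages are simple arithmetic means over the unique
off-diagonal pairs of each kind; a technology with a single member has no
within average.

## CCSWA / ComDim

Blocks are column-centered and scaled to unit total variance (Frobenius
norm 1) inside the fit — idempotent with the same preprocessing step — so
saliences read directly as fractions of a block's variance and are
comparable across blocks whose feature counts differ by orders of
magnitude. Per component: saliences initialize at 1; the compromise
`W = Σ λ_k X_k X_k'` is formed; its dominant eigenvector comes from a full
symmetric eigendecomposition of the n × n matrix (deterministic; n is
small); saliences update as `λ_k = q'X_kX_k'q`; iteration stops when the
maximum salience change falls below `tol` (default 1e-10, `max_iter` 500 —
the algorithm converges in a handful of iterations on non-degenerate
input, so hitting the cap raises an explicit error naming the component).
Every block is then deflated by the global score (`X_k ← X_k − qq'X_k`),
which makes successive global scores exactly orthonormal.

Sign convention: each global score is oriented so its largest-magnitude
entry (first such entry on ties) is positive; the fit is therefore
reproducible and invariant to sign flips of any block. Score scaling is
emitted both ways — unit-norm scores and scores scaled by the square root
of the component's total salience — since score plots are drawn under
either convention.

Block projections use unit-salience scaling `t_ka = X_kX_k'q_a/√λ_ka`;
components with salience below 1e-12 for a block are reported as undefined
(NaN) rather than divided through. The barycentre display summarizes each
sample as the mean of its per-platform scores with the RMS dispersion of
the platforms around it.

The group-separation statistic on a component is the standardized mean
difference (pooled SD) of its global scores between the two label groups,
with a seeded label-permutation p-value `(1 + #{|d*| ≥ |d|})/(n_perm + 1)`.
Calibration caveat: in a *paired* design with no planted contrast the
labels alternate within pairs while the metabotype factors are
pair-constant, so free label permutation is conservative there; the test
is exactly calibrated for unpaired designs, which is how the type-I
property is asserted.

## Feature selection

Correlations are plain Pearson correlations between each (centered)
feature column and the component's global score; zero-variance features
are reported as 0 and flagged rather than propagating NaNs. Two rules:
`abs_r` keeps `|r| >` threshold (default 0.8; two-sided, because the sign
of a component is an orientation convention); `zscore` standardizes the
correlation vector across the block's features and keeps `|z| >` threshold
(default 2.0) — the population for the z-standardization is the block's
own correlation vector, the natural reading for binned NMR tables where an
absolute-r cutoff tuned for LC-MS would be miscalibrated. Thresholds are
strict (ties excluded). A zero-spread correlation vector makes the z rule
degenerate; the selection is then empty and flagged. Overlap percentages
are reported relative to the first (component-based) selection. No
multiplicity control is applied; the threshold is exposed instead.

## Networks

Edges use `RV ≥ cutoff` (inclusive). The automatic cutoff searches the
observed off-diagonal RV values in decreasing order (finite, deterministic
grid) and returns the largest value leaving at most `allowed_isolated`
nodes isolated — the sparsest network subject to inclusion; the parameter
exists because published networks occasionally tolerate one excluded
instrument at their stated cutoff. Exports are GraphML (round-trips the
graph and its attributes), SIF (one edge per line plus lone lines for
isolated nodes) and a node-attribute CSV, all Cytoscape-loadable.

## Pipeline determinism and problem sizes

All report files are plain text written with fixed float formatting and
sorted keys; two runs with the same configuration and seed are
byte-identical (asserted in the tests). The bundled `test1_like` study
(14 blocks, 28 samples, ~29k features total, 199 permutations per block
pair, 4 components) runs in a few seconds on one CPU. The statistical
acceptance checks use deliberately modest problem sizes — 20-seed
replicates for share recovery and selection precision, 100 + 50 seeded
runs for calibration and power, 50 × 2000/3000 tables for the large-p
check — chosen so the whole suite stays interactive while the Monte-Carlo
error remains well inside the asserted margins.

## Known limitations

* The homoscedastic Gaussian factor model understates the heavy tails and
  intensity-dependent variance of real feature tables; RV and salience
  levels on real data will be lower than on the synthetic studies.
* The modified RV retains an upward bias when applied to per-feature
  centered tables (see above); it is reported as defined, not re-adjusted.
* `sg_normalize` presumes specific gravities strictly above 1.0; values at
  or below 1.0 (measurement error) are rejected, not imputed.
* Missing values are rejected at parse time rather than imputed; the
  package consumes complete post-processed tables.
* The permutation schemes (rows of the second table for RV; free label
  shuffles for separation) ignore pairing structure by design; paired
  no-effect designs make the separation test conservative.
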