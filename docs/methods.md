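# Methods

## Signal model and forward simulation

One acquisition interleaves an inversion-recovery (IR) preparation with a
CPMG echo train: 32 inversion times TI log-spaced from 5 ms to 15 s, 5000
echoes at an inter-echo time TE = 3 ms, 40 digitised points per echo. The
ideal-pulse signal of a single relaxation site is

    S(TI, t) = M0 · (1 − 2·exp(−TI/T1)) · exp(−t/T2),

with the inversion efficiency fixed at 2 (perfect 180° pulse); pulse
imperfections, B0/B1 inhomogeneity and intra-echo shape are outside scope.
A sample is a finite mixture of sites. Per replicate, each site's (T1, T2)
is jittered log-normally (std in log10 seconds) and i.i.d. Gaussian noise
of std `noise_sigma` (default 0.01 relative to unit equilibrium
magnetization, i.e. SNR 100 on the first fully recovered echo) is added to
every digitised point. The 40 intra-echo points are simulated as the echo
amplitude with independent noise; collapsing them by the mean reduces the
per-echo noise by √40.

### The phenotype library

The cell-line and MSC peak positions are package defaults, not measured
values: no per-line (T1, T2) table exists to import. Cell peaks are spread
over T1 ∈ [0.35, 1.45] s and T2 ∈ [0.035, 0.23] s; the media peak sits at
(2.5 s, 1.6 s) — long T1, and T2 kept below T1, which is the physical
ordering for these samples; the lipid peak of differentiated MSCs at
(0.28 s, 0.19 s), shorter T1 and longer T2 than the water cell peak.
Per-replicate jitter of the cell peaks is 0.06 / 0.10 log10 units (T1/T2).
This single calibration was chosen so the synthetic centroid clouds show
the qualitative structure of the measured data — elongation along T2 and
partial overlap between neighbouring lines, so that two-line
classification is essentially perfect while the ten-line task drops to
~50–65 % — and is not revisited per experiment. The cohort composition
mirrors the study: ten cell lines (counts 16–61, two variants provided
because the source's per-line table sums to 339 while its text states 354;
the "text" variant pads round-robin and is flagged as a stand-in), plus 8
undifferentiated and 7 differentiated MSC samples, 369 samples in total.

What the generator does *not* emulate: magnitude-detection noise floors,
temperature drift, B1 miscalibration, exchange between compartments, and
any within-line biological covariance beyond independent positional
jitter. Passing tests therefore demonstrate that the *pipeline* recovers
and classifies what the model family can express — not that real scanner
data will behave identically.

## Preprocessing

Echo collapse (mean of the 40 points), re-gridding of the 5000 echoes onto
256 log-spaced times (bin averaging; empty bins interpolated linearly in
log-time), normalization to unit maximum amplitude (scale retained),
PCA/truncated-SVD denoising (default rank 8 — the noiseless signal of a
p-site sample is exactly rank p, so rank 8 is conservative), and a global
polarity convention ("orientation in T1"): the longest-TI row is made
nonnegative on average, leaving pre-null rows negative. The alternative
reading of the source's inversion step — a data reversal along TI — is not
used; a sign convention is the only interpretation under which the IR
kernel fits the data.

## 2D inverse Laplace transform

The spectrum minimizes ‖S − K1 F K2ᵀ‖²_F + α‖F‖²_F subject to F ≥ 0 on
log-spaced grids, default 300 × 300 over T1 ∈ [1 ms, 15 s], T2 ∈ [1 ms,
5 s] (the grid bounds are package choices spanning the TI range and every
plotted peak; the source states only the 300 × 300 size). Both kernels are
SVD-truncated (defaults r1 = 16, r2 = 32; singular values decay
geometrically, truncation error ≪ noise) and the compressed problem is
solved by FISTA with projection onto the nonnegative orthant, iteration
cap 5000, relative-change tolerance 1e-8. Full-rank compression is an
exact reformulation (verified against a direct active-set NNLS oracle on
small problems). Non-convergence warns by default; `strict=True` raises
with the last iterate attached.

α defaults to 1e-3 on normalized data. When the noise level is known or
estimable, the discrepancy principle is used instead: the largest α on a
25-rung geometric ladder whose residual does not exceed (1 + τ)·σ·√N
(τ = 0.1). Residuals are non-decreasing in α, so the chosen α is
non-decreasing in σ.

Validation grids are 64–100 points per axis; parameter recovery at SNR 100
places the spectral centroid of a single-site phantom within one grid cell
of truth in 20/20 trials for T1 up to about TI_max/3 (≈ 5 s). Beyond that
the IR kernel flattens and the regularized estimate biases long by more
than a cell — an identifiability limit of the experiment, not of the
solver; cells, phantom and crop window all live well inside the reliable
range.

## Features

Peaks are 8-connected components of {intensity ≥ 0.05·max}, discarding
components of fewer than 4 cells or less than 1 % of total intensity (the
source gives no numeric thresholds; these are package defaults). Tagging:
centroid T1 ≥ 2 s → media; otherwise cell; when two peaks fall in the cell
window the shorter-T1 one is tagged lipid. The weighted centroid is the
intensity-weighted mean (T1, T2) in linear seconds over the peak mask
only. The CNN input window is T1 ≤ 3.0079 s, T2 ≤ 0.4062 s. Samples
without a cell peak (media-only controls) are logged and excluded, never
raised.

## Augmentation

Each detected peak is independently translated by a Gaussian shift (std in
seconds) and scaled about its centroid by 1 + s with s ~ N(0, stretch_std),
both in linear coordinates. Implementation: the isolated peak is
re-sampled by bilinear interpolation at inverse-transformed node positions
and then rescaled to its exact original mass, so total intensity is
conserved to machine precision and zero-parameter draws are exact
identities at grid nodes. Draws whose forward-mapped bounding box leaves
the grid are redrawn (cap 100) rather than clipped, keeping the applied
distribution unbiased. One resampling pass blurs the peak by O(h²) of the
local grid spacing — negligible at 300 grid points, visible in
second-moment checks below ~100 points. Presets: 1 % stretch with 5 ms
shift for the MSC task, 1 % stretch with 1 ms shift for the cell-line
task, augmentation factor 5, originals kept and flagged (`_Original`
files).

## Classifiers

**SVM.** Polynomial kernel, degree 2, coef0 = 0, C = 1, gamma "scale",
features = raw centroid coordinates in seconds, evaluated over 300
independent class-stratified 50/50 splits with derived seeds. With
coef0 = 0 the kernel is homogeneous and even, so centering the features
would make antipodal clusters inseparable; standardization is therefore
off by default (available as an option).

**CNN.** Two VGG-derived stacks in a self-contained NumPy engine (im2col
convolution, batch normalization, 2 × 2 max pooling, dense layers,
inverted dropout, softmax cross-entropy, Adamax): the MSC variant has 7
conv layers (pooling after every other conv starting after the first) and
4 dense layers; the cell-line variant 4 conv layers each followed by
pooling, and 4 dense layers with 25 % dropout. ReLU throughout, 12 epochs.
Published information fixes only layer counts, activations, optimizer,
dropout and epochs; kernel size (3 × 3), channel widths (doubling from a
base of 16), dense widths (256/128/64), learning rate (1e-3) and batch
size (16) are configurable stand-ins. "Normalization layers" are realized
as batch normalization. Inputs are cell-window crops rasterized to
max-normalized grayscale, default 128 × 128; validation uses 32 × 32 with
base 8 channels, which the engine trains in under a second per replicate.

**Splits.** The celltype-aware split assigns parents per class: 25 % test,
20 % of the remaining pool validation, rest training, rounded per class
with at least one parent per partition (classes need ≥ 3 parents);
augmented descendants always follow their parent, so no information leaks
across partitions. Replicated runs (default 10) re-split every time and
report mean/std curves and the averaged confusion matrix.

## Problem sizes in the test-suite and acceptance script

Routine validation runs the chain at 1000 echoes (one point per echo),
128 T2 bins, 64–100-point grids, 32 × 32 CNN inputs with narrow channels,
and quarter-scale cohorts; these sizes give the same qualitative behaviour
as the full configuration at a small fraction of the cost, and all
full-size parameters remain the package defaults. The acceptance script
recomputes: phantom recovery rate, SVM accuracy for k = 2…10 lines and
its Spearman correlation with k, the MSC SVM baseline, CNN accuracy with
and without factor-5 augmentation, the two-line CNN accuracy, and the
worst augmentation conservation error.

## Known limitations

- Peak positions per cell line are invented defaults; absolute accuracies
  on synthetic cohorts characterize the pipeline under the calibrated
  overlap, not the scanner.
- T1 beyond ~TI_max/3 and T2 beyond the echo-train duration are weakly
  encoded; spectra there are qualitative.
- The ILT provides no uncertainty quantification; maximum-entropy or
  Bayesian variants are out of scope.
- The augmentation operators assume peaks remain separated; heavily
  merged peaks are moved as one component.
- CNN hyperparameters beyond the published layer structure are stand-ins;
  conclusions should rest on relative comparisons (augmented vs not,
  class-count sweeps), which are robust to them.
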