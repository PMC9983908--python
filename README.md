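# relaxcell

Non-destructive cell-type classification from 2D T1/T2 NMR relaxometry.

Benchtop low-field NMR can fingerprint a living cell suspension without
staining or lysis: an inversion-recovery (IR) preparation encodes the
longitudinal relaxation time T1 while a CPMG echo train encodes the
transverse relaxation time T2. Different cell types — and differentiation
states such as adipogenically maturing mesenchymal stromal cells (MSCs),
whose lipid droplets add a peak of their own — occupy different regions of
the joint T1/T2 plane. `relaxcell` implements the complete analysis chain
that turns such raw echo-train data into a cell-type call, together with a
forward simulator so every stage is testable without scanner data.

## The model

The signal of a single relaxation site (T1, T2) with amplitude M0,
measured at inversion time TI and echo time t, is

```
S(TI, t) = M0 · (1 − 2·exp(−TI/T1)) · exp(−t/T2)
```

A sample is a mixture of such sites (cell peak, media peak, optionally a
lipid peak). The acquired 32 × 5000-echo data matrix `S` is modelled as

```
S = K1 F K2ᵀ + noise,    K1[i,k] = 1 − 2·exp(−TI_i/T1_k),   K2[j,l] = exp(−t_j/T2_l)
```

and the nonnegative spectrum `F` on 300 × 300 log-spaced grids is the
Tikhonov-regularized nonnegative least-squares solution

```
min_{F ≥ 0}  ‖S − K1 F K2ᵀ‖²_F + α‖F‖²_F
```

solved by FISTA after SVD compression of both kernels (the 2D inverse
Laplace transform). Each detected peak is reduced to its intensity-weighted
centroid — the feature pair for a polynomial-kernel SVM (degree 2,
coef0 = 0, 300 random 50/50 splits) — or the spectrum is cropped to the
cell-peak window (T1 ≤ 3.0079 s, T2 ≤ 0.4062 s), multiplied by random
peak-shift/stretch augmentation, and fed to a VGG-derived CNN trained with
Adamax for 12 epochs under a celltype-aware 75/20/25 split.

## Worked example

Simulate a CHO-like sample, invert it, and classify two cell lines:

```python
from relaxcell import (default_protocol, default_phenotype_library, simulate_sample,
                       preprocess, detect_peaks, tag_peaks, CentroidSVM, SvmConfig,
                       centroid_table, simulate_cohort, CohortManifest)
from relaxcell.ilt import SpectrumModel

protocol = default_protocol(n_echoes=1000, points_per_echo=1, noise_sigma=0.01)
library = default_phenotype_library()
raw = simulate_sample(library["CHO"], protocol, seed=42)
series = preprocess(raw, n_t2=128)
result = SpectrumModel(series, n_t1=100, n_t2=100).fit(alpha=1e-3)
print(result.summary())
for peak in tag_peaks(detect_peaks(result.spectrum)):
    print(f"{peak.tag:6s} T1 = {peak.centroid_t1:.3f} s   T2 = {peak.centroid_t2:.3f} s")
```

prints

```
2D inverse Laplace transform (Tikhonov-regularized NNLS)
========================================================
sample:           CHO
grid:             100 x 100 (T1 0.001-15 s, T2 0.001-5 s)
alpha:            0.001
residual norm:    0.2532
objective:        0.0641
iterations:       5000 (budget reached)
total intensity:  1.075

cell   T1 = 0.478 s   T2 = 0.028 s
media  T1 = 2.622 s   T2 = 1.748 s
```

The sample's two signal clusters are recovered: the short-relaxation cell
peak (near the generator's CHO position of 0.45 s / 0.035 s, offset by the
per-replicate jitter this seed drew) and the long-relaxation media peak
from the excess culture medium. Continuing,

```python
manifest = CohortManifest.from_counts({"CHO": 15, "K562": 15}, seed=7)
cohort = simulate_cohort(manifest, library, protocol)
spectra = [SpectrumModel(preprocess(r, n_t2=128), n_t1=64, n_t2=64).fit(alpha=1e-3).spectrum
           for r in cohort]
records = centroid_table(spectra)
print(CentroidSVM(records, SvmConfig(replicates=300, seed=0)).fit().summary())
```

```
Polynomial-kernel SVM on weighted centroids
================================================
classes:        CHO, K562
replicates:     300
split:          50% train
mean accuracy:  100.00%
std accuracy:   0.00%
min / max:      100.00% / 100.00%
```

CHO and K562 occupy well-separated centroid clusters, so every one of the
300 random 50/50 splits classifies the held-out half perfectly. Growing
the roster to all ten lines drives the mean accuracy down to roughly 50 %
— the overlapping-cluster regime the SVM cannot resolve, which is what
motivates the CNN track on full spectral maps.

A command-line interface wraps the same stages:

```bash
relaxcell run-all --preset reduced --seed 7 --out runs/demo
relaxcell report --out runs/demo
```

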