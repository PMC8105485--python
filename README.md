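# petqa

Digital-phantom evaluation of PET reconstruction algorithms.

Brain PET quantification has historically relied on filtered back-projection
(FBP) for its linearity, but modern PET-MR systems offer only iterative
reconstructions: OSEM, and Bayesian penalized-likelihood BSREM (marketed as
Q.Clear), whose relative-difference penalty — weighted by a parameter β —
trades resolution against noise.  Choosing β for quantitative brain studies
requires knowing how each metric moves as β changes and how far each
reconstruction sits from the FBP reference.  `petqa` reproduces that whole
evaluation in software, for physicists and methods developers who want the
comparison without scanner time: it simulates NEMA image-quality and
Hoffman-style brain phantom acquisitions, reconstructs them with all three
algorithm families, scores the images with the standard metrics, and
compares everything against FBP with a 5 mm filter.

## What it computes

Per NEMA sphere of diameter *d* (ROI of the same diameter on the
sphere-centre slice; 60 background ROIs: 12 positions × 5 slices):

```
hot contrast (%)   = 100 ((C_H/C_B) − 1) / ((a_H/a_B) − 1)
cold contrast (%)  = 100 (1 − C_C/C_B)
SD                 = sqrt( Σ_k (C_{B,k} − C_B)² / (K − 1) ),   K = 60
background var (%) = 100 SD / C_B
```

Per brain phantom: effective resolution FWHM(x,y) and FWHM(z), estimated by
convolving the noiseless digital phantom with separable Gaussians over a
3–18 mm grid (0.5 mm steps) and maximising Pearson correlation with the
reconstructed image; axial uniformity `100 σ_P / C_P` over a 2400 mm³
right-putamen VOI; and `SNR = (C_P − C_W)/σ_W` against a zero-activity
white-matter VOI.

Reconstructions: FBP (ramp filter + Gaussian post-filter), OSEM (ordered
subsets, multiplicative EM), and BSREM with the relative-difference prior

```
R(f) = Σ_j Σ_{k∈N(j)} w_jk (f_j − f_k)² / (f_j + f_k + γ|f_j − f_k|)
```

optimised by block-sequential one-step-late penalized EM over a β grid of
100…1000.  Comparison: differences `reference − method` vs `FBP_5mm`,
Bland-Altman bias and 1.96 SD limits of agreement, and mean/SD/median/CV%
summaries.  See `docs/methods.md` for models, parameters and limitations.

## Worked example

```python
from petqa import (Grid, HoffmanSurrogateSpec, ReconConfig,
                   generate_hoffman_surrogate, forward_project,
                   add_poisson_noise, bsrem_reconstruct)
from petqa.hoffman import estimate_fwhm, snr

grid = Grid((96, 96, 32), (2.0, 2.0, 2.78))
vol, labels = generate_hoffman_surrogate(HoffmanSurrogateSpec(seed=1), grid)
sino = add_poisson_noise(forward_project(vol, 180), 5e6, seed=1)
for beta in (100, 1000):
    rec = bsrem_reconstruct(sino, ReconConfig("BSREM", iterations=25,
                                              subsets=12, beta=beta), grid)
    est = estimate_fwhm(rec, vol, (3.0, 18.0, 0.5))
    print(beta, est.fwhm_xy_mm, round(snr(rec, labels).snr, 1))
```

prints

```
100 3.0 11.9
1000 5.0 504.2
```

— at β=100 the image keeps the sharpest in-plane resolution (3.0 mm, the
search-grid minimum) but a poor signal-to-noise ratio; at β=1000 the
penalty smooths the image (5.0 mm) and SNR improves by more than an order
of magnitude.  That resolution/SNR trade-off across the β grid is the
central result of the emulated study design.

The same pipeline at full design-matrix scale is driven by the numbered
scripts:

```
python analysis/01_simulate_phantoms.py      # phantoms + noisy sinograms
python analysis/02_reconstruct_matrix.py     # 6 PET-CT + 13 PET-MR rows/dataset
python analysis/03_image_quality_metrics.py  # tidy metrics.csv
python analysis/04_compare_reconstructions.py  # differences, Bland-Altman, summaries
```

Tables land under `results/` (volumes and figures under `scratch/`, not
tracked).  From one such run: the brain-phantom FWHM(x,y) rises 3.0 → 4.5 mm
from QClear100 to QClear1000 while SNR rises 9.0 → 715; uniformity %SD is
worst at β=100 (71.8%); and NEMA hot-sphere contrast is highest for the
low-β BSREM reconstructions and grows with sphere diameter for every
method.  There is also a `petqa` CLI (`simulate`, `reconstruct`,
`analyze-nema`, `analyze-hoffman`, `compare`, `run-all`) wrapping the same
library calls.

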