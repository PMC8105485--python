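# Methods

`petqa` emulates a phantom-based comparison of PET reconstruction
algorithms entirely in software: digital phantoms are voxelized, projected,
corrupted with count noise, reconstructed with FBP / OSEM / BSREM, and
scored with the standard image-quality metrics.  This note records the
models, the parameters that matter, and the design choices made where the
procedure was genuinely open.

## Acquisition model

The scanner is modelled as a 2D parallel-beam system applied slice by
slice.  The projector is pixel-driven with linear interpolation: each pixel
deposits its value into the two radial bins bracketing
`t = (x cos θ − y sin θ)`, with one radial bin per image column, the
rotation centre at index `n // 2` and angles uniform over `[0, π)`.  This
geometry deliberately matches `skimage.transform.radon`, which serves as an
independent cross-check of the projection and as the filtering backend for
FBP.  Line integrals are expressed in pixel-length units, so the sinogram
sum per angle equals the slice activity sum exactly.

Because the projector is an explicit sparse matrix, the iterative
reconstructions use its exact adjoint.  Known limitation: at views that are
exact odd multiples of 45° the pixel-driven model shows a small zigzag over
the radial bins that rotation-based projectors lack; it is immaterial after
backprojection but visible in bin-by-bin comparisons.

No attenuation, scatter, randoms, detector blur or time-of-flight effects
are modelled: the metrics under study respond to reconstruction-dependent
blur and noise, which this chain produces.  Poisson noise is applied by
scaling the noiseless sinogram to a prescribed expected total count and
sampling each bin independently (`numpy` generator, explicit seed).

## Phantoms

**NEMA IQ.** A cylindrical warm body (default radius 140 mm, background
5.6 kBq/mL) carrying six spheres of 10/13/17/22/30/39 mm diameter on a
57.2 mm ring, 60° apart.  The four smallest are hot at a 4:1 ratio
(22.4 kBq/mL); the two largest are cold (zero).  Sphere membership is
voxel-centre-inside-surface, which converges to the analytic volume as the
grid refines.  The body radius was chosen so that twelve non-overlapping
background ROIs of the largest sphere's diameter fit at ≥ 15 mm from the
body edge while clearing every sphere; a narrower body cannot host the full
NEMA background layout.

**Hoffman surrogate.** The true Hoffman atlas is proprietary, so the brain
is generated procedurally: an ellipsoidal brain (semi-axes a fixed fraction
of the grid extent), a cortical gray shell whose inner surface is folded by
a seeded sum of angular/axial harmonics, a white interior, two ellipsoidal
putamina (right putamen volume 2400 mm³ by construction, 1 : 1.8 : 1.1
proportions), and a white-matter background VOI of the same volume placed
posteriorly.  Gray matter and the putamina carry activity 1.0; white matter
is devoid of activity by default (`wm_activity_mode="devoid"`, matching the
background-VOI assumption of the SNR metric) or filled at `1/gm_wm_ratio`
in `"scaled"` mode.  The background VOI is exactly zero in both modes.  The
surrogate reproduces the features the metrics depend on — GM/WM contrast, a
small bright nucleus, a cold reference region, structure at gyrus scale in
all three axes — but not human anatomy; results transfer to real data only
at the level of orderings and trends, not absolute values.

## Reconstruction

**FBP** — ramp-filtered backprojection per slice (`skimage.iradon` on the
matched geometry) followed by a separable Gaussian post-filter
(σ = FWHM/2√(2 ln 2) per axis, in voxel units).  Linear; negative voxels
permitted.

**OSEM** — multiplicative EM over interleaved angle subsets (subset *s*
takes angles ≡ *s* mod *S*), initialised to ones, zero-sensitivity voxels
frozen at zero.  `subsets = 1` is plain MLEM.  Subset counts must divide
the number of angles; this is enforced as a configuration error.  The
default study acquisition uses 180 views, which is incompatible with the
8/16-subset OSEM rows of the design matrix, so full design-matrix runs use
192 views (divisible by 8, 12 and 16) while single-algorithm studies keep
180.

**BSREM** — block-sequential penalized EM with the relative-difference
prior (RDP)

    R(f) = Σ_j Σ_{k∈N(j)} w_jk (f_j − f_k)² / (f_j + f_k + γ|f_j − f_k|),

γ = 2, 26-neighbourhood, inverse-physical-distance weights normalised to
the nearest in-plane neighbour.  Each subset applies the multiplicative
one-step-late update

    f ← f · A_sᵀ(g_s / A_s f) / max(S_s + (β_eff/S) ∇R(f), 0.05 S_s),

with the penalty gradient evaluated at the current estimate.  The
one-step-late linearisation keeps the update multiplicative — hence
non-negative and stable — where an additive EM-preconditioned ascent step
diverged at the upper end of the beta grid in development.  The penalty
gradient is recomputed every subset; a cheaper per-epoch refresh produced
limit cycles (non-monotone objective) at high beta.  With β = 0 the update
reduces exactly to OSEM, which is asserted in tests.  Relaxation is a
constant unit step by default so that the β = 0 equivalence is exact; a
diminishing schedule α_n = 1/(1 + decay·n) is available via
`ReconConfig.relaxation_decay`.  The fixed epoch budget (default 25) stands
in for "iterate to convergence"; the penalized objective is exposed per
epoch and is non-decreasing on the test problems.

**Beta scale.** The configuration keeps the vendor-style grid β =
100…1000 purely to mirror the study design.  Internally the penalty weight
is `β × BETA_SCALE` with `BETA_SCALE = 0.002`, a fixed normalisation chosen
so that, at the default count level and geometry, the grid spans the
under-smoothed to clearly-smoothed regime (estimated in-plane FWHM rising
by roughly a factor of two across the grid) while the one-step-late
denominator stays clear of its stability floor.  No numeric equivalence to
any scanner's beta is claimed.

## Metrics

NEMA NU 2-2012 quantities per sphere of diameter d: a circular ROI of
diameter d on the sphere-centre slice gives C_H (or C_C); 60 background
ROIs — 12 in-plane positions × 5 slices (centre, ±1 cm, ±2 cm, rounded to
the nearest slice with ties toward the centre) — give C_B and its SD
(K−1 denominator):

    hot contrast (%)  = 100 ((C_H/C_B) − 1) / ((a_H/a_B) − 1)
    cold contrast (%) = 100 (1 − C_C/C_B)
    background variability (%) = 100 SD / C_B

ROI membership is voxel-centre-inside-circle with no partial weighting, so
every result is bit-reproducible given the layout.  The exact in-plane
background positions are not standardised to the millimetre; the default
layout is derived deterministically from the phantom geometry (greedy
search over concentric candidate rings, outermost first) under the
constraints above, and an explicit position list can be substituted.  The
same position set is used concentrically for every sphere size, and the
cold spheres share the background sets of their diameter.

Brain-phantom metrics: the effective resolution is estimated without point
sources by exhaustively convolving the noiseless digital phantom with
separable Gaussians over a (FWHM_xy, FWHM_z) grid — default 3–18 mm in
0.5 mm steps, matching the granularity of typical reported values — and
taking the Pearson-correlation argmax over the voxels where the digital
phantom is positive.  Ties resolve to the smaller FWHM.  The search is
joint by default; a sequential mode (in-plane first at the axial grid
minimum, then axial) exists for sensitivity analysis.  Axial template
blurs are applied in one shot per grid value: an incremental
variance-cascade was measurably biased for sub-voxel sigma increments on
2.78 mm slices.  Uniformity is 100·σ_P/C_P over the right-putamen VOI and
SNR is (C_P − C_W)/σ_W against the zero-activity white-matter VOI; both
VOI standard deviations use the population (N) denominator, since the
defining ratios do not specify N vs N−1.

## Comparison

The design matrix mirrors the study: PET-CT datasets × {FBP, OSEM} × three
post-filters (6 rows); PET-MR datasets × {OSEM × 3 filters, BSREM ×
β 100…1000} (13 rows); NEMA datasets use 8 OSEM subsets and Hoffman 16.
Differences are `reference − method` against FBP with the 5 mm filter —
the sign convention under which the study's printed examples (SNR 23.0 vs
84.8 → −61.8; FWHM 7.5 vs 16.5 mm → −9.0 mm) reproduce exactly.
Bland-Altman agreement pairs sphere-resolved metric series and reports the
mean difference with ±1.96 SD (N−1) limits; summary statistics report
mean, sample SD, median and CV% (printed to one decimal).

## Problem sizes and reproducibility

The package's desk-scale defaults are 96×96×32 voxels at 2×2×2.78 mm for
the brain surrogate, 80×80×24 at 4.7×4.7×5 mm for the NEMA phantom (the
in-plane voxel size of the study's NEMA reconstructions), 180 projection
angles (192 for full design-matrix runs, see above) and 5×10⁶ expected
counts — a count level at which the beta trends are clearly resolved while
a full beta sweep runs in minutes on one CPU.  Blur-recovery validation
runs at 128×128×40 with 1×1×2.78 mm voxels.  Every stochastic step takes
an explicit seed; the pipeline manifest records the configuration hash and
all derived seeds, and reruns reproduce every output byte-for-byte.

## Known limitations

- EM-family reconstructions at this count level are run to a fixed epoch
  budget; at the lowest beta the converged images are substantially noisier
  than clinical scans, so absolute SNR/uniformity values are not comparable
  to scanner measurements — only their orderings across algorithms and
  penalties are meaningful.
- The surrogate brain's axial structure is smoother than real anatomy, and
  axial FWHM estimates on noisy reconstructions saturate near the search
  grid minimum at low beta; the in-plane estimate is the sensitive one.
- No attenuation/scatter chain: quantities depending on quantitative
  calibration (absolute kBq/mL recovery) are out of scope.
- The RDP is edge-preserving; at extreme penalty weights (well above the
  mapped grid) converged-EM noise can be frozen rather than smoothed.  The
  shipped `BETA_SCALE` keeps the grid inside the stable regime.
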