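# Methods

This note documents the models implemented in `cortexflow`, the parameter
choices that matter, what the synthetic phantoms do and do not emulate, and
the numerical conventions fixed for reproducibility.

## Gyrification index

The gyrification index of a brain mask is the area ratio of its pial
surface to a smooth superficial surface enclosing it. The pipeline is:

1. **Mask assembly** — the cortical grey + white matter voxels of the
   requested region (whole brain or one lobe) are selected through a label
   scheme mapping every segmentation label to a (tissue, lobe) pair.
2. **Cleaning** — a 3×3×3 volumetric median filter, then retention of the
   largest 26-connected component. Median filtering is applied in mask
   space (not mesh space) so the result is deterministic and the meshed
   surface watertight.
3. **Pial surface** — marching cubes at iso-level 0.5 on the padded binary
   volume, vertices scaled to millimetres, then classic Laplacian
   relaxation (each vertex moved half-way to its neighbour centroid,
   10 iterations).
4. **Hull surface** — the cleaned mask is closed by `n_dilations` dilations
   followed by `n_erosions` erosions (default 3/2) with a 6-connected
   cross structuring element; the closed mask provably encloses the input,
   and on a convex body the 3/2 recipe reduces to exactly one net
   dilation. The closed mask is meshed and smoothed like the pial surface.
5. **GI** = pial area / hull area, both by the triangle cross-product
   formula. GI < 1 is legal (the net dilation slightly inflates a convex
   hull); it is never clamped.

### Why both surfaces are smoothed

Marching cubes on a *binary* volume produces staircase facets that inflate
the area of a smooth shape by ~6–9% (a digital ball of radius 40–56 voxels
measures +8.8% before smoothing and −0.2% after). If only the pial surface
were smoothed, that shared discretisation bias would sit entirely in the
denominator: a voxelised ball would read GI ≈ 0.89 rather than ≈ 0.97.
Smoothing both meshes cancels the common bias so the ratio reflects
geometry; `GIParameters(smooth_hull=False)` restores pial-only smoothing.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `median_size` | 3 | cleaning kernel, voxels |
| `n_dilations` / `n_erosions` | 3 / 2 | hull closing recipe |
| `connectivity` | 6 | structuring element (6 = cross, 26 = cube) |
| `smooth_iterations` | 10 | Laplacian relaxation steps |
| `smooth_relaxation` | 0.5 | per-step vertex displacement factor |
| `smooth_hull` | True | smooth the hull mesh as well |

Every `GIResult` records the parameters that produced it.

### Lobar GI

Lobar GI restricts the mask to one lobe before running the identical
pipeline, so the flat faces cut at lobe boundaries contribute to both the
pial and hull areas. Consequence: lobar GI is pulled toward 1 relative to
the whole-brain value, and the whole-brain GI need **not** lie between the
lobar extremes (on the four-lobe phantom the cut planes dominate each
wedge's area budget and all lobar GIs sit below the whole-brain GI). The
alternative — assigning whole-brain surface patches to lobes — would avoid
this but requires a surface parcellation; mask restriction was chosen for
its determinism and is reported as such.

## The folded-cortex phantom and its oracle

The phantom's pial surface is the radial perturbation

r(θ, φ) = R + a·sin(kθ)·sin(2kφ)

voxelised into background / white matter / a cortical ribbon of fixed
thickness, partitioned into four azimuthal "lobes". Its exact area is the
2000×2000 midpoint quadrature of the first-fundamental-form element
f·√(f²sin²θ + f_θ²sin²θ + f_φ²); its hull is the envelope sphere of radius
R + a, valid only when the fold wavelength π(R+a)/k is at most 3× the
closing radius — specs outside that regime are rejected by the area oracle
rather than silently mis-oracled.

**Scale pairing.** The cleaning filters (3³ median, 10-step Laplacian)
operate at a fixed scale of ~2–3 voxels, so sinusoidal folds narrower than
~15 voxels lose a large fraction of their area excess in the pial branch —
and the envelope-validity guard ties the wavelength to the closing radius.
The phantom validation therefore runs the pipeline with fold wavelength and
closing radius scaled *together* above the filter scale: R = 45 mm, k = 6
(wavelength ≈ 26 mm), 0.8 mm voxels, closing 12/11. In that regime the
pipeline agrees with the quadrature oracle to −3% (sphere), −6% (a = 3 mm)
and −9% (a = 4.5 mm), and GI is strictly monotone in fold amplitude. The
residual deficit is fold-crest rounding by the median/Laplacian steps plus
the one net dilation in the hull. At the clinical default closing (3/2) the
same phantoms still rank correctly by amplitude but read closer to 1 — a
property of applying fixed-scale cleaning to near-filter-scale sinusoids,
not of the implementation. Resolution convergence is assessed with the
closing radius held fixed in millimetres (dilation counts scaled with
1/voxel); holding the *count* fixed instead changes the physical hull and
is not a convergent scheme.

What the phantom does not emulate: real neonatal folding (deep slit-like
sulci with near-touching walls, which survive median/Laplacian cleaning far
better than sinusoids), anatomical atlases, segmentation noise, partial
volume, or motion artefacts. Passing phantom tests therefore validates the
geometry pipeline, not segmentation robustness.

## Flow phantom and CDO₂

Each of three non-overlapping vessels carries a parabolic (Poiseuille)
profile v(r, p) = v_peak·m_p·(1 − (r/R_v)²) with a non-negative, mean-1
cardiac waveform m; the analytic time-averaged flow is
(v_peak/2)·πR_v²·mean(m)·60 ml/min. Defaults are neonatal-scale: radii
1.5/1.5/1.2 mm, peak velocities 60/60/50 cm/s (all below the 140 cm/s
encoding ceiling the generator enforces), 20 cardiac phases, 0.3 mm pixels
(≤ R/5, at which discretised flow lands within 5% — measured <1% — of the
closed form). Measured flow integrates *signed* velocity (net flow), is
exactly linear in velocity and ROI area, and CBF is the exact sum of the
three vessel flows.

CDO₂ is computed in two modes. `as_printed` evaluates
SaO₂ × [Hb](g/dL) × 1.36 × CBF(ml/min) literally, matching the magnitude
convention of the clinical literature (≈1600 for SaO₂ 0.98, Hb 16.1 g/dL,
CBF 76 ml/min); `si` divides by 10 (haemoglobin per ml of blood), the
dimensionally conventional variant. Haemoglobin given in g/L (values > 25)
is converted to g/dL. Saturations must be fractions; percent inputs raise
with guidance rather than silently scaling.

## Cohort generator and statistics

The cohort generator draws GA and PMA from shared normals (matched-cohort
assumption), a latent oxygen-delivery value for every subject, and builds
gyrification and grey-matter volume as linear functions of that latent
CDO₂ plus a group offset (CHD only) and Gaussian noise. Defaults are set to
a term neonatal cohort: n = 30 per group, GA 38.7 ± 0.8 wk, PMA
39.2 ± 0.7 wk, CDO₂ 1700 ± 450, GI ≈ 2.4 scale with population
R²(GI, CDO₂) ≈ 0.28, volume slope/noise giving population
R²(volume, CDO₂) ≈ 0.48, group offsets −0.091 (GI) and −27 ml (volume).
CDO₂ is reported only for the CHD rows (as acquired in the emulated
design) though the latent value drives both groups' outcomes.

Statistical conventions:

* **Matching** — one-to-one assignment minimising total Euclidean distance
  in (GA, PMA), solved exactly as a linear assignment problem; rows sorted
  by subject id first so ties break deterministically. Verified equal to
  exhaustive enumeration for all pools up to 8 candidates.
* **ANCOVA** — per-outcome OLS `outcome ~ group + PMA (+ extras)`, group
  coded control = 0, CHD = 1 so effects read CHD − control; listwise
  deletion with the dropped count reported; singular designs rejected with
  the offending columns named. A numerically zero-residual, zero-effect fit
  (constant outcome) reports p = 1 rather than 0/0 noise. Type-I error
  under a null simulation (1000 cohorts) is ~5%.
* **Mann–Whitney** — exact null distribution when n₁·n₂ ≤ 400 and no
  cross-sample ties, otherwise normal approximation with tie correction;
  the branch taken is reported. All-tied input returns p = 1 with a flag.
* **Fisher exact** — two-sided by summing hypergeometric probabilities no
  larger than the observed table's.
* **Bonferroni** — α/m, applied to the four-lobe GI family only (0.0125 at
  α = 0.05); other comparisons are exploratory and uncorrected.
* **Repeatability** — Pearson correlation (and its square) of paired
  repeated NIRS readings.

## Pipeline and provenance

A run is a JSON `RunConfig`; outputs are plain CSV plus a manifest with the
config, its hash and the seed, sufficient to re-execute the run. Identical
config + seed give byte-identical outputs. Per-subject failures are
recorded in an `error` column, never silently dropped; subjects without
flow data keep their volumetric/GI fields with empty haemodynamics.

## Problem sizes

Phantom GI studies use 144³ voxel grids (0.8 mm, brain-scale R = 45 mm) and
2000² quadrature; the demonstration cohort uses 48³ miniature brains so a
full two-group end-to-end run completes in seconds; calibration simulations
use 1000 replicates (type-I error, R² envelope) and 200 replicates (effect
recovery). These sizes are the package's test conditions, chosen to make
the validation exhaustive yet quick on a single CPU.

## Known limitations

* The GI pipeline measures a *filtered* surface: cleaning removes genuine
  structure at or below its ~3-voxel scale. Real sulcal walls survive this
  far better than the phantom's sinusoids, but very fine secondary sulci at
  coarse resolution will be under-counted.
* The hull's one net dilation biases GI slightly low (≈3% at R ≈ 56
  voxels); comparisons across cohorts processed identically are unaffected.
* Vessel ROIs are taken as given (manual in the emulated workflow); no
  background-phase correction or velocity unwrapping is performed, and
  vertebral flow (a few percent of total) is not modelled.
* "Whole brain" is defined as cGM + WM + deep GM + cerebellum, excluding
  ventricles and extra-axial CSF, which are reported separately.
* Growth-reference z-scores are accepted as optional pre-computed inputs;
  no external reference data are bundled.
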