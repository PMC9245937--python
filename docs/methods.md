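# Methods

## The coverage statistic

Inhibitory synaptic coverage of a neuron is defined as C′ = N_s / A(d):
the count of GAD+ puncta overlapping the neuronal membrane divided by
the area of the segmented neuron, reported as puncta per µm² neuronal
membrane. The algorithm has three parts: (i) segmentation of the neuron
boundary from the neurofilament channel, (ii) segmentation of synaptic
puncta from the GAD (or synaptophysin) channel, and (iii) their
combination into C′. Counting puncta, rather than summing punctum area,
avoids committing to an exact synapse boundary, which is not resolvable
at light-microscopic scale.

**A(d) semantics.** The literature phrase "area of the segmented neuron"
coexists with the unit "per µm² neuronal membrane". We take A(d) to be
the full segmented-neuron area — the interior plus the delineated
boundary ring, in µm² — which is the same quantity reported as neuron
size (the sum of the area within the segmented boundary and the area of
the boundary itself). The units string "per µm² neuronal membrane" is
carried through outputs verbatim. This ambiguity is inherent to the
definition and is surfaced here rather than hidden.

**Segmented-region partition.** The segmented region is split into a
boundary (region pixels with at least one 8-neighbour outside the
region) and an interior (the region minus that ring); a 10×10-pixel
solid square therefore has a 64-pixel interior and a 36-pixel boundary.
Note the inner ring is a resolution-dependent fraction of the region
(≈ perimeter × pixel size), so the interior alone underestimates the
object's area by that fraction; every reported quantity (A(d), neuron
size) uses interior + boundary, which is resolution-stable.

## Image processing

All stages operate on unit-interval float images; every parameter lives
in one config object and is echoed into run manifests.

- **Normalization** — per-channel linear rescale of the 1st–99th
  percentile onto [0, 1], then clipping. Absolute fluorescence in
  post-mortem material is confounded by fixation time, post-mortem
  interval and tissue pH, so only scale-free intensities are ever
  thresholded; any clipping-free multiplicative drift cancels exactly.
  A constant channel raises a degenerate-channel error (caught by QC as
  poor contrast), never silently zeroed. Thresholding is per-image (the
  alternative — per-case — is noted as an open choice; per-image is
  what the QC contrast rule expects).
- **Neuron segmentation** — Otsu threshold (overridable fixed value) →
  morphological closing (radius 0.6 µm) → hole filling → removal of
  components under 100 µm² → largest remaining component. The number of
  surviving components is reported for QC. Otsu on a structureless
  (noise-only) channel still returns a cut, so a separability guard
  rejects channels whose between-class variance fraction η falls below
  0.85 (pure noise gives η ≈ 0.75, any real soma ≥ 0.92).
- **Punctum detection** — white top-hat (radius 1.2 µm) → Gaussian
  smoothing (σ 0.10 µm) → robust background threshold (median +
  5 × 1.4826 × MAD of the suppressed image, floored at 0.1 for the
  noise-free limit) → watershed seeded at local maxima (1-pixel
  suppression radius; plateau ties broken by lexicographic (row, col)
  order, deterministic) → size filter [3 px, area of a 1.5 µm disc].
  The watershed split is applied to *every* supra-threshold component,
  not only oversized ones: at membrane densities of 0.30–0.35
  puncta/µm² a merged pair need not exceed the single-punctum area
  bound, and splitting only oversized components systematically
  undercounts.
- **Membrane counting** — a punctum counts toward N_s (once) if its
  pixel mask intersects the membrane band, the boundary dilated by the
  band half-width (default 0.5 µm). The discrete dilation radius is the
  ceiling of halfwidth/pixel-size so the physical band is always
  covered.
- **DAB quantification** — colour deconvolution of RGB brightfield
  images into haematoxylin/eosin/DAB optical densities (standard stain
  matrix), threshold 0.15 on the DAB density, reported as millions of
  positive pixels per mm².

## Quality control

Four deletion reasons, evaluated in priority order, always returning a
status: poor contrast (raw neurofilament p99 − p1 below 0.15 full
scale), two neurons (≥ 2 components above the soma-size floor),
multiple processes captured (solidity of the retained component below
0.80), incorrect neuron (no component of soma size). Failed neurons
keep their records with the reason attached, so deletion bookkeeping
(counts per reason, percent deleted, retained total) is exactly
reproducible, and reason counts sum to the deletion total by
construction.

## Synthetic image generator

The generator is the package's study stand-in, not a test fixture: it
plants exact ground truth and its defaults are the study conditions the
pipeline must recover.

- **Soma** — an irregular 8–12-vertex polygon with controlled radial
  jitter (±22 %), scaled in µm space to exactly the requested area
  before rasterization, approximating a layer-5 pyramidal profile
  (~400–530 µm²). Geometry is generated in µm and only then rasterized,
  so planted areas and counts are independent of pixel size.
- **Puncta** — exactly round(coverage × area) isotropic Gaussian blobs,
  peak intensity uniform on 0.6–1.0 before intensity drift, centroids
  uniform along the membrane band (perimeter position × normal offset
  within ±0.6 µm) under a 0.5 µm hard-core minimum separation. The
  rendered FWHM is 0.26 µm, matching the diffraction-limited spot of a
  far-red dye on a 60×/1.4 NA system (0.51 λ/NA ≈ 0.24 µm). These three
  values are coupled: at the planted densities the mean centre spacing
  on the membrane is only ~0.5–0.6 µm, and blobs wider than ~2σ of that
  spacing are physically unresolvable regardless of detector, while a
  much larger hard core cannot be packed onto the band at the highest
  planted counts (random sequential placement jams near 55 % area
  fraction).
- **Nucleus** — a disc of 0.4 × the soma-equivalent radius in the DAPI
  channel.
- **Acquisition model** — per-case multiplicative intensity drift drawn
  uniform on 0.6–1.4 (exercising normalization), clipping to [0, 1],
  then additive Gaussian noise (SD 0.03 full scale, clipped again).
  Pixel size defaults to 0.2 µm/px, a plausible 60×-oil sampling;
  it is always explicit in the config and never inferred.
- **Degenerate images** — four generators mirror the QC reasons: a
  dim soma (contrast below the QC floor), a soma with four thin
  radiating appendages (solidity ≈ 0.4), two disjoint somata above the
  size floor, and a sub-threshold fragment.
- **DAB images** — a smoothed random field is cut at the quantile that
  yields *exactly* the requested positive-pixel count; positives are
  composed in DAB optical density and negatives in haematoxylin before
  conversion to RGB, so deconvolution-based extraction is checked
  against an exact truth.

What the generator does **not** emulate: out-of-focus light and 3D
sectioning, dendritic/axonal GAD, autofluorescence, spatially varying
illumination, chromatic offsets between channels, and tissue context
around the soma. Passing recovery tests therefore demonstrates the
correctness and calibration of the computational pipeline under
controlled degradations — not robustness to every artefact of real
tissue imagery.

## Cohort generator

Per-case tables (47 MS cases split 21/26 by *HLA-DRB1\*15* carriage,
plus 10 controls) with group means and SDs taken from the published
summary statistics (SDs back-computed from SEM × √n). Marker
expressions, lymphocyte counts and fibrinogen are log-normal
(non-negative, right-skewed); neuron density is zero-truncated normal;
sex is Bernoulli with the published group proportions; ages and
post-mortem intervals are range-truncated normals.

Rank correlations are planted through a Gaussian copula: a target
Spearman r_s is converted to the latent Pearson ρ = 2 sin(π r_s/6) (the
exact bivariate-normal relation), and monotone marginal transforms
preserve it. Markers are conditionally independent given the
neuron-density factor (latent marker–marker correlation ρ_i ρ_j), which
is positive definite by construction; explicit overrides are checked by
Cholesky and rejected with the offending entries named. The planted
*population* value is exact; the *sample* Spearman estimator carries the
known small-n attenuation (e.g. E[r_s] ≈ 0.718 at n = 26 for a planted
0.740), which is a property of the estimator, not of the generator.
Fibrinogen's planted correlation with neuron density defaults to −0.30;
no canonical magnitude exists for it, so it is configurable.

## Statistics

Spearman correlations use tie-averaged ranks; the two-sided p-value is
the exact permutation probability for n ≤ 10 without ties (bitmask
dynamic programme over the Σd² distribution, verified against full
enumeration), and the t approximation otherwise. Adjusted models are
OLS with the outcome and predictor z-scored, so the reported estimate
is a standardized β in [−1, 1]; covariates default to age, sex (binary
indicator) and post-mortem interval, optionally fibrinogen. The
"transform as required" convention is operationalized as a
pre-registered rule: log the outcome when its Shapiro–Wilk statistic is
below 0.95 raw but not logged; the decision is recorded per model. No
interaction terms are fitted and **no multiple-testing correction is
applied** (α = 0.05, two-sided, each test on its own) — this mirrors
the analysis convention of the source field and must be kept in mind
when reading any result table this package emits.

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.default_rng` seeds;
  identical seed ⇒ bit-identical images and tables.
- Placement failure (band cannot hold the requested punctum count under
  the hard-core constraint) raises an error naming the attempted count
  rather than silently under-planting.
- An empty punctum set is a valid detection result; a constant channel,
  a missing RGB channel, mismatched image shapes, non-positive areas
  and out-of-range fractions are errors with dedicated exception types.
- Group contrasts fall back to Welch's t only when there are too few
  cases for the adjusted model (logged); the percent difference is
  always relative to the stated reference group.

## Calibration and problem sizes

Against planted truth at 0.2 µm/px, segmentation recovers soma area to
within ~0.5 %, and C′ carries a −1 to −3 % bias from residual merging
of diffraction-limited punctum pairs plus occasional membrane-band
misses; the bias is nearly density-independent over 0.25–0.40
puncta/µm², so *contrasts* between groups are recovered essentially
unbiased. Detection precision and recall both exceed 0.95 at the
planted densities under default noise.

The recovery experiments use 10 MS-like + 7 control-like cases of 30
neurons, averaged over 20 replicate seed streams, in the acceptance
script, and reduced sizes (10-neuron cases, 2–3 replicates) in the test
suite; at these sizes the Monte-Carlo standard error of the recovered
contrasts is well under one percentage point, far inside the ±3-point
acceptance band.

## Known limitations

- The boundary between "merged pair" and "single punctum" is set by
  diffraction and sampling, not by the detector; at 0.2 µm/px a few
  percent of puncta at the highest planted densities are unresolvable
  in principle. Halving the pixel size removes most of this bias.
- The QC thresholds (contrast 0.15, solidity 0.80) are operational
  definitions chosen for the synthetic degradations; real-tissue
  tuning would require annotated examples.
- Cohort covariates are drawn independently of the copula block, so the
  generator cannot plant marker–covariate confounding beyond what the
  configurable correlation structure expresses.
- The `stats` module implements the source field's conventions,
  including its omission of multiplicity control; treat per-row
  p-values accordingly.
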