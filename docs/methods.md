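# Methods

This note records the models, parameter choices and numerical conventions
behind `tme3d`, and what the synthetic benchmarks do and do not establish
about real tissue data.

## Acquisition model

The simulated instrument is a Bessel-type light-sheet microscope imaging
cleared tissue blocks. Its geometry is carried by `AcquisitionConfig`:

| parameter | default | unit | origin |
|---|---|---|---|
| camera pixel pitch | 6.5 | μm | sCMOS sensor |
| overall magnification | ×11.1 | – | 10× objective (180 mm reference) behind a 200 mm tube lens |
| object-space pixel | 0.59 | μm | 6.5 / 11.1 |
| plane step | 2.0 | μm | x-scan step |
| optical section depth | 300 | μm | sheet geometry at 31.5° incidence |
| z-stage step | 250 | μm | gives (300−250)/300 = 16.7% overlap for stitching |
| sheet axial extent | 3.5 | μm | FWHM of the illumination sheet |
| penetration depth | 660 / 780 / 900 | μm | at 488 / 532 / 637 nm excitation |

The PSF is an anisotropic Gaussian: σ_z defaults to 3.5/2.355 ≈ 1.49 μm
(the sheet thickness read as a FWHM, the standard conversion), σ_xy to
1.0 μm. The config validates σ_z ≥ σ_xy — light-sheet axial resolution is
never better than lateral.

## Synthetic tissue blocks

`simulate_point_pattern` draws typed point patterns in a physical box:

- **poisson** — homogeneous Poisson with the configured intensity
  (count ~ Poisson(λV), uniform positions).
- **thomas_cluster** — Poisson parents, Poisson-sized Gaussian offspring
  clouds; offspring falling outside the domain are discarded.
- **paired_attraction** — a fraction of the population is placed on
  spherical shells around anchor cells (chosen with replacement — one
  T cell can host several conjugates) at distances drawn uniformly from
  2–10 μm, strictly below the 15-μm conjugation threshold by construction;
  the remainder is uniform background.
- **co-positivity** — a Bernoulli fraction of a population is re-emitted at
  identical coordinates under a second label (Ki67); detection-side
  matching (5 μm radius) absorbs the coordinate jitter real two-channel
  detections would have.

Attraction dependencies are resolved in topological order; cycles are an
error. All randomness flows from one integer seed per call through
`numpy.random.SeedSequence` spawning, so regeneration is bit-identical and
no global RNG state is touched.

Absolute per-type densities in tissue are not established quantities; the
packaged disease presets use order-of-magnitude choices in the
10⁻⁵–10⁻⁴ cells/μm³ range, chosen once: T cells (CD3) at 1×10⁻⁴ (the most
abundant type in all conditions), and per condition

| population | RLN-like | DLBCL-like | AITL-like |
|---|---|---|---|
| CD20 density / attached fraction | 5×10⁻⁵ / 0.10 | 1×10⁻⁴ / 0.45 | 5×10⁻⁵ / 0.10 |
| FOXP3 density / attached fraction | 1.5×10⁻⁵ / 0.10 | 1.5×10⁻⁵ / 0.10 | 4×10⁻⁵ / 0.45 |
| CD163 density / attached fraction | 2×10⁻⁵ / 0.10 | 2×10⁻⁵ / 0.10 | 4.5×10⁻⁵ / 0.45 |
| CD15 density / attached fraction | 2×10⁻⁵ / 0.20 | 2×10⁻⁵ / 0.20 | 1×10⁻⁵ / 0.05 |
| Ki67 fraction of CD8 | 0.50 | 0.30 | 0.20 |
| Ki67 fraction of CD20 | 0.30 | 0.30 | 0.30 |

encoding the qualitative structure of the three conditions: B-cell
enrichment near T cells in the B-cell-dominated condition,
immunosuppressive Treg/TAM neighborhoods in the AITL-like condition with
depleted neutrophils, highest CD8 proliferation in the reactive condition,
flat B-cell proliferation. CD68 and CD14 are identical across conditions
and act as negative controls.

## Rendering

Each cell of a channel's marker becomes an anisotropic Gaussian blob whose
peak is scaled by exp(−depth/attenuation length), where depth is measured
from the illuminated face. A constant background (default 100 counts) is
added, Poisson shot noise applied, and the field quantized to the camera
bit depth with saturation clipping. Voxel (0,0,0) is centered half a voxel
inside the field corner, so physical = origin + index·Δ throughout. A
configurable voxel-count cap rejects fields that would not fit in memory
rather than truncating silently. Not modeled: optical wave propagation,
refractive-index or clearing artifacts, vignetting, striping.

## Spot detection

The detector is single-scale LoG blob detection: per-axis σ in voxels is
(d/(2√3))/Δ so the 2-μm plane step and 0.59-μm pixels are both treated
correctly (σ below 0.5 voxel on any axis is rejected as unresolvable).
The image is demeaned before filtering because the discrete LoG kernel does
not sum exactly to zero, which would leak a constant offset into the
response. Candidates are 26-connected positive local maxima; "auto"
thresholding is Otsu on the positive response values; non-maximum
suppression is greedy in descending quality with ties broken by (z, y, x)
for determinism, at a minimum separation of half the expected diameter.
Subvoxel refinement takes the intensity-weighted centroid in a
diameter-sized window (min-subtracted); windows truncated by the volume
border are kept and flagged `edge`. Detection-vs-truth scoring uses greedy
ascending-distance one-to-one matching — the standard benchmarking
convention, which coincides with optimal assignment when matches are
unambiguous (verified against exhaustive assignment on small instances).

## Stitching

The stage moves only in z between sections, so registration is a 1D search
over integer-voxel z shifts within a radius of the nominal offset,
maximizing normalized cross-correlation over the shared planes; candidates
are visited nominal-outward so ties resolve toward the nominal, and a
zero-variance overlap returns the nominal with score 0 and a warning.
Fusion feathers each tile linearly from its edges and normalizes per voxel
(weights sum to 1, constants preserved; single-coverage voxels are copied
verbatim up to rounding). Chains with a coverage gap are an error. No
subvoxel registration, xy mosaicking, global bundle adjustment or
illumination flattening.

## Spatial statistics conventions

- Distances are Euclidean in physical μm, never voxels.
- ROI membership is half-open: a point on the upper face is outside.
- Radial bins are half-open [r, r+5), so the ten shells partition [0, 50);
  a neighbor at exactly 50 μm is excluded.
- The conjugation threshold is strict (< 15 μm), and conjugation counts
  pairs, not a matching — one cell may appear in several pairs.
- The default radial edge policy, `interior_only`, drops centers closer
  than 50 μm to an ROI face so every shell lies inside the ROI and the CSR
  expectation λ·(4/3)π(r₂³−r₁³) holds without edge correction; `none`
  reproduces naive counting. An ROI thinner than 100 μm has no interior,
  which yields zero centers (reported as NaN means with a warning), not an
  error.
- A record counted as both center and neighbor never counts as its own
  neighbor (index identity, not coordinate identity, so coincident
  co-positive duplicates do count).
- The KD-tree implementations are contractually equal to the O(n²) double
  loop and are tested for exact integer parity against distance-matrix
  references.
- ROI selection is seeded rejection sampling of non-overlapping boxes; a
  jammed partial packing restarts after 500 consecutive failures, and a
  bounded total attempt budget turns infeasible requests into a
  diagnostic error.

## Group comparison

Kruskal–Wallis H is assembled from mid-ranks with the tie-correction
divisor and a χ²_{k−1} p-value. The chi-square approximation is adequate
for the intended group sizes (tens of ROIs per group); a `small_groups`
flag is raised when any group has fewer than 5 values. All pooled values
identical is degenerate (H = 0, p = 1, flagged). The unit of analysis is
the ROI by default; the tidy per-ROI tables allow re-aggregation at block
level. Boxplot summaries use median-of-halves quartiles (median excluded
from both halves at odd n) and 1.5·IQR whiskers. Post-hoc pairwise tests,
multiple-testing correction and factorial (bin × group) models are out of
scope; `radial.csv` is tidy so any stats package can fit the latter.

## Benchmark problem sizes

The self-validation benchmarks (`tme3d.validation`, also driven by
`scripts/acceptance.py`) use desk-scale problems: 256×256-px × 150-plane
rendered fields (not full 2048×1024 camera tiles) with 60 cells spaced two
diameters apart for detection; a 60×60×1000-μm column cut into four
jittered sections for the stitching round trip; a 1-mm³ box with ~600
sparse interior centers for the radial closed form (sparse so per-center
shell counts are effectively independent and the empirical SE is valid);
1000 CSR replicates with the 200 a-points drawn from the 15-μm interior of
the 500-μm box, which makes the n_a·n_b·(4/3)πr³/V expectation exact
rather than edge-biased; 2000 null replicates for the rank test's type-I
error; and 50 seeded three-condition runs for directional structure
recovery, simulating only the four cell types entering the checked
statistics.

## What passing tests do and do not show

The generator matches the statistical structure the analysis assumes —
Poisson counts, configured attraction, exponential depth attenuation,
Poisson shot noise, rigid z-jitter. Real cleared-tissue volumes add
effects deliberately not modeled: non-uniform background and autofluorescence,
scattering-induced PSF broadening with depth, striping, chromatic offsets
between channels, segmentation ambiguity in dense clusters, and biological
heterogeneity between blocks of one patient. Green benchmarks therefore
establish correctness of the computations and well-posedness of the
pipeline under its stated model, not detector or stitcher performance on
arbitrary clinical data; detection parameters (expected diameter, quality
threshold) remain exposed because their in-study values are
instrument- and stain-dependent.
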