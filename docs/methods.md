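# Methods

## Scope

`myddoquant` quantifies clustered membrane signaling puncta from
two-channel TIRF time-lapse movies and fixed-cell immunofluorescence. The
pipeline converts raw intensities into scaffold copy numbers via
single-fluorophore calibration, classifies puncta into complex-count
classes, measures recruitment kinetics of a second-channel partner, and
normalizes fixed-cell staining against a reference condition. Because the
method's correctness cannot be established on real data (no ground truth
exists there), the package ships a simulator whose complete event record is
the reference against which every stage is validated.

## The simulator

### Dynamics

Clusters of complexes nucleate on a 2D plane as a spatio-temporal Poisson
process and perform Brownian motion with per-axis step SD `√(2 D_eff Δt)`.
A cluster of `n` complexes moves with `D_eff = D/√n`, a Stokes-like
slowdown chosen because large assemblies are observed to be nearly
immobile; no mobility law is established for these assemblies, so the
exponent is a modelling choice. Two clusters fuse when their centroids
approach within `merge_radius_um`; the fused cluster carries the union of
members, the fluorophore-weighted centroid, and the surviving (larger)
cluster's identity and nucleation time. Splitting, off by default, detaches
either one complex or a random sub-cluster (`split_mode`), since the
observed topology of splitting is ambiguous. With a corral grid
(`grid_pitch_um` of 1.0 or 2.5), every cluster is confined to the grid
square it nucleated in by perfectly reflecting walls, and merging never
crosses walls.

Each complex holds `fluor_per_complex = 6` fluorophores (assembly
instantaneous by default; an optional linear ramp and optional exponential
photobleaching exist but are off, as neither process is part of the
quantification model). Per-fluorophore brightness is drawn once per
fluorophore from `N(μ, (cv·μ)²)` clipped at zero and persists for the
movie: the coefficient of variation (default 0.3) is molecule-to-molecule
dispersion, so a cluster's true brightness is constant between composition
changes, and frame-to-frame variation in the rendered movie comes from
camera noise alone. These draws are part of the ground truth
(`cluster_frames.gfp_equiv`, in units of the mean single fluorophore),
because the method's size classes are *intensity-defined*: validation must
compare the pipeline's intensity-based estimate against the intensity
truth, not against stoichiometry, or brightness dispersion would be
scored as pipeline error.

### Recruitment

A partner (the E3-ligase channel) binds a cluster with hazard
`h = h₀ (1 + c·(n−1))` for `n` complexes, active only after a refractory
delay from cluster nucleation, and stays for an exponential lifetime.
Defaults — `h₀ = 3.4·10⁻⁴ s⁻¹`, `c = 3.0`, delay 40 s, lifetime mean
60 s — were calibrated so that a ten-minute observation reproduces the
experimentally reported scale of TRAF6 positivity: ≈ 9 % of single
complexes, ≈ 50 % of 3-complex and ≈ 80 % of 6-complex clusters. The
linear-in-size hazard is the model's defining assumption; the calibration
fixes its scale to the published dose-response, not to any internal test.

### Camera model

Frames are sums of pixel-integrated 2D Gaussians (σ default 0.12 μm at
0.15 μm pixels) plus a constant background, passed through
`Poisson(signal) + N(0, read_noise) + dark_offset`, rounded and clipped at
zero (uint16). Random streams are split per sub-process (dynamics,
brightness, camera noise, stain, partner brightness), so toggling noise
never shifts trajectories, and a config plus seed determines every output
bit-for-bit.

### What the simulator does not emulate

No evanescent-field depth profile, no ligand–receptor chemistry, no
structural assembly kinetics, no drift, no uneven illumination, no
photophysics beyond static brightness dispersion (no blinking), and cells
are not explicitly modelled in movies (fields are uniform). Passing tests
therefore demonstrate correctness of the measurement chain under the
method's own statistical assumptions; they do not certify performance on
real data with drift, autofluorescence or blinking.

## The measurement chain

**Background.** Per frame: subtract the camera dark frame, then a
median-blurred copy (disk radius 25 px, reflective edges); negatives clamp
to zero. The integer path uses the sliding-histogram rank filter on a
reflect-padded frame, exactly matching the generic float path.

**Segmentation.** Cells: Otsu threshold on the log-transformed temporal
max projection (intensities span decades; a linear-scale Otsu separates
puncta from cytosol instead of cell from background), minimum area 500 px²,
holes filled. Fixed-cell puncta: same log-scale Otsu, equivalent-circle
diameter within 3–30 px. Nuclei: Otsu on DAPI, diameter 30–60 px, dropped
unless their centroid lies in a phalloidin-segmented cell; cytoplasm is the
set difference.

**Detection and linking.** Scale-normalized Laplacian-of-Gaussian response
at the PSF scale; local maxima above a threshold (default 10× the
MAD-based response noise); subpixel intensity-weighted centroid in a
(2⌈σ⌉+1)² window; duplicates within 1 px suppressed. Linking is per-frame
Hungarian assignment on squared displacement with a hard gate
(`max_disp_px`) and gap closing over ≤ `max_gap` missing frames. Merges
are handled implicitly: after fusion one spot persists and one track ends,
which is what a point detector sees.

**Intensity and copy number.** Per frame, the sum of the 3×3 pixel block at
the rounded centroid (round-half-away-from-zero); gap frames are linearly
interpolated and flagged, border-clipped windows flagged. Copy number is
the series divided by the calibrated single-fluorophore mean; the 3×3
window captures only ≈ 88 % of the PSF mass, but calibration molecules and
cellular puncta share the window so the factor cancels and no aperture
correction is needed for ratios. An optional per-frame subpixel aperture
correction (divide by the closed-form window mass at the measured offset)
removes the ±3–4 % modulation of the raw sum as a spot wanders within its
pixel; it matters only for statistics that take extremes over frames and
must be applied to calibration and movie identically.

**Calibration.** Single fluorophores adsorbed to glass are processed
through the identical chain (gap closing off); per-molecule intensity is
the track mean; values above 3× the median are discarded as overlapping
molecules; the retained mean and CV define the model. Fits from fewer than
100 molecules carry a warning flag.

**Classification and binning.** A punctum with maximum copy number ≥ 4.5
GFP equivalents contains at least one complex, ≥ 9 a cluster; complex
count is copy number / 4.5, real-valued. For size bins the count is
rounded (half up) and grouped: single, then 2–4, 5–7, 8–10, … For bin
*assignment* the maximum is taken after a 3-frame rolling median
(`max_complex_count_smoothed`): the raw maximum of a long track inherits
its single largest photometric excursion — a noise tail or a neighbour
transiting the 3×3 window — which systematically promotes one-complex
puncta (true brightness 1.33 complexes) across the 1.5-complex rounding
boundary. The raw maximum remains available (`smoothed=False`).

**Colocalization and kinetics.** Two tracks colocalize when their centroid
distance is ≤ 0.25 μm for ≥ 2 consecutive frames (the radius is physical
and does not scale with pixel size). Onset is the first frame of the first
qualifying run; positivity counts once per scaffold track even with
multiple partners; recruitment time is measured from the scaffold's first
detected frame; landing size is the complex count at exactly the onset
frame (flagged if the onset falls in an interpolated gap). Lifetimes
censored by the movie end are flagged and included. Lifetime summaries
split at 50 s.

**Fixed-cell normalization.** Intensities are normalized against the pooled
reference condition ("off grid"): `(I − q_lo)/(q_hi − q_lo)` with
(0.01, 0.99) for puncta and (0.05, 0.95) for the nucleus-to-cytoplasm
ratio; the fitted anchors are recorded so runs are reproducible, and the
transform is applied unchanged to all conditions (values outside [0, 1]
allowed). Normalized scaffold intensity ≥ 0.5 defines a cluster; dividing
by 0.5 estimates complexes per punctum; dividing the normalized stain by
that count gives per-complex staining. The stain–scaffold relation is an
unweighted OLS fit with Pearson correlation.

## Validation experiment design

The experiments in `myddoquant.validation` (run by `tests/test_acceptance.py`
and `scripts/acceptance.py`) fix their own conditions:

* **Colocalization oracle** — 200 random instances of ≤ 50 random-walk
  tracks, compared exactly against a naive all-pairs/all-frames scan.
* **Copy-number recovery** — static fields, true counts
  {1, 2, 6, 12, 18, 30}, 200 puncta per level, default brightness
  (single-fluorophore peak SNR ≈ 5.5). The pooled median relative error is
  the score: at cv = 0.3 the generator's own molecule-to-molecule
  dispersion puts a floor of ≈ 20 % on the per-level median for count 1
  (0.674 × cv), which no estimator can beat; the pooled median across
  levels is the meaningful accuracy summary.
* **Kinetics recovery** — one ten-minute two-channel movie of a 96×96 μm
  field, ≈ 650 scaffold tracks, nucleation seeding pre-formed clusters of
  1–8 complexes weighted toward singles so each size bin is populated.
  Conditions are deliberately sparse (0.08 clusters/μm², D = 0.002 μm²/s,
  merge radius 0.45 μm ≈ the two-spot resolution limit) and bright
  (1000 counts/fluorophore): the experiment isolates recovery of the
  recruitment kinetics; at high density the per-track maximum is
  contaminated by unresolvable neighbours and merge-approach blending,
  which are resolution limits of any point-detector pipeline rather than
  kinetics errors, and the copy-number experiment stresses photometry
  separately at its stated SNR. A merge radius below the resolution limit
  would create an unphysical regime where two ground-truth clusters are
  one detector spot for many frames.
* **Corral confinement** — matched 13-minute arms (0.06 nucleations
  /μm²/min, D = 0.012 μm²/s) with and without a 1 μm grid; ground truth
  must show zero wall crossings, and the measured per-track maximum sizes
  on grid must be stochastically smaller (one-sided Mann–Whitney) than off
  grid, since corrals suppress coalescence.
* **Translocation recovery** — 200 noiseless synthetic cells with nuclear
  enrichment 1.8; the camera offset is subtracted before the ratio (an
  additive offset otherwise compresses it).

Problem sizes were chosen so each experiment gives statistically stable
percentages per bin while the full suite completes in a few minutes on one
core.

## Numerical choices and edge cases

* Rounded-centroid convention: round half away from zero on 0-based pixel
  indices; the 3×3 block is centred there.
* Empty inputs propagate as empty results (empty masks, empty tables), not
  errors; degenerate normalization references (q_hi = q_lo) and
  zero-variance regressions raise.
* Ties in merging (equal fluorophore counts) resolve to the lower cluster
  id; the survivor is otherwise the brighter cluster.
* Track tables round-trip through tab-separated text with `%.10g` floats,
  making CLI outputs byte-stable for a fixed config and seed.
* Calibration placement uses uniform dart throwing with grid-hashed
  rejection (minimum separation 4σ), not a sequential space-filling
  sampler, because the latter clusters its first points around the seed
  dart and biases local background estimates.

## Known limitations

* Tracking does not model merge events explicitly (no merge links); track
  identity through a fusion follows the assignment cost, so population
  statistics are validated rather than per-identity lineage.
* The 4.5× GFP single-complex intensity and the 0.5 normalized cluster
  threshold are adopted as method constants, not re-derived; the 0.5
  cutoff is relative to the reference condition's distribution and is
  recorded with the fitted anchors.
* Sub-resolution multi-emitter fitting is out of scope: puncta closer than
  ≈ 3 px are measured as one object, and validation conditions are chosen
  accordingly.
* The per-level copy-number error for counts ≤ 2 is dominated by the
  fluorophore brightness dispersion itself, not by the pipeline.
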