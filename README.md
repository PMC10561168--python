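# myddoquant

Copy-number-calibrated quantification of clustered membrane signaling
puncta from TIRF microscopy, with a ground-truth movie simulator.

## The problem

Innate-immune signaling through the IL-1 receptor proceeds through the
Myddosome, an oligomeric scaffold of nominally six MyD88 molecules per
complex that assembles into diffraction-limited puncta at the cell–bilayer
interface, diffuses, and coalesces into clusters. Cluster size controls the
recruitment of downstream effectors — the E3 ligase TRAF6 and the LUBAC
subunit HOIL1 — and ultimately NF-κB activation. Quantifying this requires
converting raw fluorescence into *absolute copy numbers*, classifying
puncta into size classes, and measuring two-channel recruitment kinetics.

`myddoquant` implements that measurement chain for anyone analysing
two-channel TIRF time-lapse or fixed-cell immunofluorescence of clustered
membrane assemblies:

* **simulate** — synthetic TIRF movies, single-fluorophore calibration
  fields and fixed-cell micrographs with a complete ground-truth event
  record (nucleation, diffusion, merging, corral confinement,
  size-dependent partner recruitment, camera noise);
* **preprocess** — dark-frame and median-blur (25 px disk) background
  subtraction; Otsu segmentation of cells, nuclei (30–60 px diameter
  filter) and cytoplasm;
* **detect_track** — Laplacian-of-Gaussian spot detection with subpixel
  centroids, Hungarian-assignment linking with gap closing, and the
  3×3-pixel intensity readout;
* **calibrate** — single-fluorophore intensity calibration and conversion
  to copy number; a punctum with intensity ≥ 4.5× GFP holds ≥ 1 complex,
  ≥ 9× GFP a cluster of ≥ 2; complex counts bin as single, 2–4, 5–7, …;
* **kinetics** — colocalization (centroids ≤ 0.25 μm for ≥ 2 consecutive
  frames), recruitment time, landing size, % positive per size bin,
  lifetime splits at 50 s;
* **fixedcell** — fixed-cell puncta quantification with reference-condition
  quantile normalization, `Norm = (I − q01_ref)/(q99_ref − q01_ref)`,
  the 0.5 cluster threshold, per-complex staining intensity, scaffold–stain
  correlation, and the RelA nucleus-to-cytoplasm translocation ratio
  (q05/q95 normalization).

## The core statistics

With single-fluorophore mean intensity `I₁` measured from surface-adsorbed
GFP under identical settings, a punctum's copy number is `n(t) = I(t)/I₁`
(3×3-pixel sums in both numerator and denominator, so the PSF mass missed
by the window cancels). Complex count is `n/4.5`. For a scaffold track
nucleating at `t₀` whose partner first colocalizes at `t₁`:

* recruitment time = `t₁ − t₀`,
* landing size = complex count at exactly `t₁`,
* a track is partner-positive if any colocalized run lasts ≥ 2 frames,
* % positive is tabulated per rounded max-complex-count bin.

## Worked example

```python
import myddoquant as mq

cfg = mq.SimConfig(field_size_px=(256, 256), n_frames=100,
                   nucleation_rate=3e-4, seed=1)
truth = mq.simulate_dynamics(cfg)
movie = mq.render_movie(truth)

# calibration from a simulated single-GFP field
cal_cfg = mq.SimConfig(field_size_px=(256, 256), nucleation_rate=0, seed=2)
cal_stack, _ = mq.simulate_calibration_field(cal_cfg, 400, n_frames=5)
model = mq.calibrate_from_field(cal_stack)

records, events, partner_tracks = mq.analyze_two_channel(
    movie["gfp"], movie["partner"], model)
table = mq.fraction_positive_by_bin(records, events)
print(f"calibration: {model.single_fluor_mean:.1f} counts/GFP "
      f"(cv {model.single_fluor_cv:.2f})")
print(f"{len(records)} scaffold tracks, {len(events)} recruitment events")
print(table[["bin", "n", "pct_positive"]].to_string(index=False))
```

prints

```
calibration: 168.6 counts/GFP (cv 0.26)
399 scaffold tracks, 12 recruitment events
        bin   n  pct_positive
sub-complex  43      0.000000
     single 194      1.030928
        2-4 158      4.430380
        5-7   4     50.000000
```

The calibration mean is the single-GFP intensity inside the 3×3 window;
each track's intensity divided by it gives MyD88 copy number; `table`
reports, per cluster-size bin, how many scaffold puncta recruited a
partner within the movie — the dose-response of effector recruitment on
cluster size (positivity rises from singles through 2–4 to the sparsely
populated 5–7 bin in this small example).

A CLI mirrors the library:

```bash
myddoquant simulate movie --seed 1 --out run/
myddoquant preprocess --input run/gfp.tif --out run/gfp_bg.tif
myddoquant track --input run/gfp_bg.tif --out run/gfp_tracks.tsv
myddoquant kinetics --myd88 run/gfp_tracks.tsv --partner run/p_tracks.tsv \
    --single-fluor-mean 168.6 --out run/kinetics/
```

All outputs are deterministic given config + seed, byte for byte.

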