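"""Ground-truth validation experiments.

Each experiment simulates data under the generator's study conditions, runs
the full measurement pipeline on the rendered images, and scores the
pipeline's estimates against the quantities computed directly from the
simulator's event record. These drivers are shared by the test suite and
the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .calibrate import (CalibrationModel, bin_by_complex_count,
                        build_puncta_records)
from .kinetics import (landing_size, fraction_positive_by_bin,
                       recruitment_time)
from .pipeline import (TrackingParams, analyze_two_channel,
                       calibrate_from_field, track_stack)
from .preprocess import subtract_background
from .simulate import (GroundTruth, SimConfig, render_movie,
                       simulate_calibration_field, simulate_dynamics,
                       simulate_fixed_cell, simulate_rela_field)

__all__ = [
    "default_calibration",
    "ground_truth_kinetics",
    "pipeline_kinetics",
    "kinetics_experiment",
    "copy_number_experiment",
    "corral_experiment",
    "rela_experiment",
    "brute_force_positive_tracks",
    "random_track_set",
]

#: one fully assembled complex in GFP equivalents (method constant)
COMPLEX_GFP = 4.5


def default_calibration(seed: int, n_molecules: int = 400,
                        field_px: int = 256,
                        fluor_intensity_mean: float | None = None,
                        ) -> CalibrationModel:
    """Fit a calibration model from a simulated single-fluorophore field.

    Uses subpixel aperture correction, consistently with the experiments
    below.
    """
    kw = {}
    if fluor_intensity_mean is not None:
        kw["fluor_intensity_mean"] = fluor_intensity_mean
    cfg = SimConfig(field_size_px=(field_px, field_px), nucleation_rate=0.0,
                    seed=seed, **kw)
    stack, _ = simulate_calibration_field(cfg, n_molecules, n_frames=5)
    return calibrate_from_field(
        stack, params=TrackingParams(max_gap=0, aperture_correction=True))


def ground_truth_kinetics(truth: GroundTruth,
                          min_span_frames: int = 2) -> dict:
    """Recruitment statistics computed directly from the event record.

    Only events whose partner is visible for at least ``min_span_frames``
    frame times count, matching the definition the measurement applies;
    recruitment time and landing size come from each cluster's first such
    event. Sizes use the cluster's true photometric brightness in GFP
    equivalents divided by 4.5 — the intensity-defined quantity the
    copy-number pipeline estimates.
    """
    cf = truth.cluster_frames
    ev = truth.recruitment_events
    rows = []
    for e in ev.itertuples():
        sel = cf[(cf["cluster_id"] == e.cluster_id)
                 & (cf["t_s"] >= e.onset_time_s)
                 & (cf["t_s"] < e.end_time_s)]
        if len(sel) < min_span_frames:
            continue
        rows.append((e.cluster_id, e.onset_time_s,
                     float(sel["gfp_equiv"].iloc[0]) / COMPLEX_GFP))
    first = {}
    for cid, onset, landing in rows:
        if cid not in first or onset < first[cid][0]:
            first[cid] = (onset, landing)
    nuc = truth.clusters.set_index("cluster_id")["nucleation_time_s"]
    rec_times = [onset - nuc[cid] for cid, (onset, _) in first.items()]
    landings = [landing for (_, landing) in first.values()]

    max_fluor = cf.groupby("cluster_id")["gfp_equiv"].max()
    bins = (max_fluor / COMPLEX_GFP).map(bin_by_complex_count)
    positive = max_fluor.index.isin(first.keys())
    per_bin = (pd.DataFrame({"bin": bins.values, "positive": positive})
               .groupby("bin")["positive"].agg(["mean", "count"]))
    pct = {b: 100.0 * r["mean"] for b, r in per_bin.iterrows()}
    n_bin = {b: int(r["count"]) for b, r in per_bin.iterrows()}
    return {
        "mean_recruitment_time_s": float(np.mean(rec_times)) if rec_times else np.nan,
        "mean_landing_size": float(np.mean(landings)) if landings else np.nan,
        "pct_positive": pct,
        "n_per_bin": n_bin,
        "n_positive": len(first),
        "n_clusters": len(max_fluor),
    }


def pipeline_kinetics(channels: dict, model: CalibrationModel,
                      params: TrackingParams | None = None) -> dict:
    """The same statistics measured from the rendered movie."""
    records, events, _ = analyze_two_channel(channels["gfp"],
                                             channels["partner"], model,
                                             params=params)
    by_id: dict[int, list] = {}
    for e in events:
        by_id.setdefault(e.myd88_track_id, []).append(e)
    recmap = {r.track.track_id: r for r in records}
    rec_times, landings = [], []
    for tid, evs in by_id.items():
        first = min(evs, key=lambda x: x.onset_frame)
        rec_times.append(recruitment_time(first, recmap[tid]))
        landings.append(landing_size(first, recmap[tid]))
    table = fraction_positive_by_bin(records, events)
    pct = dict(zip(table["bin"], table["pct_positive"]))
    n_bin = dict(zip(table["bin"], table["n"]))
    return {
        "mean_recruitment_time_s": float(np.mean(rec_times)) if rec_times else np.nan,
        "mean_landing_size": float(np.mean(landings)) if landings else np.nan,
        "pct_positive": pct,
        "n_per_bin": n_bin,
        "n_positive": len(by_id),
        "n_tracks": len(records),
        "records": records,
        "events": events,
    }


def kinetics_experiment(seed: int, n_frames: int = 150,
                        field_px: int = 640) -> dict:
    """Two-channel recruitment experiment with known kinetics.

    A 10-minute movie of a sparse field (cluster encounters are rare, so
    trajectory identity is unambiguous) under bright, well-exposed
    acquisition: the experiment isolates recovery of the recruitment
    kinetics — delay, hazard-size coefficient, partner lifetime — from
    photometric stress, which the copy-number experiment applies
    separately at its stated signal-to-noise level. Nucleation seeds
    clusters of 1–8 pre-formed complexes, weighted toward single
    complexes, so every size bin carries enough tracks for per-bin
    percentages. Returns ground-truth and pipeline statistics side by
    side.
    """
    cfg = SimConfig(
        field_size_px=(field_px, field_px), n_frames=n_frames,
        nucleation_rate=1.3e-4, diffusion_coeff=0.002,
        merge_radius_um=0.45, fluor_intensity_mean=1000.0,
        initial_complexes_choices=tuple(range(1, 9)),
        initial_complexes_probs=(0.42, 0.17, 0.12, 0.09, 0.07, 0.05, 0.04, 0.04),
        seed=seed,
    )
    truth = simulate_dynamics(cfg)
    channels = render_movie(truth)
    model = default_calibration(seed + 900_001, fluor_intensity_mean=1000.0)
    gt = ground_truth_kinetics(truth)
    params = TrackingParams(max_disp_px=5.0, max_gap=2, min_track_len=2,
                            aperture_correction=True)
    pipe = pipeline_kinetics(channels, model, params)
    return {"config": cfg, "truth": truth, "gt": gt, "pipe": pipe,
            "model": model}


def copy_number_experiment(seed: int, n_per_level: int = 200,
                           levels: tuple[int, ...] = (1, 2, 6, 12, 18, 30),
                           ) -> dict:
    """Copy-number recovery across true counts, scored per punctum.

    Static fields of puncta at each true copy number are rendered with the
    full camera model, measured through the standard pipeline (background
    subtraction, detection, 3×3 intensity, calibration), and each matched
    detection's maximum copy number is compared with the truth.
    """
    model = default_calibration(seed + 900_002, n_molecules=600,
                                field_px=320)
    from scipy.spatial import cKDTree

    rel_errors = []
    level_medians = {}
    n_single_total = 0
    n_single_as_cluster = 0
    rng = np.random.default_rng(seed)
    for level in levels:
        placed = 0
        sub = []
        while placed < n_per_level:
            batch = min(n_per_level - placed, 120)
            cfg = SimConfig(field_size_px=(320, 320), nucleation_rate=0.0,
                            seed=int(rng.integers(2 ** 31)))
            chans, tt = simulate_fixed_cell(cfg, batch,
                                            copy_numbers=np.full(batch, level))
            bg = subtract_background(chans["gfp"])
            tracks = track_stack(bg, TrackingParams(max_gap=0,
                                                    aperture_correction=True))
            if not tracks:
                placed += batch
                continue
            recs = build_puncta_records(tracks, model)
            xy = np.array([[t.x[0], t.y[0]] for t in tracks])
            d, idx = cKDTree(xy).query(tt[["x_px", "y_px"]].to_numpy())
            for row, j, dist in zip(tt.itertuples(), idx, d):
                if dist > 1.5:
                    continue
                est = recs[j].max_copy_number
                err = abs(est - row.copy_number) / row.copy_number
                sub.append(err)
                rel_errors.append(err)
                if level == 6:
                    n_single_total += 1
                    if recs[j].punc_class == "cluster":
                        n_single_as_cluster += 1
            placed += batch
        level_medians[level] = float(np.median(sub)) if sub else np.nan
    return {
        "median_rel_error": float(np.median(rel_errors)),
        "level_medians": level_medians,
        "n_scored": len(rel_errors),
        "pct_single_misclassified_as_cluster":
            100.0 * n_single_as_cluster / n_single_total if n_single_total else np.nan,
        "model": model,
    }


def _max_sizes_from_movie(truth: GroundTruth, model: CalibrationModel,
                          params: TrackingParams) -> np.ndarray:
    """Measured per-track maximum puncta size (complex count)."""
    channels = render_movie(truth)
    bg = subtract_background(channels["gfp"])
    tracks = track_stack(bg, params)
    recs = build_puncta_records(tracks, model)
    return np.array([r.max_complex_count_smoothed for r in recs])


def corral_experiment(seed: int, n_frames: int = 200,
                      field_px: int = 256, n_tracks: int = 200) -> dict:
    """Corral confinement vs free diffusion.

    Same nucleation and mobility in both arms; the gridded arm confines
    every cluster to the 1 μm corral it nucleated in. Reports ground-truth
    boundary crossings (must be zero) and a one-sided Mann–Whitney U test
    that the measured on-grid max puncta sizes are stochastically smaller
    than off grid.
    """
    common = dict(field_size_px=(field_px, field_px), n_frames=n_frames,
                  nucleation_rate=2.2e-4, diffusion_coeff=0.012,
                  merge_radius_um=0.45)
    model = default_calibration(seed + 900_003)
    params = TrackingParams(max_disp_px=8.0, max_gap=2, min_track_len=2,
                            aperture_correction=True)

    cfg_off = SimConfig(**common, seed=seed + 1)
    cfg_on = SimConfig(**common, grid_pitch_um=1.0, seed=seed + 2)
    truth_off = simulate_dynamics(cfg_off)
    truth_on = simulate_dynamics(cfg_on)
    sizes_off = _max_sizes_from_movie(truth_off, model, params)[:n_tracks * 4]
    sizes_on = _max_sizes_from_movie(truth_on, model, params)[:n_tracks * 4]
    stat, p = mannwhitneyu(sizes_on, sizes_off, alternative="less")
    return {
        "boundary_crossings": truth_on.boundary_crossings(),
        "n_on": len(sizes_on),
        "n_off": len(sizes_off),
        "median_size_on": float(np.median(sizes_on)),
        "median_size_off": float(np.median(sizes_off)),
        "mannwhitney_p": float(p),
    }


def rela_experiment(seed: int, n_cells: int = 200,
                    enrichment: float = 1.8) -> dict:
    """Nuclear-translocation recovery on a noiseless synthetic field.

    Cells with a known nuclear enrichment factor are segmented from the
    DAPI/phalloidin channels; the mean nucleus-to-cytoplasm ratio should
    recover the enrichment. The transcription-factor image is camera-offset
    corrected before the ratio (the ratio of means is otherwise shifted by
    the additive dark level).
    """
    from .fixedcell import rela_ratio
    from .preprocess import segment_nucleus_and_cell

    cfg = SimConfig(field_size_px=(1600, 1600), nucleation_rate=0.0, seed=seed)
    channels, truth = simulate_rela_field(cfg, n_cells, enrichment,
                                          cell_diameter_px=70.0,
                                          nucleus_diameter_px=40.0)
    offset = cfg.dark_offset + cfg.bg_level
    nuc, _cell, cyt = segment_nucleus_and_cell(channels["dapi"].pixels[0],
                                               channels["phalloidin"].pixels[0])
    cells = rela_ratio(nuc, cyt, channels["rela"].pixels[0] - offset)
    ratios = np.array([c.ratio for c in cells])
    return {
        "n_cells": len(cells),
        "mean_ratio": float(ratios.mean()) if len(cells) else np.nan,
        "true_ratio": float(enrichment),
        "rel_error": float(abs(ratios.mean() / enrichment - 1.0))
        if len(cells) else np.nan,
    }


def random_track_set(rng: np.random.Generator, n_tracks: int,
                     n_frames: int = 40, channel: str = "x"):
    """Random-walk tracks with random spans, for oracle comparisons."""
    from .core import Track

    tracks = []
    for tid in range(n_tracks):
        start = int(rng.integers(0, n_frames - 2))
        length = int(rng.integers(2, n_frames - start + 1))
        x0, y0 = rng.uniform(5, 60, 2)
        steps = rng.normal(0, 0.8, (length, 2))
        pos = np.cumsum(steps, axis=0) + (x0, y0)
        tracks.append(Track(
            track_id=tid, channel=channel,
            frames=np.arange(start, start + length),
            x=pos[:, 0], y=pos[:, 1], quality=np.ones(length),
        ))
    return tracks


def brute_force_positive_tracks(myd88_tracks, partner_tracks,
                                max_distance_um: float = 0.25,
                                min_consecutive: int = 2,
                                ) -> dict[tuple[int, int], int]:
    """All-pairs/all-frames reference for colocalization.

    Plain nested loops over every frame of every track pair; returns
    {(myd88_id, partner_id): onset_frame} for every pair with a run of at
    least ``min_consecutive`` consecutive close frames.
    """
    out = {}
    for m in myd88_tracks:
        for p in partner_tracks:
            run = 0
            onset = None
            found = None
            for f in range(int(min(m.frames[0], p.frames[0])),
                           int(max(m.frames[-1], p.frames[-1])) + 1):
                im = np.where(m.frames == f)[0]
                ip = np.where(p.frames == f)[0]
                close = False
                if len(im) and len(ip):
                    dx = (m.x[im[0]] - p.x[ip[0]]) * m.pixel_size_um
                    dy = (m.y[im[0]] - p.y[ip[0]]) * m.pixel_size_um
                    close = dx * dx + dy * dy <= max_distance_um ** 2
                if close:
                    if run == 0:
                        onset = f
                    run += 1
                    if run >= min_consecutive and found is None:
                        found = onset
                else:
                    run = 0
            if found is not None:
                out[(m.track_id, p.track_id)] = found
    return out
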