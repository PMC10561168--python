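"""End-to-end composition of the quantification stages.

These helpers wire the module-level operations into the workflows the study
performs: background subtraction → detection → linking → 3×3 intensity →
copy-number calibration → colocalization kinetics. They are what the CLI and
the validation experiments call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .calibrate import (CalibrationModel, ClassificationRule, PunctaRecord,
                        build_puncta_records, fit_single_fluorophore)
from .core import FrameStack, Track
from .detect_track import detect_spots_stack, link_tracks, measure_intensity
from .kinetics import ColocalizationRule, RecruitmentEvent, find_colocalizations
from .preprocess import subtract_background

__all__ = ["TrackingParams", "auto_threshold", "track_stack",
           "calibration_intensities", "calibrate_from_field",
           "analyze_two_channel"]


@dataclass
class TrackingParams:
    """Detection/linking knobs; sigma defaults to the optical PSF scale."""

    sigma_px: float = 0.8
    threshold: float | None = None  # None → auto (10× robust response noise)
    threshold_nsigma: float = 10.0
    max_disp_px: float = 5.0
    max_gap: int = 1
    min_track_len: int = 1
    # divide each 3×3 sum by the PSF mass the window captures at the
    # measured subpixel offset (see measure_intensity); use the same
    # setting for calibration fields and cellular movies
    aperture_correction: bool = False


def auto_threshold(frame: np.ndarray, sigma_px: float,
                   nsigma: float = 10.0) -> float:
    """Detection threshold as a multiple of the robust LoG response noise.

    MAD-based, so bright spots do not inflate the estimate.
    """
    response = -(sigma_px ** 2) * ndi.gaussian_laplace(
        np.asarray(frame, dtype=float), sigma_px)
    mad = np.median(np.abs(response - np.median(response)))
    return float(nsigma * 1.4826 * mad)


def track_stack(stack: FrameStack, params: TrackingParams | None = None
                ) -> list[Track]:
    """Detect, link and measure a background-subtracted stack."""
    params = params or TrackingParams()
    thr = params.threshold
    if thr is None:
        thr = auto_threshold(stack.pixels[0], params.sigma_px,
                             params.threshold_nsigma)
    spots = detect_spots_stack(stack, params.sigma_px, thr)
    tracks = link_tracks(spots, params.max_disp_px, params.max_gap,
                         channel=stack.channel,
                         pixel_size_um=stack.pixel_size_um,
                         frame_interval_s=stack.frame_interval_s)
    tracks = [t for t in tracks if len(t) >= params.min_track_len]
    ap = params.sigma_px if params.aperture_correction else None
    return [measure_intensity(stack, t, aperture_sigma_px=ap) for t in tracks]


def calibration_intensities(stack: FrameStack, dark_frame=None,
                            params: TrackingParams | None = None,
                            median_radius_px: int = 25) -> np.ndarray:
    """Per-molecule mean 3×3 intensities from a single-fluorophore field.

    The calibration stack is processed identically to cellular data
    (background subtraction, detection, tracking, 3×3 measurement); each
    immobile molecule's intensity is the mean of its track's series. Gap
    closing is off: an immobile molecule that blinks out is two tracks, not
    an interpolated one.
    """
    params = params or TrackingParams(max_gap=0)
    bg = subtract_background(stack, dark_frame, median_radius_px)
    tracks = track_stack(bg, params)
    return np.array([float(np.mean(t.intensity)) for t in tracks
                     if t.intensity is not None and len(t) > 0])


def calibrate_from_field(stack: FrameStack, dark_frame=None,
                         params: TrackingParams | None = None,
                         channel: str = "") -> CalibrationModel:
    """Fit the single-fluorophore model straight from a calibration stack."""
    vals = calibration_intensities(stack, dark_frame, params)
    return fit_single_fluorophore(vals, channel=channel or stack.channel)


def analyze_two_channel(gfp_stack: FrameStack, partner_stack: FrameStack,
                        model: CalibrationModel,
                        dark_frame=None,
                        params: TrackingParams | None = None,
                        coloc_rule: ColocalizationRule | None = None,
                        rule: ClassificationRule | None = None,
                        median_radius_px: int = 25,
                        ) -> tuple[list[PunctaRecord], list[RecruitmentEvent],
                                   list[Track]]:
    """Full two-channel kinetics workflow on raw stacks.

    Returns the calibrated scaffold puncta records, the colocalization
    events, and the partner-channel tracks.
    """
    params = params or TrackingParams()
    gfp_bg = subtract_background(gfp_stack, dark_frame, median_radius_px)
    partner_bg = subtract_background(partner_stack, dark_frame, median_radius_px)
    gfp_tracks = track_stack(gfp_bg, params)
    partner_tracks = track_stack(partner_bg, params)
    records = build_puncta_records(gfp_tracks, model, rule)
    events = find_colocalizations(gfp_tracks, partner_tracks,
                                  coloc_rule or ColocalizationRule(),
                                  n_movie_frames=gfp_stack.n_frames)
    return records, events, partner_tracks
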