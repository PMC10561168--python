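"""Shared containers for calibrated image stacks, detected spots and tracks.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(x, y)`` floats, ``x`` along axis 1 (columns),
  ``y`` along axis 0 (rows);
* physical positions are micrometres, ``x_um = x_px * pixel_size_um``;
* times are seconds, ``t_s = frame * frame_interval_s``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile

#: default physical pixel size of the acquisition system (μm)
DEFAULT_PIXEL_SIZE_UM = 0.15
#: default frame interval of time-lapse acquisition (s)
DEFAULT_FRAME_INTERVAL_S = 4.0


@dataclass
class FrameStack:
    """A single-channel, multi-frame image stack with physical calibration.

    Parameters
    ----------
    pixels : ndarray, shape (T, H, W)
        Intensity data; any numeric dtype, finite values.
    pixel_size_um : float
        Physical size of one pixel (μm).
    frame_interval_s : float
        Time between consecutive frames (s).
    channel : str
        Channel label, e.g. ``"MyD88-GFP"`` or ``"mScarlet-TRAF6"``.
    """

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    channel: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None]
        if self.pixels.ndim != 3:
            raise ValueError(f"pixels must be T×H×W, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1:
            raise ValueError("stack needs at least one frame")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel values must be finite")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def max_projection(self) -> np.ndarray:
        return self.pixels.max(axis=0)

    def save(self, path) -> None:
        """Write as a multi-page TIFF, frame-major, with calibration metadata."""
        tifffile.imwrite(
            path,
            np.asarray(self.pixels),
            metadata={
                "pixel_size_um": self.pixel_size_um,
                "frame_interval_s": self.frame_interval_s,
                "channel": self.channel,
            },
        )

    @classmethod
    def load(cls, path, pixel_size_um: float | None = None,
             frame_interval_s: float | None = None,
             channel: str | None = None) -> "FrameStack":
        with tifffile.TiffFile(path) as tf:
            pixels = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        return cls(
            pixels=pixels,
            pixel_size_um=pixel_size_um if pixel_size_um is not None
            else float(meta.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM)),
            frame_interval_s=frame_interval_s if frame_interval_s is not None
            else float(meta.get("frame_interval_s", DEFAULT_FRAME_INTERVAL_S)),
            channel=channel if channel is not None else str(meta.get("channel", "")),
        )


@dataclass
class Spot:
    """A detected diffraction-limited spot in one frame."""

    frame: int
    x: float  # subpixel centroid, px (axis 1)
    y: float  # subpixel centroid, px (axis 0)
    quality: float  # detector response at the maximum
    channel: str = ""


@dataclass
class Track:
    """A linked trajectory of spots in one channel.

    ``frames`` is strictly increasing; closed gaps appear as interpolated
    entries flagged in ``flags`` (bit 1 = interpolated gap, bit 2 = clipped
    border window).
    """

    track_id: int
    channel: str
    frames: np.ndarray  # int, strictly increasing, gaps filled after closing
    x: np.ndarray  # px
    y: np.ndarray  # px
    quality: np.ndarray
    intensity: np.ndarray | None = None  # background-corrected 3×3 sums
    flags: np.ndarray | None = None
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.quality = np.asarray(self.quality, dtype=float)
        if not np.all(np.diff(self.frames) > 0):
            raise ValueError("track frames must be strictly increasing")
        if self.flags is None:
            self.flags = np.zeros(len(self.frames), dtype=int)

    FLAG_GAP = 1
    FLAG_BORDER = 2

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])

    @property
    def end_frame(self) -> int:
        return int(self.frames[-1])

    @property
    def lifetime_s(self) -> float:
        """(end − start) × frame interval, the trajectory duration."""
        return (self.end_frame - self.start_frame) * self.frame_interval_s

    @property
    def nucleation_time_s(self) -> float:
        """Time of first detection; time origin of recruitment measurements."""
        return self.start_frame * self.frame_interval_s

    def positions_um(self) -> np.ndarray:
        return np.column_stack([self.x, self.y]) * self.pixel_size_um


def tracks_to_table(tracks: list[Track]) -> pd.DataFrame:
    """Flatten tracks to the delimited-text export schema."""
    rows = []
    for tr in tracks:
        for i in range(len(tr)):
            rows.append(
                (tr.track_id, tr.channel, int(tr.frames[i]),
                 tr.frames[i] * tr.frame_interval_s,
                 tr.x[i], tr.y[i],
                 tr.x[i] * tr.pixel_size_um, tr.y[i] * tr.pixel_size_um,
                 float(tr.intensity[i]) if tr.intensity is not None else np.nan,
                 int(tr.flags[i]))
            )
    return pd.DataFrame(
        rows,
        columns=["track_id", "channel", "frame", "t_s", "x_px", "y_px",
                 "x_um", "y_um", "intensity", "flags"],
    )


def tracks_from_table(table: pd.DataFrame, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                      frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S) -> list[Track]:
    """Inverse of :func:`tracks_to_table`."""
    tracks = []
    for tid, grp in table.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(Track(
            track_id=int(tid),
            channel=str(grp["channel"].iloc[0]),
            frames=grp["frame"].to_numpy(),
            x=grp["x_px"].to_numpy(),
            y=grp["y_px"].to_numpy(),
            quality=np.zeros(len(grp)),
            intensity=grp["intensity"].to_numpy(),
            flags=grp["flags"].to_numpy().astype(int),
            pixel_size_um=pixel_size_um,
            frame_interval_s=frame_interval_s,
        ))
    return tracks


def write_table(df: pd.DataFrame, path) -> None:
    """Deterministic delimited-text writer used by every CLI export.

    %.10g round-trips the doubles produced here while keeping byte output
    independent of dtype promotion details.
    """
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
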