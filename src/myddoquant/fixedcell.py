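"""Fixed-cell immunofluorescence quantification.

Puncta are segmented from the scaffold channel by Otsu threshold with a
3–30 px equivalent-diameter filter, intensities are normalized against the
pooled reference condition (the off-grid data) by

    Norm = (I − q_lo(ref)) / (q_hi(ref) − q_lo(ref)),

with quantiles (0.01, 0.99) for puncta intensities and (0.05, 0.95) for the
nucleus-to-cytoplasm translocation ratio. Puncta with normalized scaffold
intensity ≥ 0.5 are classified as clusters; dividing by 0.5 estimates the
number of complexes per punctum, and dividing the normalized stain intensity
by that count gives the per-complex staining intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress, pearsonr
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops

__all__ = [
    "NormalizationParams",
    "CellStainSummary",
    "segment_fixed_puncta",
    "quantile_normalize",
    "classify_and_per_complex",
    "correlate_stain",
    "rela_ratio",
    "CLUSTER_NORM_THRESHOLD",
]

#: normalized scaffold intensity at/above which a punctum is a cluster;
#: also the normalized intensity of one complex when estimating counts
CLUSTER_NORM_THRESHOLD = 0.5


@dataclass
class NormalizationParams:
    """Reference-condition quantile anchors for intensity normalization."""

    q_lo: float
    q_hi: float
    lo_value: float
    hi_value: float
    reference: str = "off grid"

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_lo < self.q_hi <= 1.0):
            raise ValueError("need 0 ≤ q_lo < q_hi ≤ 1")
        if self.hi_value == self.lo_value:
            raise ValueError("degenerate reference distribution: q_hi == q_lo")

    @classmethod
    def fit(cls, reference_values, q_lo: float = 0.01, q_hi: float = 0.99,
            reference: str = "off grid") -> "NormalizationParams":
        """Fit the anchors from the pooled reference-condition values."""
        v = np.asarray(list(reference_values), dtype=float)
        if v.size == 0:
            raise ValueError("empty reference sample")
        return cls(q_lo=q_lo, q_hi=q_hi,
                   lo_value=float(np.quantile(v, q_lo)),
                   hi_value=float(np.quantile(v, q_hi)),
                   reference=reference)


def quantile_normalize(values, params: NormalizationParams) -> np.ndarray:
    """(v − lo) / (hi − lo) with reference-condition anchors.

    Applied unchanged to every condition; values outside [0, 1] are allowed
    (conditions brighter than the reference 99th percentile exceed 1).
    """
    v = np.asarray(values, dtype=float)
    return (v - params.lo_value) / (params.hi_value - params.lo_value)


def segment_fixed_puncta(gfp_image: np.ndarray,
                         diameter_px: tuple[float, float] = (3.0, 30.0),
                         channels: dict[str, np.ndarray] | None = None
                         ) -> pd.DataFrame:
    """Segment scaffold puncta and measure them in every registered channel.

    Otsu threshold on the (background-subtracted) scaffold image, connected
    components filtered to equivalent-circle diameter within ``diameter_px``.
    Returns one row per retained punctum with centroid, area, equivalent
    diameter, and integrated/mean intensity of the scaffold plus every extra
    channel (columns ``integrated_<name>``, ``mean_<name>``).
    """
    img = np.asarray(gfp_image, dtype=float)
    extra = {k: np.asarray(v, dtype=float) for k, v in (channels or {}).items()}
    for k, v in extra.items():
        if v.shape != img.shape:
            raise ValueError(f"channel {k!r} shape {v.shape} != {img.shape}")
    cols = ["puncta_id", "x_px", "y_px", "area_px", "equivalent_diameter_px",
            "integrated_gfp", "mean_gfp"]
    for k in extra:
        cols += [f"integrated_{k}", f"mean_{k}"]
    if not np.any(img > 0) or img.max() == img.min():
        return pd.DataFrame(columns=cols)
    # threshold on the log scale: puncta intensities span decades, and a
    # linear-scale Otsu cuts each spot at a brightness-dependent height,
    # shrinking dim puncta below the diameter filter
    log_img = np.log1p(np.clip(img - img.min(), 0, None))
    labels = sk_label(log_img > threshold_otsu(log_img), connectivity=2)
    lo, hi = diameter_px
    rows = []
    pid = 0
    for prop in regionprops(labels, intensity_image=img):
        if not (lo <= prop.equivalent_diameter_area <= hi):
            continue
        mask = labels == prop.label
        cy, cx = prop.centroid
        row = [pid, cx, cy, int(prop.area), float(prop.equivalent_diameter_area),
               float(img[mask].sum()), float(img[mask].mean())]
        for k, v in extra.items():
            row += [float(v[mask].sum()), float(v[mask].mean())]
        rows.append(row)
        pid += 1
    return pd.DataFrame(rows, columns=cols)


def classify_and_per_complex(puncta: pd.DataFrame,
                             myd88_col: str = "norm_gfp",
                             stain_col: str | None = "norm_stain"
                             ) -> pd.DataFrame:
    """Annotate normalized puncta with complex counts and per-complex stain.

    ``n_complexes`` = normalized scaffold intensity / 0.5; class is
    "cluster" at ≥ 0.5 normalized intensity and "single" below; the
    per-complex stain intensity is the normalized stain divided by
    ``n_complexes`` (undefined and flagged when the count is ≤ 0).
    """
    out = puncta.copy()
    norm = out[myd88_col].to_numpy(dtype=float)
    n_complexes = norm / CLUSTER_NORM_THRESHOLD
    out["n_complexes"] = n_complexes
    out["class"] = np.where(norm >= CLUSTER_NORM_THRESHOLD, "cluster", "single")
    out["flagged"] = n_complexes <= 0
    if stain_col is not None and stain_col in out:
        stain = out[stain_col].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            per = np.where(n_complexes > 0, stain / n_complexes, np.nan)
        out["per_complex_stain"] = per
    return out


def correlate_stain(puncta: pd.DataFrame, x_col: str = "integrated_gfp",
                    y_col: str = "integrated_stain", bins: int = 50
                    ) -> dict:
    """OLS fit and Pearson correlation of stain intensity on scaffold
    intensity, plus the 2D histogram used for display.

    Returns dict with slope, intercept, pearson_r, p_value, and the
    histogram (counts, x_edges, y_edges).
    """
    if len(puncta) < 3:
        raise ValueError("need at least 3 puncta for a correlation")
    x = puncta[x_col].to_numpy(dtype=float)
    y = puncta[y_col].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the scaffold intensity")
    fit = linregress(x, y)
    if np.ptp(y) == 0:
        r, p = (1.0 if fit.slope >= 0 else -1.0), 0.0  # exact collinearity
    else:
        r, p = pearsonr(x, y)
    counts, xe, ye = np.histogram2d(x, y, bins=bins)
    return {"slope": float(fit.slope), "intercept": float(fit.intercept),
            "pearson_r": float(r), "p_value": float(p),
            "hist2d": (counts, xe, ye), "n": len(x)}


@dataclass
class CellStainSummary:
    """Per-cell nuclear translocation readout."""

    cell_id: int
    nucleus_mean: float
    cytoplasm_mean: float

    @property
    def ratio(self) -> float:
        return self.nucleus_mean / self.cytoplasm_mean


def rela_ratio(nucleus_mask: np.ndarray, cytoplasm_mask: np.ndarray,
               rela_image: np.ndarray) -> list[CellStainSummary]:
    """Per-cell nucleus-to-cytoplasm mean-intensity ratio.

    Cells whose cytoplasm is empty or has non-positive mean intensity are
    dropped (the ratio is undefined there). Normalize the returned ratios
    against the unstimulated/off-grid reference with quantiles (0.05, 0.95)
    via :func:`quantile_normalize`.
    """
    rela = np.asarray(rela_image, dtype=float)
    out = []
    for cid in np.unique(nucleus_mask[nucleus_mask > 0]):
        nuc = nucleus_mask == cid
        cyt = cytoplasm_mask == cid
        if not cyt.any():
            continue
        cyt_mean = float(rela[cyt].mean())
        if cyt_mean <= 0:
            continue
        out.append(CellStainSummary(cell_id=int(cid),
                                    nucleus_mean=float(rela[nuc].mean()),
                                    cytoplasm_mean=cyt_mean))
    return out
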