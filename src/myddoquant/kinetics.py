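"""Two-channel colocalization and recruitment statistics.

A scaffold (MyD88) track is *positive* for a partner (TRAF6/HOIL1) when some
partner track stays within 0.25 μm of it for at least two consecutive
frames. For each such event the pipeline reports:

* recruitment time — from scaffold nucleation (time 0 = first frame the
  scaffold punctum appears) to partner onset;
* landing size — the scaffold's complex count (copy number / 4.5) at exactly
  the onset frame;
* partner lifetime — duration of the partner track, flagged when censored by
  the end of the movie.

Summaries follow the study structure: percentage of positive scaffold tracks
per cluster-size bin, and lifetime splits at the 50 s threshold separating
short-lived from long-lived puncta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrate import PunctaRecord, bin_by_complex_count, bin_sort_key
from .core import Track

__all__ = [
    "ColocalizationRule",
    "RecruitmentEvent",
    "find_colocalizations",
    "recruitment_time",
    "landing_size",
    "fraction_positive_by_bin",
    "lifetime_stats",
    "events_to_table",
]


@dataclass
class ColocalizationRule:
    """Two puncta are colocalized when their centroids are ≤ 0.25 μm apart
    for at least two consecutive frames."""

    max_distance_um: float = 0.25
    min_consecutive_frames: int = 2

    def __post_init__(self) -> None:
        if self.max_distance_um <= 0 or self.min_consecutive_frames <= 0:
            raise ValueError("colocalization rule parameters must be positive")


@dataclass
class RecruitmentEvent:
    """One scaffold/partner colocalization span."""

    myd88_track_id: int
    partner_track_id: int
    onset_frame: int
    span_frames: int  # length of the first qualifying run
    partner_start_frame: int
    partner_end_frame: int
    frame_interval_s: float
    censored: bool = False  # partner track runs to the end of the movie
    flagged: bool = False  # onset fell in an interpolated gap / zero signal

    @property
    def onset_time_s(self) -> float:
        return self.onset_frame * self.frame_interval_s

    @property
    def partner_lifetime_s(self) -> float:
        return (self.partner_end_frame - self.partner_start_frame) \
            * self.frame_interval_s


def _coloc_runs(myd88: Track, partner: Track, max_dist_um: float
                ) -> list[tuple[int, int]]:
    """Maximal runs of consecutive frames with centroid distance ≤ cutoff.

    Returns (start_frame, length) for each run over the common frame range.
    """
    common, ia, ib = np.intersect1d(myd88.frames, partner.frames,
                                    return_indices=True)
    if len(common) == 0:
        return []
    dx = (myd88.x[ia] - partner.x[ib]) * myd88.pixel_size_um
    dy = (myd88.y[ia] - partner.y[ib]) * myd88.pixel_size_um
    close = (dx * dx + dy * dy) <= max_dist_um ** 2
    runs = []
    i = 0
    while i < len(common):
        if close[i]:
            j = i
            # consecutive in *frame number*, not just in index
            while (j + 1 < len(common) and close[j + 1]
                   and common[j + 1] == common[j] + 1):
                j += 1
            runs.append((int(common[i]), j - i + 1))
            i = j + 1
        else:
            i += 1
    return runs


def find_colocalizations(myd88_tracks: list[Track], partner_tracks: list[Track],
                         rule: ColocalizationRule | None = None,
                         n_movie_frames: int | None = None
                         ) -> list[RecruitmentEvent]:
    """All qualifying scaffold/partner colocalization events.

    Every (scaffold, partner) pair with a run of ≥ ``min_consecutive_frames``
    close frames yields one event whose onset is the first frame of the first
    qualifying run; positivity downstream is counted once per scaffold track.
    """
    rule = rule or ColocalizationRule()
    events: list[RecruitmentEvent] = []
    for m in myd88_tracks:
        for p in partner_tracks:
            if not np.isclose(m.frame_interval_s, p.frame_interval_s):
                raise ValueError(
                    f"tracks disagree on frame interval: {m.frame_interval_s} "
                    f"vs {p.frame_interval_s}")
            runs = [r for r in _coloc_runs(m, p, rule.max_distance_um)
                    if r[1] >= rule.min_consecutive_frames]
            if not runs:
                continue
            onset, span = runs[0]
            censored = (n_movie_frames is not None
                        and p.end_frame >= n_movie_frames - 1)
            events.append(RecruitmentEvent(
                myd88_track_id=m.track_id, partner_track_id=p.track_id,
                onset_frame=onset, span_frames=span,
                partner_start_frame=p.start_frame,
                partner_end_frame=p.end_frame,
                frame_interval_s=m.frame_interval_s,
                censored=censored))
    return events


def recruitment_time(event: RecruitmentEvent, myd88_record: PunctaRecord
                     ) -> float:
    """Seconds from scaffold nucleation to partner onset."""
    nuc = myd88_record.track.start_frame
    if event.onset_frame < nuc:
        raise ValueError(
            f"onset frame {event.onset_frame} precedes nucleation frame {nuc}")
    return (event.onset_frame - nuc) * myd88_record.track.frame_interval_s


def landing_size(event: RecruitmentEvent, myd88_record: PunctaRecord
                 ) -> float:
    """Scaffold complex count at exactly the onset frame (real-valued).

    Onsets falling on an interpolated gap sample use the interpolated value
    and flag the event; a zero copy number at onset is likewise flagged.
    """
    tr = myd88_record.track
    idx = event.onset_frame - tr.start_frame
    if idx < 0 or idx >= len(tr.frames):
        raise ValueError("onset frame outside the scaffold record")
    value = float(myd88_record.complex_count_series[idx])
    if (tr.flags is not None and tr.flags[idx] & Track.FLAG_GAP) or value == 0.0:
        event.flagged = True
    return value


def fraction_positive_by_bin(records: list[PunctaRecord],
                             events: list[RecruitmentEvent],
                             cell_ids: dict[int, int] | None = None,
                             smoothed: bool = True) -> pd.DataFrame:
    """Percentage of partner-positive scaffold tracks per cluster-size bin.

    Each scaffold record is binned by its rounded maximum complex count
    ("single", then 2-4, 5-7, …); by default the median-smoothed maximum
    is used for bin assignment (``smoothed=False`` bins on the raw frame
    maximum). A record is positive when at least one event references it.
    With ``cell_ids`` (track_id → cell label) the table additionally carries
    the across-cell mean ± SEM of the per-cell percentages, matching the
    replicate structure of the study.
    """
    positive_ids = {ev.myd88_track_id for ev in events}
    rows = []
    for rec in records:
        tid = rec.track.track_id
        size = (rec.max_complex_count_smoothed if smoothed
                else rec.max_complex_count)
        rows.append((tid, bin_by_complex_count(size),
                     tid in positive_ids,
                     cell_ids.get(tid, 0) if cell_ids else 0))
    df = pd.DataFrame(rows, columns=["track_id", "bin", "positive", "cell"])
    out = []
    for b, grp in df.groupby("bin"):
        n = len(grp)
        pct = 100.0 * grp["positive"].sum() / n if n else np.nan
        per_cell = grp.groupby("cell")["positive"].mean() * 100.0
        sem = per_cell.sem() if len(per_cell) > 1 else np.nan
        out.append((b, n, pct, per_cell.mean() if len(per_cell) else np.nan, sem))
    table = pd.DataFrame(out, columns=["bin", "n", "pct_positive",
                                       "pct_positive_cell_mean",
                                       "pct_positive_cell_sem"])
    return table.sort_values("bin", key=lambda s: s.map(bin_sort_key),
                             ignore_index=True)


def lifetime_stats(records: list[PunctaRecord],
                   events: list[RecruitmentEvent],
                   threshold_s: float = 50.0,
                   n_movie_frames: int | None = None) -> pd.DataFrame:
    """Scaffold lifetimes split at the long-lived threshold (50 s default).

    Per split: track count, number censored by the movie end (flagged but
    included), % partner-positive, and the partner lifetimes of events whose
    scaffold falls in the split (mean and count).
    """
    positive_ids = {ev.myd88_track_id for ev in events}
    ev_by_id: dict[int, list[RecruitmentEvent]] = {}
    for ev in events:
        ev_by_id.setdefault(ev.myd88_track_id, []).append(ev)
    rows = []
    for name, keep in ((f"<{threshold_s:g}s", lambda lt: lt < threshold_s),
                       (f">={threshold_s:g}s", lambda lt: lt >= threshold_s)):
        sel = [r for r in records if keep(r.lifetime_s)]
        n = len(sel)
        censored = sum(
            1 for r in sel
            if n_movie_frames is not None
            and r.track.end_frame >= n_movie_frames - 1)
        pos = sum(1 for r in sel if r.track.track_id in positive_ids)
        partner_lt = [e.partner_lifetime_s for r in sel
                      for e in ev_by_id.get(r.track.track_id, [])]
        rows.append((name, n, censored,
                     100.0 * pos / n if n else np.nan,
                     float(np.mean(partner_lt)) if partner_lt else np.nan,
                     len(partner_lt)))
    return pd.DataFrame(rows, columns=[
        "lifetime_split", "n_tracks", "n_censored", "pct_positive",
        "partner_lifetime_mean_s", "n_partner_lifetimes"])


def events_to_table(events: list[RecruitmentEvent],
                    records: list[PunctaRecord] | None = None) -> pd.DataFrame:
    """Events export: one row per scaffold/partner colocalization."""
    by_id = {r.track.track_id: r for r in records} if records else {}
    rows = []
    for ev in events:
        rec = by_id.get(ev.myd88_track_id)
        rows.append((ev.myd88_track_id, ev.partner_track_id,
                     ev.onset_time_s,
                     recruitment_time(ev, rec) if rec else np.nan,
                     landing_size(ev, rec) if rec else np.nan,
                     ev.partner_lifetime_s, int(ev.censored),
                     int(ev.flagged), ev.span_frames))
    return pd.DataFrame(rows, columns=[
        "myd88_id", "partner_id", "onset_s", "recruitment_time_s",
        "landing_size", "partner_lifetime_s", "censored", "flagged",
        "span_frames"])
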