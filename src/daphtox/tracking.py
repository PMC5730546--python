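"""Frame-to-frame linking of detections into per-animal trajectories.

Per frame, live tracks are matched to detections by optimal one-to-one
assignment (Hungarian algorithm) minimizing summed squared distance, with
matches beyond a distance gate forbidden.  Short detection dropouts are
bridged by linear interpolation; tracks missing for longer are closed.
No motion model is used (constant-position prediction): hop-and-rest
locomotion — near-stationary rests punctuated by abrupt bursts — is
poorly served by constant-velocity extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .detection import DetectionRecord, ImagingConfig
from .simulator import AnimalGroundTruth

__all__ = [
    "TrackingConfig",
    "Track",
    "link",
    "evaluate_tracking",
    "TrackingReport",
    "tracks_to_dataframe",
    "dataframe_to_tracks",
    "truths_to_tracks",
]

_BIG_COST = 1e12


@dataclass(frozen=True)
class TrackingConfig:
    """Linker settings.

    ``gate_mm`` is the maximum plausible displacement per frame interval
    (default 3x the mean hop length); a track undetected for up to
    ``max_gap_frames`` is bridged, longer dropouts close it; tracks
    shorter than ``min_track_frames`` samples are not reported.
    """

    gate_mm: float = 4.5
    max_gap_frames: int = 3
    min_track_frames: int = 15

    def __post_init__(self) -> None:
        if not self.gate_mm > 0:
            raise ValueError("gate_mm must be > 0")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")
        if self.min_track_frames < 1:
            raise ValueError("min_track_frames must be >= 1")


@dataclass
class Track:
    """One reconstructed trajectory in chamber (mm) coordinates."""

    track_id: int
    frame: np.ndarray          # int, strictly increasing, contiguous
    t_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    interpolated: np.ndarray   # bool gap flags per sample

    @property
    def n_samples(self) -> int:
        return len(self.frame)

    @property
    def path_length_mm(self) -> float:
        return float(np.hypot(np.diff(self.x_mm), np.diff(self.y_mm)).sum())


@dataclass
class _LiveTrack:
    created: int
    frames: list = field(default_factory=list)
    xs: list = field(default_factory=list)
    ys: list = field(default_factory=list)
    interp: list = field(default_factory=list)
    missed: int = 0

    @property
    def last(self) -> tuple[float, float]:
        return self.xs[-1], self.ys[-1]


def _coerce_frames(detections, imaging: ImagingConfig) -> dict[int, list]:
    """Group detections by frame as (x_mm, y_mm) pairs sorted by (x, y)."""
    by_frame: dict[int, list] = {}
    if isinstance(detections, pd.DataFrame):
        if detections.empty:
            return by_frame
        for f, sub in detections.groupby("frame"):
            pts = sorted(
                zip(
                    sub["x_px"].to_numpy() * imaging.mm_per_px,
                    sub["y_px"].to_numpy() * imaging.mm_per_px,
                )
            )
            by_frame[int(f)] = pts
    else:
        for r in detections:
            if not isinstance(r, DetectionRecord):
                raise TypeError("expected DetectionRecord items or a DataFrame")
            by_frame.setdefault(r.frame_index, []).append(
                (r.x_px * imaging.mm_per_px, r.y_px * imaging.mm_per_px)
            )
        for pts in by_frame.values():
            pts.sort()
    return by_frame


def link(
    detections,
    config: TrackingConfig,
    imaging: ImagingConfig,
) -> list[Track]:
    """Link per-frame detections into tracks.

    ``detections`` is a DataFrame (columns ``frame, x_px, y_px``) or a
    list of :class:`DetectionRecord`.  Empty input yields an empty list.
    The result is deterministic and invariant to the detection order
    within a frame (detections are canonically sorted; ties resolved by
    lowest track id, then lowest detection x).
    """
    if imaging is None or not imaging.mm_per_px > 0:
        raise ValueError("pixel-to-mm calibration (ImagingConfig) is required")
    by_frame = _coerce_frames(detections, imaging)
    if not by_frame:
        return []

    f_min, f_max = min(by_frame), max(by_frame)
    live: list[_LiveTrack] = []
    done: list[_LiveTrack] = []
    n_created = 0

    for f in range(f_min, f_max + 1):
        dets = by_frame.get(f, [])
        live.sort(key=lambda tr: tr.created)
        matched_tracks: set[int] = set()
        matched_dets: set[int] = set()
        if live and dets:
            cost = np.full((len(live), len(dets)), _BIG_COST)
            for i, tr in enumerate(live):
                gate = config.gate_mm * (1 + tr.missed)
                lx, ly = tr.last
                for j, (dx, dy) in enumerate(dets):
                    d2 = (dx - lx) ** 2 + (dy - ly) ** 2
                    if d2 <= gate * gate:
                        cost[i, j] = d2
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if cost[i, j] >= _BIG_COST:
                    continue
                tr = live[i]
                x, y = dets[j]
                if tr.missed > 0:
                    # bridge the gap linearly
                    f0 = tr.frames[-1]
                    x0, y0 = tr.last
                    g = f - f0
                    for k in range(1, g):
                        w = k / g
                        tr.frames.append(f0 + k)
                        tr.xs.append(x0 + w * (x - x0))
                        tr.ys.append(y0 + w * (y - y0))
                        tr.interp.append(True)
                tr.frames.append(f)
                tr.xs.append(x)
                tr.ys.append(y)
                tr.interp.append(False)
                tr.missed = 0
                matched_tracks.add(i)
                matched_dets.add(j)
        still_live = []
        for i, tr in enumerate(live):
            if i in matched_tracks:
                still_live.append(tr)
            else:
                tr.missed += 1
                if tr.missed > config.max_gap_frames:
                    done.append(tr)
                else:
                    still_live.append(tr)
        live = still_live
        for j, (x, y) in enumerate(dets):
            if j not in matched_dets:
                tr = _LiveTrack(created=n_created)
                n_created += 1
                tr.frames.append(f)
                tr.xs.append(x)
                tr.ys.append(y)
                tr.interp.append(False)
                live.append(tr)
    done.extend(live)

    done = [tr for tr in done if len(tr.frames) >= config.min_track_frames]
    done.sort(key=lambda tr: (tr.frames[0], tr.created))
    tracks = []
    for tid, tr in enumerate(done):
        frames = np.asarray(tr.frames, dtype=int)
        tracks.append(
            Track(
                track_id=tid,
                frame=frames,
                t_s=frames / imaging.fps,
                x_mm=np.asarray(tr.xs),
                y_mm=np.asarray(tr.ys),
                interpolated=np.asarray(tr.interp, dtype=bool),
            )
        )
    return tracks


@dataclass
class TrackingReport:
    """Tracker quality vs ground truth (synthetic runs only)."""

    n_swaps: int
    matched_fraction: float
    distance_error_mm: float
    n_tracks: int
    n_truth: int


def evaluate_tracking(
    tracks: list[Track],
    truths: list[AnimalGroundTruth],
    body_length_mm: float | None = None,
) -> TrackingReport:
    """Score tracks against simulator ground truth.

    Identity swaps: per track, the number of transitions of the
    nearest-truth identity (matches within one body length).  Matched
    fraction: share of truth samples with a track sample within one body
    length at the same frame.  Distance error: absolute difference of
    summed path length, tracks vs truth.
    """
    if not truths:
        raise ValueError("ground truth required")
    if body_length_mm is None:
        body_length_mm = truths[0].body_length_mm
    n_frames = truths[0].n_frames
    t_ref = truths[0].t_s
    for tr in truths:
        if tr.n_frames != n_frames:
            raise ValueError("truths have mismatched time bases")
    for tk in tracks:
        if np.any(tk.frame >= n_frames) or np.any(tk.frame < 0):
            raise ValueError("track frames outside the truth time base")
        if not np.allclose(tk.t_s, t_ref[tk.frame], atol=1e-9):
            raise ValueError("track timestamps mismatch the truth time base")

    truth_x = np.stack([tr.x_mm for tr in truths])  # (A, F)
    truth_y = np.stack([tr.y_mm for tr in truths])

    n_swaps = 0
    covered = np.zeros((len(truths), n_frames), dtype=bool)
    for tk in tracks:
        dx = truth_x[:, tk.frame] - tk.x_mm[None, :]
        dy = truth_y[:, tk.frame] - tk.y_mm[None, :]
        dist = np.hypot(dx, dy)  # (A, n_samples)
        nearest = np.argmin(dist, axis=0)
        ok = dist[nearest, np.arange(len(tk.frame))] <= body_length_mm
        ids = np.where(ok, nearest, -1)
        covered[ids[ok], tk.frame[ok]] = True
        matched_ids = ids[ids >= 0]
        if matched_ids.size > 1:
            n_swaps += int(np.count_nonzero(np.diff(matched_ids) != 0))

    matched_fraction = float(covered.mean()) if covered.size else 0.0
    truth_dist = sum(tr.path_length_mm for tr in truths)
    track_dist = sum(tk.path_length_mm for tk in tracks)
    return TrackingReport(
        n_swaps=n_swaps,
        matched_fraction=matched_fraction,
        distance_error_mm=abs(track_dist - truth_dist),
        n_tracks=len(tracks),
        n_truth=len(truths),
    )


def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    """Trajectory exchange format: track_id, frame, t_s, x_mm, y_mm, interpolated."""
    parts = []
    for tk in tracks:
        parts.append(
            pd.DataFrame(
                {
                    "track_id": tk.track_id,
                    "frame": tk.frame,
                    "t_s": tk.t_s,
                    "x_mm": tk.x_mm,
                    "y_mm": tk.y_mm,
                    "interpolated": tk.interpolated,
                }
            )
        )
    if not parts:
        return pd.DataFrame(
            columns=["track_id", "frame", "t_s", "x_mm", "y_mm", "interpolated"]
        )
    return pd.concat(parts, ignore_index=True)


def dataframe_to_tracks(df: pd.DataFrame) -> list[Track]:
    tracks = []
    for tid, sub in df.groupby("track_id"):
        sub = sub.sort_values("frame")
        tracks.append(
            Track(
                track_id=int(tid),
                frame=sub["frame"].to_numpy(dtype=int),
                t_s=sub["t_s"].to_numpy(dtype=float),
                x_mm=sub["x_mm"].to_numpy(dtype=float),
                y_mm=sub["y_mm"].to_numpy(dtype=float),
                interpolated=sub["interpolated"].to_numpy(dtype=bool),
            )
        )
    return tracks


def truths_to_tracks(truths: list[AnimalGroundTruth]) -> list[Track]:
    """Truth-bypass lane: present ground-truth trajectories as tracks."""
    tracks = []
    for tr in truths:
        n = tr.n_frames
        tracks.append(
            Track(
                track_id=tr.animal_id,
                frame=np.arange(n),
                t_s=tr.t_s.copy(),
                x_mm=tr.x_mm.copy(),
                y_mm=tr.y_mm.copy(),
                interpolated=np.zeros(n, dtype=bool),
            )
        )
    return tracks
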