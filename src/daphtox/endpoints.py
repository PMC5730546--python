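"""Behavioral endpoints per chamber and timepoint.

Computes the population-level locomotory endpoints used in chip-based
*Daphnia* ecotoxicology — average distance travelled, average speed, mean
absolute acceleration, fraction of active organisms and number of
non-motile animals — normalizes treated chambers to concurrent controls
as percentage change, and classifies response syndromes (hypoactivity,
hyperactivity, cessation).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .detection import ImagingConfig
from .simulator import ChamberSpec
from .tracking import Track

__all__ = [
    "TrackMetrics",
    "EndpointRecord",
    "NormalizedResponse",
    "track_metrics",
    "classify_motility",
    "chamber_summary",
    "normalize_to_control",
    "classify_response",
    "DEFAULT_JITTER_FLOOR_MM_S",
    "MOTILE",
    "NON_MOTILE",
    "INDETERMINATE",
]

logger = logging.getLogger(__name__)

#: default jitter floor expressed as a speed; divided by fps it gives the
#: per-step displacement threshold (0.05 mm per step at 30 fps).  It
#: suppresses centroid jitter and passive sedimentation drift so that the
#: distance endpoint reflects active swimming, independent of frame rate.
DEFAULT_JITTER_FLOOR_MM_S = 1.5

#: an animal is "active" in a clip when it covers more than this many body lengths
ACTIVE_BODY_LENGTHS = 2.0

MOTILE = "motile"
NON_MOTILE = "non_motile"
INDETERMINATE = "indeterminate"

CESSATION_PCT = -80.0
HYPERACTIVITY_PCT = 20.0
HYPOACTIVITY_PCT = -20.0
HYPER_WINDOW_H = (1.0, 8.0)
ALPHA = 0.05
CONTROL_CONSISTENCY_TOL = 0.05


@dataclass(frozen=True)
class TrackMetrics:
    total_distance_mm: float
    mean_speed_mm_s: float
    mean_abs_acceleration_mm_s2: float
    duration_s: float
    n_samples: int


@dataclass
class EndpointRecord:
    """Population summary of one chamber at one sampling timepoint."""

    chamber_id: str
    time_h: float
    n_tracks: int
    total_distance_mm: float        # population mean per animal
    mean_speed_mm_s: float
    mean_abs_acceleration_mm_s2: float
    frac_active: float
    n_non_motile: int
    valid: bool = True


@dataclass
class NormalizedResponse:
    """Percentage change of one metric vs concurrent controls."""

    concentration: float
    time_h: float
    pct_change: float
    p_value: float
    label: str = "none"


def _resolve_floor(
    imaging: ImagingConfig, jitter_floor_mm: float | None
) -> float:
    if jitter_floor_mm is not None:
        return jitter_floor_mm
    return DEFAULT_JITTER_FLOOR_MM_S / imaging.fps


def track_metrics(
    track: Track,
    imaging: ImagingConfig,
    jitter_floor_mm: float | None = None,
) -> TrackMetrics:
    """Distance, speed and acceleration of one track.

    Total distance sums frame-to-frame Euclidean displacements, zeroing
    steps below the jitter floor (default: 1.5 mm/s equivalent, i.e.
    0.05 mm per step at 30 fps) so that detection noise and passive
    sinking do not inflate the swimming distance.  Interpolated samples
    are included.  Mean speed is total distance over track duration; mean
    absolute acceleration comes from finite differences of the per-step
    speeds.
    """
    if track.n_samples < 2:
        raise ValueError("track must have at least 2 samples")
    floor = _resolve_floor(imaging, jitter_floor_mm)
    steps = np.hypot(np.diff(track.x_mm), np.diff(track.y_mm))
    steps = np.where(steps < floor, 0.0, steps)
    total = float(steps.sum())
    dts = np.diff(track.t_s)
    duration = float(track.t_s[-1] - track.t_s[0])
    speeds = steps / dts
    if len(speeds) > 1:
        accel = np.diff(speeds) / dts[1:]
        mean_abs_acc = float(np.abs(accel).mean())
    else:
        mean_abs_acc = 0.0
    return TrackMetrics(
        total_distance_mm=total,
        mean_speed_mm_s=total / duration,
        mean_abs_acceleration_mm_s2=mean_abs_acc,
        duration_s=duration,
        n_samples=track.n_samples,
    )


def classify_motility(
    track: Track,
    chamber: ChamberSpec,
    window_s: float = 10.0,
    eps_mm: float = 0.3,
) -> str:
    """Classify a track as motile / non-motile / indeterminate.

    The imaging analog of the standard immobility criterion (no reaction
    within 10 s): a track is non-motile when its positional extent stays
    below ``eps_mm`` in every sliding 10 s window AND its mean position
    lies in the bottom 10% band of the chamber (a sedimented animal).
    Tracks shorter than the window are indeterminate.
    """
    span = track.t_s[-1] - track.t_s[0]
    if span < window_s:
        return INDETERMINATE
    dt = float(np.median(np.diff(track.t_s)))
    w = max(int(round(window_s / dt)) + 1, 2)
    if w > track.n_samples:
        return INDETERMINATE
    xw = sliding_window_view(track.x_mm, w)
    yw = sliding_window_view(track.y_mm, w)
    extent = np.hypot(
        xw.max(axis=1) - xw.min(axis=1), yw.max(axis=1) - yw.min(axis=1)
    )
    quiet = bool(np.all(extent < eps_mm))
    sedimented = float(np.mean(track.y_mm)) >= chamber.bottom_band_y_mm
    return NON_MOTILE if (quiet and sedimented) else MOTILE


def chamber_summary(
    tracks: list[Track],
    imaging: ImagingConfig,
    chamber: ChamberSpec,
    time_h: float,
    chamber_id: str = "",
    n_animals: int | None = None,
    jitter_floor_mm: float | None = None,
) -> EndpointRecord:
    """Average per-animal metrics over the chamber population.

    ``n_animals`` (the known number of animals loaded in the chamber)
    normalizes the summed track distance to a per-animal population mean;
    when unknown, the number of tracks is used.  ``frac_active`` is the
    fraction of animals covering more than two body lengths in the clip.
    A chamber with zero reportable tracks yields an invalid record
    (excluded downstream) with a logged warning.
    """
    if not tracks:
        logger.warning(
            "chamber %s at %.1f h has no reportable tracks; excluded",
            chamber_id, time_h,
        )
        return EndpointRecord(
            chamber_id, time_h, 0, np.nan, np.nan, np.nan, np.nan, 0, valid=False
        )
    metrics = [track_metrics(tk, imaging, jitter_floor_mm) for tk in tracks]
    n = n_animals if n_animals is not None else len(tracks)
    if n < 1:
        raise ValueError("n_animals must be >= 1")
    total_per_animal = sum(m.total_distance_mm for m in metrics) / n
    active_thresh = ACTIVE_BODY_LENGTHS * imaging.body_length_mm
    n_active = sum(m.total_distance_mm > active_thresh for m in metrics)
    n_non_motile = sum(
        classify_motility(tk, chamber) == NON_MOTILE for tk in tracks
    )
    return EndpointRecord(
        chamber_id=chamber_id,
        time_h=time_h,
        n_tracks=len(tracks),
        total_distance_mm=total_per_animal,
        mean_speed_mm_s=float(np.mean([m.mean_speed_mm_s for m in metrics])),
        mean_abs_acceleration_mm_s2=float(
            np.mean([m.mean_abs_acceleration_mm_s2 for m in metrics])
        ),
        frac_active=min(n_active / n, 1.0),
        n_non_motile=n_non_motile,
    )


def normalize_to_control(
    treated: list[EndpointRecord],
    control: list[EndpointRecord],
    metric: str = "total_distance_mm",
    concentration: float = np.nan,
) -> list[NormalizedResponse]:
    """Percentage change of ``metric`` vs concurrent controls per timepoint.

    The change is computed from replicate chamber means,
    ``100 * (treated - control) / control``; the p-value is a two-sample
    t-test on the replicate chamber values.  Replicate controls differing
    by 5% or more trigger a consistency warning.
    """
    treated = [r for r in treated if r.valid]
    control = [r for r in control if r.valid]
    t_times = sorted({r.time_h for r in treated})
    c_times = sorted({r.time_h for r in control})
    shared = [t for t in t_times if t in set(c_times)]
    if not shared or t_times != c_times:
        raise ValueError("treated and control must share sampling timepoints")

    out = []
    for time_h in shared:
        tv = np.array([getattr(r, metric) for r in treated if r.time_h == time_h])
        cv = np.array([getattr(r, metric) for r in control if r.time_h == time_h])
        mean_c = cv.mean()
        if mean_c == 0:
            raise ValueError(
                f"control {metric} is zero at {time_h} h; percentage change undefined"
            )
        if len(cv) > 1 and mean_c != 0:
            spread = (cv.max() - cv.min()) / abs(mean_c)
            if spread >= CONTROL_CONSISTENCY_TOL:
                warnings.warn(
                    f"replicate controls differ by {100 * spread:.1f}% "
                    f"(>= {100 * CONTROL_CONSISTENCY_TOL:.0f}%) at {time_h} h",
                    stacklevel=2,
                )
        pct = float(100.0 * (tv.mean() - mean_c) / mean_c)
        if len(tv) > 1 and len(cv) > 1:
            p = float(stats.ttest_ind(tv, cv).pvalue)
        else:
            p = np.nan
        out.append(NormalizedResponse(concentration, time_h, pct, p))
    return out


def classify_response(
    series: list[NormalizedResponse],
) -> list[NormalizedResponse]:
    """Label each timepoint with a response syndrome.

    Cessation: change <= -80% at the first post-exposure timepoint
    (precedence over hypoactivity).  Hyperactivity: change >= +20% with
    p < 0.05 within hours 1-8.  Hypoactivity: change <= -20% with
    p < 0.05.  Otherwise none.
    """
    if not series:
        return []
    ordered = sorted(series, key=lambda r: r.time_h)
    first_t = ordered[0].time_h
    out = []
    for r in ordered:
        label = "none"
        significant = np.isfinite(r.p_value) and r.p_value < ALPHA
        if r.time_h == first_t and r.pct_change <= CESSATION_PCT:
            label = "cessation"
        elif (
            HYPER_WINDOW_H[0] <= r.time_h <= HYPER_WINDOW_H[1]
            and r.pct_change >= HYPERACTIVITY_PCT
            and significant
        ):
            label = "hyperactivity"
        elif r.pct_change <= HYPOACTIVITY_PCT and significant:
            label = "hypoactivity"
        out.append(replace(r, label=label))
    return out
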