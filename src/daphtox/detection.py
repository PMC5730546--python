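"""Blob detection: frames -> time-stamped candidate animal positions.

Back-illuminated chambers image the animals as dark blobs on a light
background.  A per-pixel temporal median estimates the static background;
pixels darker than the background by more than a threshold become
foreground, and connected components within a plausible animal-area range
are reported with intensity-weighted (sub-pixel) centroids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

__all__ = [
    "ImagingConfig",
    "DetectionRecord",
    "estimate_background",
    "estimate_noise_sd",
    "detect_frame",
    "detect_clip",
    "detections_to_dataframe",
]

MIN_BACKGROUND_FRAMES = 5
#: default detection threshold as a multiple of the estimated noise SD
NOISE_SD_MULTIPLIER = 5.0


@dataclass(frozen=True)
class ImagingConfig:
    """Calibration and detector settings for one chamber's video.

    ``threshold_offset`` is the intensity margin below background required
    for a foreground pixel; when ``None`` it defaults to 5x the noise SD
    estimated robustly (scaled MAD) from the background-subtracted pixels.
    Accepted blob areas lie in ``[min_area_factor, max_area_factor]`` times
    the expected animal area (an ellipse of major axis ``body_length_mm``
    with 2:1 aspect): the lower gate rejects specks, the upper gate keeps
    partially occluded pairs.
    """

    mm_per_px: float
    fps: float
    body_length_mm: float = 0.6
    threshold_offset: float | None = None
    min_area_factor: float = 0.25
    max_area_factor: float = 4.0
    intensity_polarity: str = "dark"  # animals darker than background (fixed)

    def __post_init__(self) -> None:
        if not self.mm_per_px > 0:
            raise ValueError("mm_per_px must be > 0")
        if not self.fps > 0:
            raise ValueError("fps must be > 0")
        if not 0 < self.min_area_factor < self.max_area_factor:
            raise ValueError("need 0 < min_area_factor < max_area_factor")
        if self.intensity_polarity != "dark":
            raise ValueError("only dark-on-light imaging is supported")

    @property
    def expected_area_px(self) -> float:
        """Expected animal area in pixels: pi * L/2 * L/4 / mm_per_px^2."""
        a = self.body_length_mm / 2.0
        return math.pi * a * (a / 2.0) / self.mm_per_px**2


@dataclass(frozen=True)
class DetectionRecord:
    """One candidate animal in one frame (centroid in pixel coordinates)."""

    frame_index: int
    t_s: float
    x_px: float
    y_px: float
    area_px: float
    mean_intensity: float


def estimate_background(frames: np.ndarray) -> np.ndarray:
    """Per-pixel temporal median of a frame stack.

    Moving animals occupy any given pixel in a minority of frames, so the
    median recovers the static background.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < MIN_BACKGROUND_FRAMES:
        raise ValueError(
            f"need at least {MIN_BACKGROUND_FRAMES} frames of shape (n, H, W)"
        )
    return np.median(frames.astype(np.float32), axis=0)


def estimate_noise_sd(frames: np.ndarray, background: np.ndarray) -> float:
    """Robust noise SD (scaled MAD) of background-subtracted pixels."""
    resid = np.asarray(frames, dtype=np.float32) - background
    mad = np.median(np.abs(resid - np.median(resid)))
    return float(1.4826 * mad)


def detect_frame(
    frame: np.ndarray,
    background: np.ndarray,
    config: ImagingConfig,
    frame_index: int = 0,
    noise_sd: float | None = None,
) -> list[DetectionRecord]:
    """Detect animal-sized dark blobs in one frame.

    Foreground = pixels with ``background - frame > threshold``; connected
    components (8-connectivity) with areas inside the configured gate
    become records.  Centroids are centers of mass weighted by the
    background-subtracted intensity.  Records are sorted by (x, y) for
    determinism.
    """
    frame = np.asarray(frame)
    background = np.asarray(background)
    if frame.shape != background.shape:
        raise ValueError(
            f"frame shape {frame.shape} != background shape {background.shape}"
        )
    diff = background.astype(np.float32) - frame.astype(np.float32)

    thr = config.threshold_offset
    if thr is None:
        if noise_sd is None:
            mad = np.median(np.abs(diff - np.median(diff)))
            noise_sd = float(1.4826 * mad)
        thr = NOISE_SD_MULTIPLIER * max(noise_sd, 0.5)

    mask = diff > thr
    labels = measure.label(mask, connectivity=2)
    lo = config.min_area_factor * config.expected_area_px
    hi = config.max_area_factor * config.expected_area_px
    t_s = frame_index / config.fps

    records = []
    for region in measure.regionprops(labels, intensity_image=diff):
        if not lo <= region.area <= hi:
            continue
        cy, cx = region.centroid_weighted
        sl = region.slice
        mean_int = float(frame[sl][region.image].mean())
        records.append(
            DetectionRecord(
                frame_index=frame_index,
                t_s=t_s,
                x_px=float(cx),
                y_px=float(cy),
                area_px=float(region.area),
                mean_intensity=mean_int,
            )
        )
    records.sort(key=lambda r: (r.x_px, r.y_px))
    return records


def detect_clip(frames: np.ndarray, config: ImagingConfig) -> pd.DataFrame:
    """Run background estimation and per-frame detection on a frame stack.

    Returns a DataFrame with columns
    ``frame, t_s, x_px, y_px, area_px, mean_intensity``.
    """
    frames = np.asarray(frames)
    background = estimate_background(frames)
    noise_sd = estimate_noise_sd(frames, background)
    all_records: list[DetectionRecord] = []
    for i in range(frames.shape[0]):
        all_records.extend(
            detect_frame(frames[i], background, config, i, noise_sd)
        )
    return detections_to_dataframe(all_records)


def detections_to_dataframe(records: list[DetectionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame": [r.frame_index for r in records],
            "t_s": [r.t_s for r in records],
            "x_px": [r.x_px for r in records],
            "y_px": [r.y_px for r in records],
            "area_px": [r.area_px for r in records],
            "mean_intensity": [r.mean_intensity for r in records],
        }
    )
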