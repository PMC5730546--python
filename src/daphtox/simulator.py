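"""Synthetic hop-and-rest locomotion and immobilization generator.

*Daphnia magna* neonates swim in a characteristic "hop and rest" cycle:
short antenna-powered bursts alternating with passive rests during which
the ~600 µm animal sediments under gravity.  This module generates
ground-truth trajectories of that process inside a vertically mounted
cuboid test chamber, draws Hill-model immobilization outcomes, and renders
grayscale video clips (dark animals on a light, back-illuminated
background) with known ground truth, so that the detection → tracking →
endpoint pipeline can be validated end to end without chip hardware.

Coordinate convention: ``x`` runs along the chamber width (horizontal),
``y`` along the chamber length (vertical), with gravity pointing toward
increasing ``y`` (the image row axis).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from scipy.special import expit

__all__ = [
    "ChamberSpec",
    "LocomotionParams",
    "ToxicantEffect",
    "AnimalGroundTruth",
    "SyntheticClip",
    "PHASE_HOPPING",
    "PHASE_RESTING",
    "PHASE_IMMOBILE",
    "PHASE_NAMES",
    "hill_probability",
    "sample_trajectory",
    "sample_separated_trajectories",
    "apply_dose",
    "sample_immobilization",
    "render_clip",
    "chamber_background",
    "generate_assay",
    "AssayObservation",
    "AssayDataset",
]

PHASE_HOPPING = 0
PHASE_RESTING = 1
PHASE_IMMOBILE = 2
PHASE_NAMES = ("hopping", "resting", "immobile")

#: fraction of the chamber length counted as the sedimentation band at the bottom
BOTTOM_BAND_FRACTION = 0.10

# rendering intensity levels (uint8 scale)
_BACKGROUND_LEVEL = 220.0
_BORDER_LEVEL = 40.0
_ANIMAL_LEVEL = 30.0
_BORDER_PX = 2


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("an explicit integer seed (or Generator) is required")
    return np.random.default_rng(seed)


def _check_positive(value: float, name: str) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be finite and > 0, got {value!r}")


def _check_nonneg(value: float, name: str) -> None:
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class ChamberSpec:
    """Geometry and calibration of one cuboid test chamber.

    The default 13 x 8 x 2 mm chamber is mounted vertically; the 2 mm depth
    is not rendered (analysis is in the x-y plane).  ``mm_per_px`` carries
    the optical calibration; rendered image dimensions are
    ``ceil(extent / mm_per_px)``.
    """

    length_mm: float = 13.0   # vertical extent (gravity axis)
    width_mm: float = 8.0     # horizontal extent
    depth_mm: float = 2.0     # out-of-plane, not rendered
    mm_per_px: float = 13.0 / 512.0
    gravity_axis: str = "+y"

    def __post_init__(self) -> None:
        _check_positive(self.length_mm, "length_mm")
        _check_positive(self.width_mm, "width_mm")
        _check_positive(self.depth_mm, "depth_mm")
        _check_positive(self.mm_per_px, "mm_per_px")
        if self.gravity_axis != "+y":
            raise ValueError("gravity_axis must be '+y' (image rows point down)")

    @property
    def shape_px(self) -> tuple[int, int]:
        """Rendered image shape as (rows, cols) = (length, width)."""
        return (
            math.ceil(self.length_mm / self.mm_per_px),
            math.ceil(self.width_mm / self.mm_per_px),
        )

    @property
    def bottom_band_y_mm(self) -> float:
        """y coordinate above which a position counts as 'sedimented'."""
        return self.length_mm * (1.0 - BOTTOM_BAND_FRACTION)

    def contains(self, x_mm, y_mm) -> np.ndarray:
        x = np.asarray(x_mm, float)
        y = np.asarray(y_mm, float)
        return (x >= 0) & (x <= self.width_mm) & (y >= 0) & (y <= self.length_mm)


@dataclass(frozen=True)
class LocomotionParams:
    """Kinematic parameters of the hop-and-rest renewal process.

    ``hop_rate_hz`` is the Poisson rate of hop initiations while the animal
    is motile, so the expected swimming path per unit time is
    ``hop_rate_hz * hop_length_mm_mean`` (passive sinking drift excluded).
    """

    hop_rate_hz: float = 1.0
    hop_length_mm_mean: float = 1.5
    hop_length_mm_sd: float = 0.5
    hop_duration_s: float = 0.2
    sink_speed_mm_s: float = 0.5
    upward_bias: float = 0.7
    body_length_mm: float = 0.6

    def __post_init__(self) -> None:
        _check_nonneg(self.hop_rate_hz, "hop_rate_hz")
        _check_nonneg(self.hop_length_mm_mean, "hop_length_mm_mean")
        _check_nonneg(self.hop_length_mm_sd, "hop_length_mm_sd")
        _check_positive(self.hop_duration_s, "hop_duration_s")
        _check_nonneg(self.sink_speed_mm_s, "sink_speed_mm_s")
        if not np.isfinite(self.upward_bias) or not 0 <= self.upward_bias <= 1:
            raise ValueError(
                f"upward_bias must be in [0, 1], got {self.upward_bias!r}"
            )
        _check_positive(self.body_length_mm, "body_length_mm")

    @property
    def expected_distance_mm_per_s(self) -> float:
        """Closed-form expected hop path length per second (drift excluded)."""
        return self.hop_rate_hz * self.hop_length_mm_mean


@dataclass(frozen=True)
class ToxicantEffect:
    """Dose-dependent effect of a toxicant on behavior and immobilization.

    Immobilization follows a two-parameter Hill curve
    ``p(c) = c^h / (ec50^h + c^h)`` (exactly 0.5 at ``c = ec50``).
    ``activity_curve(concentration, time_h)`` returns a non-negative
    multiplier on the hop initiation rate: values < 1 encode hypoactivity,
    values > 1 hyperactivity.  The multiplier only applies once
    ``time_h >= onset_lag_h``.
    """

    ec50: float
    hill_slope: float
    activity_curve: Callable[[float, float], float] | None = None
    onset_lag_h: float = 0.0
    name: str = ""
    units: str = "mg/L"

    def __post_init__(self) -> None:
        _check_positive(self.ec50, "ec50")
        _check_positive(self.hill_slope, "hill_slope")
        _check_nonneg(self.onset_lag_h, "onset_lag_h")

    def immobilization_probability(self, concentration) -> np.ndarray:
        return hill_probability(concentration, self.ec50, self.hill_slope)

    def activity_multiplier(self, concentration: float, time_h: float) -> float:
        if concentration == 0 or time_h < self.onset_lag_h:
            return 1.0
        if self.activity_curve is None:
            return 1.0
        m = float(self.activity_curve(concentration, time_h))
        if not np.isfinite(m) or m < 0:
            raise ValueError(f"activity multiplier must be >= 0, got {m!r}")
        return m


def hill_probability(concentration, ec50: float, hill_slope: float):
    """Hill immobilization probability ``c^h / (ec50^h + c^h)``.

    Evaluated as a logistic in log-concentration for numerical stability;
    zero concentration maps to exactly 0.
    """
    _check_positive(ec50, "ec50")
    _check_positive(hill_slope, "hill_slope")
    c = np.asarray(concentration, float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    with np.errstate(divide="ignore"):
        logc = np.log(np.where(c > 0, c, 1.0))
    p = expit(hill_slope * (logc - math.log(ec50)))
    p = np.where(c > 0, p, 0.0)
    return p if p.ndim else float(p)


@dataclass
class AnimalGroundTruth:
    """True trajectory and behavioral state of one simulated animal."""

    animal_id: int
    t_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    phase: np.ndarray          # integer codes, see PHASE_NAMES
    immobile: bool
    body_length_mm: float = 0.6
    #: exact active swimming path within the sampled window (sum of hop
    #: displacement magnitudes, excluding passive sinking); the sampled
    #: polyline slightly underestimates this where hops bend off walls.
    swim_distance_mm: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.t_s)
        if not (len(self.x_mm) == len(self.y_mm) == len(self.phase) == n):
            raise ValueError("trajectory arrays must have equal length")

    @property
    def n_frames(self) -> int:
        return len(self.t_s)

    @property
    def path_length_mm(self) -> float:
        """Total polyline length of the sampled trajectory."""
        return float(
            np.hypot(np.diff(self.x_mm), np.diff(self.y_mm)).sum()
        )

    @property
    def phase_labels(self) -> list[str]:
        return [PHASE_NAMES[p] for p in self.phase]


@dataclass
class SyntheticClip:
    """Rendered frame stack plus the ground truth that produced it."""

    frames: np.ndarray             # (n_frames, rows, cols) uint8
    fps: float
    duration_s: float
    truth: list[AnimalGroundTruth]
    chamber: ChamberSpec
    noise_sd: float = 0.0
    blur_px: float = 0.0

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _fold(p, lo: float, hi: float):
    """Specular reflection of an unconstrained coordinate into [lo, hi]."""
    span = hi - lo
    if span <= 0:
        return np.full_like(np.asarray(p, float), lo)
    q = np.mod(np.asarray(p, float) - lo, 2.0 * span)
    return lo + (span - np.abs(q - span))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Draw from N(mean, sd^2) truncated at zero (rejection sampling)."""
    if sd == 0:
        return max(mean, 0.0)
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v >= 0:
            return v
    return max(mean, 0.0)  # pathological mean << -sd


def sample_trajectory(
    params: LocomotionParams,
    chamber: ChamberSpec,
    duration_s: float = 30.0,
    fps: float = 30.0,
    seed=None,
    start_xy: tuple[float, float] | None = None,
    immobile: bool = False,
    animal_id: int = 0,
    y_bounds_mm: tuple[float, float] | None = None,
) -> AnimalGroundTruth:
    """Sample one hop-and-rest trajectory at the rendering frame rate.

    Hop initiations form a Poisson process at ``hop_rate_hz``; each hop
    displaces the animal by a truncated-normal length in a direction
    uniform in angle, the vertical component pointing against gravity with
    probability ``upward_bias``.  The displacement is spread over
    ``hop_duration_s`` (compressed when the next hop starts sooner, so the
    drawn displacement is always completed).  Between hops the animal
    rests and sinks at ``sink_speed_mm_s`` until it reaches the chamber
    floor.  Hops reflect specularly off the walls.

    With ``immobile=True`` the animal is rendered already sedimented: a
    clip is a 30 s snapshot taken at hour-scale exposure timepoints, long
    after an immobilized animal has settled into the bottom band.

    ``y_bounds_mm`` optionally confines the vertical excursion to a
    sub-interval of the chamber (used by benchmark fixtures that need
    guaranteed-separated animals).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if fps <= 0:
        raise ValueError("fps must be > 0")
    rng = _as_rng(seed)

    n_frames = round(fps * duration_s)
    t = np.arange(n_frames) / fps

    margin = params.body_length_mm / 2.0
    x_lo, x_hi = margin, chamber.width_mm - margin
    if y_bounds_mm is None:
        y_lo, y_hi = margin, chamber.length_mm - margin
    else:
        y_lo = max(y_bounds_mm[0], margin)
        y_hi = min(y_bounds_mm[1], chamber.length_mm - margin)
    if x_lo >= x_hi or y_lo >= y_hi:
        raise ValueError("chamber too small for body_length_mm margin")

    if immobile:
        band_lo = max(chamber.bottom_band_y_mm + margin * 0.1, y_lo)
        band_hi = min(chamber.length_mm - margin, y_hi) if y_bounds_mm else chamber.length_mm - margin
        if band_hi <= band_lo:  # confined lane above the bottom band
            band_lo, band_hi = y_hi - 0.1 * (y_hi - y_lo), y_hi
        x0 = rng.uniform(x_lo, x_hi)
        y0 = rng.uniform(band_lo, band_hi)
        xs = np.full(n_frames, x0)
        ys = np.full(n_frames, y0)
        phase = np.full(n_frames, PHASE_IMMOBILE, dtype=np.uint8)
        return AnimalGroundTruth(
            animal_id, t, xs, ys, phase, True, params.body_length_mm, 0.0
        )

    if start_xy is None:
        x0 = rng.uniform(x_lo, x_hi)
        y0 = rng.uniform(y_lo, y_hi)
    else:
        x0, y0 = start_xy
        if not (x_lo <= x0 <= x_hi and y_lo <= y0 <= y_hi):
            raise ValueError("start_xy outside chamber bounds (with body margin)")

    # --- build the piecewise-linear timeline -----------------------------
    # segments: (t0, t1, vx, vy, phase); rests sink (clamped at floor),
    # hops move ballistically with specular reflection.
    segs: list[tuple[float, float, float, float, int]] = []
    rate = params.hop_rate_hz
    if rate > 0:
        init_times = []
        tt = rng.exponential(1.0 / rate)
        while tt < duration_s:
            init_times.append(tt)
            tt += rng.exponential(1.0 / rate)
    else:
        init_times = []

    cursor = 0.0
    for k, ti in enumerate(init_times):
        if ti > cursor:
            segs.append((cursor, ti, 0.0, params.sink_speed_mm_s, PHASE_RESTING))
        next_init = init_times[k + 1] if k + 1 < len(init_times) else duration_s
        hop_dur = min(params.hop_duration_s, next_init - ti, duration_s - ti)
        hop_dur = max(hop_dur, 1e-9)
        length = _truncated_normal(
            rng, params.hop_length_mm_mean, params.hop_length_mm_sd
        )
        theta = rng.uniform(0.0, 2.0 * math.pi)
        up = rng.random() < params.upward_bias
        dx = length * math.cos(theta)
        dy = length * abs(math.sin(theta)) * (-1.0 if up else 1.0)
        segs.append((ti, ti + hop_dur, dx / hop_dur, dy / hop_dur, PHASE_HOPPING))
        cursor = ti + hop_dur
    if cursor < duration_s:
        segs.append((cursor, duration_s, 0.0, params.sink_speed_mm_s, PHASE_RESTING))

    # --- integrate, sampling at frame times ------------------------------
    xs = np.empty(n_frames)
    ys = np.empty(n_frames)
    phase = np.empty(n_frames, dtype=np.uint8)
    x, y = x0, y0
    i = 0
    for (t0, t1, vx, vy, ph) in segs:
        j = i
        while j < n_frames and t[j] < t1 - 1e-12:
            j += 1
        dt = t[i:j] - t0
        if ph == PHASE_HOPPING:
            xs[i:j] = _fold(x + vx * dt, x_lo, x_hi)
            ys[i:j] = _fold(y + vy * dt, y_lo, y_hi)
        else:
            xs[i:j] = x
            ys[i:j] = np.minimum(y + vy * dt, y_hi)
        phase[i:j] = ph
        seg_dt = t1 - t0
        if ph == PHASE_HOPPING:
            x = float(_fold(x + vx * seg_dt, x_lo, x_hi))
            y = float(_fold(y + vy * seg_dt, y_lo, y_hi))
        else:
            y = min(y + vy * seg_dt, y_hi)
        i = j
    xs[i:] = x
    ys[i:] = y
    phase[i:] = PHASE_RESTING

    # exact hop path length inside the sampled window [0, t_last]
    t_last = t[-1] if n_frames else 0.0
    swim = 0.0
    for (t0, t1, vx, vy, ph) in segs:
        if ph == PHASE_HOPPING:
            overlap = max(min(t1, t_last) - t0, 0.0)
            swim += math.hypot(vx, vy) * overlap

    return AnimalGroundTruth(
        animal_id, t, xs, ys, phase, False, params.body_length_mm, swim
    )


def sample_separated_trajectories(
    n_animals: int,
    params: LocomotionParams,
    chamber: ChamberSpec,
    duration_s: float = 30.0,
    fps: float = 30.0,
    seed=None,
    lane_margin_mm: float = 0.75,
) -> list[AnimalGroundTruth]:
    """Sample animals confined to disjoint horizontal lanes of the chamber.

    Benchmark configuration guaranteeing pairwise separation of at least
    ``2 * lane_margin_mm`` at every frame, used to measure detector and
    tracker accuracy free of occlusion.  Free motion of several animals in
    a 13 x 8 mm chamber cannot stay non-overlapping for a whole clip.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    rng = _as_rng(seed)
    lane_h = chamber.length_mm / n_animals
    usable = lane_h - 2 * lane_margin_mm
    if usable <= params.body_length_mm:
        raise ValueError("lanes too thin; reduce n_animals or lane_margin_mm")
    truths = []
    for k in range(n_animals):
        lo = k * lane_h + lane_margin_mm
        hi = (k + 1) * lane_h - lane_margin_mm
        truths.append(
            sample_trajectory(
                params,
                chamber,
                duration_s,
                fps,
                seed=rng,
                animal_id=k,
                y_bounds_mm=(lo, hi),
            )
        )
    return truths


def apply_dose(
    params: LocomotionParams,
    effect: ToxicantEffect,
    concentration: float,
    time_h: float,
) -> LocomotionParams:
    """Return locomotion parameters modulated by a toxicant exposure.

    The hop initiation rate is multiplied by
    ``effect.activity_curve(concentration, time_h)`` once the exposure time
    has passed ``onset_lag_h``; all other fields are preserved.  A zero
    concentration (or a pre-onset time) returns the parameters unchanged.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if time_h < 0:
        raise ValueError("time_h must be >= 0")
    m = effect.activity_multiplier(concentration, time_h)
    if m == 1.0:
        return params
    return dataclasses.replace(params, hop_rate_hz=params.hop_rate_hz * m)


def sample_immobilization(
    effect: ToxicantEffect, concentration: float, n_animals: int, seed=None
) -> list[bool]:
    """Draw per-animal immobilization outcomes from the Hill model."""
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    rng = _as_rng(seed)
    p = effect.immobilization_probability(concentration)
    return list(rng.random(n_animals) < p)


def chamber_background(
    chamber: ChamberSpec, blur_px: float = 1.0
) -> np.ndarray:
    """Noise-free rendered background: light field with a dark wall border."""
    rows, cols = chamber.shape_px
    img = np.full((rows, cols), _BACKGROUND_LEVEL, dtype=np.float32)
    b = _BORDER_PX
    img[:b, :] = _BORDER_LEVEL
    img[-b:, :] = _BORDER_LEVEL
    img[:, :b] = _BORDER_LEVEL
    img[:, -b:] = _BORDER_LEVEL
    if blur_px > 0:
        img = ndimage.gaussian_filter(img, blur_px)
    return img


def _draw_animal(
    img: np.ndarray, cx_px: float, cy_px: float, a_px: float, b_px: float
) -> None:
    """Stamp a dark filled ellipse (semi-axes a_px horizontal, b_px vertical)."""
    rows, cols = img.shape
    r0 = max(int(math.floor(cy_px - b_px - 1)), 0)
    r1 = min(int(math.ceil(cy_px + b_px + 2)), rows)
    c0 = max(int(math.floor(cx_px - a_px - 1)), 0)
    c1 = min(int(math.ceil(cx_px + a_px + 2)), cols)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = ((cc - cx_px) / a_px) ** 2 + ((rr - cy_px) / b_px) ** 2 <= 1.0
    patch = img[r0:r1, c0:c1]
    patch[inside] = _ANIMAL_LEVEL


def render_clip(
    truths: Sequence[AnimalGroundTruth],
    chamber: ChamberSpec,
    fps: float | None = None,
    noise_sd: float = 2.0,
    blur_px: float = 1.0,
    seed=0,
) -> SyntheticClip:
    """Render ground-truth trajectories as a grayscale frame stack.

    Each animal is drawn as a dark ellipse (major axis ``body_length_mm``
    horizontal, 2:1 aspect) at its true position on a uniform light
    background with a dark chamber border, Gaussian-blurred by ``blur_px``
    and corrupted by additive Gaussian noise of SD ``noise_sd`` (uint8
    intensity units), clipped to [0, 255].
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    truths = list(truths)
    if truths:
        t_ref = truths[0].t_s
        for tr in truths[1:]:
            if len(tr.t_s) != len(t_ref) or not np.allclose(tr.t_s, t_ref):
                raise ValueError("all truths must share one time base")
        for tr in truths:
            if not np.all(chamber.contains(tr.x_mm, tr.y_mm)):
                raise ValueError(
                    f"animal {tr.animal_id} leaves the chamber bounds"
                )
        n_frames = len(t_ref)
        inferred_fps = (
            1.0 / float(np.median(np.diff(t_ref))) if n_frames > 1 else 30.0
        )
    else:
        if fps is None:
            raise ValueError("fps required when rendering an empty scene")
        n_frames = round(fps * 1.0)
        inferred_fps = fps
    if fps is None:
        fps = inferred_fps

    rng = _as_rng(seed)
    rows, cols = chamber.shape_px
    base = np.full((rows, cols), _BACKGROUND_LEVEL, dtype=np.float32)
    b = _BORDER_PX
    base[:b, :] = _BORDER_LEVEL
    base[-b:, :] = _BORDER_LEVEL
    base[:, :b] = _BORDER_LEVEL
    base[:, -b:] = _BORDER_LEVEL

    frames = np.empty((n_frames, rows, cols), dtype=np.uint8)
    for i in range(n_frames):
        img = base.copy()
        for tr in truths:
            a_px = (tr.body_length_mm / 2.0) / chamber.mm_per_px
            b_px = a_px / 2.0
            cx = tr.x_mm[i] / chamber.mm_per_px
            cy = tr.y_mm[i] / chamber.mm_per_px
            _draw_animal(img, cx, cy, a_px, b_px)
        if blur_px > 0:
            img = ndimage.gaussian_filter(img, blur_px)
        if noise_sd > 0:
            img = img + noise_sd * rng.standard_normal(img.shape, dtype=np.float32)
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)

    duration = n_frames / fps
    return SyntheticClip(frames, fps, duration, truths, chamber, noise_sd, blur_px)


# ---------------------------------------------------------------------------
# assay generation


@dataclass
class AssayObservation:
    """One chamber filmed at one sampling timepoint."""

    chamber_id: str
    group: str
    concentration: float
    replicate: int
    time_h: float
    truths: list[AnimalGroundTruth]
    immobile: list[bool]
    clip: SyntheticClip | None = None


@dataclass
class AssayDataset:
    design: dict
    seed: int
    observations: list[AssayObservation] = field(default_factory=list)

    def chambers(self) -> list[str]:
        return sorted({o.chamber_id for o in self.observations})


_DEFAULT_DESIGN = {
    "animals_per_chamber": 5,
    "replicates": 3,
    "duration_s": 30.0,
    "fps": 30.0,
    "sampling_times_h": [1.0],
    "render": True,
    "noise_sd": 2.0,
    "blur_px": 1.0,
}


def generate_assay(design: dict, seed: int) -> AssayDataset:
    """Generate a full synthetic assay: chambers x timepoints with truth.

    ``design`` mirrors the chip layout: a list of ``groups`` (each with a
    name and concentration; a zero-concentration control group is
    mandatory), ``replicates`` chambers per group (default 3, emulating
    the chip's eight clusters of three), ``animals_per_chamber`` (default
    5), and ``sampling_times_h``.  ``effect`` configures the toxicant
    (``ec50``, ``hill_slope``, optional constant ``activity_multiplier``
    and ``onset_lag_h``).  Per-animal immobilization is drawn once per
    chamber and applied at every timepoint.  Deterministic per seed.
    """
    cfg = {**_DEFAULT_DESIGN, **design}
    groups = cfg.get("groups")
    if not groups:
        raise ValueError("design must list at least one group")
    if not any(float(g.get("concentration", 0.0)) == 0.0 for g in groups):
        raise ValueError(
            "design must include a control group (concentration 0); "
            "normalization requires concurrent controls"
        )
    replicates_default = int(cfg["replicates"])
    n_animals = int(cfg["animals_per_chamber"])
    if n_animals < 1:
        raise ValueError("animals_per_chamber must be >= 1")

    chamber = ChamberSpec(**cfg.get("chamber", {}))
    params = LocomotionParams(**cfg.get("locomotion", {}))
    eff_cfg = dict(cfg.get("effect", {}))
    mult = eff_cfg.pop("activity_multiplier", None)
    if eff_cfg:
        if mult is not None:
            eff_cfg["activity_curve"] = lambda c, t, _m=float(mult): _m
        effect = ToxicantEffect(**eff_cfg)
    else:
        effect = None

    times = [float(t) for t in cfg["sampling_times_h"]]
    ss = np.random.SeedSequence(seed)

    dataset = AssayDataset(design=cfg, seed=seed)
    chamber_index = 0
    for g in groups:
        conc = float(g.get("concentration", 0.0))
        reps = int(g.get("replicates", replicates_default))
        if reps < 1:
            raise ValueError(f"group {g.get('name', conc)!r} has no replicates")
        for rep in range(reps):
            cid = f"{g.get('name', f'c{conc:g}')}-r{rep + 1}"
            chamber_ss = np.random.SeedSequence(
                entropy=ss.entropy, spawn_key=(chamber_index,)
            )
            imm_rng = np.random.default_rng(chamber_ss.spawn(1)[0])
            if effect is not None and conc > 0:
                immobile = sample_immobilization(effect, conc, n_animals, imm_rng)
            else:
                immobile = [False] * n_animals
            for it, time_h in enumerate(times):
                tp_rng = np.random.default_rng(
                    np.random.SeedSequence(
                        entropy=ss.entropy, spawn_key=(chamber_index, it + 1)
                    )
                )
                if effect is not None:
                    dosed = apply_dose(params, effect, conc, time_h)
                else:
                    dosed = params
                truths = [
                    sample_trajectory(
                        dosed,
                        chamber,
                        cfg["duration_s"],
                        cfg["fps"],
                        seed=tp_rng,
                        immobile=immobile[a],
                        animal_id=a,
                    )
                    for a in range(n_animals)
                ]
                clip = None
                if cfg["render"]:
                    clip = render_clip(
                        truths,
                        chamber,
                        fps=cfg["fps"],
                        noise_sd=cfg["noise_sd"],
                        blur_px=cfg["blur_px"],
                        seed=tp_rng,
                    )
                dataset.observations.append(
                    AssayObservation(
                        cid, str(g.get("name", conc)), conc, rep + 1,
                        time_h, truths, list(immobile), clip,
                    )
                )
            chamber_index += 1
    return dataset
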