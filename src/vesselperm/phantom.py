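"""Ground-truthed synthetic perfusion phantoms.

Emulates the on-chip permeability assay: a circular microvascular chamber
(default diameter 2.4 mm) containing perfusable cylindrical vessel segments
is perfused with fluorescent 70 kDa dextran and imaged every 10 s for up to
10 min. Each phantom carries the true wall permeability of every segment so
the downstream estimator can be validated against known ground truth.

The dye-transport model is the analytic inverse of the permeability
estimator: lumen pixels ramp from background to a plateau when the dye
front arrives, and after filling a leaked-dye field accumulates in a thin
perivascular band at exactly the rate that makes the measurement-window
mean rise with slope ``dI/dt = P_true * delta_I * 2 / r``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomConfig",
    "TubeGeometry",
    "GroundTruth",
    "ImageStack",
    "PlacementError",
    "IntensityRangeError",
    "generate_network",
    "simulate_timelapse",
    "simulate_experiment",
]


class PlacementError(RuntimeError):
    """Vessel segments could not be placed without overlap (density too high)."""


class IntensityRangeError(ValueError):
    """Simulated leak exceeds the representable intensity range."""


@dataclass(frozen=True)
class PhantomConfig:
    """Full parameterization of one simulated perfusion experiment.

    Defaults reproduce the imaging protocol of the assay this package
    targets: frames every 10 s for 10 min in a 2.4 mm circular chamber,
    with 5-7 evaluable cylindrical segments per chip.

    Parameters
    ----------
    chamber_diameter_um
        Diameter of the circular culture chamber (µm).
    pixel_size_um
        Image sampling (µm per pixel). The microscope objective used in
        the original assay is not recorded; 2 µm/px (a low-magnification
        widefield objective with binning, resolving the full chamber) is
        the package default.
    frame_interval_s, duration_s
        Time-lapse sampling. The stack has ``floor(duration/interval)+1``
        frames (frame 0 at t=0).
    n_segments
        Number of straight cylindrical segments to place.
    radius_range_um
        (min, max) vessel radius in µm; radii are drawn uniformly.
    true_permeability_um_s
        Ground-truth wall permeability P, either one global value or one
        value per segment (µm/s).
    lumen_plateau, background
        Intensity step of a filled lumen pixel above background, and the
        constant background level (camera offset), in camera units.
    arrival_time_s
        Time at which the dye front reaches the segments (simultaneous
        across segments unless ``arrival_offsets_s`` is given).
    fill_rise_s
        Duration of the (linear) lumen filling ramp. Convective filling
        of a perfused microvessel is fast relative to the 10 s frame
        interval; the default keeps it sub-frame.
    noise_sd
        SD of i.i.d. additive Gaussian camera noise, applied last.
    bleach_rate_per_s
        Global mono-exponential photobleaching rate (fraction/s).
    diffusion_sigma_um
        Gaussian blur applied to the leaked-dye field each frame (halo
        spreading). Default 0 keeps the window-mean trace analytically
        exact.
    shell_width_um
        Width of the perivascular shell used for ground-truth measurement
        windows (lumen + shell).
    leak_band_um
        Width of the thin perivascular band in which leaked dye is
        deposited. Must not exceed ``shell_width_um``.
    arrival_offsets_s
        Optional per-segment dye arrival offsets (s), default all zero.
    max_intensity
        Representable intensity ceiling (16-bit camera full well by
        default); the simulation refuses configurations that exceed it.
    seed
        Seed for geometry placement and noise.
    """

    chamber_diameter_um: float = 2400.0
    pixel_size_um: float = 2.0
    frame_interval_s: float = 10.0
    duration_s: float = 600.0
    n_segments: int = 6
    radius_range_um: tuple[float, float] = (10.0, 30.0)
    true_permeability_um_s: float | Sequence[float] = 0.05
    lumen_plateau: float = 100.0
    background: float = 20.0
    arrival_time_s: float = 60.0
    fill_rise_s: float = 5.0
    noise_sd: float = 1.0
    bleach_rate_per_s: float = 0.0
    diffusion_sigma_um: float = 0.0
    shell_width_um: float = 25.0
    leak_band_um: float = 10.0
    arrival_offsets_s: tuple[float, ...] | None = None
    max_intensity: float = 65535.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chamber_diameter_um <= 0:
            raise ValueError("chamber_diameter_um must be > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.duration_s < 2 * self.frame_interval_s:
            raise ValueError("duration_s must cover at least two frame intervals")
        rmin, rmax = self.radius_range_um
        if not (0 < rmin <= rmax):
            raise ValueError("radius_range_um must satisfy 0 < min <= max")
        if rmax >= self.chamber_diameter_um / 4:
            raise ValueError("max radius must be small relative to the chamber")
        if self.n_segments < 0:
            raise ValueError("n_segments must be >= 0")
        if np.any(np.asarray(self.true_permeability_um_s, dtype=float) < 0):
            raise ValueError("true_permeability_um_s must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.fill_rise_s < 0:
            raise ValueError("fill_rise_s must be >= 0")
        if not (0 < self.leak_band_um <= self.shell_width_um):
            raise ValueError("leak_band_um must lie in (0, shell_width_um]")
        p = np.atleast_1d(np.asarray(self.true_permeability_um_s, dtype=float))
        if p.size not in (1, self.n_segments) and self.n_segments > 0:
            raise ValueError(
                "true_permeability_um_s must be scalar or one value per segment"
            )
        if self.arrival_offsets_s is not None and len(self.arrival_offsets_s) != self.n_segments:
            raise ValueError("arrival_offsets_s must have one entry per segment")

    # -- derived quantities -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return int(np.floor(self.duration_s / self.frame_interval_s)) + 1

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    @property
    def grid_shape(self) -> tuple[int, int]:
        n = int(np.ceil(self.chamber_diameter_um / self.pixel_size_um))
        return (n, n)

    def permeability_per_segment(self) -> np.ndarray:
        p = np.atleast_1d(np.asarray(self.true_permeability_um_s, dtype=float))
        if p.size == 1:
            p = np.repeat(p, self.n_segments)
        return p

    def arrival_per_segment(self) -> np.ndarray:
        if self.arrival_offsets_s is None:
            return np.full(self.n_segments, self.arrival_time_s)
        return self.arrival_time_s + np.asarray(self.arrival_offsets_s, dtype=float)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(d["true_permeability_um_s"], tuple):
            d["true_permeability_um_s"] = list(d["true_permeability_um_s"])
        return d


@dataclass
class TubeGeometry:
    """One straight cylindrical segment: endpoints in pixel coordinates
    (row, col, 0-based), radius in µm and pixels."""

    segment_id: int
    p0: np.ndarray
    p1: np.ndarray
    radius_um: float
    radius_px: float

    @property
    def length_px(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))


@dataclass
class ImageStack:
    """T-ordered 2D intensity frames with physical calibration."""

    frames: np.ndarray  # (T, H, W), float32, >= 0
    pixel_size_um: float
    frame_interval_s: float
    channel: str = "RITC-dextran-70kDa"

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def save(self, path: str | Path) -> None:
        """Write a multi-page TIFF (one page per frame) plus a JSON sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.frames)
        meta = {
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_s": self.frame_interval_s,
            "channel": self.channel,
            "n_frames": int(self.n_frames),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path, meta_path: str | Path | None = None) -> "ImageStack":
        path = Path(path)
        meta_path = Path(meta_path) if meta_path else path.with_suffix(".json")
        meta = json.loads(meta_path.read_text())
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        return cls(
            frames=np.asarray(frames, dtype=np.float32),
            pixel_size_um=float(meta["pixel_size_um"]),
            frame_interval_s=float(meta["frame_interval_s"]),
            channel=meta.get("channel", ""),
        )


@dataclass
class GroundTruth:
    """Per-segment truth carried alongside a simulated stack."""

    config: PhantomConfig
    tubes: list[TubeGeometry]
    label_mask: np.ndarray  # (H, W) int, 0 = background, i+1 = lumen of tube i
    band_mask: np.ndarray  # (H, W) int, i+1 = leak band of tube i
    p_true_um_s: np.ndarray
    arrival_time_s: np.ndarray

    def lumen_mask(self, i: int) -> np.ndarray:
        return self.label_mask == i + 1

    def window_mask(self, i: int) -> np.ndarray:
        """Ground-truth measurement window: lumen + perivascular shell."""
        from scipy.ndimage import distance_transform_edt

        shell_px = self.config.shell_width_um / self.config.pixel_size_um
        return distance_transform_edt(~self.lumen_mask(i)) <= shell_px

    def analytic_window_trace(self, i: int) -> np.ndarray:
        """Noise/bleach/blur-free window-mean time course of segment ``i``.

        Piecewise: flat baseline, linear fill ramp of height ΔI (the
        window fill step), then linear leak with slope P·ΔI·2/r.
        """
        cfg = self.config
        t = cfg.times_s
        window = self.window_mask(i)
        n_win = int(window.sum())
        n_lum = int(self.lumen_mask(i).sum())
        delta_i = cfg.lumen_plateau * n_lum / n_win
        arrival = self.arrival_time_s[i]
        t_fill = arrival + cfg.fill_rise_s
        g = _fill_fraction(t, arrival, cfg.fill_rise_s)
        slope = self.p_true_um_s[i] * delta_i * 2.0 / self.tubes[i].radius_um
        leak = slope * np.clip(t - t_fill, 0.0, None)
        return cfg.background + delta_i * g + leak

    def to_frame(self):
        """Segment-level truth as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "segment_id": [t.segment_id for t in self.tubes],
                "radius_um": [t.radius_um for t in self.tubes],
                "P_true_um_s": self.p_true_um_s,
                "arrival_time_s": self.arrival_time_s,
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# geometry


def _segment_segment_distance(a0, a1, b0, b1) -> float:
    """Minimum distance between two 2D line segments."""
    # project all four endpoints; handle degenerate (point) segments
    def point_seg(p, q0, q1):
        d = q1 - q0
        denom = float(d @ d)
        if denom == 0.0:
            return float(np.linalg.norm(p - q0))
        s = np.clip((p - q0) @ d / denom, 0.0, 1.0)
        return float(np.linalg.norm(p - (q0 + s * d)))

    if _segments_intersect(a0, a1, b0, b1):
        return 0.0
    return min(
        point_seg(a0, b0, b1),
        point_seg(a1, b0, b1),
        point_seg(b0, a0, a1),
        point_seg(b1, a0, a1),
    )


def _segments_intersect(a0, a1, b0, b1) -> bool:
    def cross(o, p, q):
        return (p[0] - o[0]) * (q[1] - o[1]) - (p[1] - o[1]) * (q[0] - o[0])

    d1 = cross(b0, b1, a0)
    d2 = cross(b0, b1, a1)
    d3 = cross(a0, a1, b0)
    d4 = cross(a0, a1, b1)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def _paint_tube(mask: np.ndarray, tube: TubeGeometry, value: int, outer_px: float, inner_px: float = -1.0) -> None:
    """Set pixels with inner < dist(centerline) <= outer to ``value``.

    Pixels already claimed by another tube (nonzero) are left untouched.
    """
    h, w = mask.shape
    p0, p1 = tube.p0, tube.p1
    rmax = outer_px + 1.5
    r0 = max(int(np.floor(min(p0[0], p1[0]) - rmax)), 0)
    r1 = min(int(np.ceil(max(p0[0], p1[0]) + rmax)), h - 1)
    c0 = max(int(np.floor(min(p0[1], p1[1]) - rmax)), 0)
    c1 = min(int(np.ceil(max(p0[1], p1[1]) + rmax)), w - 1)
    rows, cols = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    pts = np.stack([rows, cols], axis=-1).astype(float)
    d = p1 - p0
    denom = float(d @ d)
    if denom == 0.0:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        s = np.clip((pts - p0) @ d / denom, 0.0, 1.0)
        proj = p0 + s[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
    sel = (dist <= outer_px) & (dist > inner_px)
    view = mask[r0 : r1 + 1, c0 : c1 + 1]
    sel &= view == 0
    view[sel] = value


def generate_network(
    config: PhantomConfig,
    *,
    max_tries: int = 500,
) -> tuple[list[TubeGeometry], np.ndarray]:
    """Place non-overlapping straight tubes inside the chamber circle.

    Returns the tube geometries and an integer lumen label mask
    (0 = background, ``i+1`` = lumen of tube ``i``). Deterministic for a
    fixed config (including its seed).

    Raises
    ------
    PlacementError
        If a tube cannot be placed after ``max_tries`` rejection-sampling
        attempts; the requested density is too high for the chamber.
    """
    rng = np.random.default_rng([config.seed, 0])
    h, w = config.grid_shape
    mask = np.zeros((h, w), dtype=np.int32)
    if config.n_segments == 0:
        return [], mask

    px = config.pixel_size_um
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    chamber_r_px = config.chamber_diameter_um / 2.0 / px
    shell_px = config.shell_width_um / px
    rmin, rmax_r = config.radius_range_um
    tubes: list[TubeGeometry] = []

    for i in range(config.n_segments):
        placed = False
        for _ in range(max_tries):
            radius_um = float(rng.uniform(rmin, rmax_r))
            radius_px = radius_um / px
            # tube length: a sizeable fraction of the chamber so every
            # segment clears the minimum-length filter downstream
            length_px = float(rng.uniform(0.25, 0.45)) * 2 * chamber_r_px
            theta = float(rng.uniform(0, np.pi))
            u = np.array([np.sin(theta), np.cos(theta)])
            # midpoint anywhere that keeps the whole window inside the chamber
            margin = radius_px + shell_px + 2.0
            max_c = chamber_r_px - margin - length_px / 2.0
            if max_c <= 0:
                continue
            rho = np.sqrt(rng.uniform(0, 1)) * max_c
            phi = rng.uniform(0, 2 * np.pi)
            mid = center + rho * np.array([np.sin(phi), np.cos(phi)])
            p0 = mid - u * length_px / 2.0
            p1 = mid + u * length_px / 2.0
            if max(np.linalg.norm(p0 - center), np.linalg.norm(p1 - center)) > chamber_r_px - margin:
                continue
            ok = True
            for t in tubes:
                gap = _segment_segment_distance(p0, p1, t.p0, t.p1)
                if gap < radius_px + t.radius_px + 2 * shell_px + 2.0:
                    ok = False
                    break
            if ok:
                tube = TubeGeometry(i, p0, p1, radius_um, radius_px)
                tubes.append(tube)
                _paint_tube(mask, tube, i + 1, outer_px=radius_px)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place segment {i} after {max_tries} tries: "
                f"n_segments={config.n_segments} with radii up to "
                f"{rmax_r} um and shell {config.shell_width_um} um is too "
                f"dense for a {config.chamber_diameter_um} um chamber"
            )
    return tubes, mask


# ---------------------------------------------------------------------------
# dye transport


def _fill_fraction(t: np.ndarray, arrival_s: float, rise_s: float) -> np.ndarray:
    """Lumen fill fraction: linear ramp from arrival to arrival+rise."""
    t = np.asarray(t, dtype=float)
    if rise_s == 0.0:
        return (t > arrival_s).astype(float)
    return np.clip((t - arrival_s) / rise_s, 0.0, 1.0)


def simulate_timelapse(
    network: tuple[list[TubeGeometry], np.ndarray],
    config: PhantomConfig,
) -> tuple[ImageStack, GroundTruth]:
    """Render the dye-transport time-lapse for a generated network.

    Lumen pixels ramp from ``background`` to ``background+lumen_plateau``
    over ``fill_rise_s`` starting at the dye arrival time. After filling,
    dye is deposited in a thin perivascular band at the constant total
    rate ``P_true * (2/r) * lumen_plateau * n_lumen_px`` per second, so
    that the mean of any window containing lumen + band rises with slope
    ``P_true * delta_I * 2 / r`` where ``delta_I`` is that window's fill
    step — the exact inverse of the permeability estimator. Optional
    Gaussian halo blur and global mono-exponential bleaching are applied
    before additive Gaussian noise.
    """
    tubes, label_mask = network
    cfg = config
    t = cfg.times_s
    h, w = label_mask.shape
    p_true = cfg.permeability_per_segment()[: len(tubes)]
    arrivals = cfg.arrival_per_segment()[: len(tubes)]

    band_mask = np.zeros_like(label_mask)
    band_px = cfg.leak_band_um / cfg.pixel_size_um
    for tube in tubes:
        _paint_tube(
            band_mask, tube, tube.segment_id + 1,
            outer_px=tube.radius_px + band_px, inner_px=tube.radius_px,
        )
    band_mask[label_mask > 0] = 0

    # per-band-pixel deposition rate (intensity/s)
    rate_px = np.zeros(len(tubes))
    t_fill = arrivals + cfg.fill_rise_s
    for i, tube in enumerate(tubes):
        n_lum = int((label_mask == i + 1).sum())
        n_band = int((band_mask == i + 1).sum())
        if n_band == 0:
            raise PlacementError(f"segment {i} has an empty leak band")
        total_rate = p_true[i] * (2.0 / tube.radius_um) * cfg.lumen_plateau * n_lum
        rate_px[i] = total_rate / n_band

    # refuse configurations that saturate the camera
    if len(tubes):
        peak = cfg.background + cfg.lumen_plateau + float(
            np.max(rate_px * np.clip(t[-1] - t_fill, 0.0, None))
        )
        if peak > cfg.max_intensity:
            raise IntensityRangeError(
                f"leaked intensity reaches {peak:.0f} > max_intensity "
                f"{cfg.max_intensity:.0f}; shorten duration_s or reduce "
                "true_permeability_um_s"
            )

    lumen_step = np.where(label_mask > 0, cfg.lumen_plateau, 0.0).astype(np.float32)
    rate_img = np.zeros((h, w), dtype=np.float32)
    for i in range(len(tubes)):
        rate_img[band_mask == i + 1] = rate_px[i]
    sigma_px = cfg.diffusion_sigma_um / cfg.pixel_size_um
    rng = np.random.default_rng([cfg.seed, 1])
    simultaneous = len(tubes) == 0 or np.ptp(arrivals) == 0.0

    if simultaneous and sigma_px == 0 and cfg.bleach_rate_per_s == 0:
        # fast path: only lumen/band pixels vary, as rank-1 products in time
        frames = np.full((cfg.n_frames, h, w), cfg.background, dtype=np.float32)
        if len(tubes):
            g = _fill_fraction(t, arrivals[0], cfg.fill_rise_s).astype(np.float32)
            lt = np.clip(t - t_fill[0], 0.0, None).astype(np.float32)
            rows, cols = np.nonzero((lumen_step > 0) | (rate_img > 0))
            vals = np.multiply.outer(g, lumen_step[rows, cols])
            vals += np.multiply.outer(lt, rate_img[rows, cols])
            frames[:, rows, cols] += vals
    else:
        frames = np.empty((cfg.n_frames, h, w), dtype=np.float32)
        for k, tk in enumerate(t):
            frame = np.full((h, w), cfg.background, dtype=np.float32)
            leak = np.zeros((h, w), dtype=np.float32)
            for i, tube in enumerate(tubes):
                g = float(_fill_fraction(np.array([tk]), arrivals[i], cfg.fill_rise_s)[0])
                if g:
                    frame[label_mask == i + 1] += np.float32(g * cfg.lumen_plateau)
                dt_leak = max(0.0, tk - t_fill[i])
                if dt_leak > 0.0:
                    sel = band_mask == i + 1
                    leak[sel] += np.float32(rate_px[i] * dt_leak)
            if sigma_px > 0 and leak.any():
                leak = gaussian_filter(leak, sigma_px)
            frame += leak
            if cfg.bleach_rate_per_s > 0:
                frame *= np.float32(np.exp(-cfg.bleach_rate_per_s * tk))
            frames[k] = frame
    if cfg.noise_sd > 0:
        noise = rng.standard_normal(frames.shape, dtype=np.float32)
        noise *= np.float32(cfg.noise_sd)
        frames += noise
    np.clip(frames, 0.0, None, out=frames)

    stack = ImageStack(frames, cfg.pixel_size_um, cfg.frame_interval_s)
    truth = GroundTruth(cfg, tubes, label_mask, band_mask, p_true, arrivals)
    return stack, truth


def simulate_experiment(config: PhantomConfig) -> tuple[ImageStack, GroundTruth]:
    """Generate geometry and render its time-lapse in one call."""
    return simulate_timelapse(generate_network(config), config)
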