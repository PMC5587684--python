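"""Per-segment permeability estimation and hierarchical aggregation.

The wall permeability of a cylindrical vessel segment is estimated from
the time course of the mean intensity over its measurement window
(lumen + perivascular shell) as

    P = (1/ΔI) · (dI/dt) · (r/2)

where ΔI is the initial intensity increase when the dye fills the lumen
(the window fill step), dI/dt the subsequent slow rise of the window
mean as dye crosses the wall, and r the segment radius. Units: with r
in µm and time in s, P is in µm/s (also reported in cm/s).

Segments are the measurement unit; chips average their segments and
samples average their chips, mirroring the assay's evaluation hierarchy
(five to seven segments per chip, two to six chips per sample).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .phantom import ImageStack
from .segmentation import VesselSegment

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityTrace",
    "PermeabilityRecord",
    "NoPerfusionError",
    "UnanalyzableSegmentError",
    "extract_trace",
    "detect_arrival",
    "estimate_delta_i",
    "estimate_slope",
    "compute_permeability",
    "analyze_segment",
    "analyze_stack",
    "aggregate",
]


class NoPerfusionError(RuntimeError):
    """No dye arrival detected in the trace."""


class UnanalyzableSegmentError(RuntimeError):
    """The trace cannot yield a permeability estimate (e.g. ΔI <= 0)."""


@dataclass
class IntensityTrace:
    """Window-mean time course of one segment, with fit annotations."""

    segment_id: str
    times_s: np.ndarray
    window_mean: np.ndarray
    baseline: float = np.nan
    arrival_frame: int = -1
    plateau_frame: int = -1
    delta_i: float = np.nan
    slope: float = np.nan
    fit_window: tuple[int, int] = (-1, -1)
    fit_r2: float = np.nan
    flags: list[str] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.window_mean)


def extract_trace(stack: ImageStack, segment: VesselSegment) -> IntensityTrace:
    """Window-mean intensity per frame for one segment.

    The baseline is filled in by :func:`detect_arrival`; here only the
    raw trace is computed.
    """
    if stack.n_frames < 3:
        raise ValueError("need at least 3 frames to build a trace")
    mask = segment.window_mask
    if mask.shape != stack.frames.shape[1:]:
        raise ValueError("window mask does not match stack geometry")
    if not mask.any():
        raise ValueError("empty window mask")
    window_mean = stack.frames[:, mask].mean(axis=1).astype(float)
    return IntensityTrace(
        segment_id=segment.segment_id,
        times_s=stack.times_s.astype(float),
        window_mean=window_mean,
    )


def detect_arrival(
    trace: IntensityTrace,
    *,
    k: float = 5.0,
    baseline_frames: int = 3,
    plateau_frac: float = 0.1,
) -> tuple[int, int]:
    """Locate the dye arrival frame and the end of lumen filling.

    Arrival is the first frame whose window mean exceeds
    ``baseline + k·sd`` (baseline and noise sd from the first
    ``baseline_frames`` frames) *and stays above it for the rest of the
    recording*: dye that has filled the lumen does not leave, so a
    sustained crossing is required. This suppresses false triggers from
    the short-baseline noise estimate, which has too few degrees of
    freedom to be trusted on its own.

    The plateau (fill complete) is the first frame after arrival whose
    frame-to-frame increase, in excess of the eventual leak slope, drops
    below ``plateau_frac`` of the largest excess increase of the fill
    phase. Measuring increments in excess of a robust tail-slope
    estimate keeps the rule valid when the leak itself is steep; with a
    flat tail it reduces to the plain fraction-of-maximum rule.

    Updates the trace in place and returns ``(arrival, plateau)``.
    """
    m = trace.window_mean
    n = len(m)
    if n < 5:
        raise ValueError("need at least 5 frames to detect arrival")
    b = min(baseline_frames, n - 2)
    baseline = float(np.mean(m[:b]))
    sd = float(np.std(m[:b], ddof=1)) if b > 1 else 0.0
    eps = 1e-12 + 1e-9 * abs(baseline)
    thresh = baseline + k * max(sd, eps)

    above = m > thresh
    # suffix_all[i]: trace stays above threshold from frame i onward
    suffix_all = np.logical_and.accumulate(above[::-1])[::-1]
    arrival = -1
    for i in range(b, n):
        if suffix_all[i]:
            arrival = i
            break
    if arrival < 0:
        raise NoPerfusionError("no perfusion detected: trace never crosses the arrival threshold")

    d = np.diff(m)  # d[i] = m[i+1] - m[i]
    post = d[arrival - 1 :]  # increments from the arrival jump onward
    tail_start = max(1, len(post) // 2)
    tail_slope = float(np.median(post[tail_start:])) if len(post) > tail_start else 0.0
    excess = post - tail_slope
    d_max = float(np.max(excess))
    plateau = -1
    if d_max <= 0:
        plateau = arrival + 1
    else:
        for j in range(arrival + 1, n):
            if excess[j - arrival] < plateau_frac * d_max:
                plateau = j
                break
    if plateau < 0 or plateau >= n:
        raise NoPerfusionError("lumen filling never plateaus within the recording")

    trace.baseline = baseline
    trace.arrival_frame = arrival
    trace.plateau_frame = plateau
    return arrival, plateau


def _post_plateau_fit(trace: IntensityTrace, settle: int) -> tuple[float, float, float, tuple[int, int]]:
    """OLS fit of window mean vs time over frames strictly after
    ``plateau_frame + settle``; returns (slope, intercept, r2, window)."""
    start = trace.plateau_frame + settle + 1
    end = trace.n_frames - 1
    n_fit = end - start + 1
    if n_fit < 3:
        raise UnanalyzableSegmentError(
            f"only {max(n_fit, 0)} frames after plateau+settle; need at least 3"
        )
    t = trace.times_s[start:]
    y = trace.window_mean[start:]
    res = sps.linregress(t, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), (start, end)


def estimate_delta_i(
    trace: IntensityTrace,
    *,
    m_frames: int = 3,
    settle: int = 2,
) -> float:
    """ΔI, the window fill step.

    The mean of the first ``m_frames`` frames after the plateau is taken
    with the post-plateau leak slope removed — each value is corrected by
    extrapolating the post-plateau linear fit back to the fill time —
    and the baseline subtracted. The extrapolation anchor is the
    midpoint between the last pre-arrival frame and the arrival frame:
    leaked dye is zero there, so ΔI reflects the fill step only (the
    anchor is unbiased when lumen filling completes within about one
    frame interval).
    """
    if trace.arrival_frame < 0 or trace.plateau_frame < 0:
        raise ValueError("run detect_arrival first")
    slope, _, _, _ = _post_plateau_fit(trace, settle)
    a = trace.arrival_frame
    t = trace.times_s
    t0 = 0.5 * (t[a - 1] + t[a]) if a >= 1 else t[0]
    idx = np.arange(trace.plateau_frame + 1, min(trace.plateau_frame + 1 + m_frames, trace.n_frames))
    if len(idx) == 0:
        raise UnanalyzableSegmentError("no frames after plateau to estimate delta_I")
    corrected = trace.window_mean[idx] - slope * (t[idx] - t0)
    delta_i = float(np.mean(corrected) - trace.baseline)
    if delta_i <= 0:
        trace.flags.append("delta_I<=0")
        raise UnanalyzableSegmentError(
            f"delta_I = {delta_i:.3g} <= 0; segment excluded as unanalyzable"
        )
    trace.delta_i = delta_i
    return delta_i


def estimate_slope(
    trace: IntensityTrace,
    *,
    settle: int = 2,
    background_trace: np.ndarray | None = None,
) -> float:
    """dI/dt, the post-fill leak slope of the window mean (OLS).

    If ``background_trace`` (the mean of a vessel-free region per frame)
    is given, a mono-exponential bleach factor is fitted to it and the
    window trace is divided by that factor before fitting.
    """
    if trace.plateau_frame < 0:
        raise ValueError("run detect_arrival first")
    if background_trace is not None:
        bg = np.asarray(background_trace, dtype=float)
        if len(bg) != trace.n_frames or np.any(bg <= 0):
            raise ValueError("background trace must be positive and match the stack length")
        lam = -sps.linregress(trace.times_s, np.log(bg)).slope
        trace.window_mean = trace.window_mean / np.exp(-lam * trace.times_s)
        trace.flags.append(f"bleach_corrected(lambda={lam:.3g}/s)")
    slope, _, r2, window = _post_plateau_fit(trace, settle)
    trace.slope = slope
    trace.fit_r2 = r2
    trace.fit_window = window
    return slope


def compute_permeability(delta_i: float, slope: float, radius_um: float) -> float:
    """P = (1/ΔI)·(dI/dt)·(r/2), in µm/s.

    Negative slopes give negative P; they are retained (not clipped) so
    that group statistics remain unbiased, and flagged downstream.
    """
    if delta_i <= 0:
        raise ValueError("delta_I must be > 0")
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    return slope / delta_i * radius_um / 2.0


@dataclass
class PermeabilityRecord:
    """Per-segment estimate with lineage for hierarchical aggregation."""

    segment_id: str
    chip_id: str
    sample_id: str
    condition: str
    matched_pair_id: str
    radius_um: float
    delta_i: float
    slope: float
    p_um_s: float
    fit_r2: float
    flags: str = ""

    @property
    def p_cm_s(self) -> float:
        return self.p_um_s * 1e-4


def analyze_segment(
    stack: ImageStack,
    segment: VesselSegment,
    *,
    sample_id: str = "",
    condition: str = "",
    matched_pair_id: str = "",
    background_trace: np.ndarray | None = None,
    **detect_kwargs,
) -> PermeabilityRecord:
    """Full trace → ΔI, dI/dt, P pipeline for one segment."""
    trace = extract_trace(stack, segment)
    detect_arrival(trace, **detect_kwargs)
    estimate_slope(trace, background_trace=background_trace)
    estimate_delta_i(trace)
    p = compute_permeability(trace.delta_i, trace.slope, segment.radius_um)
    flags = list(trace.flags)
    if p < 0:
        flags.append("negative_P")
    return PermeabilityRecord(
        segment_id=segment.segment_id,
        chip_id=segment.chip_id,
        sample_id=sample_id,
        condition=condition,
        matched_pair_id=matched_pair_id,
        radius_um=segment.radius_um,
        delta_i=trace.delta_i,
        slope=trace.slope,
        p_um_s=p,
        fit_r2=trace.fit_r2,
        flags=";".join(flags),
    )


def analyze_stack(
    stack: ImageStack,
    segments: list[VesselSegment],
    **kwargs,
) -> pd.DataFrame:
    """Per-segment permeability table for one stack; unanalyzable
    segments are excluded with a log entry."""
    records = []
    for seg in segments:
        try:
            records.append(analyze_segment(stack, seg, **kwargs))
        except (UnanalyzableSegmentError, NoPerfusionError) as exc:
            logger.warning("segment %s excluded: %s", seg.segment_id, exc)
    return records_to_frame(records)


def records_to_frame(records: list[PermeabilityRecord]) -> pd.DataFrame:
    cols = [
        "segment_id", "chip_id", "sample_id", "condition", "matched_pair_id",
        "radius_um", "delta_i", "slope", "p_um_s", "p_cm_s", "fit_r2", "flags",
    ]
    rows = [
        {c: getattr(r, c) for c in cols}
        for r in records
    ]
    return pd.DataFrame(rows, columns=cols)


def aggregate(
    records: pd.DataFrame,
    level: str,
    *,
    min_segments: int = 3,
    method: str = "mean",
) -> pd.DataFrame:
    """Aggregate segment records to chip or sample level.

    A chip's value is the mean of its segments' P; a sample's value is
    the mean of its chip values. Chips with fewer than ``min_segments``
    analyzable segments are flagged (``low_n``). ``method='median'``
    swaps the mean for a median at both levels.
    """
    if level not in ("chip", "sample"):
        raise ValueError(f"unknown aggregation level {level!r}; use 'chip' or 'sample'")
    if method not in ("mean", "median"):
        raise ValueError(f"unknown method {method!r}")
    agg = "mean" if method == "mean" else "median"
    meta_cols = [c for c in ("sample_id", "condition", "matched_pair_id") if c in records.columns]

    by_chip = (
        records.groupby(["chip_id"] + meta_cols, sort=False, as_index=False)
        .agg(p_um_s=("p_um_s", agg), n_segments=("segment_id", "count"))
    )
    by_chip["low_n"] = by_chip["n_segments"] < min_segments
    if level == "chip":
        by_chip["p_cm_s"] = by_chip["p_um_s"] * 1e-4
        return by_chip

    sample_meta = [c for c in ("condition", "matched_pair_id") if c in by_chip.columns]
    by_sample = (
        by_chip.groupby(["sample_id"] + sample_meta, sort=False, as_index=False)
        .agg(p_um_s=("p_um_s", agg), n_chips=("chip_id", "count"), n_segments=("n_segments", "sum"))
    )
    by_sample["p_cm_s"] = by_sample["p_um_s"] * 1e-4
    return by_sample
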