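"""Ancillary quantifications: region mean intensity, geometric MFI,
and 2^-ΔΔCT relative expression.

These are the study's companion readouts to the permeability assay:
mean immunofluorescence intensity over a fixed 1.5 mm × 1.5 mm region
per well, geometric mean fluorescence intensity (MFI) of a flow-style
event population, and qPCR relative quantification normalized to three
internal reference genes and a calibrator sample (defined as 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MFIResult",
    "mean_region_intensity",
    "geometric_mfi",
    "relative_expression",
]


def mean_region_intensity(
    image: np.ndarray,
    region_center: tuple[float, float],
    pixel_size_um: float,
    region_size_um: float = 1500.0,
) -> float:
    """Arithmetic mean intensity over an axis-aligned square region.

    ``region_center`` is (row, col) in pixels; the square has side
    ``region_size_um`` (default the assay's 1.5 mm quantification area).
    Raises ``ValueError`` if the region does not fit inside the image.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a single 2D image")
    side_px = int(round(region_size_um / pixel_size_um))
    if side_px < 1:
        raise ValueError("region smaller than one pixel")
    r0 = int(round(region_center[0] - side_px / 2))
    c0 = int(round(region_center[1] - side_px / 2))
    r1, c1 = r0 + side_px, c0 + side_px
    if r0 < 0 or c0 < 0 or r1 > image.shape[0] or c1 > image.shape[1]:
        raise ValueError(
            f"{region_size_um} um region at {region_center} exceeds image bounds {image.shape}"
        )
    return float(image[r0:r1, c0:c1].mean())


@dataclass
class MFIResult:
    mfi: float
    n_events: int
    n_excluded: int  # non-positive intensities, excluded from the geometric mean


def geometric_mfi(events: pd.DataFrame, channel: str) -> MFIResult:
    """Geometric mean fluorescence intensity of one channel.

    ``exp(mean(ln(x)))`` over events with positive intensity; events
    with non-positive values are excluded (FlowJo-compatible) and their
    count reported.
    """
    if channel not in events.columns:
        raise KeyError(f"channel {channel!r} not in event table")
    x = np.asarray(events[channel], dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("event intensities must be finite")
    pos = x[x > 0]
    n_excluded = len(x) - len(pos)
    if n_excluded:
        logger.info("geometric_mfi: excluded %d non-positive events in %s", n_excluded, channel)
    if len(pos) == 0:
        raise ValueError(f"no positive events in channel {channel!r}")
    return MFIResult(float(np.exp(np.mean(np.log(pos)))), len(pos), n_excluded)


def relative_expression(
    ct: pd.DataFrame,
    reference_genes: list[str],
    calibrator: str,
    *,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Relative expression by the 2^-ΔΔCT method with 3 reference genes.

    Replicate Cts are averaged per (sample, gene); ΔCt is the gene Ct
    minus the arithmetic mean of the three reference-gene Cts of the
    same sample (equivalently, normalization to the geometric mean of
    their linear quantities); ΔΔCt subtracts the calibrator sample's
    ΔCt, and RQ = efficiency^(-ΔΔCt) with efficiency 2 (100% primer
    efficiency) by default. The calibrator's RQ is 1 for every gene.

    Samples missing any reference-gene Ct get null RQs with a logged
    reason.

    Parameters
    ----------
    ct
        Long table with columns ``sample_id``, ``gene_id``, ``ct`` (an
        optional ``replicate`` column is allowed and averaged over).
    """
    required = {"sample_id", "gene_id", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if len(set(reference_genes)) != 3:
        raise ValueError("exactly 3 distinct reference genes are required")
    if not np.all(np.isfinite(ct["ct"])):
        raise ValueError("Ct values must be finite")

    mean_ct = ct.groupby(["sample_id", "gene_id"], sort=False)["ct"].mean().unstack()
    if calibrator not in mean_ct.index:
        raise ValueError(f"calibrator sample {calibrator!r} not in table")
    missing_refs = [g for g in reference_genes if g not in mean_ct.columns]
    if missing_refs:
        raise ValueError(f"reference genes {missing_refs} absent from table")

    ref_mean = mean_ct[list(reference_genes)].mean(axis=1)
    incomplete = mean_ct[list(reference_genes)].isna().any(axis=1)
    for s in mean_ct.index[incomplete]:
        logger.warning("sample %s lacks a reference-gene Ct; RQs set to null", s)
    ref_mean[incomplete] = np.nan
    if incomplete.loc[calibrator]:
        raise ValueError(f"calibrator {calibrator!r} lacks a reference-gene Ct")

    dct = mean_ct.sub(ref_mean, axis=0)
    ddct = dct.sub(dct.loc[calibrator], axis=1)
    rq = np.power(float(efficiency), -ddct)

    out = rq.stack().rename("rq").reset_index()
    out = out.merge(
        ddct.stack().rename("ddct").reset_index(), on=["sample_id", "gene_id"], how="left"
    )
    # re-insert null rows for incomplete samples
    if incomplete.any():
        null_rows = [
            {"sample_id": s, "gene_id": g, "rq": np.nan, "ddct": np.nan}
            for s in mean_ct.index[incomplete]
            for g in mean_ct.columns
        ]
        out = pd.concat([out, pd.DataFrame(null_rows)], ignore_index=True)
    return out.sort_values(["sample_id", "gene_id"]).reset_index(drop=True)
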