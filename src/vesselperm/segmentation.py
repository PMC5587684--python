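"""Vessel segment extraction from perfusion time-lapse stacks.

Turns an image stack into the assay's evaluation units: branch-free
cylindrical segments with a centerline, a radius, and a measurement
window (lumen + perivascular shell). The lumen is thresholded on a
median of post-arrival reference frames, skeletonized, and split at
branch points; each surviving branch becomes one candidate segment.
The assay evaluates five to seven segments per chip, so retention is
capped (longest first) at a configurable maximum, default 7.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize
from skimage.segmentation import watershed

from .phantom import ImageStack

logger = logging.getLogger(__name__)

__all__ = [
    "VesselSegment",
    "SegmentationError",
    "choose_reference_frames",
    "segment_lumen",
    "extract_segments",
    "segments_to_frame",
]


class SegmentationError(ValueError):
    """Lumen segmentation failed (no foreground, or implausible coverage)."""


@dataclass
class VesselSegment:
    """One cylindrical vessel segment.

    ``centerline`` is an ordered (N, 2) array of 0-based (row, col)
    skeleton pixel coordinates. ``window_mask`` is the lumen dilated by
    the perivascular shell; window masks of retained segments are
    pairwise disjoint.
    """

    segment_id: str
    centerline: np.ndarray
    radius_um: float
    length_um: float
    lumen_mask: np.ndarray
    window_mask: np.ndarray
    chip_id: str = ""

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius_um must be > 0")


def choose_reference_frames(stack: ImageStack, n_ref: int = 1) -> tuple[int, int]:
    """Pick reference frames just after dye arrival.

    The lumen must be segmented while vessels are filled but leaked dye
    is still dim, so the best reference is the first frame after the
    fill transient: at high permeability the perivascular band brightens
    within a frame or two of filling and would otherwise be absorbed
    into the lumen mask. The global mean-intensity trace jumps when the
    dye front floods the lumens; the frame(s) immediately after its
    largest frame-to-frame jump are returned as a half-open range.
    """
    if stack.n_frames < 3:
        raise ValueError("need at least 3 frames")
    trace = stack.frames.mean(axis=(1, 2))
    jump = int(np.argmax(np.diff(trace))) + 1
    start = min(jump, stack.n_frames - 1)
    stop = min(start + n_ref, stack.n_frames)
    return (start, stop)


def segment_lumen(
    stack: ImageStack,
    reference_frames: tuple[int, int],
    *,
    min_object_px: int = 64,
) -> np.ndarray:
    """Binary perfused-lumen mask from post-arrival reference frames.

    The median of ``reference_frames`` (a half-open ``(start, stop)``
    frame range chosen after dye arrival, while leak is still small) is
    thresholded with Otsu's method, then objects below ``min_object_px``
    pixels are removed. The result is invariant to a constant intensity
    offset.

    Raises
    ------
    SegmentationError
        If no foreground survives (failed perfusion / blank stack) or
        the foreground covers more than half the field (mis-set
        reference frames or flooded chamber).
    """
    start, stop = reference_frames
    if not (0 <= start < stop <= stack.n_frames):
        raise ValueError(f"reference_frames {reference_frames} outside stack of {stack.n_frames} frames")
    ref = np.median(stack.frames[start:stop], axis=0)
    if np.ptp(ref) == 0:
        raise SegmentationError("no vessel foreground: reference image is constant")
    thr = threshold_otsu(ref)
    mask = ref > thr
    # a real lumen is far brighter than the background spread; pure
    # noise split at its own middle is not (separation ~1.6 sd)
    fg, bg = ref[mask], ref[~mask]
    if fg.size and bg.size:
        if fg.mean() - bg.mean() < 4.0 * bg.std():
            raise SegmentationError(
                "no vessel foreground: threshold separation is "
                "indistinguishable from noise"
            )
    # drop speckle below the minimum object size; 4-connectivity keeps
    # percolating noise from merging into one giant pseudo-object
    labels, n_obj = ndimage.label(mask)
    if n_obj:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_object_px)
        mask[np.isin(labels, small[small > 0])] = False
    frac = mask.mean()
    if not mask.any():
        raise SegmentationError("no vessel foreground after thresholding")
    if frac > 0.5:
        raise SegmentationError(
            f"foreground covers {frac:.0%} of the field; check reference "
            "frames (dye not yet arrived, or chamber flooded)"
        )
    return mask


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])

# circular order of the 8 neighbors for crossing-number computation
_RING = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _branch_count(skel: np.ndarray) -> np.ndarray:
    """Number of distinct skeleton branches meeting at each pixel.

    Counts runs of occupied neighbors around the 8-neighborhood ring;
    unlike the raw neighbor count this does not flag sharp corners of a
    simple 8-connected path as junctions.
    """
    padded = np.pad(skel, 1).astype(np.int8)
    rings = np.stack(
        [padded[1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc]
         for dr, dc in _RING]
    )
    nxt = np.roll(rings, -1, axis=0)
    return ((rings == 1) & (nxt == 0)).sum(axis=0)


def _order_branch(coords: np.ndarray) -> np.ndarray:
    """Order the pixels of a simple skeleton branch into a polyline."""
    if len(coords) <= 2:
        return coords
    coord_set = {tuple(c) for c in coords}
    # adjacency under 8-connectivity
    nbrs: dict[tuple[int, int], list[tuple[int, int]]] = {c: [] for c in coord_set}
    for r, c in coord_set:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                q = (r + dr, c + dc)
                if q in coord_set:
                    nbrs[(r, c)].append(q)
    ends = [c for c, n in nbrs.items() if len(n) <= 1]
    start = ends[0] if ends else min(coord_set)  # loops: arbitrary start
    path = [start]
    seen = {start}
    while True:
        nxt = [q for q in nbrs[path[-1]] if q not in seen]
        if not nxt:
            break
        # prefer 4-connected continuation for a tighter polyline
        nxt.sort(key=lambda q: abs(q[0] - path[-1][0]) + abs(q[1] - path[-1][1]))
        path.append(nxt[0])
        seen.add(nxt[0])
    if len(path) < len(coords):  # disconnected leftovers; keep walked part
        logger.debug("branch ordering kept %d of %d pixels", len(path), len(coords))
    return np.array(path)


def _prune_spurs(skel: np.ndarray, edt: np.ndarray, max_iter: int = 10) -> np.ndarray:
    """Remove short leaf branches ("spurs") produced by boundary noise.

    A leaf branch attached to a junction whose length is on the order of
    the local vessel radius is a skeletonization artifact, not a vessel:
    pruning it lets the flanking pieces of the true centerline rejoin.
    Branches with two free endpoints (whole isolated vessels) are never
    pruned.
    """
    skel = skel.copy()
    for _ in range(max_iter):
        runs = _branch_count(skel)
        junctions = skel & (runs >= 3)
        if not junctions.any():
            break
        nbr = ndimage.convolve(skel.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant")
        branches = skel & ~junctions
        labels, n_labels = ndimage.label(branches, structure=np.ones((3, 3), dtype=int))
        grown = ndimage.grey_dilation(labels, size=3)
        junction_adjacent = set(np.unique(grown[junctions])) - {0}
        endpoint_labels = set(np.unique(labels[skel & (nbr == 1)])) - {0}
        removed = False
        for lab in endpoint_labels & junction_adjacent:
            coords = np.argwhere(labels == lab)
            local_r = float(edt[coords[:, 0], coords[:, 1]].max())
            if len(coords) <= 1.5 * local_r + 2:
                skel[coords[:, 0], coords[:, 1]] = False
                removed = True
        if not removed:
            break
    return skel


def _polyline_length_px(path: np.ndarray) -> float:
    if len(path) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(path, axis=0), axis=1).sum())


def extract_segments(
    lumen_mask: np.ndarray,
    pixel_size_um: float,
    *,
    min_segment_length_um: float = 100.0,
    shell_width_um: float = 25.0,
    max_segments: int = 7,
    chip_id: str = "",
) -> list[VesselSegment]:
    """Split a lumen mask into branch-free cylindrical segments.

    The mask skeleton is cut at branch points; branches shorter than
    ``min_segment_length_um`` are discarded. The radius of a segment is
    the median medial-axis (Euclidean distance transform) value along
    its centerline, less half a pixel of digitization offset, converted
    to µm. Lumen pixels are apportioned to branches by watershed on the
    distance transform, and each window is the branch lumen dilated by
    ``shell_width_um``. Overlapping windows are resolved by keeping the
    longer segment; at most ``max_segments`` (longest first) are
    retained.
    """
    lumen_mask = np.asarray(lumen_mask, dtype=bool)
    if not lumen_mask.any():
        return []
    edt = ndimage.distance_transform_edt(lumen_mask)
    skel = _prune_spurs(skeletonize(lumen_mask), edt)
    branches = skel & (_branch_count(skel) <= 2)
    labels, n_labels = ndimage.label(branches, structure=np.ones((3, 3), dtype=int))
    if n_labels == 0:
        logger.warning("skeleton reduced to branch points only; no segments")
        return []

    # the skeleton can sit up to half a pixel off the true axis; the
    # local EDT ridge restores the on-axis distance
    edt_ridge = ndimage.maximum_filter(edt, size=3)

    candidates = []
    for lab in range(1, n_labels + 1):
        coords = np.argwhere(labels == lab)
        path = _order_branch(coords)
        length_um = _polyline_length_px(path) * pixel_size_um
        if length_um < min_segment_length_um:
            continue
        # the EDT measures to the nearest background pixel *center*,
        # overshooting the true wall by 0..1 px depending on the tube
        # orientation (0 for generic angles, 1 for lattice-aligned);
        # subtracting half a pixel centers that error within half a pixel
        radius_px = float(np.median(edt_ridge[path[:, 0], path[:, 1]])) - 0.5
        if radius_px <= 0:
            continue
        candidates.append((lab, path, length_um, radius_px))

    if not candidates:
        logger.warning(
            "no skeleton branch longer than %.0f um; returning no segments",
            min_segment_length_um,
        )
        return []

    # apportion the full lumen to branches (junction pixels go to the
    # nearest surviving branch basin)
    markers = np.zeros(lumen_mask.shape, dtype=np.int32)
    for lab, path, _, _ in candidates:
        markers[path[:, 0], path[:, 1]] = lab
    basins = watershed(-edt, markers=markers, mask=lumen_mask)

    shell_px = shell_width_um / pixel_size_um

    candidates.sort(key=lambda c: -c[2])  # longest first
    retained: list[VesselSegment] = []
    occupied = np.zeros(lumen_mask.shape, dtype=bool)
    for lab, path, length_um, radius_px in candidates:
        if len(retained) >= max_segments:
            break
        seg_lumen = basins == lab
        # dilation by shell_px via the EDT of the complement
        window = ndimage.distance_transform_edt(~seg_lumen) <= shell_px
        if (window & occupied).any():
            logger.info("dropping segment (window overlap): length %.0f um", length_um)
            continue
        occupied |= window
        retained.append(
            VesselSegment(
                segment_id=f"seg{len(retained):03d}",
                centerline=path,
                radius_um=radius_px * pixel_size_um,
                length_um=length_um,
                lumen_mask=seg_lumen,
                window_mask=window,
                chip_id=chip_id,
            )
        )
    return retained


def segments_to_frame(segments: list[VesselSegment]):
    """Segment table (segment_id, chip_id, radius_um, length_um)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "segment_id": [s.segment_id for s in segments],
            "chip_id": [s.chip_id for s in segments],
            "radius_um": [s.radius_um for s in segments],
            "length_um": [s.length_um for s in segments],
        }
    )
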