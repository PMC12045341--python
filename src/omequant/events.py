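"""Intercellular transfer-event detection and classification.

Trajectory points are assigned to cells via a label image, boundary crossings
between adjacent cells are recorded, and each crossing track is classified as
unidirectional (one boundary, never returning), bidirectional (the particle
returns to a previously visited cell) or serial (two or more distinct
boundaries across three or more cells).  The diffusion of crossing particles
is measured by delegating to the spt MSD machinery, and crossing points are
tested for proximity to receptor foci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.ndimage

from .spt import DiffusionEstimate, Trajectory, diffusion_from_tracks

log = logging.getLogger(__name__)

__all__ = [
    "CellMaskSet",
    "Crossing",
    "TransferEvent",
    "ProximityResult",
    "assign_cells",
    "detect_crossings",
    "event_diffusion",
    "focus_proximity",
]

PROXIMITY_THRESHOLD_UM = 0.320  # two pixels, mirroring the linking gate


@dataclass
class CellMaskSet:
    """Labeled cell raster: 0 = background, positive integers = cells."""

    label_image: np.ndarray
    pixel_size: float = 0.160

    def __post_init__(self) -> None:
        self.label_image = np.asarray(self.label_image)
        if self.label_image.ndim != 2:
            raise ValueError("label image must be 2-D")
        if self.label_image.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def cell_ids(self) -> set[int]:
        return {int(v) for v in np.unique(self.label_image) if v != 0}

    @property
    def adjacency(self) -> set[frozenset[int]]:
        """Pairs of cells whose masks lie within 3 pixels of each other.

        The margin mirrors the gap-bridging rule: a boundary whose ambiguous
        pixels span at most a couple of frames of background still counts as
        shared.
        """
        pairs: set[frozenset[int]] = set()
        lab = self.label_image
        for a in self.cell_ids:
            grown = scipy.ndimage.binary_dilation(lab == a, iterations=3)
            touching = np.unique(lab[grown])
            for b in touching:
                if b != 0 and b != a:
                    pairs.add(frozenset((a, int(b))))
        return pairs


@dataclass
class Crossing:
    frame: int
    from_cell: int
    to_cell: int
    crossing_point: tuple[float, float]  # μm


@dataclass
class TransferEvent:
    track_id: int
    crossings: list[Crossing]
    n_boundaries: int  # number of distinct cell-cell boundaries crossed
    event_type: str  # unidirectional | bidirectional | serial
    D_event: float | None = None

    @property
    def n_crossings(self) -> int:
        return len(self.crossings)


@dataclass
class ProximityResult:
    crossing_point: tuple[float, float]
    nearest_focus_distance: float
    within_threshold: bool
    threshold: float


def assign_cells(track: Trajectory, masks: CellMaskSet) -> np.ndarray:
    """Per-frame cell label for a trajectory (0 = unassigned/background)."""
    h, w = masks.label_image.shape
    px = masks.pixel_size
    cols = np.rint(track.xy[:, 0] / px).astype(int)
    rows = np.rint(track.xy[:, 1] / px).astype(int)
    if (rows < 0).any() or (cols < 0).any() or (rows >= h).any() or (cols >= w).any():
        raise ValueError("trajectory extends outside the mask raster")
    return masks.label_image[rows, cols].astype(int)


def _bridge_gaps(labels: np.ndarray, max_gap: int) -> np.ndarray:
    """Fill runs of <= max_gap unassigned frames with the preceding label.

    Particles sitting on the ambiguous boundary pixels flicker to background;
    bridging short runs avoids double-counted crossings.  Leading unassigned
    frames take the first assigned label if the run is short enough.
    """
    out = labels.copy()
    n = out.size
    i = 0
    while i < n:
        if out[i] == 0:
            j = i
            while j < n and out[j] == 0:
                j += 1
            run = j - i
            if run <= max_gap:
                if i > 0:
                    out[i:j] = out[i - 1]
                elif j < n:
                    out[i:j] = out[j]
            i = j
        else:
            i += 1
    return out


def classify_visits(visited: list[int]) -> str:
    """Event type from the collapsed sequence of visited cells."""
    if len(set(visited)) < len(visited):
        return "bidirectional"
    if len(set(visited)) >= 3:
        return "serial"
    return "unidirectional"


def detect_crossings(
    track: Trajectory,
    masks: CellMaskSet,
    labels: np.ndarray | None = None,
    max_gap: int = 2,
) -> TransferEvent | None:
    """Detect and classify the boundary crossings of one trajectory.

    A crossing is recorded at each frame where the gap-bridged label changes
    between two adjacent cells; its coordinate is the midpoint of the two
    flanking localizations.  A label change between non-adjacent cells is a
    teleport artifact: the track is excluded (returns None with a warning).
    Returns None when no crossing occurs.
    """
    if labels is None:
        labels = assign_cells(track, masks)
    raw = np.asarray(labels, dtype=int)
    lab = _bridge_gaps(raw, max_gap)
    adjacency = masks.adjacency
    crossings: list[Crossing] = []
    prev = 0
    prev_idx = -1
    for i, cur in enumerate(lab):
        if cur == 0:
            continue
        if prev != 0 and cur != prev:
            if i - prev_idx > max_gap + 1:
                # lost in an unbridged background run: no crossing frame or
                # coordinate can be assigned; treat as a tracking break
                prev, prev_idx = int(cur), i
                continue
            if frozenset((int(prev), int(cur))) not in adjacency:
                log.warning("track %d: label jump %d->%d between non-adjacent "
                            "cells at frame %d; excluded as teleport artifact",
                            track.track_id, prev, cur, int(track.frames[i]))
                return None
            mid = 0.5 * (track.xy[i - 1] + track.xy[i])
            crossings.append(Crossing(frame=int(track.frames[i]),
                                      from_cell=int(prev), to_cell=int(cur),
                                      crossing_point=(float(mid[0]), float(mid[1]))))
        prev, prev_idx = int(cur), i
    if not crossings:
        return None
    visited = [crossings[0].from_cell] + [c.to_cell for c in crossings]
    boundaries = {frozenset((c.from_cell, c.to_cell)) for c in crossings}
    return TransferEvent(
        track_id=track.track_id,
        crossings=crossings,
        n_boundaries=len(boundaries),
        event_type=classify_visits(visited),
    )


def event_diffusion(
    tracks: list[Trajectory],
    frame_interval: float = 0.015,
    fit_lags: int = 4,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[DiffusionEstimate, list[float]]:
    """Pooled and per-track D of crossing trajectories.

    Pure delegation to the spt MSD pipeline: the pooled estimate treats the
    crossing tracks as one population; the per-track list holds each track's
    own origin-constrained D (clamped at 0).
    """
    pooled = diffusion_from_tracks(tracks, frame_interval=frame_interval,
                                   fit_lags=fit_lags, n_boot=n_boot if len(tracks) > 1 else 0,
                                   seed=seed)
    per_track = []
    for t in tracks:
        est = diffusion_from_tracks([t], frame_interval=frame_interval,
                                    fit_lags=min(fit_lags, t.length - 1), n_boot=0)
        per_track.append(est.D)
    return pooled, per_track


def focus_proximity(
    event: TransferEvent,
    foci: np.ndarray,
    threshold: float = PROXIMITY_THRESHOLD_UM,
) -> list[ProximityResult]:
    """Distance from each crossing point to the nearest receptor focus."""
    foci = np.asarray(foci, dtype=float).reshape(-1, 2)
    if foci.size == 0:
        raise ValueError("need at least one focus position")
    out = []
    for c in event.crossings:
        p = np.asarray(c.crossing_point)
        d = float(np.min(np.hypot(foci[:, 0] - p[0], foci[:, 1] - p[1])))
        out.append(ProximityResult(crossing_point=c.crossing_point,
                                   nearest_focus_distance=d,
                                   within_threshold=d <= threshold,
                                   threshold=threshold))
    return out
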