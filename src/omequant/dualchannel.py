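"""Dual-channel (beam-splitter) focus pairing and stoichiometric ratio.

Two spectrally split half-images view the same foci through a fixed
registration offset.  After registration, each channel-A focus is paired to
its nearest channel-B focus within a tolerance; molecule counts per channel
come from independent photobleach step counting, and the inter-channel
stoichiometry is the zero-intercept least-squares slope of count_B on
count_A (a focus with zero receptor cannot host its partner protein).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RegisteredFocusPair", "RatioFit", "register_and_pair", "fit_ratio"]


@dataclass
class RegisteredFocusPair:
    roi_id: int
    count_A: int
    count_B: int
    pair_distance: float = 0.0  # μm, after registration

    def __post_init__(self) -> None:
        if self.count_A < 1 or self.count_B < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class RatioFit:
    slope: float  # B molecules per A molecule
    n_pairs: int
    residual_sd: float
    ratio_tally: dict[tuple[int, int], int]
    intercept: float = 0.0
    mean_of_ratios: float = 0.0
    total_count_ratio: float = 0.0


def register_and_pair(
    foci_A: np.ndarray,
    foci_B: np.ndarray,
    offset: tuple[float, float] = (0.0, 0.0),
    tolerance: float = 0.320,
) -> tuple[list[tuple[int, int, float]], list[int], list[int]]:
    """Pair channel-A foci with channel-B foci after applying the offset.

    ``offset`` (μm) maps B coordinates into the A frame: candidate pairs with
    registered distance <= tolerance are accepted greedily by ascending
    distance.  Returns (pairs, unpaired_A, unpaired_B) where pairs are
    (index_A, index_B, distance) tuples.
    """
    A = np.asarray(foci_A, dtype=float).reshape(-1, 2)
    B = np.asarray(foci_B, dtype=float).reshape(-1, 2) + np.asarray(offset, dtype=float)
    cand: list[tuple[float, int, int]] = []
    for i, p in enumerate(A):
        d = np.hypot(B[:, 0] - p[0], B[:, 1] - p[1])
        for j in np.nonzero(d <= tolerance)[0]:
            cand.append((float(d[j]), i, int(j)))
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for dist, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j, dist))
    unpaired_a = [i for i in range(len(A)) if i not in used_a]
    unpaired_b = [j for j in range(len(B)) if j not in used_b]
    return pairs, unpaired_a, unpaired_b


def fit_ratio(pairs: list[RegisteredFocusPair], intercept: bool = False) -> RatioFit:
    """Stoichiometric ratio of channel B to channel A across paired foci.

    The primary statistic is the least-squares slope through the origin,
    slope = Σ(a·b)/Σ(a²).  The mean of per-focus ratios and the
    total-count ratio Σb/Σa are reported alongside, and an ordinary
    regression with intercept is available via ``intercept=True``.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    a = np.array([p.count_A for p in pairs], dtype=float)
    b = np.array([p.count_B for p in pairs], dtype=float)
    if intercept:
        slope, b0 = np.polyfit(a, b, 1)
        resid = b - (slope * a + b0)
        dof = max(len(pairs) - 2, 1)
    else:
        slope = float(np.dot(a, b) / np.dot(a, a))
        b0 = 0.0
        resid = b - slope * a
        dof = max(len(pairs) - 1, 1)
    tally: dict[tuple[int, int], int] = {}
    for p in pairs:
        key = (p.count_A, p.count_B)
        tally[key] = tally.get(key, 0) + 1
    return RatioFit(
        slope=float(slope),
        n_pairs=len(pairs),
        residual_sd=float(math.sqrt(np.sum(resid**2) / dof)),
        ratio_tally=tally,
        intercept=float(b0),
        mean_of_ratios=float(np.mean(b / a)),
        total_count_ratio=float(b.sum() / a.sum()),
    )
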