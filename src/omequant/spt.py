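"""Single-particle tracking and MSD-based diffusion estimation.

Particles are localized by symmetric 2D Gaussian fits, linked frame-to-frame
within a 320-nm gate (two pixels), filtered to 4-12-frame trajectories, and
the population diffusion coefficient is obtained from an origin-constrained
linear fit MSD = 4DΔt to the first four points of the time-and-ensemble
averaged MSD.  Uncertainty comes from a bootstrap over trajectories.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage
import scipy.optimize

log = logging.getLogger(__name__)

__all__ = [
    "Detection",
    "Trajectory",
    "MSDCurve",
    "DiffusionEstimate",
    "detect_particles",
    "link",
    "filter_trajectories",
    "compute_msd",
    "estimate_D",
    "bootstrap_D",
    "diffusion_from_tracks",
]

LINK_GATE_UM = 0.320  # two pixels at 160 nm


@dataclass
class Detection:
    """A subpixel particle localization (positions in μm)."""

    frame: int
    x: float
    y: float
    amplitude: float = 0.0
    sigma: float = 0.0
    background: float = 0.0
    fit_rss: float = 0.0


@dataclass
class Trajectory:
    """A chain of localizations on strictly consecutive frames."""

    track_id: int
    frames: np.ndarray
    xy: np.ndarray  # (L, 2) μm
    detections: list[Detection] | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if self.frames.size != self.xy.shape[0]:
            raise ValueError("frames and positions disagree in length")
        if self.frames.size > 1 and not np.all(np.diff(self.frames) == 1):
            raise ValueError("trajectory frames must be strictly consecutive")

    @property
    def length(self) -> int:
        return int(self.frames.size)


@dataclass
class MSDCurve:
    lags: np.ndarray  # Δt values, s
    msd: np.ndarray  # μm²
    n_pairs: np.ndarray
    frame_interval: float = 0.015


@dataclass
class DiffusionEstimate:
    D: float  # μm²/s, clamped at 0
    bootstrap_sd: float | None = None
    n_trajectories: int = 0
    fit_lags: int = 4
    raw_slope: float = 0.0  # unclamped 4D slope, for diagnostics


# ---------------------------------------------------------------------------
# localization


def _gauss2d_residual(p, rr, cc, z):
    a, r0, c0, s, b = p
    m = a * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * s * s)) + b
    return (m - z).ravel()


def _gauss2d_jac(p, rr, cc, z):
    a, r0, c0, s, b = p
    dr = rr - r0
    dc = cc - c0
    q = (dr * dr + dc * dc) / (s * s)
    e = np.exp(-0.5 * q)
    n = e.size
    jac = np.empty((n, 5))
    jac[:, 0] = e.ravel()
    jac[:, 1] = (a * e * dr / (s * s)).ravel()
    jac[:, 2] = (a * e * dc / (s * s)).ravel()
    jac[:, 3] = (a * e * q / s).ravel()
    jac[:, 4] = 1.0
    return jac


def detect_particles(
    image: np.ndarray,
    intensity_threshold: float,
    window: int = 7,
    pixel_size: float = 0.160,
    psf_sigma: float = 0.100,
    frame: int = 0,
    max_sigma_factor: float = 2.0,
) -> list[Detection]:
    """Localize particles in one frame by 2D Gaussian fitting.

    Candidate peaks are local maxima of the PSF-matched-filtered image lying
    more than ``intensity_threshold`` above the median background; each is
    refined by a nonlinear least-squares fit of
    ``A·exp(-((x-x0)²+(y-y0)²)/2σ²) + b`` over a ``window`` x ``window``
    region.  Fits that fail to converge, wander outside their window, or
    return a width outside (0.25, ``max_sigma_factor``) x the nominal PSF
    sigma (blurry out-of-focus objects) are discarded.

    Positions are returned in μm: x along columns, y along rows, origin at
    the center of the top-left pixel.
    """
    if window < 5 or window % 2 == 0:
        raise ValueError("window must be odd and >= 5")
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    s_px = psf_sigma / pixel_size
    bg = float(np.median(img))
    smooth = scipy.ndimage.gaussian_filter(img, s_px, mode="nearest")
    half = window // 2
    # local maxima of the matched-filtered image above background + threshold
    footprint = 2 * max(1, half) + 1
    maxed = scipy.ndimage.maximum_filter(smooth, size=footprint, mode="nearest")
    cand = (smooth == maxed) & (smooth > float(np.median(smooth)) + intensity_threshold)
    peaks = np.argwhere(cand)
    out: list[Detection] = []
    for r, c in peaks:
        a0 = max(r - half, 0)
        b0 = min(r + half + 1, h)
        a1 = max(c - half, 0)
        b1 = min(c + half + 1, w)
        z = img[a0:b0, a1:b1]
        rr, cc = np.mgrid[a0:b0, a1:b1]
        p0 = (max(img[r, c] - bg, 1e-3), float(r), float(c), s_px, bg)
        try:
            with warnings.catch_warnings():
                # non-convergent fits are dropped below; no need to warn
                warnings.simplefilter("ignore", RuntimeWarning)
                popt, ier = scipy.optimize.leastsq(
                    _gauss2d_residual, p0, args=(rr, cc, z), Dfun=_gauss2d_jac,
                    xtol=1e-8, maxfev=400)
        except Exception:  # pragma: no cover - defensive
            log.debug("fit raised at peak (%d, %d); dropped", r, c)
            continue
        if ier not in (1, 2, 3, 4):
            log.debug("non-convergent fit at peak (%d, %d); dropped", r, c)
            continue
        a, r0, c0, s, b = popt
        s = abs(s)
        if a <= 0:
            continue
        rss = float(np.sum(_gauss2d_residual(popt, rr, cc, z) ** 2))
        if not (0.25 * s_px <= s <= max_sigma_factor * s_px):
            continue
        if abs(r0 - r) > half or abs(c0 - c) > half:
            continue
        if not (-0.5 <= r0 <= h - 0.5 and -0.5 <= c0 <= w - 0.5):
            continue
        out.append(
            Detection(frame=frame, x=float(c0 * pixel_size), y=float(r0 * pixel_size),
                      amplitude=float(a), sigma=float(s * pixel_size),
                      background=float(b), fit_rss=rss)
        )
    return out


def detect_stack(stack: np.ndarray, intensity_threshold: float, window: int = 7,
                 pixel_size: float = 0.160, psf_sigma: float = 0.100) -> list[Detection]:
    """Run :func:`detect_particles` on every frame of a stack."""
    dets: list[Detection] = []
    for t, frame_img in enumerate(np.asarray(stack)):
        dets.extend(detect_particles(frame_img, intensity_threshold, window,
                                     pixel_size=pixel_size, psf_sigma=psf_sigma, frame=t))
    return dets


# ---------------------------------------------------------------------------
# linking


def link(detections: list[Detection], max_disp: float = LINK_GATE_UM) -> list[Trajectory]:
    """Greedy nearest-neighbor linking between consecutive frames.

    Candidate pairs closer than ``max_disp`` are assigned in order of
    ascending distance (deterministic tie-break by detection order); each
    detection joins at most one track, unmatched detections start new tracks,
    and frame gaps are never closed.
    """
    by_frame: dict[int, list[Detection]] = {}
    for d in detections:
        by_frame.setdefault(int(d.frame), []).append(d)
    frames = sorted(by_frame)
    track_of: dict[id, int] = {}
    tracks: dict[int, list[Detection]] = {}
    next_id = 0
    for d in by_frame.get(frames[0], []) if frames else []:
        tracks[next_id] = [d]
        track_of[id(d)] = next_id
        next_id += 1
    for f_prev, f in zip(frames[:-1], frames[1:]):
        prev = by_frame[f_prev]
        cur = by_frame[f]
        pairs: list[tuple[float, int, int]] = []
        if f == f_prev + 1:
            for i, p in enumerate(prev):
                for j, q in enumerate(cur):
                    dist = math.hypot(p.x - q.x, p.y - q.y)
                    if dist <= max_disp:
                        pairs.append((dist, i, j))
            pairs.sort()
        used_p: set[int] = set()
        used_c: set[int] = set()
        for dist, i, j in pairs:
            if i in used_p or j in used_c:
                continue
            used_p.add(i)
            used_c.add(j)
            tid = track_of[id(prev[i])]
            tracks[tid].append(cur[j])
            track_of[id(cur[j])] = tid
        for j, q in enumerate(cur):
            if j not in used_c:
                tracks[next_id] = [q]
                track_of[id(q)] = next_id
                next_id += 1
    out = []
    for tid in sorted(tracks):
        dets = tracks[tid]
        out.append(Trajectory(
            track_id=tid,
            frames=np.array([d.frame for d in dets]),
            xy=np.array([[d.x, d.y] for d in dets]),
            detections=dets,
        ))
    return out


def _optimal_link_oracle(prev: list[tuple[float, float]], cur: list[tuple[float, float]],
                         max_disp: float) -> set[tuple[int, int]]:
    """Brute-force minimum-total-distance assignment (test oracle, tiny n)."""
    best: set[tuple[int, int]] = set()
    best_cost = (0, 0.0)  # maximize matches, then minimize distance
    idx_c = list(range(len(cur)))
    for k in range(min(len(prev), len(cur)), -1, -1):
        found = False
        for sub_p in itertools.combinations(range(len(prev)), k):
            for perm in itertools.permutations(idx_c, k):
                dists = [math.hypot(prev[i][0] - cur[j][0], prev[i][1] - cur[j][1])
                         for i, j in zip(sub_p, perm)]
                if any(d > max_disp for d in dists):
                    continue
                cost = sum(d * d for d in dists)
                if not found or cost < best_cost[1]:
                    best = set(zip(sub_p, perm))
                    best_cost = (k, cost)
                    found = True
        if found:
            break
    return best


def filter_trajectories(tracks: list[Trajectory], min_len: int = 4, max_len: int = 12,
                        long_policy: str = "drop") -> list[Trajectory]:
    """Keep tracks with min_len <= length <= max_len.

    Tracks longer than ``max_len`` are dropped by default, or truncated to
    their first ``max_len`` frames with ``long_policy='truncate'``.
    """
    if long_policy not in ("drop", "truncate"):
        raise ValueError("long_policy must be 'drop' or 'truncate'")
    out = []
    for t in tracks:
        if t.length < min_len:
            continue
        if t.length > max_len:
            if long_policy == "drop":
                continue
            t = Trajectory(t.track_id, t.frames[:max_len], t.xy[:max_len])
        out.append(t)
    return out


# ---------------------------------------------------------------------------
# MSD and diffusion


def _track_sq_disp_sums(track: Trajectory, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-lag (sum of squared displacements, number of pairs) for one track."""
    xy = track.xy
    L = xy.shape[0]
    sums = np.zeros(max_lag)
    npairs = np.zeros(max_lag, dtype=int)
    for k in range(1, min(max_lag, L - 1) + 1):
        d = xy[k:] - xy[:-k]
        sums[k - 1] = np.einsum("ij,ij->", d, d)
        npairs[k - 1] = L - k
    return sums, npairs


def compute_msd(tracks: list[Trajectory], max_lag: int,
                frame_interval: float = 0.015) -> MSDCurve:
    """Time-and-ensemble averaged MSD pooled over all tracks.

    MSD(kΔt) = mean over every track and every valid start frame of
    |r(t+kΔt) - r(t)|².
    """
    if not tracks:
        raise ValueError("need at least one track")
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if all(t.length <= 1 for t in tracks):
        raise ValueError("need at least one track of length >= 2")
    if not any(t.length > 1 and t.length - 1 >= 1 for t in tracks):
        raise ValueError("no displacements available")
    if max_lag > max(t.length - 1 for t in tracks):
        raise ValueError("max_lag exceeds every track length")
    sums = np.zeros(max_lag)
    npairs = np.zeros(max_lag, dtype=int)
    for t in tracks:
        s, n = _track_sq_disp_sums(t, max_lag)
        sums += s
        npairs += n
    keep = npairs > 0
    # trailing lags with no pairs are dropped; n_pairs is non-increasing
    last = int(np.max(np.nonzero(keep)[0])) + 1
    lags = np.arange(1, last + 1) * frame_interval
    msd = np.where(npairs[:last] > 0, sums[:last] / np.maximum(npairs[:last], 1), 0.0)
    return MSDCurve(lags=lags, msd=msd, n_pairs=npairs[:last],
                    frame_interval=frame_interval)


def estimate_D(msd: MSDCurve, fit_lags: int = 4, intercept: bool = False) -> DiffusionEstimate:
    """Linear fit of MSD = 4DΔt over the first ``fit_lags`` points.

    By default the fit is constrained through the origin (slope
    = Σ t·y / Σ t²); with ``intercept=True`` an ordinary straight-line fit is
    used and the offset (which absorbs static localization error) is
    discarded.  Negative fitted slopes clamp to D = 0 with the raw slope kept
    in ``raw_slope``.
    """
    if msd.lags.size < fit_lags:
        raise ValueError(f"MSD curve has {msd.lags.size} points; need {fit_lags}")
    t = msd.lags[:fit_lags]
    y = msd.msd[:fit_lags]
    if intercept:
        slope = float(np.polyfit(t, y, 1)[0])
    else:
        slope = float(np.dot(t, y) / np.dot(t, t))
    d_raw = slope / 4.0
    if d_raw < 0:
        log.info("negative fitted slope %.3g clamped to D=0", slope)
    return DiffusionEstimate(D=max(d_raw, 0.0), raw_slope=slope, fit_lags=fit_lags)


def bootstrap_D(
    tracks: list[Trajectory],
    n_boot: int = 1000,
    seed: int = 0,
    fit_lags: int = 4,
    frame_interval: float = 0.015,
    method: str = "resample",
) -> float:
    """Bootstrap SD of D under resampling whole trajectories with replacement.

    ``method='resample'`` draws ``n_boot`` bootstrap samples (the standard
    procedure); ``method='enumerate'`` computes the exact SD of the bootstrap
    distribution by enumerating all resample multisets with their multinomial
    weights (feasible for ~12 tracks or fewer).
    """
    if len(tracks) < 2:
        raise ValueError("bootstrap needs at least 2 tracks")
    max_lag = fit_lags
    per_track = np.array([np.concatenate(_track_sq_disp_sums(t, max_lag))
                          for t in tracks])  # (n, 2*max_lag)
    S = per_track[:, :max_lag]
    N = per_track[:, max_lag:]
    tvec = np.arange(1, max_lag + 1) * frame_interval
    denom_t = float(np.dot(tvec, tvec))

    def d_of_weights(w: np.ndarray) -> np.ndarray:
        # w: (..., n) multiplicities; returns clamped D per row
        s = w @ S
        n = w @ N
        msd = np.where(n > 0, s / np.maximum(n, 1e-300), 0.0)
        slope = (msd @ tvec) / denom_t
        return np.maximum(slope / 4.0, 0.0)

    n = len(tracks)
    if method == "enumerate":
        multisets = list(itertools.combinations_with_replacement(range(n), n))
        W = np.zeros((len(multisets), n))
        logfact = np.cumsum(np.log(np.arange(1, n + 1)))
        logfact = np.concatenate(([0.0], logfact))
        probs = np.empty(len(multisets))
        for i, ms in enumerate(multisets):
            for j in ms:
                W[i, j] += 1
            logp = logfact[n] - n * math.log(n) - np.sum(logfact[W[i].astype(int)])
            probs[i] = math.exp(logp)
        d = d_of_weights(W)
        mean = float(np.dot(probs, d))
        var = float(np.dot(probs, (d - mean) ** 2))
        return math.sqrt(max(var, 0.0))
    if method != "resample":
        raise ValueError("method must be 'resample' or 'enumerate'")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    W = np.zeros((n_boot, n))
    rows = np.repeat(np.arange(n_boot), n)
    np.add.at(W, (rows, idx.ravel()), 1.0)
    d = d_of_weights(W)
    return float(np.std(d))


def diffusion_from_tracks(
    tracks: list[Trajectory],
    frame_interval: float = 0.015,
    fit_lags: int = 4,
    n_boot: int = 1000,
    seed: int = 0,
    intercept: bool = False,
) -> DiffusionEstimate:
    """Convenience: pooled MSD -> D with bootstrap SD over trajectories."""
    msd = compute_msd(tracks, max_lag=fit_lags, frame_interval=frame_interval)
    est = estimate_D(msd, fit_lags=fit_lags, intercept=intercept)
    est.n_trajectories = len(tracks)
    if n_boot and len(tracks) >= 2:
        est.bootstrap_sd = bootstrap_D(tracks, n_boot=n_boot, seed=seed,
                                       fit_lags=fit_lags, frame_interval=frame_interval)
    return est
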