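"""Analysis of protein-on-DNA traces.

Classifies each frame of a ProteinDNATrajectory into one of the four
facilitated-diffusion transport modes (sliding, hopping, 3D diffusion,
intersegmental transfer), estimates the 1D diffusion coefficient D1 from
mean-squared displacements along the DNA contour, and derives the derived
search statistics: mode propensities, rotation-sliding coupling, unique
intersegmental transfer counts, the fraction of DNA scanned via transfer,
and per-bp residence times.

Numeric mode thresholds are package defaults exposed in
:class:`ModeThresholds`: the sliding shell is the contact-well range
(r_slide = 15 A), hopping reaches to about twice that (r_hop = 30 A) and
must rebind within ``rebind_window`` frames, and an intersegmental
transfer is a jump of more than ``jump_sep`` bp along the sequence that
moves the probe less than ``jump_spatial_max`` in space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import circular_separation
from .walker import MODES, ProteinDNATrajectory


@dataclass
class ModeThresholds:
    r_slide: float = 15.0        # A
    r_hop: float = 30.0          # A
    rebind_window: int = 20      # frames
    jump_sep: int = 50           # bp (defaults to the jp criterion N_c)
    jump_spatial_max: float = 60.0  # A (defaults to d_cutoff)

    def __post_init__(self) -> None:
        if not 0 < self.r_slide < self.r_hop:
            raise ValueError("need 0 < r_slide < r_hop")
        if self.jump_sep <= 0:
            raise ValueError("jump_sep must be positive")


def classify_frames(traj: ProteinDNATrajectory,
                    thresholds: ModeThresholds | None = None) -> np.ndarray:
    """Per-frame transport-mode labels (every frame gets exactly one).

    Priority: an intersegmental arrival (sequence jump > jump_sep bp,
    spatial displacement < jump_spatial_max) wins; then sliding
    (R < r_slide, |dbp| <= 2); then hopping (R in [r_slide, r_hop) with a
    return below r_slide within rebind_window frames and |dbp| <=
    jump_sep); everything else is 3D diffusion.
    """
    th = thresholds or ModeThresholds()
    R = traj.R
    bp = traj.bp_index
    n = traj.n_bp
    T = len(traj)
    labels = np.full(T, "diffusion3d", dtype=object)

    dbp = np.zeros(T)
    dbp[1:] = circular_separation(bp[1:] - 1, bp[:-1] - 1, n)
    dxyz = np.zeros(T)
    dxyz[1:] = np.linalg.norm(traj.xyz[1:] - traj.xyz[:-1], axis=1)

    below = R < th.r_slide
    for t in range(T):
        if t > 0 and dbp[t] > th.jump_sep and dxyz[t] < th.jump_spatial_max:
            labels[t] = "intersegmental"
        elif below[t] and dbp[t] <= 2:
            labels[t] = "sliding"
        elif th.r_slide <= R[t] < th.r_hop and dbp[t] <= th.jump_sep:
            # hopping requires rebinding below the sliding shell soon
            w = below[t + 1: t + 1 + th.rebind_window]
            if w.any():
                labels[t] = "hopping"
    return labels


@dataclass
class DiffusionEstimate:
    d1: float               # bp^2/frame
    stderr: float
    fit_window: tuple[int, int]
    n_segments: int
    ballistic: bool = False  # True when MSD grows superlinearly (drift)


def _attached_segments(bp: np.ndarray, labels: np.ndarray | None,
                       include: tuple[str, ...], n_bp: int) -> list[np.ndarray]:
    """Contiguous runs of circularly-unwrapped bp positions.

    Intersegmental frames are excised and the flanking runs stitched with
    zero displacement across the cut, so transfer jumps do not inflate the
    MSD; other excluded frames break the series into separate segments.
    """
    T = len(bp)
    if labels is None:
        mask = np.ones(T, dtype=bool)
        inter = np.zeros(T, dtype=bool)
    else:
        mask = np.isin(labels, include)
        inter = labels == "intersegmental"
    steps = (np.diff(bp.astype(float)) + n_bp / 2) % n_bp - n_bp / 2

    segments: list[list[float]] = []
    cur: list[float] = []
    pos = 0.0
    for t in range(T):
        if inter[t] and cur:
            # stitch: keep the segment going, no displacement added
            cur.append(cur[-1])
            pos = cur[-1]
            continue
        if mask[t]:
            if cur:
                pos += steps[t - 1] if t > 0 else 0.0
                cur.append(pos)
            else:
                pos = 0.0
                cur = [pos]
        else:
            if len(cur) > 1:
                segments.append(cur)
            cur = []
    if len(cur) > 1:
        segments.append(cur)
    return [np.asarray(c) for c in segments]


def msd(segments: list[np.ndarray], lags: np.ndarray) -> np.ndarray:
    """Mean-squared displacement over all time origins in all segments."""
    out = np.empty(len(lags))
    for k, lag in enumerate(lags):
        num, den = 0.0, 0
        for seg in segments:
            if len(seg) > lag:
                d = seg[lag:] - seg[:-lag]
                num += float(np.dot(d, d))
                den += d.size
        out[k] = num / den if den else np.nan
    return out


def msd_d1(traj: ProteinDNATrajectory,
           labels: np.ndarray | None = None,
           include: tuple[str, ...] = ("sliding", "hopping"),
           fit_window: tuple[int, int] = (1, 10),
           min_frames: int = 1000,
           n_bootstrap: int = 50,
           seed: int = 0) -> DiffusionEstimate:
    """D1 (bp^2/frame) from the MSD of the bp coordinate.

    Circular displacements are unwrapped, intersegmental frames excised
    (segments stitched), and MSD(tau) is fit to 2*D1*tau + c over
    ``fit_window``; the free intercept absorbs the lag-independent offset
    contributed by integer bp discretization (the analogue of
    localization noise in single-particle tracking).  The standard error
    comes from a bootstrap over segments.  A fit where MSD grows markedly
    superlinearly is flagged ballistic (drift) rather than diffusive.
    """
    segments = _attached_segments(traj.bp_index, labels, include, traj.n_bp)
    usable = sum(len(s) for s in segments)
    if usable < min_frames:
        raise ValueError(f"only {usable} usable frames (need {min_frames})")
    lags = np.arange(fit_window[0], fit_window[1] + 1)
    m = msd(segments, lags)
    slope = float(np.polyfit(lags, m, 1)[0])

    # drift diagnostic: quadratic growth makes MSD(2t)/MSD(t) approach 4
    ballistic = False
    if m[0] > 0 and len(m) >= 2:
        k = len(lags) // 2
        if k >= 1 and m[k] > 0:
            ratio = m[-1] / m[k] * (lags[k] / lags[-1])
            ballistic = ratio > 1.5

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        pick = rng.integers(0, len(segments), size=len(segments))
        bm = msd([segments[i] for i in pick], lags)
        if np.isfinite(bm).all():
            boots.append(float(np.polyfit(lags, bm, 1)[0]) / 2.0)
    stderr = float(np.std(boots)) if len(boots) > 1 else float("nan")
    return DiffusionEstimate(d1=max(0.0, slope / 2.0), stderr=stderr,
                             fit_window=fit_window,
                             n_segments=len(segments), ballistic=ballistic)


def pooled_msd_d1(trajs, labels_list=None, **kwargs) -> DiffusionEstimate:
    """Pool replicas by averaging their MSD curves, not their D1 values."""
    fit_window = kwargs.get("fit_window", (1, 10))
    lags = np.arange(fit_window[0], fit_window[1] + 1)
    all_segments = []
    for k, traj in enumerate(trajs):
        labels = labels_list[k] if labels_list is not None else None
        all_segments.extend(_attached_segments(
            traj.bp_index, labels, kwargs.get("include", ("sliding", "hopping")),
            traj.n_bp))
    m = msd(all_segments, lags)
    slope = float(np.polyfit(lags, m, 1)[0])
    return DiffusionEstimate(d1=max(0.0, slope / 2.0), stderr=float("nan"),
                             fit_window=fit_window,
                             n_segments=len(all_segments))


def mode_propensities(labels: np.ndarray) -> dict[str, float]:
    """Fraction of frames per transport mode (sums to 1)."""
    labels = np.asarray(labels)
    T = len(labels)
    return {m: float(np.sum(labels == m)) / T for m in MODES}


def rotation_coupling(traj: ProteinDNATrajectory,
                      labels: np.ndarray | None = None,
                      min_frames: int = 100) -> float:
    """Pearson correlation of per-frame (dtheta, dz) over sliding frames."""
    if labels is None:
        mask = np.ones(len(traj), dtype=bool)
    else:
        mask = np.asarray(labels) == "sliding"
    # frame-to-frame increments within sliding runs only
    ok = mask[1:] & mask[:-1]
    dth = np.diff(traj.theta)[ok]
    dz = np.diff(traj.z)[ok]
    if dth.size < min_frames:
        raise ValueError(f"only {dth.size} sliding increments "
                         f"(need {min_frames})")
    if np.std(dth) == 0 or np.std(dz) == 0:
        return 1.0 if np.allclose(dth * dz >= 0, True) else 0.0
    return float(np.corrcoef(dth, dz)[0, 1])


def _transfer_events(labels: np.ndarray) -> np.ndarray:
    return np.where(np.asarray(labels) == "intersegmental")[0]


def count_unique_intersegmental(labels: np.ndarray, bp_series: np.ndarray,
                                granularity: int = 10) -> int:
    """Number of distinct (source, destination) transfer region pairs.

    Regions are ``granularity``-bp bins; a repeated jump between the same
    pair of regions (either direction) counts once.
    """
    events = _transfer_events(labels)
    seen = set()
    for t in events:
        if t == 0:
            continue
        src = int(bp_series[t - 1] - 1) // granularity
        dst = int(bp_series[t] - 1) // granularity
        seen.add((min(src, dst), max(src, dst)))
    return len(seen)


def scanned_fraction_by_transfer(labels: np.ndarray,
                                 bp_series: np.ndarray) -> float:
    """Fraction of unique visited bp first reached in a post-transfer run.

    A scanning run opened by an intersegmental event ends at the next
    detachment (3D frame) or the next transfer.  Returns 0 when there are
    no transfers and, by construction, 1 when every first visit follows a
    transfer.
    """
    labels = np.asarray(labels)
    visited: set[int] = set()
    via_transfer: set[int] = set()
    in_run = False
    for t in range(len(labels)):
        lab = labels[t]
        if lab == "intersegmental":
            in_run = True
        elif lab == "diffusion3d":
            in_run = False
        b = int(bp_series[t])
        if b not in visited:
            visited.add(b)
            if in_run:
                via_transfer.add(b)
    if not visited:
        return 0.0
    return len(via_transfer) / len(visited)


def residence_time(traj: ProteinDNATrajectory,
                   labels: np.ndarray | None = None
                   ) -> tuple[np.ndarray, float]:
    """Per-bp visit counts and the mean dwell per visit (frames).

    A visit is a maximal run of consecutive frames at the same bp (frames
    labeled 3D, when labels are given, end the current visit and are not
    counted).  Returns (counts indexed 0..n_bp-1 for bp 1..n_bp,
    mean dwell).
    """
    bp = traj.bp_index
    counts = np.zeros(traj.n_bp, dtype=np.int64)
    if labels is None:
        attached = np.ones(len(bp), dtype=bool)
    else:
        attached = np.asarray(labels) != "diffusion3d"
    dwells = []
    run = 0
    for t in range(len(bp)):
        if attached[t]:
            counts[bp[t] - 1] += 1
            if t > 0 and attached[t - 1] and bp[t] == bp[t - 1]:
                run += 1
            else:
                if run:
                    dwells.append(run)
                run = 1
        else:
            if run:
                dwells.append(run)
            run = 0
    if run:
        dwells.append(run)
    mean_dwell = float(np.mean(dwells)) if dwells else 0.0
    return counts, mean_dwell
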