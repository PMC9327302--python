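"""Twist propagation along the minicircle: local frames and C(t, i).

Torsional stress travels along supercoiled DNA as reorientation of the
local material frame.  For each junction i the unit tangent a_i connects
consecutive bp centers, the binormal b_i = (a_{i-1} x a_i)/|.| captures
the local bending plane, and c_i = a_i x b_i completes the frame.  The
autocorrelation landscape C(t, i) = < c_i(0) . c_i(t) > (ensemble and
time-origin averaged) tracks which segments have already reoriented:
C close to 1 marks segments yet to undergo twisting.  The per-index lag
at which C first drops below a threshold defines a decorrelation
boundary whose local slope is the twist propagation speed (bp per lag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import ChainConfiguration, ChainError, ChainTrajectory


@dataclass
class FrameField:
    """Per-junction orthonormal frame vectors of one configuration."""

    a: np.ndarray  # (n, 3) tangents
    b: np.ndarray  # (n, 3) binormals
    c: np.ndarray  # (n, 3) a x b


def local_frames(config: ChainConfiguration) -> FrameField:
    """Discrete Frenet-style frames of the chain axis.

    a_i is the normalized vector from center i to center i+1;
    b_i = (a_{i-1} x a_i) normalized; c_i = a_i x b_i.  Near-collinear
    junctions (undefined binormal) inherit the previous junction's
    binormal transported by the minimal rotation taking a_{i-1} to a_i;
    a fully straight chain is refused.
    """
    bonds = config.bond_vectors()
    a = bonds / np.linalg.norm(bonds, axis=1)[:, None]
    n = a.shape[0]
    cross = np.cross(np.roll(a, 1, axis=0), a)
    norms = np.linalg.norm(cross, axis=1)
    ok = norms > 1e-9
    if not ok.any():
        raise ChainError("fully straight chain: binormal undefined everywhere")
    b = np.empty_like(a)
    b[ok] = cross[ok] / norms[ok, None]
    if not ok.all():
        # parallel-transport the previous valid binormal through the
        # degenerate junctions
        start = int(np.argmax(ok))
        for k in range(n):
            i = (start + k) % n
            if ok[i]:
                continue
            prev = (i - 1) % n
            ai_prev, ai = a[prev], a[i]
            axis = np.cross(ai_prev, ai)
            s = np.linalg.norm(axis)
            if s < 1e-12:
                b[i] = b[prev]
            else:
                axis = axis / s
                ang = np.arcsin(min(1.0, s))
                if np.dot(ai_prev, ai) < 0:
                    ang = np.pi - ang
                b[i] = _rotate(b[prev], axis, ang)
    c = np.cross(a, b)
    return FrameField(a=a, b=b, c=c)


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    return (v * np.cos(angle) + np.cross(axis, v) * np.sin(angle)
            + axis * np.dot(axis, v) * (1.0 - np.cos(angle)))


def frame_field_series(traj: ChainTrajectory) -> np.ndarray:
    """(T, n, 3) array of c_i vectors over a trajectory."""
    return np.stack([local_frames(f).c for f in traj.frames])


@dataclass
class TwistLandscape:
    C: np.ndarray          # (n_lags, n_bp), C[0] = 1 exactly
    lags: np.ndarray
    boundary: np.ndarray   # (n_bp,) first lag with C < c_thresh (or max lag)
    c_thresh: float

    def propagation_speed(self, index_window: tuple[int, int]) -> float:
        """Twist propagation speed (bp/lag) over a 0-based index window.

        Least-squares slope of the decorrelation boundary versus bp index
        over the window; the speed is the inverse magnitude of that slope
        (a steep front in lag-vs-index means slow propagation).
        """
        i0, i1 = index_window
        idx = np.arange(i0, i1)
        y = self.boundary[i0:i1].astype(float)
        slope = np.polyfit(idx, y, 1)[0]
        if abs(slope) < 1e-12:
            return float("inf")
        return float(1.0 / abs(slope))


def autocorrelation_landscape(c_series_list: list[np.ndarray],
                              max_lag: int | None = None,
                              c_thresh: float = 0.8,
                              origin_stride: int = 1) -> TwistLandscape:
    """C(t, i) from one or more replicas of c_i(t) vector series.

    Each replica is a (T, n, 3) array; the estimate averages
    c_i(t0) . c_i(t0 + t) over all time origins (with ``origin_stride``)
    and replicas.  C(0, i) = 1 exactly for unit vectors.
    """
    if not c_series_list:
        raise ValueError("need at least one replica")
    T = min(cs.shape[0] for cs in c_series_list)
    if max_lag is None:
        max_lag = T // 2
    if T < 2 or max_lag < 1:
        raise ValueError("series too short for autocorrelation")
    n = c_series_list[0].shape[1]
    lags = np.arange(0, max_lag + 1)
    C = np.zeros((len(lags), n))
    for k, lag in enumerate(lags):
        num = np.zeros(n)
        den = 0
        for cs in c_series_list:
            origins = np.arange(0, cs.shape[0] - lag, origin_stride)
            prod = np.einsum("tij,tij->ti", cs[origins], cs[origins + lag])
            num += prod.sum(axis=0)
            den += len(origins)
        C[k] = num / den
    C[0] = 1.0  # exact for unit vectors; guards rounding
    below = C < c_thresh
    boundary = np.where(below.any(axis=0), below.argmax(axis=0), max_lag)
    return TwistLandscape(C=C, lags=lags, boundary=boundary,
                          c_thresh=c_thresh)


def twist_autocorrelation(replicas: list[ChainTrajectory],
                          max_lag: int | None = None,
                          c_thresh: float = 0.8,
                          origin_stride: int = 1,
                          min_frames: int = 100,
                          min_replicas: int = 2) -> TwistLandscape:
    """Ensemble-averaged twist-propagation landscape of chain replicas."""
    if len(replicas) < min_replicas:
        raise ValueError(f"need >= {min_replicas} replicas for the "
                         "ensemble average")
    if min(len(r) for r in replicas) < min_frames:
        raise ValueError(f"need >= {min_frames} frames per replica")
    series = [frame_field_series(r) for r in replicas]
    return autocorrelation_landscape(series, max_lag=max_lag,
                                     c_thresh=c_thresh,
                                     origin_stride=origin_stride)
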