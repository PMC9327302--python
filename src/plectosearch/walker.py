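"""Synthetic protein-on-DNA traces.

Two generators produce ProteinDNATrajectory inputs for the trajectory
analyses:

* :func:`simulate_walker` -- a charged-proxy probe diffusing on a relaxed
  minicircle ensemble: attachment/detachment, groove-coupled sliding,
  brief hopping excursions, and stochastic intersegmental jumps whenever
  the probe sits within d_cutoff of a sequence-distant segment (i.e. at a
  juxtaposition site).
* :func:`generate_labeled_walk` -- a parametric walk with ground-truth
  per-frame mode labels and known sliding diffusivity, used to validate
  the mode classifier and the MSD-based D1 estimator.

Per-frame observables are the protein-DNA distance R (probe to nearest bp
center, A), the nearest bp index (1-based), the axial coordinate z along
the DNA contour (A), the unwrapped rotation angle theta about the local
DNA axis (rad), and the 3D probe position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .chain import ChainTrajectory, circular_separation
from .juxtaposition import DEFAULT_DCUTOFF, DEFAULT_NC

MODES = ("sliding", "hopping", "diffusion3d", "intersegmental")


@dataclass
class WalkerParams:
    """Proxy-walker interaction and kinetics (rates are per step)."""

    contact_strength: float = 4.0     # kT, depth of the nonspecific well
    screening_length: float = 10.0    # A, range of the attractive well
    slide_step: float = 0.7           # bp RMS displacement per bound step
    hop_rate: float = 0.01
    detach_rate: float = 0.002
    jump_rate_at_jp: float = 0.05
    groove_coupling: float = 1.0      # fraction of sliding turned into rotation
    steps_per_frame: int = 20         # walker steps per chain frame
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.hop_rate, self.detach_rate, self.jump_rate_at_jp):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1] per step")
        if not 0.0 <= self.groove_coupling <= 1.0:
            raise ValueError("groove_coupling must lie in [0, 1]")


@dataclass
class ProteinDNATrajectory:
    """Per-frame protein observables on a DNA substrate."""

    R: np.ndarray            # (T,) distance to nearest bp center, A
    bp_index: np.ndarray     # (T,) nearest bp, 1-based int
    z: np.ndarray            # (T,) axial coordinate along the contour, A
    theta: np.ndarray        # (T,) unwrapped rotation angle, rad
    xyz: np.ndarray          # (T, 3) probe position, A
    n_bp: int
    frame_interval: int = 1
    seed: int = 0
    rise: float = 3.34
    helical_repeat: float = 10.5
    truth_labels: np.ndarray | None = None   # (T,) strings from MODES
    truth_states: np.ndarray | None = None   # (T,) sliding sub-state labels

    def __post_init__(self) -> None:
        T = len(self.R)
        for name in ("bp_index", "z", "theta"):
            if len(getattr(self, name)) != T:
                raise ValueError(f"{name} length mismatch")
        if self.xyz.shape != (T, 3):
            raise ValueError("xyz must be (T, 3)")
        if (self.R < 0).any():
            raise ValueError("R must be non-negative")
        if ((self.bp_index < 1) | (self.bp_index > self.n_bp)).any():
            raise ValueError("bp_index out of [1, n_bp]")

    def __len__(self) -> int:
        return len(self.R)


def _local_axes(centers: np.ndarray):
    """Unit tangent per bead plus two transverse unit vectors."""
    n = centers.shape[0]
    tang = np.roll(centers, -1, axis=0) - np.roll(centers, 1, axis=0)
    tang /= np.linalg.norm(tang, axis=1)[:, None]
    ref = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(tang, ref)
    bad = np.linalg.norm(e1, axis=1) < 1e-6
    e1[bad] = np.cross(tang[bad], np.array([1.0, 0.0, 0.0]))
    e1 /= np.linalg.norm(e1, axis=1)[:, None]
    e2 = np.cross(tang, e1)
    return tang, e1, e2


def simulate_walker(chain_traj: ChainTrajectory, params: WalkerParams,
                    n_c: int = DEFAULT_NC,
                    d_cutoff: float = DEFAULT_DCUTOFF) -> ProteinDNATrajectory:
    """Diffuse a proxy probe over the frames of a minicircle trajectory.

    The probe starts detached.  While detached it diffuses in the periodic
    box and attaches when it comes within the capture range of a bp
    center.  While bound it slides (Gaussian bp steps, rotation advancing
    at groove_coupling x 2*pi per helical repeat), hops (short excursions
    beyond the sliding shell that rebind nearby), detaches, and -- when
    the current bp lies within ``d_cutoff`` of a bp more than ``n_c``
    away -- performs intersegmental jumps with probability
    ``jump_rate_at_jp`` per step.
    """
    if params.contact_strength == 0.0 and params.slide_step > 0:
        warnings.warn("zero contact_strength: walker will never bind",
                      UserWarning, stacklevel=2)
    rng = np.random.default_rng(params.seed)
    box = chain_traj.params.box_edge
    rise = chain_traj.frames[0].rise
    hrep = chain_traj.frames[0].helical_repeat
    n = chain_traj.n_bp
    spf = params.steps_per_frame
    T = len(chain_traj) * spf

    R = np.empty(T)
    bp = np.empty(T, dtype=np.int64)
    z = np.empty(T)
    theta = np.empty(T)
    xyz = np.empty((T, 3))

    capture = 3.0 * params.screening_length
    bound = False
    s = 0.0                      # continuous bp coordinate while bound
    th = 0.0                     # unwrapped rotation angle
    z_unwrapped = 0.0
    pos = chain_traj.frames[0].centers[0] + np.array([capture + 20.0, 0, 0])
    hop_left = 0                 # frames remaining in a hop excursion
    hop_R = 0.0

    t = 0
    for cframe in chain_traj.frames:
        centers = cframe.centers
        tang, e1, e2 = _local_axes(centers)
        # distance matrix row lookup for jp adjacency at this frame
        idx = np.arange(n)
        for _ in range(spf):
            if bound and hop_left == 0:
                u = rng.random()
                i = int(np.floor(s)) % n
                if u < params.detach_rate and params.contact_strength > 0:
                    bound = False
                    pos = centers[i] + (capture + 5.0) * e1[i]
                elif u < params.detach_rate + params.hop_rate:
                    hop_left = int(rng.integers(2, 8))
                    hop_R = 18.0 + 8.0 * rng.random()
                else:
                    # intersegmental channel when at a juxtaposition site
                    jumped = False
                    if params.jump_rate_at_jp > 0:
                        d = np.linalg.norm(centers - centers[i], axis=1)
                        far = circular_separation(idx, i, n) > n_c
                        close = far & (d < d_cutoff)
                        if close.any() and rng.random() < params.jump_rate_at_jp:
                            j = int(rng.choice(np.where(close)[0]))
                            ds_arc = (j - s) % n
                            s = float(j) + rng.random() - 0.5
                            jumped = True
                    if not jumped:
                        ds = rng.normal(0.0, params.slide_step)
                        s += ds
                        th += params.groove_coupling * 2.0 * np.pi * ds / hrep
                        z_unwrapped += ds * rise
            elif bound:
                hop_left -= 1
                if hop_left == 0:
                    s += rng.normal(0.0, 2.0)
            else:
                pos = pos + rng.normal(0.0, 8.0, size=3)
                # periodic wrap into the origin-centred box, never an error
                pos = (pos + box / 2.0) % box - box / 2.0
                d = np.linalg.norm(centers - pos, axis=1)
                j = int(np.argmin(d))
                if d[j] < capture and params.contact_strength > 0:
                    bound = True
                    s = float(j)
                    hop_left = 0

            i = int(np.floor(s)) % n
            if bound and hop_left == 0:
                frac = s - np.floor(s)
                base = centers[i] + frac * (centers[(i + 1) % n] - centers[i])
                offset = (np.cos(th) * e1[i] + np.sin(th) * e2[i])
                pos = base + params.screening_length * 0.5 * offset
                R[t] = np.linalg.norm(pos - base) + 0.5 * rng.random()
            elif bound:
                base = centers[i]
                pos = base + hop_R * e1[i]
                R[t] = hop_R + rng.random()
            else:
                R[t] = float(np.min(np.linalg.norm(centers - pos, axis=1)))
            bp[t] = i + 1
            z[t] = z_unwrapped
            theta[t] = th
            xyz[t] = pos
            t += 1

    return ProteinDNATrajectory(R=R, bp_index=bp, z=z, theta=theta, xyz=xyz,
                                n_bp=n, seed=params.seed, rise=rise,
                                helical_repeat=hrep)


def generate_labeled_walk(n_frames: int,
                          mode_rates: dict | None = None,
                          jp_positions: list[tuple[int, int]] | None = None,
                          d1_true: float = 0.5,
                          n_bp: int = 336,
                          groove_coupling: float = 1.0,
                          theta_noise: float = 0.0,
                          n_c: int = DEFAULT_NC,
                          fast_slow: tuple[float, float, float] | None = None,
                          seed: int = 0) -> ProteinDNATrajectory:
    """Ground-truth-labeled piecewise walk.

    Sliding frames advance the bp coordinate with variance ``2 * d1_true``
    per frame (R within the contact shell); hopping excursions raise R
    into [15, 30) A for a few frames and rebind nearby; 3D segments have
    large R; intersegmental events teleport the bp index across one of the
    ``jp_positions`` pairs while moving the probe less than a few A in
    space.  ``mode_rates`` gives per-frame entry probabilities for
    ``hopping``, ``diffusion3d`` and ``intersegmental`` (the remainder is
    sliding); their sum must be <= 1.  Truth labels are recorded per
    frame.

    ``fast_slow = (d1_slow, d1_fast, switch_prob)`` replaces the single
    sliding diffusivity with a two-state slow/fast sliding model (the
    state flips with ``switch_prob`` per frame); the per-frame sub-state
    is recorded in ``truth_states`` so per-state diffusivities can be
    recovered.
    """
    mode_rates = dict(mode_rates or {})
    for key in mode_rates:
        if key not in ("hopping", "diffusion3d", "intersegmental"):
            raise ValueError(f"unknown mode '{key}'")
    if sum(mode_rates.values()) > 1.0:
        raise ValueError("mode entry rates must sum to <= 1")
    jp_positions = list(jp_positions or [])
    for a, b in jp_positions:
        if circular_separation(a - 1, b - 1, n_bp) <= n_c:
            raise ValueError(
                f"jp pair ({a}, {b}) separated by <= N_c = {n_c} bp is not "
                "an intersegmental pair")
    rng = np.random.default_rng(seed)
    rise, hrep = 3.34, 10.5

    R = np.empty(n_frames)
    bp = np.empty(n_frames, dtype=np.int64)
    z = np.empty(n_frames)
    theta = np.empty(n_frames)
    xyz = np.zeros((n_frames, 3))
    labels = np.empty(n_frames, dtype=object)

    s = n_bp / 2.0
    th = 0.0
    zc = 0.0
    spatial = np.zeros(3)
    step_sd = np.sqrt(2.0 * d1_true)
    states = np.empty(n_frames, dtype=object) if fast_slow else None
    state_fast = False
    if fast_slow is not None:
        d1_slow, d1_fast, switch_prob = fast_slow

    t = 0
    while t < n_frames:
        u = rng.random()
        p_hop = mode_rates.get("hopping", 0.0)
        p_3d = mode_rates.get("diffusion3d", 0.0)
        p_jump = mode_rates.get("intersegmental", 0.0) if jp_positions else 0.0
        if u < p_hop:
            length = min(int(rng.integers(3, 10)), n_frames - t)
            drift = rng.integers(-3, 4)
            for k in range(length):
                s += drift / length
                spatial += rng.normal(0, 2.0, 3)
                R[t] = 15.0 + 14.0 * rng.random()
                labels[t] = "hopping"
                bp[t] = int(np.floor(s)) % n_bp + 1
                z[t] = zc
                theta[t] = th
                xyz[t] = spatial
                t += 1
                if t >= n_frames:
                    break
            # rebind frame keeps the label contract: R back under the shell
        elif u < p_hop + p_3d:
            length = min(int(rng.integers(5, 20)), n_frames - t)
            for k in range(length):
                spatial += rng.normal(0, 10.0, 3)
                R[t] = 35.0 + 30.0 * rng.random()
                labels[t] = "diffusion3d"
                bp[t] = int(np.floor(s)) % n_bp + 1
                z[t] = zc
                theta[t] = th
                xyz[t] = spatial
                t += 1
                if t >= n_frames:
                    break
        elif u < p_hop + p_3d + p_jump:
            a, b = jp_positions[int(rng.integers(len(jp_positions)))]
            cur = int(np.floor(s)) % n_bp + 1
            target = b if circular_separation(cur - 1, a - 1, n_bp) <= \
                circular_separation(cur - 1, b - 1, n_bp) else a
            # snap onto the pair first if the walker wandered off it
            s = float(target - 1)
            spatial += rng.normal(0, 1.0, 3)   # spatially tiny jump
            R[t] = 4.0 + rng.random()
            labels[t] = "intersegmental"
            bp[t] = int(np.floor(s)) % n_bp + 1
            z[t] = zc
            theta[t] = th
            xyz[t] = spatial
            t += 1
        else:
            if fast_slow is not None:
                if rng.random() < switch_prob:
                    state_fast = not state_fast
                step_sd = np.sqrt(2.0 * (d1_fast if state_fast else d1_slow))
                states[t] = "fast" if state_fast else "slow"
            ds = rng.normal(0.0, step_sd)
            s += ds
            dz = ds * rise
            zc += dz
            th += groove_coupling * 2.0 * np.pi * ds / hrep \
                + theta_noise * rng.normal()
            spatial += np.array([dz, 0.0, 0.0]) + rng.normal(0, 0.3, 3)
            R[t] = 4.0 + 2.0 * rng.random()
            labels[t] = "sliding"
            bp[t] = int(np.floor(s)) % n_bp + 1
            z[t] = zc
            theta[t] = th
            xyz[t] = spatial
            t += 1

    return ProteinDNATrajectory(R=R, bp_index=bp, z=z, theta=theta, xyz=xyz,
                                n_bp=n_bp, seed=seed, rise=rise,
                                helical_repeat=hrep,
                                truth_labels=labels,
                                truth_states=states)
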