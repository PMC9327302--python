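"""Metropolis Monte Carlo relaxation of twistable minicircles.

The chain is a discrete twistable worm-like chain: one bead per base pair,
bending stiffness lp/b per joint and torsional stiffness lt/(2b) per
junction (lp, lt = bending/torsional persistence lengths, b = rise), with
a hard excluded-volume core between sequence-distant beads.  The move set
(twist transfer, small and large crankshaft arcs, single-bead
displacements) and the exact linking-number bookkeeping are documented in
``_mc_kernel``: every accepted geometry move compensates its writhe change
by uniformly shifting the twist increments of the moved arc, so
Lk = Tw + Wr is conserved along the trajectory and strand passage is
excluded by the hard-core veto.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from . import _mc_kernel
from .chain import (
    BOND_TOLERANCE,
    ChainConfiguration,
    ChainTrajectory,
    SimParams,
    build_minicircle,
    ev_min_separation,
)


class MCWarning(UserWarning):
    """Non-fatal Monte Carlo diagnostics (e.g. very low acceptance)."""


def mc_relax(config: ChainConfiguration, params: SimParams,
             delta_lk: int | None = None) -> ChainTrajectory:
    """Relax a minicircle by Metropolis MC.

    The input frame is recorded as frame 0 and a snapshot is stored every
    ``params.frame_interval`` attempted moves.  With ``n_steps = 0`` the
    trajectory is the single input frame, unchanged.  Identical seed and
    parameters reproduce the trajectory bit for bit.
    """
    config.validate(params.excluded_diameter)
    centers = np.ascontiguousarray(config.centers, dtype=float).copy()
    twist = np.ascontiguousarray(config.twist_increments, dtype=float).copy()
    n = centers.shape[0]
    n_frames = params.n_steps // params.frame_interval if params.frame_interval else 0
    frames_out = np.empty((n_frames, n, 3))
    twists_out = np.empty((n_frames, n))

    kappa = params.bending_persistence / config.rise
    ct = params.torsional_persistence / (2.0 * config.rise)
    phi0 = 2.0 * np.pi / config.helical_repeat
    ev_sep = ev_min_separation(params.excluded_diameter, config.rise)

    n_acc, n_att, n_acc_first, n_att_first = _mc_kernel.run_mc(
        centers, twist, params.n_steps, params.frame_interval,
        frames_out, twists_out,
        kappa, ct, phi0, ev_sep, params.excluded_diameter,
        params.crankshaft_amplitude, params.large_arc_prob, params.max_arc,
        params.displacement_amplitude, config.rise, BOND_TOLERANCE,
        params.twist_move_prob, params.disp_move_prob, params.twist_quantum,
        int(params.seed) % (2 ** 31),
    )
    if n_att_first >= 500 and n_acc_first / n_att_first < 0.01:
        warnings.warn(
            f"MC acceptance {n_acc_first / n_att_first:.3%} over the first "
            f"{n_att_first} steps; move amplitudes likely too large",
            MCWarning, stacklevel=2)

    frames = [config.copy()]
    for k in range(n_frames):
        frames.append(ChainConfiguration(
            frames_out[k].copy(), twists_out[k].copy(),
            config.helical_repeat, config.rise))
    acc = n_acc / n_att if n_att else 0.0
    return ChainTrajectory(frames, params.frame_interval, params,
                           delta_lk=delta_lk, acceptance_rate=acc)


def ensemble(n_bp: int, delta_lk_list, params: SimParams,
             n_replicas: int = 1) -> dict[int, list[ChainTrajectory]]:
    """Independent relaxation trajectories per (delta_lk, replica).

    Replica seeds are derived from ``params.seed`` via SeedSequence
    spawning and logged on each trajectory's params; duplicate derived
    seeds are refused.  Returns ``{delta_lk: [trajectory, ...]}``.
    """
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    delta_lk_list = list(delta_lk_list)
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(len(delta_lk_list) * n_replicas)
    seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]
    if len(set(seeds)) != len(seeds):
        raise ValueError("duplicate derived seeds; choose another base seed")
    out: dict[int, list[ChainTrajectory]] = {}
    k = 0
    for dlk in delta_lk_list:
        start = build_minicircle(n_bp, dlk,
                                 excluded_diameter=params.excluded_diameter)
        trajs = []
        for _ in range(n_replicas):
            p = replace(params, seed=seeds[k])
            k += 1
            trajs.append(mc_relax(start, p, delta_lk=dlk))
        out[dlk] = trajs
    return out
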