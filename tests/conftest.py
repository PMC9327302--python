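"""Shared fixtures: analytic curves and relaxed minicircle ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from plectosearch.chain import ChainConfiguration, SimParams, build_minicircle
from plectosearch.montecarlo import mc_relax


def lemniscate_curve(t: np.ndarray, lift: float, scale: float = 178.0
                     ) -> np.ndarray:
    """Figure-8 space curve: planar Gerono lemniscate lifted out of plane.

    As ``lift -> 0`` the curve approaches a single signed crossing and its
    writhe approaches +1 (the mirror, negative lift, gives -1).
    """
    return np.column_stack([
        scale * np.cos(t),
        scale * np.sin(t) * np.cos(t),
        lift * np.sin(t),
    ])


def figure8_config(n: int = 336, lift: float = 8.0) -> ChainConfiguration:
    """A chain tracing the lifted lemniscate with relaxed uniform twist."""
    t = (np.arange(n) + 0.5) * 2.0 * np.pi / n
    pts = lemniscate_curve(t, lift)
    return ChainConfiguration(pts, np.full(n, 2.0 * np.pi * 32.0 / n))


def quadrature_writhe(curve_fn, n: int = 2000) -> float:
    """Independent writhe oracle: midpoint-rule Gauss double integral on a
    smooth closed curve given as a function of the parameter t in [0, 2pi)."""
    t = (np.arange(n) + 0.5) * 2.0 * np.pi / n
    dt = 2.0 * np.pi / n
    r = curve_fn(t)
    eps = 1e-6
    dr = (curve_fn(t + eps) - curve_fn(t - eps)) / (2.0 * eps)
    total = 0.0
    for i in range(n):
        d = r[i] - r
        nrm = np.linalg.norm(d, axis=1)
        mask = nrm > 1e-9
        cr = np.cross(dr[i], dr)
        num = (cr * d).sum(axis=1)
        total += np.sum(num[mask] / nrm[mask] ** 3) * dt * dt
    return total / (4.0 * np.pi)


def random_wiggly_loop(rng: np.random.Generator, n: int = 120,
                       scale: float = 60.0) -> np.ndarray:
    """Random smooth closed curve (low-order Fourier series) that often
    self-approaches; used to exercise juxtaposition detection."""
    t = 2.0 * np.pi * np.arange(n) / n
    pts = np.zeros((n, 3))
    for dim in range(3):
        coeffs = rng.normal(0, 1, size=4) / (1 + np.arange(4))
        phases = rng.uniform(0, 2 * np.pi, size=4)
        for k in range(4):
            pts[:, dim] += coeffs[k] * np.cos((k + 1) * t + phases[k])
    pts *= scale
    return pts


# -- relaxed minicircle ensembles (shared, computed once per session) ------

RELAX_STEPS = {0: 40_000, 5: 60_000, -4: 60_000}
RELAX_SEED = {0: 101, 5: 105, -4: 107}


@pytest.fixture(scope="session")
def relaxed_runs():
    """One relaxed trajectory per delta-Lk in {-4, 0, +5}.

    Step counts are desk-scale: enough for torsional stress to convert
    into writhe and plectonemes to form at |delta-Lk| >= 4.
    """
    runs = {}
    for dlk, steps in RELAX_STEPS.items():
        params = SimParams(n_steps=steps, frame_interval=2000,
                           seed=RELAX_SEED[dlk])
        runs[dlk] = mc_relax(build_minicircle(336, dlk), params,
                             delta_lk=dlk)
    return runs


@pytest.fixture(scope="session")
def relaxed_zero_pair():
    """Two short independent replicas at delta-Lk = 0 (for the ensemble
    twist-propagation average)."""
    trajs = []
    for seed in (11, 12):
        params = SimParams(n_steps=10_000, frame_interval=100, seed=seed)
        trajs.append(mc_relax(build_minicircle(336, 0), params, delta_lk=0))
    return trajs
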