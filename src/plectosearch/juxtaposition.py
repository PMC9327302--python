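"""Juxtaposition sites: detection, tracking, diffusivity and roughness.

A juxtaposition (jp) site is a pair of sequentially distant DNA segments
(circular separation > N_c bp) brought within d_cutoff of each other by
supercoiling.  Detection follows the standard scanning algorithm for
plectonemes: walk the circle base pair by base pair; the first bp whose
minimum distance to any sequence-distant partner drops below the cutoff
opens a site; skipping N_c bp, the partner closest to the opening bp
closes it.  Defaults N_c = 50 bp and d_cutoff = 60 A.

The roughness of the effective potential felt by a diffusing jp site is
estimated on a 10-A cubic-cell grid: each cell's excess chemical potential
is mu_cell = -kT ln( cell average of exp(-U/kT) ) when per-sample energies
are available, or the occupancy Boltzmann inversion
mu_cell = -kT ln(n_cell / n_total) + const otherwise; the roughness
sigma(mu) is the standard deviation of mu_cell over visited cells (the
additive constant drops out).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .chain import ChainConfiguration, ChainTrajectory, circular_separation

DEFAULT_NC = 50          # bp, minimum sequence separation of a jp pair
DEFAULT_DCUTOFF = 60.0   # A, spatial cutoff for juxtaposition


@dataclass
class JuxtapositionRecord:
    """One detected juxtaposition site (bp indices 1-based)."""

    frame: int
    begin_bp: int
    end_bp: int
    midpoint_xyz: np.ndarray

    @property
    def midpoint_bp(self) -> float:
        return 0.5 * (self.begin_bp + self.end_bp)


def detect_juxtapositions(config: ChainConfiguration, n_c: int = DEFAULT_NC,
                          d_cutoff: float = DEFAULT_DCUTOFF,
                          frame: int = 0) -> list[JuxtapositionRecord]:
    """Scan a frame for juxtaposition sites.

    Walking bp i = 1..n_bp, the first i whose minimum distance to partners
    at circular separation > n_c falls below d_cutoff is a site's begin;
    after skipping n_c bp downstream of the begin, the closest bp is the
    site's end.  Scanning resumes after the end index, so one physical
    crossing yields one record and multiple sites are found in turn.
    """
    n = config.n_bp
    if n_c >= n / 2:
        raise ValueError(f"n_c = {n_c} must be below n_bp/2 = {n / 2:.0f}")
    centers = config.centers
    dists = cdist(centers, centers)
    idx = np.arange(n)
    far = circular_separation(idx[:, None], idx[None, :], n) > n_c

    records: list[JuxtapositionRecord] = []
    i = 0
    while i < n:
        partners = far[i]
        if partners.any() and dists[i][partners].min() < d_cutoff:
            begin = i
            # skip n_c bp downstream, then take the bp closest to the begin
            cand = np.array([(begin + n_c + k) % n for k in range(1, n - 2 * n_c)])
            end = int(cand[np.argmin(dists[begin][cand])])
            # a begin near a previous site's end pairing back to that
            # site's begin is the same crossing seen from the other arm
            mirror = any(
                circular_separation(begin, r.end_bp - 1, n) <= n_c // 2
                and circular_separation(end, r.begin_bp - 1, n) <= n_c // 2
                for r in records)
            if not mirror:
                records.append(JuxtapositionRecord(
                    frame=frame, begin_bp=begin + 1, end_bp=end + 1,
                    midpoint_xyz=0.5 * (centers[begin] + centers[end])))
                # resume after the end index; an end that wrapped past the
                # origin closes the scan
                i = end + 1 if end > begin else n
            else:
                i += 1
        else:
            i += 1
    return records


def detect_trajectory(chain_traj: ChainTrajectory, n_c: int = DEFAULT_NC,
                      d_cutoff: float = DEFAULT_DCUTOFF,
                      ) -> list[list[JuxtapositionRecord]]:
    """Per-frame juxtaposition detection over a trajectory."""
    return [detect_juxtapositions(f, n_c, d_cutoff, frame=k)
            for k, f in enumerate(chain_traj.frames)]


@dataclass
class JpSeries:
    """A juxtaposition site followed across frames by identity linking."""

    frames: list[int] = field(default_factory=list)
    begin_bp: list[int] = field(default_factory=list)
    end_bp: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    def midpoints(self) -> np.ndarray:
        return 0.5 * (np.asarray(self.begin_bp) + np.asarray(self.end_bp))


def track_jp_positions(detections, n_bp: int,
                       link_threshold: int = 20) -> list[JpSeries]:
    """Link per-frame detections into site series.

    A site in frame t+1 continues the series whose last begin index is the
    nearest circular match within ``link_threshold`` bp; larger moves (or
    no match) terminate the series and start a new one.  ``detections``
    may be a list of per-frame record lists or a ChainTrajectory-shaped
    object already detected with :func:`detect_trajectory`.
    """
    series: list[JpSeries] = []
    active: list[JpSeries] = []
    for t, recs in enumerate(detections):
        used = [False] * len(recs)
        still_active: list[JpSeries] = []
        for s in active:
            best, best_d = None, link_threshold + 1
            for k, r in enumerate(recs):
                if used[k]:
                    continue
                d = int(circular_separation(s.begin_bp[-1] - 1,
                                            r.begin_bp - 1, n_bp))
                if d < best_d:
                    best, best_d = k, d
            if best is not None and best_d <= link_threshold:
                r = recs[best]
                used[best] = True
                s.frames.append(t)
                s.begin_bp.append(r.begin_bp)
                s.end_bp.append(r.end_bp)
                still_active.append(s)
        for k, r in enumerate(recs):
            if not used[k]:
                s = JpSeries([t], [r.begin_bp], [r.end_bp])
                series.append(s)
                still_active.append(s)
        active = still_active
    return series


def jp_diffusivity(series: JpSeries | np.ndarray, n_bp: int,
                   fit_lags: int = 10, min_length: int = 50) -> float:
    """Diffusivity of a jp-site midpoint in bp^2/frame.

    Half the slope of the mean-squared circular displacement of the site
    midpoint index versus lag, fit through the origin over the first
    ``fit_lags`` lags.  Series shorter than ``min_length`` frames are
    refused.
    """
    mid = (series.midpoints() if isinstance(series, JpSeries)
           else np.asarray(series, dtype=float))
    if mid.size < min_length:
        raise ValueError(
            f"series of {mid.size} frames is too short (need {min_length})")
    # unwrap circular midpoint index before differencing
    steps = (np.diff(mid) + n_bp / 2) % n_bp - n_bp / 2
    pos = np.concatenate([[0.0], np.cumsum(steps)])
    lags = np.arange(1, min(fit_lags, mid.size - 1) + 1)
    msd = np.array([np.mean((pos[l:] - pos[:-l]) ** 2) for l in lags])
    # least-squares slope through the origin: MSD = 2 D tau
    slope = float(np.dot(lags, msd) / np.dot(lags, lags))
    return max(0.0, slope / 2.0)


KB_KCAL = 0.0019872041  # kcal/mol/K, used only to express kT in energy mode


@dataclass
class RoughnessReport:
    """Cell potentials and their spread, in units of kT."""

    cell_size: float
    mu_cells: dict
    sigma_mu: float
    n_cells_visited: int


def jp_roughness(midpoint_samples: np.ndarray,
                 energies: np.ndarray | None = None,
                 cell_size: float = 10.0,
                 temperature: float = 300.0,
                 min_samples: int = 500) -> RoughnessReport:
    """Roughness sigma(mu_cell) of the potential felt by a diffusing site.

    Space is partitioned into cubic cells of ``cell_size`` (A, default 10).
    With ``energies`` (kT units) given, mu_cell = -ln<exp(-U)> over the
    samples falling in the cell; otherwise the occupancy inversion
    mu_cell = -ln(n_cell/n_total) is used (equal up to a constant when
    sampling is Boltzmann).  sigma_mu is the standard deviation over
    visited cells; unvisited cells are excluded.  Fewer than 3 visited
    cells, or fewer than ``min_samples`` samples, are refused.
    """
    pts = np.asarray(midpoint_samples, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.shape[0] < min_samples:
        raise ValueError(
            f"{pts.shape[0]} samples < required minimum {min_samples}")
    cells = np.floor(pts / cell_size).astype(np.int64)
    keys = [tuple(c) for c in cells]
    mu: dict = {}
    if energies is not None:
        energies = np.asarray(energies, dtype=float)
        if energies.shape[0] != pts.shape[0]:
            raise ValueError("one energy per sample required")
        acc: dict = {}
        for k, e in zip(keys, energies):
            acc.setdefault(k, []).append(e)
        for k, es in acc.items():
            es = np.asarray(es)
            # -ln of the cell average of the Boltzmann factor
            m = es.min()
            mu[k] = -(np.log(np.mean(np.exp(-(es - m)))) - m)
    else:
        counts: dict = {}
        for k in keys:
            counts[k] = counts.get(k, 0) + 1
        total = pts.shape[0]
        for k, c in counts.items():
            mu[k] = -np.log(c / total)
    if len(mu) < 3:
        raise ValueError(
            f"only {len(mu)} visited cells; roughness undefined (need >= 3)")
    values = np.array(list(mu.values()))
    return RoughnessReport(cell_size=cell_size, mu_cells=mu,
                           sigma_mu=float(values.std()),
                           n_cells_visited=len(mu))
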