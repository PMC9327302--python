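"""Closed DNA minicircle representation.

A minicircle is modelled as a closed chain of base-pair centers (one bead
per bp, coordinates in Angstrom) plus a scalar twist increment per junction
i -> i+1 (radians).  The linking number of a freshly built circle is set by
the canonical relation Lk = n_bp / helical_repeat + delta_lk, so a relaxed
336-bp circle carries Lk0 = 336 / 10.5 = 32 helical turns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

DEFAULT_HELICAL_REPEAT = 10.5  # bp per helical turn (B-DNA)
DEFAULT_RISE = 3.34  # Angstrom per bp
DEFAULT_EXCLUDED_DIAMETER = 20.0  # Angstrom, duplex hard-core diameter

BOND_TOLERANCE = 0.20  # consecutive-center distance must stay in rise +/- 20%


class ChainError(ValueError):
    """Raised when a chain violates its structural invariants."""


@dataclass
class ChainConfiguration:
    """One closed minicircle snapshot.

    Attributes
    ----------
    centers
        (n_bp, 3) float array of base-pair center coordinates in Angstrom.
        Circular indexing: junction ``n_bp - 1 -> 0`` closes the chain.
    twist_increments
        (n_bp,) float array, twist of each junction ``i -> i+1`` in radians.
    helical_repeat, rise
        Geometry of relaxed B-DNA (bp/turn, Angstrom/bp).
    """

    centers: np.ndarray
    twist_increments: np.ndarray
    helical_repeat: float = DEFAULT_HELICAL_REPEAT
    rise: float = DEFAULT_RISE

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.twist_increments = np.asarray(self.twist_increments, dtype=float)
        if self.centers.ndim != 2 or self.centers.shape[1] != 3:
            raise ChainError("centers must be an (n_bp, 3) array")
        if self.twist_increments.shape != (self.centers.shape[0],):
            raise ChainError("need exactly one twist increment per junction")

    @property
    def n_bp(self) -> int:
        return self.centers.shape[0]

    def bond_vectors(self) -> np.ndarray:
        """Junction vectors r[i+1] - r[i], including the closing junction."""
        return np.roll(self.centers, -1, axis=0) - self.centers

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.bond_vectors(), axis=1)

    def total_twist(self) -> float:
        """Total twist Tw in turns: sum of junction increments over 2*pi."""
        return float(self.twist_increments.sum() / (2.0 * np.pi))

    def copy(self) -> "ChainConfiguration":
        return ChainConfiguration(
            self.centers.copy(), self.twist_increments.copy(),
            self.helical_repeat, self.rise,
        )

    def validate(self, excluded_diameter: float = DEFAULT_EXCLUDED_DIAMETER) -> None:
        """Check closure, bond lengths, excluded volume and finite twist."""
        lengths = self.bond_lengths()
        lo = self.rise * (1.0 - BOND_TOLERANCE)
        hi = self.rise * (1.0 + BOND_TOLERANCE)
        if lengths.min() < lo or lengths.max() > hi:
            raise ChainError(
                f"bond lengths outside rise +/- {BOND_TOLERANCE:.0%}: "
                f"range [{lengths.min():.2f}, {lengths.max():.2f}] A"
            )
        if not np.isfinite(self.twist_increments).all():
            raise ChainError("non-finite twist increment")
        min_sep = ev_min_separation(excluded_diameter, self.rise)
        d = min_nonneighbor_distance(self.centers, min_sep)
        if d < excluded_diameter:
            raise ChainError(
                f"excluded volume violated: min non-neighbor distance {d:.2f} A"
            )


def circular_separation(i, j, n_bp: int):
    """Sequence separation min(|i-j|, n_bp - |i-j|) with circular indexing."""
    d = np.abs(np.asarray(i) - np.asarray(j))
    return np.minimum(d, n_bp - d)


def ev_min_separation(excluded_diameter: float = DEFAULT_EXCLUDED_DIAMETER,
                      rise: float = DEFAULT_RISE) -> int:
    """Smallest circular index separation subject to the excluded-volume core.

    With one bead per bp the bead spacing (3.34 A) is much finer than the
    duplex hard-core diameter (20 A), so beads a few junctions apart are
    necessarily closer than the core; the hard core applies only to pairs
    whose contour separation exceeds the core diameter, i.e. pairs that can
    belong to distinct duplex segments.
    """
    return int(np.ceil(excluded_diameter / rise)) + 2


def min_nonneighbor_distance(centers: np.ndarray, min_sep: int = 8) -> float:
    """Minimum pair distance over beads with circular index separation >= min_sep."""
    n = centers.shape[0]
    ii, jj = np.triu_indices(n, k=min_sep)
    keep = circular_separation(ii, jj, n) >= min_sep
    ii, jj = ii[keep], jj[keep]
    d = np.linalg.norm(centers[ii] - centers[jj], axis=1)
    return float(d.min()) if d.size else np.inf


def build_minicircle(
    n_bp: int,
    delta_lk: int,
    helical_repeat: float = DEFAULT_HELICAL_REPEAT,
    rise: float = DEFAULT_RISE,
    excluded_diameter: float = DEFAULT_EXCLUDED_DIAMETER,
) -> ChainConfiguration:
    """Build a planar, uniformly twisted minicircle at prescribed delta-Lk.

    The circle has circumference ``n_bp * rise`` and carries linking number
    ``Lk = n_bp / helical_repeat + delta_lk`` as uniform twist increments
    (all writhe is zero for a planar curve, so Tw = Lk at build time).

    Raises
    ------
    ChainError
        If ``n_bp`` is too small to close the circle without violating the
        excluded-volume diameter.
    """
    if n_bp < 30:
        raise ChainError(f"n_bp = {n_bp} below the 30-bp minimum")
    if helical_repeat <= 0:
        raise ChainError("helical_repeat must be positive")
    radius = n_bp * rise / (2.0 * np.pi)
    if 2.0 * radius < excluded_diameter:
        raise ChainError(
            f"{n_bp} bp circle (diameter {2 * radius:.1f} A) cannot close "
            f"outside the {excluded_diameter:.0f} A excluded-volume core"
        )
    phi = 2.0 * np.pi * np.arange(n_bp) / n_bp
    centers = np.column_stack(
        [radius * np.cos(phi), radius * np.sin(phi), np.zeros(n_bp)]
    )
    lk = n_bp / helical_repeat + delta_lk
    twist = np.full(n_bp, 2.0 * np.pi * lk / n_bp)
    config = ChainConfiguration(centers, twist, helical_repeat, rise)
    config.validate(excluded_diameter)
    return config


def linking_number(n_bp: int, delta_lk: int,
                   helical_repeat: float = DEFAULT_HELICAL_REPEAT) -> float:
    """Lk = n_bp / helical_repeat + delta_lk."""
    return n_bp / helical_repeat + delta_lk


@dataclass
class SimParams:
    """Monte Carlo relaxation parameters (lengths in Angstrom, T in Kelvin)."""

    bending_persistence: float = 500.0
    torsional_persistence: float = 750.0
    temperature: float = 300.0
    excluded_diameter: float = DEFAULT_EXCLUDED_DIAMETER
    box_edge: float = 600.0
    n_steps: int = 10_000
    frame_interval: int = 100
    displacement_amplitude: float = 0.4   # A, single-bead move
    crankshaft_amplitude: float = 0.6     # rad, arc rotation
    max_arc: int = 20                     # beads in a small crankshaft arc
    large_arc_prob: float = 0.3           # fraction of crankshafts up to n/2 beads
    twist_move_prob: float = 0.3          # twist-transfer moves (twist diffusion)
    disp_move_prob: float = 0.1           # single-bead displacement moves
    twist_quantum: float = 0.05           # rad, twist-transfer amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bending_persistence", "torsional_persistence",
                     "excluded_diameter", "box_edge"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class ChainTrajectory:
    """Time-ordered minicircle frames at a fixed frame interval."""

    frames: list[ChainConfiguration]
    frame_interval: int
    params: SimParams
    delta_lk: int | None = None
    acceptance_rate: float | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ChainError("trajectory needs at least one frame")
        n = self.frames[0].n_bp
        if any(f.n_bp != n for f in self.frames):
            raise ChainError("all frames must share n_bp")

    @property
    def n_bp(self) -> int:
        return self.frames[0].n_bp

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[ChainConfiguration]:
        return iter(self.frames)
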