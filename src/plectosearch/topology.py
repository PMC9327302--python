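"""Topological and geometric descriptors of minicircle configurations.

White's theorem, Lk = Tw + Wr, links the three quantities reported here:
twist (Tw, total helical winding in turns), writhe (Wr, signed coiling of
the duplex axis about itself, right-handed crossings positive) and the
linking number Lk, a topological invariant of the closed circle.  The
superhelical density sigma = delta_Lk / Lk0 normalises torsional stress by
circle size.  Shape classes follow the conventional census of minicircle
conformations: open circle, open figure-8, figure-8, racquet, and
plectonemes with 2, 3 or more juxtaposition sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _geometry
from .chain import ChainConfiguration, ChainError

SHAPE_CLASSES = (
    "open_circle", "open_figure8", "figure8", "racquet", "jp2", "jp3", "jp_gt3",
)


def twist(config: ChainConfiguration) -> float:
    """Total twist Tw in helical turns (sum of junction increments / 2*pi)."""
    return config.total_twist()


def writhe(config_or_centers) -> float:
    """Writhe of a closed polygonal chain by the exact pairwise Gauss sum.

    Accepts a ChainConfiguration or a raw (n, 3) coordinate array.  The
    curve is always treated as closed (last vertex joins the first); an
    array with fewer than 3 vertices is refused.
    """
    centers = (config_or_centers.centers
               if isinstance(config_or_centers, ChainConfiguration)
               else np.asarray(config_or_centers, dtype=float))
    if centers.ndim != 2 or centers.shape[0] < 3:
        raise ChainError("writhe needs a closed chain of >= 3 vertices")
    return float(_geometry.writhe_full(np.ascontiguousarray(centers)))


def linking_number_of(config: ChainConfiguration) -> float:
    """Lk = Tw + Wr for the frame (White's theorem)."""
    return twist(config) + writhe(config)


def superhelical_density(delta_lk: float, lk0: float) -> float:
    """sigma = delta_Lk / Lk0."""
    if lk0 == 0:
        raise ValueError("Lk0 must be nonzero")
    return delta_lk / lk0


def radius_of_gyration(config_or_centers) -> float:
    """Root-mean-square distance of bp centers from their centroid (A)."""
    centers = (config_or_centers.centers
               if isinstance(config_or_centers, ChainConfiguration)
               else np.asarray(config_or_centers, dtype=float))
    rel = centers - centers.mean(axis=0)
    return float(np.sqrt((rel ** 2).sum(axis=1).mean()))


def ellipticity(config_or_centers) -> float:
    """Major/minor axis ratio of the best-fit ellipse (always >= 1).

    The chain is projected onto its best-fit plane (two leading principal
    axes of the centered coordinates); the ratio is the square root of the
    ratio of the two largest eigenvalues of the planar second-moment
    tensor.  Collinear configurations are refused.
    """
    centers = (config_or_centers.centers
               if isinstance(config_or_centers, ChainConfiguration)
               else np.asarray(config_or_centers, dtype=float))
    rel = centers - centers.mean(axis=0)
    cov = rel.T @ rel / rel.shape[0]
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    if eigvals[1] <= 1e-12 * max(eigvals[0], 1.0):
        raise ChainError("degenerate (collinear) configuration")
    return float(np.sqrt(eigvals[0] / eigvals[1]))


def local_curvature(config: ChainConfiguration, bp_index: int,
                    window: int = 10) -> float:
    """Bend angle (degrees) across a window centered at ``bp_index``.

    The angle between the chain tangents entering and leaving the window,
    i.e. between segment directions ``window/2`` junctions before and after
    the site (circular indexing, 1-based bp index).
    """
    if window < 3:
        raise ValueError("window must be >= 3 bp")
    n = config.n_bp
    i = (bp_index - 1) % n
    h = window // 2
    bonds = config.bond_vectors()
    t_in = bonds[(i - h) % n]
    t_out = bonds[(i + h) % n]
    cosang = np.dot(t_in, t_out) / (np.linalg.norm(t_in) * np.linalg.norm(t_out))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


@dataclass
class ShapeRules:
    """Thresholds for the rule-based shape classifier."""

    writhe_open: float = 0.5     # |Wr| below which a 0-jp frame is an open circle
    racquet_loop_frac: float = 0.25  # minor-loop fraction separating racquet / figure-8


def classify_shape(config: ChainConfiguration, jp_records,
                   rules: ShapeRules | None = None) -> str:
    """Classify a frame into one of SHAPE_CLASSES.

    Rules (deterministic, monotone in intertwining): with no juxtaposition
    site the frame is an open circle if |Wr| < 0.5, else an open figure-8;
    one site splits the circle into two loops -- a racquet if the minor
    loop is under 25% of the contour, a figure-8 otherwise; two or more
    sites are binned by count.
    """
    rules = rules or ShapeRules()
    n_jp = len(jp_records)
    if n_jp == 0:
        wr = writhe(config)
        return "open_circle" if abs(wr) < rules.writhe_open else "open_figure8"
    if n_jp == 1:
        rec = jp_records[0]
        n = config.n_bp
        arc = abs(rec.end_bp - rec.begin_bp) % n
        minor = min(arc, n - arc)
        return "racquet" if minor < rules.racquet_loop_frac * n else "figure8"
    if n_jp == 2:
        return "jp2"
    if n_jp == 3:
        return "jp3"
    return "jp_gt3"


@dataclass
class TopologyReport:
    """Per-frame topology summary."""

    tw: float
    wr: float
    lk: float
    sigma: float
    rg: float
    ellipticity: float
    shape_class: str


def topology_report(config: ChainConfiguration, jp_records,
                    delta_lk: float | None = None,
                    rules: ShapeRules | None = None) -> TopologyReport:
    tw = twist(config)
    wr = writhe(config)
    lk = tw + wr
    lk0 = config.n_bp / config.helical_repeat
    if delta_lk is None:
        delta_lk = lk - lk0
    try:
        ell = ellipticity(config)
    except ChainError:
        ell = float("nan")
    return TopologyReport(
        tw=tw, wr=wr, lk=lk,
        sigma=superhelical_density(delta_lk, lk0),
        rg=radius_of_gyration(config),
        ellipticity=ell,
        shape_class=classify_shape(config, jp_records, rules),
    )
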