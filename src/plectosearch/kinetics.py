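"""Discrete-state stochastic model of facilitated target search.

A single protein searches for a target on a DNA of L binding sites
(lattice 1..L, reflecting ends, target absorbing).  From solution it binds
any site with total rate k_on (uniformly distributed, k_on/L per site),
unbinds from a nonspecific site with rate k_off, slides to lattice
neighbours with rate u each direction, and crosses each juxtaposition
link -- a pair of sequentially distant but spatially close sites -- with
rate k_t in both directions.

The mean first-passage time (MFPT) from solution is computed two ways:

* :func:`mfpt_master` -- exact linear solve of the first-passage system of
  the full continuous-time Markov chain (solution + L-1 bound states).
* :func:`mfpt_eq2` -- the closed-form search time
  ``T = (k_off L + k_on [L - S(0)]) / (k_on k_off S(0))`` where the
  auxiliary function S(0) is the sum over sites of the splitting
  probability of reaching the target before dissociating, obtained by a
  linear solve of the bound-lattice dynamics.  The identity
  1 - F_i = k_off * E[bound exit time from i] (exponential killing) makes
  the two routes mathematically equivalent; their numerical agreement is
  the package's central consistency check.

A Gillespie kinetic Monte Carlo sampler (:func:`kmc_fpt`) simulates the
same process, optionally with mobile juxtaposition links whose endpoints
perform an unbiased lattice walk of prescribed mobility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit


@dataclass
class SearchModel:
    """Target-search specification (rates in 1/s, sites 1-based)."""

    L: int = 336
    k_on: float = 112_500.0     # total solution->DNA binding rate
    k_off: float = 9e-5
    u: float = 1e3              # sliding rate, each direction
    k_t: float = 1e6            # transfer rate per jp link, each direction
    target: int = 336
    jp_links: list[tuple[int, int]] = field(default_factory=list)
    jp_mobility: float = 0.0    # sites^2/s, mobile-link variant (kMC only)
    kon_per_site: bool = False  # alternative reading: k_on applies per site

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if not 1 <= self.target <= self.L:
            raise ValueError("target must lie in [1, L]")
        for r in (self.k_on, self.k_off, self.u, self.k_t, self.jp_mobility):
            if r < 0:
                raise ValueError("rates must be non-negative")
        for a, b in self.jp_links:
            if not (1 <= a <= self.L and 1 <= b <= self.L) or a == b:
                raise ValueError(f"invalid jp link ({a}, {b})")

    @property
    def kon_total(self) -> float:
        return self.k_on * self.L if self.kon_per_site else self.k_on


def kon_from_kd(k_off: float, k_d: float) -> float:
    """Association rate from the dissociation constant: k_on = k_off / K_D.

    Units follow the inputs (e.g. k_off in 1/s and K_D in molar give the
    conventional k_on in 1/s of the discrete-state model).
    """
    if k_d <= 0:
        raise ValueError("K_D must be positive")
    return k_off / k_d


def _solve_refined(A: np.ndarray, b: np.ndarray, n_refine: int = 2
                   ) -> np.ndarray:
    """Linear solve with iterative refinement.

    Search models mix rates spanning many decades, so a single LU solve
    can lose several digits; a couple of refinement steps restore
    near-machine accuracy.
    """
    import scipy.linalg as sla

    lu, piv = sla.lu_factor(A)
    x = sla.lu_solve((lu, piv), b)
    for _ in range(n_refine):
        r = b - A @ x
        x = x + sla.lu_solve((lu, piv), r)
    return x


def _bound_generator(model: SearchModel) -> tuple[np.ndarray, np.ndarray]:
    """Off-diagonal bound-lattice rates (L x L) and rate into the target.

    Row i gives transitions of a protein bound at site i+1 to other bound
    sites; ``to_target[i]`` collects sliding/transfer rates into the
    absorbing target.  The target row is zero.
    """
    L, u, kt = model.L, model.u, model.k_t
    tgt = model.target - 1
    Q = np.zeros((L, L))
    to_target = np.zeros(L)
    for i in range(L):
        if i == tgt:
            continue
        for j in (i - 1, i + 1):        # reflecting lattice ends
            if 0 <= j < L:
                if j == tgt:
                    to_target[i] += u
                else:
                    Q[i, j] += u
    for a, b in model.jp_links:
        for i, j in ((a - 1, b - 1), (b - 1, a - 1)):
            if i == tgt:
                continue
            if j == tgt:
                to_target[i] += kt
            else:
                Q[i, j] += kt
    return Q, to_target


def splitting_probabilities(model: SearchModel) -> np.ndarray:
    """F_i: probability of reaching the target before dissociating,
    starting bound at site i (F_target = 1)."""
    L = model.L
    tgt = model.target - 1
    Q, to_target = _bound_generator(model)
    # (sum of outgoing incl. k_off) F_i - sum_j Q_ij F_j = rate_to_target_i
    out = Q.sum(axis=1) + to_target + model.k_off
    A = np.diag(out) - Q
    keep = np.arange(L) != tgt
    F = np.zeros(L)
    F[keep] = _solve_refined(A[np.ix_(keep, keep)], to_target[keep])
    F[tgt] = 1.0
    return F


def _dissociation_probabilities(model: SearchModel) -> np.ndarray:
    """G_i = 1 - F_i, the probability of dissociating before reaching the
    target, solved directly (avoids cancellation when F_i is near 1)."""
    L = model.L
    tgt = model.target - 1
    Q, to_target = _bound_generator(model)
    out = Q.sum(axis=1) + to_target + model.k_off
    A = np.diag(out) - Q
    keep = np.arange(L) != tgt
    G = np.zeros(L)
    G[keep] = _solve_refined(A[np.ix_(keep, keep)],
                             np.full(keep.sum(), model.k_off))
    return G


def s_aux(model: SearchModel) -> float:
    """The auxiliary function S(0): sum of splitting probabilities."""
    return float(splitting_probabilities(model).sum())


def mfpt_eq2(model: SearchModel) -> float:
    """Closed-form mean search time from solution.

    ``T = (k_off L + k_on [L - S(0)]) / (k_on k_off S(0))`` with k_on the
    total binding rate.  Degenerate models where the target is effectively
    unreachable (S(0) -> 0) are refused.
    """
    if model.kon_total <= 0:
        raise ValueError("k_on = 0 disconnects the model (infinite MFPT)")
    if model.k_off <= 0:
        raise ValueError("Eq. 2 needs k_off > 0; use mfpt_master instead")
    S = s_aux(model)
    if S < 1e-300:
        raise ValueError("S(0) = 0: target unreachable before unbinding")
    kon = model.kon_total
    L = model.L
    # L - S is accumulated from the directly-solved dissociation
    # probabilities; summing 1 - F_i would cancel badly when F_i -> 1
    l_minus_s = float(_dissociation_probabilities(model).sum())
    return (model.k_off * L + kon * l_minus_s) / (kon * model.k_off * S)


def mfpt_master(model: SearchModel) -> tuple[float, np.ndarray]:
    """Exact MFPT by solving the full first-passage linear system.

    Returns ``(T_from_solution, tau)`` where ``tau[i]`` is the MFPT from
    the bound state at site i+1 (``tau[target-1] = 0``).
    """
    if model.kon_total <= 0:
        raise ValueError("k_on = 0 disconnects the model (infinite MFPT)")
    L = model.L
    tgt = model.target - 1
    kon_site = model.kon_total / L
    Q, to_target = _bound_generator(model)

    # transient states: 0 = solution, 1..L = bound sites (minus target)
    n = 1 + L
    A = np.zeros((n, n))
    bvec = -np.ones(n)
    # solution row: leaves at total rate kon_total to all sites uniformly
    A[0, 0] = -model.kon_total
    for i in range(L):
        if i != tgt:
            A[0, 1 + i] = kon_site
    # bound rows
    for i in range(L):
        if i == tgt:
            continue
        out = Q[i].sum() + to_target[i] + model.k_off
        A[1 + i, 1 + i] = -out
        A[1 + i, 0] = model.k_off
        for j in range(L):
            if Q[i, j] > 0 and j != tgt:
                A[1 + i, 1 + j] = Q[i, j]
    keep = np.ones(n, dtype=bool)
    keep[1 + tgt] = False
    tau = np.zeros(n)
    tau[keep] = _solve_refined(A[np.ix_(keep, keep)], bvec[keep])
    return float(tau[0]), tau[1:]


def figure_layouts(L: int) -> list[list[tuple[int, int]]]:
    """Juxtaposition-link layouts for 0..3 sites on an L-site lattice.

    A juxtaposition placed at contour position p links sites (p, L): the
    plectoneme apex at p is spatially adjacent to the target-bearing end
    of the lattice.  Placements follow the L/2; (L/2, L/3);
    (L/4, 3L/8, L/2) convention.
    """
    p = lambda frac: int(round(L * frac))
    return [
        [],
        [(p(1 / 2), L)],
        [(p(1 / 2), L), (p(1 / 3), L)],
        [(p(1 / 4), L), (p(3 / 8), L), (p(1 / 2), L)],
    ]


def ratio_curve(model: SearchModel | None = None,
                jp_layouts: list[list[tuple[int, int]]] | None = None,
                ) -> list[tuple[int, float]]:
    """T/T0 versus number of juxtaposition sites.

    ``model`` supplies L, rates and target (defaults are the Fis search
    parameters); layouts default to :func:`figure_layouts`.  The first
    layout (no links) defines T0.
    """
    model = model or SearchModel()
    layouts = jp_layouts if jp_layouts is not None else figure_layouts(model.L)
    t0 = mfpt_eq2(replace(model, jp_links=list(layouts[0])))
    out = []
    for layout in layouts:
        t = mfpt_eq2(replace(model, jp_links=list(layout)))
        out.append((len(layout), t / t0))
    return out


@njit(cache=True)
def _kmc_one(L, kon_site, koff, u, kt, tgt, links, mobility, t_max, seed):
    """One Gillespie first-passage time.  state -1 = solution; links is an
    (m, 2) int array of 0-based endpoints, mutated in place when mobile."""
    np.random.seed(seed)
    state = -1
    t = 0.0
    m = links.shape[0]
    while t < t_max:
        if state == -1:
            rate_total = kon_site * L + 2.0 * mobility * m
            t += -np.log(np.random.random()) / rate_total
            r = np.random.random() * rate_total
            if r < kon_site * L:
                state = np.random.randint(0, L)
                if state == tgt:
                    return t
            else:
                k = int((r - kon_site * L) // (2.0 * mobility))
                if k >= m:
                    k = m - 1
                e = 0 if (r - kon_site * L - 2.0 * mobility * k) < mobility else 1
                step = -1 if np.random.random() < 0.5 else 1
                pos = links[k, e] + step
                if 0 <= pos < L:
                    links[k, e] = pos
        else:
            # bound at nonspecific site `state`
            nleft = 1 if state > 0 else 0
            nright = 1 if state < L - 1 else 0
            nlink = 0
            for q in range(m):
                if links[q, 0] == state or links[q, 1] == state:
                    nlink += 1
            rate_total = (koff + u * (nleft + nright) + kt * nlink
                          + 2.0 * mobility * m)
            t += -np.log(np.random.random()) / rate_total
            r = np.random.random() * rate_total
            if r < koff:
                state = -1
                continue
            r -= koff
            if nleft and r < u:
                state -= 1
                if state == tgt:
                    return t
                continue
            if nleft:
                r -= u
            if nright and r < u:
                state += 1
                if state == tgt:
                    return t
                continue
            if nright:
                r -= u
            done = False
            for q in range(m):
                if links[q, 0] == state or links[q, 1] == state:
                    if r < kt:
                        state = links[q, 1] if links[q, 0] == state \
                            else links[q, 0]
                        done = True
                        break
                    r -= kt
            if done:
                if state == tgt:
                    return t
                continue
            # remaining probability: a jp endpoint moves
            k = int(r // (2.0 * mobility)) if mobility > 0 else 0
            if k >= m:
                k = m - 1
            if m > 0 and mobility > 0.0:
                e = 0 if (r - 2.0 * mobility * k) < mobility else 1
                step = -1 if np.random.random() < 0.5 else 1
                pos = links[k, e] + step
                if 0 <= pos < L:
                    links[k, e] = pos
    return -1.0  # did not absorb within t_max


@dataclass
class KmcResult:
    mean: float
    stderr: float
    n_walkers: int
    n_censored: int
    samples: np.ndarray


def kmc_fpt(model: SearchModel, n_walkers: int = 1000, seed: int = 0,
            t_max_factor: float = 1e3) -> KmcResult:
    """Sample first-passage times by kinetic Monte Carlo (Gillespie).

    Each walker starts in solution.  With ``jp_mobility > 0`` the link
    endpoints perform an unbiased lattice walk (rate jp_mobility per
    endpoint per direction) interleaved exactly with the search events.
    Walkers exceeding ``t_max_factor`` times the analytic no-link MFPT are
    reported as censored with a warning, never silently truncated.
    """
    if n_walkers < 1:
        raise ValueError("n_walkers must be >= 1")
    base = mfpt_master(replace(model, jp_links=[], jp_mobility=0.0))[0]
    t_max = t_max_factor * base
    links0 = np.array([[a - 1, b - 1] for a, b in model.jp_links],
                      dtype=np.int64).reshape(-1, 2)
    kon_site = model.kon_total / model.L
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n_walkers)]
    samples = np.empty(n_walkers)
    censored = 0
    for w in range(n_walkers):
        links = links0.copy()
        fpt = _kmc_one(model.L, kon_site, model.k_off, model.u, model.k_t,
                       model.target - 1, links, model.jp_mobility,
                       t_max, seeds[w])
        if fpt < 0:
            censored += 1
            samples[w] = np.nan
        else:
            samples[w] = fpt
    good = samples[np.isfinite(samples)]
    if censored:
        warnings.warn(f"{censored}/{n_walkers} walkers not absorbed within "
                      f"{t_max:.3g} s; mean computed over absorbed walkers",
                      UserWarning, stacklevel=2)
    mean = float(good.mean()) if good.size else float("nan")
    stderr = float(good.std(ddof=1) / np.sqrt(good.size)) if good.size > 1 \
        else float("nan")
    return KmcResult(mean=mean, stderr=stderr, n_walkers=n_walkers,
                     n_censored=censored, samples=samples)
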