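"""Juxtaposition detection, tracking, diffusivity and roughness."""

import numpy as np
import pytest

from plectosearch.chain import ChainConfiguration, build_minicircle
from plectosearch.juxtaposition import (
    JpSeries,
    detect_juxtapositions,
    jp_diffusivity,
    jp_roughness,
    track_jp_positions,
)

from conftest import figure8_config, random_wiggly_loop


def brute_force_detect(centers, n_c=50, d_cutoff=60.0):
    """Independent reference implementation: plain Python loops over all
    pairs, no vectorization, same scanning semantics."""
    n = len(centers)

    def dist(i, j):
        return float(np.sqrt(sum((centers[i][k] - centers[j][k]) ** 2
                                 for k in range(3))))

    def circ(i, j):
        d = abs(i - j)
        return min(d, n - d)

    sites = []
    i = 0
    while i < n:
        hit = False
        for j in range(n):
            if circ(i, j) > n_c and dist(i, j) < d_cutoff:
                hit = True
                break
        if hit:
            begin = i
            best, best_d = None, None
            for k in range(1, n - 2 * n_c):
                j = (begin + n_c + k) % n
                d = dist(begin, j)
                if best_d is None or d < best_d:
                    best, best_d = j, d
            end = best
            mirror = False
            for b0, e0 in sites:
                if circ(begin, e0) <= n_c // 2 and circ(end, b0) <= n_c // 2:
                    mirror = True
            if not mirror:
                sites.append((begin, end))
                i = end + 1 if end > begin else n
            else:
                i += 1
        else:
            i += 1
    return [(b + 1, e + 1) for b, e in sites]


class TestDetection:
    def test_planar_circle_has_no_sites(self):
        # all sequence-distant pairs of a 178 A radius circle exceed 60 A
        assert detect_juxtapositions(build_minicircle(336, 0)) == []

    def test_figure8_has_one_site_at_the_crossing(self):
        cfg = figure8_config(lift=8.0)
        recs = detect_juxtapositions(cfg)
        assert len(recs) == 1
        # the lemniscate crossing sits near bp 84 and 252; the scan opens
        # the site where the arms first come inside the cutoff
        assert 60 <= recs[0].begin_bp <= 95
        assert 240 <= recs[0].end_bp <= 265

    def test_record_invariants(self):
        cfg = figure8_config(lift=8.0)
        for rec in detect_juxtapositions(cfg):
            sep = abs(rec.end_bp - rec.begin_bp)
            assert min(sep, 336 - sep) > 50
            d = np.linalg.norm(cfg.centers[rec.begin_bp - 1]
                               - cfg.centers[rec.end_bp - 1])
            # end is the closest admissible partner, inside or near cutoff
            assert d < 60.0 + 10.0

    def test_refuses_nc_too_large(self):
        with pytest.raises(ValueError):
            detect_juxtapositions(build_minicircle(336, 0), n_c=170)

    def test_matches_brute_force_on_random_frames(self):
        # oracle equivalence on 100 random self-approaching loops
        rng = np.random.default_rng(2024)
        n_c, d_cut = 20, 25.0
        for _ in range(100):
            pts = random_wiggly_loop(rng, n=120, scale=60.0)
            cfg = ChainConfiguration(pts, np.zeros(120))
            got = [(r.begin_bp, r.end_bp)
                   for r in detect_juxtapositions(cfg, n_c, d_cut)]
            assert got == brute_force_detect(pts, n_c, d_cut)

    def test_invariant_under_rigid_motion(self):
        cfg = figure8_config(lift=8.0)
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = ChainConfiguration(cfg.centers @ q.T + 123.0,
                                   cfg.twist_increments)
        a = [(r.begin_bp, r.end_bp) for r in detect_juxtapositions(cfg)]
        b = [(r.begin_bp, r.end_bp) for r in detect_juxtapositions(moved)]
        assert a == b


class TestTracking:
    def _frames_from_pairs(self, pairs_per_frame, n=336):
        """Synthesise per-frame detection lists from (begin, end) pairs."""
        from plectosearch.juxtaposition import JuxtapositionRecord
        out = []
        for t, pairs in enumerate(pairs_per_frame):
            out.append([JuxtapositionRecord(t, b, e, np.zeros(3))
                        for b, e in pairs])
        return out

    def test_static_site_gives_constant_series(self):
        det = self._frames_from_pairs([[(84, 252)]] * 20)
        series = track_jp_positions(det, 336)
        assert len(series) == 1
        assert series[0].begin_bp == [84] * 20

    def test_programmed_drift_recovered(self):
        det = self._frames_from_pairs(
            [[(84 + t, 252 + t)] for t in range(50)])
        series = track_jp_positions(det, 336)
        assert len(series) == 1
        slopes = np.diff(series[0].midpoints())
        np.testing.assert_allclose(slopes, 1.0)

    def test_large_move_starts_new_series(self):
        det = self._frames_from_pairs([[(84, 252)]] * 5 + [[(150, 320)]] * 5)
        series = track_jp_positions(det, 336, link_threshold=20)
        assert len(series) == 2

    def test_mobility_ratio_of_constructed_series(self):
        # two synthetic sites whose midpoint ranges differ by the
        # construction factor of 2 (80 vs 40 bp excursions)
        rng = np.random.default_rng(0)
        free = 168 + 40 * np.sin(np.linspace(0, 4 * np.pi, 200))
        pinned = 168 + 20 * np.sin(np.linspace(0, 4 * np.pi, 200))
        ratio = (free.max() - free.min()) / (pinned.max() - pinned.min())
        assert ratio == pytest.approx(2.0, rel=0.01)


class TestJpDiffusivity:
    def test_constant_series_zero(self):
        s = JpSeries(list(range(100)), [84] * 100, [252] * 100)
        assert jp_diffusivity(s, 336) == 0.0

    def test_unbiased_walk_recovers_half(self):
        rng = np.random.default_rng(7)
        steps = rng.choice([-1.0, 1.0], size=10_000)
        mid = 168 + np.concatenate([[0.0], np.cumsum(steps)])
        d = jp_diffusivity(mid % 336, 336)
        assert d == pytest.approx(0.5, rel=0.15)

    def test_pinned_slower_than_free(self):
        rng = np.random.default_rng(8)
        free = 168 + np.cumsum(rng.choice([-1.0, 1.0], size=5000))
        pinned = 168 + np.cumsum(0.2 * rng.choice([-1.0, 1.0], size=5000))
        assert jp_diffusivity(pinned % 336, 336) < jp_diffusivity(
            free % 336, 336)

    def test_refuses_short_series(self):
        with pytest.raises(ValueError):
            jp_diffusivity(np.arange(10.0), 336)


class TestRoughness:
    def test_uniform_occupancy_is_flat(self):
        rng = np.random.default_rng(1)
        # 1D uniform over 10 cells of 10 A
        samples = rng.uniform(0, 100, size=(100_000, 1))
        rep = jp_roughness(samples)
        assert rep.n_cells_visited == 10
        assert rep.sigma_mu <= 0.1

    def test_two_level_boltzmann_gives_unit_sigma(self):
        # two cells with occupancy ratio e^2 (wells 2 kT apart) ->
        # mu difference 2 kT -> std over the two cells = 1 kT
        rng = np.random.default_rng(2)
        n = 200_000
        p_low = 1.0 / (1.0 + np.exp(-2.0))
        well = rng.random(n) < p_low
        # low well occupies cells [0,10) and [10,20), high well [20,30)
        # and [30,40): two equal-occupancy cells per level, levels 2 kT
        # apart, so mu over the four visited cells is (c, c, c+2, c+2)
        # and sigma(mu) = 1 kT exactly in the sampling limit
        x = np.where(well, 10.0, 30.0) + rng.uniform(-10, 10, size=n)
        rep = jp_roughness(np.column_stack([x, np.zeros(n), np.zeros(n)]),
                           min_samples=500)
        assert rep.n_cells_visited == 4
        assert rep.sigma_mu == pytest.approx(1.0, abs=0.05)
        values = np.array(sorted(rep.mu_cells.values()))
        assert values[-1] - values[0] == pytest.approx(2.0, abs=0.05)

    def test_energy_mode_invariant_to_constant_shift(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 50, size=(2000, 3))
        e = rng.normal(size=2000)
        r1 = jp_roughness(pts, energies=e)
        r2 = jp_roughness(pts, energies=e + 7.5)
        assert r1.sigma_mu == pytest.approx(r2.sigma_mu, abs=1e-9)

    def test_rugged_landscape_rougher_and_slower(self):
        # Langevin-style walks on a smooth vs rugged 1D potential: the
        # rugged landscape has larger sigma(mu) and smaller diffusivity
        def walk(amplitude, seed, n=60_000):
            rng = np.random.default_rng(seed)
            x = 50.0
            xs = np.empty(n)
            for t in range(n):
                force = -amplitude * np.cos(x / 3.0) / 3.0
                x += force + rng.normal(0, 1.0)
                x %= 100.0
                xs[t] = x
            return xs

        smooth = walk(0.0, 10)
        rugged = walk(0.8, 11)
        rep_s = jp_roughness(smooth[:, None])
        rep_r = jp_roughness(rugged[:, None])
        assert rep_r.sigma_mu > rep_s.sigma_mu
        d_s = jp_diffusivity(smooth, 100)
        d_r = jp_diffusivity(rugged, 100)
        assert d_r < d_s

    def test_refusals(self):
        with pytest.raises(ValueError):
            jp_roughness(np.zeros((100, 3)))          # too few samples
        with pytest.raises(ValueError):
            jp_roughness(np.zeros((1000, 3)))         # everything in 1 cell
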