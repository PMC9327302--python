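"""Discrete-state target-search model: oracles, limits, kinetic MC."""

from dataclasses import replace

import numpy as np
import pytest

from plectosearch.kinetics import (
    SearchModel,
    figure_layouts,
    kmc_fpt,
    kon_from_kd,
    mfpt_eq2,
    mfpt_master,
    ratio_curve,
    s_aux,
)


def fundamental_matrix_mfpt(model: SearchModel) -> float:
    """Independent oracle: absorbing-Markov-chain fundamental matrix on
    the embedded jump chain, with state-dependent mean holding times."""
    L, tgt = model.L, model.target - 1
    states = ["sol"] + [f"b{i}" for i in range(L) if i != tgt]
    index = {s: k for k, s in enumerate(states)}
    n = len(states)
    P = np.zeros((n, n))
    hold = np.zeros(n)

    kon_site = model.kon_total / model.L
    out_sol = model.kon_total
    hold[0] = 1.0 / out_sol
    for i in range(L):
        if i != tgt:
            P[0, index[f"b{i}"]] = kon_site / out_sol
        # binding straight onto the target leaves the transient chain

    for i in range(L):
        if i == tgt:
            continue
        rates = {"sol": model.k_off}
        for j in (i - 1, i + 1):
            if 0 <= j < L:
                key = "tgt" if j == tgt else f"b{j}"
                rates[key] = rates.get(key, 0.0) + model.u
        for a, b in model.jp_links:
            for src, dst in ((a - 1, b - 1), (b - 1, a - 1)):
                if src == i:
                    key = "tgt" if dst == tgt else f"b{dst}"
                    rates[key] = rates.get(key, 0.0) + model.k_t
        total = sum(rates.values())
        k = index[f"b{i}"]
        hold[k] = 1.0 / total
        for key, r in rates.items():
            if key != "tgt":
                P[k, index[key]] = r / total

    N = np.linalg.inv(np.eye(n) - P)       # expected visits per state
    return float(N[0] @ hold)


class TestKonFromKd:
    def test_fis_rates(self):
        # k_off = 9e-5 / KD 0.8 nM gives the conventional 112500 value
        assert kon_from_kd(9e-5, 0.8e-9) == pytest.approx(112_500.0)

    def test_identity_and_powers_of_ten(self):
        assert kon_from_kd(3.7, 3.7) == 1.0
        assert kon_from_kd(1e-3, 1e-9) == pytest.approx(1e6)

    def test_refuses_nonpositive_kd(self):
        with pytest.raises(ValueError):
            kon_from_kd(1.0, 0.0)


class TestMfptMaster:
    def test_single_site_is_pure_binding(self):
        m = SearchModel(L=1, k_on=2.0, k_off=1.0, u=5.0, k_t=0.0, target=1)
        assert mfpt_master(m)[0] == pytest.approx(0.5)

    def test_matches_fundamental_matrix_oracle_without_motion(self):
        m = SearchModel(L=5, k_on=3.0, k_off=0.7, u=0.0, k_t=0.0, target=5)
        t_solver = mfpt_master(m)[0]
        t_oracle = fundamental_matrix_mfpt(m)
        assert t_solver == pytest.approx(t_oracle, rel=1e-10)
        # closed form: L binding rounds on average, L-1 of them futile
        expected = m.L / m.k_on + (m.L - 1) / m.k_off
        assert t_solver == pytest.approx(expected, rel=1e-10)

    def test_matches_fundamental_matrix_with_links(self):
        m = SearchModel(L=12, k_on=2.0, k_off=0.3, u=4.0, k_t=9.0,
                        target=12, jp_links=[(3, 10)])
        assert mfpt_master(m)[0] == pytest.approx(
            fundamental_matrix_mfpt(m), rel=1e-9)

    def test_juxtaposition_speeds_search_at_fis_rates(self):
        base = SearchModel()
        linked = replace(base, jp_links=[(168, 336)])
        assert mfpt_master(linked)[0] < mfpt_master(base)[0]

    def test_disconnected_model_refused(self):
        with pytest.raises(ValueError):
            mfpt_master(SearchModel(k_on=0.0))


class TestMfptEq2:
    def test_equals_master_on_randomized_models(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            L = int(rng.integers(5, 51))
            links = []
            for _ in range(int(rng.integers(0, 4))):
                a, b = rng.choice(np.arange(1, L + 1), size=2, replace=False)
                links.append((int(a), int(b)))
            m = SearchModel(
                L=L, k_on=float(10 ** rng.uniform(0, 5)),
                k_off=float(10 ** rng.uniform(-5, 0)),
                u=float(10 ** rng.uniform(0, 4)),
                k_t=float(10 ** rng.uniform(0, 6)),
                target=int(rng.integers(1, L + 1)), jp_links=links)
            t2, tm = mfpt_eq2(m), mfpt_master(m)[0]
            assert abs(t2 - tm) / tm < 1e-8

    def test_zero_transfer_rate_equals_no_link_model(self):
        with_links = SearchModel(k_t=0.0, jp_links=[(168, 336)])
        without = SearchModel(k_t=0.0, jp_links=[])
        assert mfpt_eq2(with_links) == pytest.approx(mfpt_eq2(without),
                                                     rel=1e-12)

    def test_perfect_scan_limit_approaches_pure_binding(self):
        # u >> L^2 k_off: once bound the protein always reaches the
        # target, so the search time collapses to the binding step 1/k_on
        m = SearchModel(L=50, k_on=10.0, k_off=1e-6, u=1e9, k_t=0.0,
                        target=50)
        assert s_aux(m) == pytest.approx(50.0, rel=1e-6)
        assert mfpt_eq2(m) == pytest.approx(1.0 / 10.0, rel=1e-3)

    def test_monotone_in_rates(self):
        base = SearchModel(L=50, k_on=100.0, k_off=0.01, u=50.0, k_t=10.0,
                           target=50, jp_links=[(10, 40)])
        t0 = mfpt_eq2(base)
        assert mfpt_eq2(replace(base, u=100.0)) <= t0
        assert mfpt_eq2(replace(base, k_t=20.0)) <= t0
        assert mfpt_eq2(replace(base, k_on=200.0)) <= t0
        assert mfpt_eq2(replace(base, L=80, target=80,
                                jp_links=[(10, 40)])) >= t0


class TestRatioCurve:
    def test_no_links_is_unity_and_curve_decreases(self):
        curve = ratio_curve()
        assert curve[0] == (0, pytest.approx(1.0))
        ratios = [r for _, r in curve]
        assert all(b < a for a, b in zip(ratios, ratios[1:]))

    def test_doubling_transfer_rate_never_slows(self):
        m = SearchModel()
        layouts = figure_layouts(336)
        for layout in layouts[1:]:
            t1 = mfpt_eq2(replace(m, jp_links=layout))
            t2 = mfpt_eq2(replace(m, k_t=2e6, jp_links=layout))
            assert t2 <= t1 * (1 + 1e-12)


class TestKmc:
    def test_static_mean_within_three_stderr_of_analytic(self):
        m = SearchModel(L=50, k_on=5.0, k_off=0.05, u=100.0, k_t=50.0,
                        target=50, jp_links=[(12, 40)])
        res = kmc_fpt(m, n_walkers=1500, seed=3)
        analytic = mfpt_master(m)[0]
        assert res.n_censored == 0
        assert abs(res.mean - analytic) <= 3 * res.stderr

    def test_zero_mobility_statistically_matches_static(self):
        m = SearchModel(L=50, k_on=5.0, k_off=0.05, u=100.0, k_t=50.0,
                        target=50, jp_links=[(12, 40)])
        static = kmc_fpt(m, n_walkers=600, seed=4)
        mobile0 = kmc_fpt(replace(m, jp_mobility=0.0), n_walkers=600, seed=4)
        # identical process and seeds: identical samples
        np.testing.assert_array_equal(static.samples, mobile0.samples)

    def test_mean_fpt_non_increasing_with_mobility(self):
        # a generic (non-target-touching) link: sweeping its mobility up
        # transports the walker to fresh lattice regions and cannot slow
        # the search
        m = SearchModel(jp_links=[(100, 250)])
        means, errs = [], []
        for mob in (0.0, 1000.0, 10_000.0):
            r = kmc_fpt(replace(m, jp_mobility=mob), n_walkers=250,
                        seed=11)
            means.append(r.mean)
            errs.append(r.stderr)
        assert means[1] <= means[0] + 2 * (errs[0] + errs[1])
        assert means[2] < means[1]
        assert means[2] < means[0]

    def test_refuses_bad_walker_count(self):
        with pytest.raises(ValueError):
            kmc_fpt(SearchModel(), n_walkers=0)
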