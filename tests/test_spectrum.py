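"""Jump likelihood, EM spectrum inference, defocalization, two-state fit."""
import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

import smtkit as sk
from smtkit.spectrum import (DiffusionGrid, _em, bound_fraction,
                             defocalization_retention,
                             expected_jumps_per_molecule, infer_spectrum,
                             jump_likelihood, monte_carlo_retention,
                             segment_log_likelihoods, split_trajectories,
                             two_state_jumplength_fit)

DT = 0.00748


class TestJumpLikelihood:
    def test_rayleigh_mode_at_scale(self):
        # D = 0: the density peaks at r = s = sqrt(2)·sigma_loc
        s = np.sqrt(2.0) * 0.03
        r = np.linspace(0.001, 0.3, 20000)
        dens = jump_likelihood(r, 0.0, 0.03, DT)
        assert r[np.argmax(dens)] == pytest.approx(s, abs=1e-4)
        assert s == pytest.approx(0.042426, abs=1e-6)

    def test_normalization(self):
        s2 = 2 * (2.0 * DT + 0.03 ** 2)
        total, _ = quad(lambda r: jump_likelihood(r, 2.0, 0.03, DT),
                        0, 10 * np.sqrt(s2))
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_mean_squared_jump_matches_closed_form(self):
        # E[r²] = 2s² = 4(D·dt + σ²)
        m2, _ = quad(lambda r: r ** 2 * jump_likelihood(r, 2.0, 0.03, DT),
                     0, 5.0, limit=200)
        assert m2 == pytest.approx(0.06344, abs=1e-4)

    def test_degenerate_density_rejected(self):
        with pytest.raises(ValueError):
            jump_likelihood(0.1, 0.0, 0.0, DT)


class TestSplit:
    @staticmethod
    def jump_table(n_jumps):
        return pd.DataFrame({"r_um": np.full(n_jumps, 0.1), "dt_s": DT,
                             "trajectory": 0, "cell_id": 0, "day_id": 0})

    @pytest.mark.parametrize("n_jumps,splitsize,sizes", [
        (7, 3, [3, 3, 1]),
        (2, 3, [2]),
        (5, 1, [1, 1, 1, 1, 1]),
    ])
    def test_segment_sizes(self, n_jumps, splitsize, sizes):
        seg = split_trajectories(self.jump_table(n_jumps), splitsize)
        assert sorted(seg.groupby("segment").size(), reverse=True) == \
            sorted(sizes, reverse=True)
        # no jump shared between segments
        assert seg.groupby("segment").size().sum() == n_jumps


class TestDefocalization:
    def test_immobile_never_leaves(self):
        assert defocalization_retention(0.0, 3 * DT, 0.7) == 1.0

    def test_monotone_in_d(self):
        d = np.logspace(-2, 2, 30)
        ret = defocalization_retention(d, 3 * DT, 0.7)
        assert np.all(np.diff(ret) <= 0)
        # strictly decreasing wherever the numerical floor is not active
        above = ret > 1e-6
        assert np.all(np.diff(ret[above]) < 0)

    def test_fourier_matches_walker_oracle(self):
        # brute-force walkers with bridge-crossing correction
        f = defocalization_retention(2.0, 3 * DT, 0.7)
        m = monte_carlo_retention(2.0, 3 * DT, 0.7, n_walkers=200_000, seed=4)
        assert f == pytest.approx(m, abs=0.005)

    def test_infinite_depth_is_identity(self):
        ret = defocalization_retention(np.array([0.01, 1.0, 100.0]),
                                       3 * DT, 1e9)
        assert np.allclose(ret, 1.0)


class TestExpectedJumps:
    def test_matches_observation_model_simulation(self):
        # independent MC of the observation process: uniform z start,
        # geometric lifetime, jump iff inside the slab at both endpoints
        rng = np.random.default_rng(3)
        D, m = 2.0, 8.0
        n = 100_000
        life = rng.geometric(1 / m, size=n)
        z = rng.uniform(-0.35, 0.35, size=n)
        prev_in = np.ones(n, dtype=bool)
        jumps = np.zeros(n)
        for i in range(1, int(life.max())):
            z = z + rng.normal(0, np.sqrt(2 * D * DT), size=n)
            inside = np.abs(z) < 0.35
            jumps += (life > i) & prev_in & inside
            prev_in = inside
        expected = expected_jumps_per_molecule(D, DT, 0.7, m)
        assert jumps.mean() == pytest.approx(expected, rel=0.02)

    def test_slow_state_approaches_bleach_limit(self):
        # an immobile molecule is lost only to photobleaching
        e = expected_jumps_per_molecule(0.0, DT, 0.7, 8.0)
        assert e == pytest.approx(7.0, rel=1e-6)


class TestInferSpectrum:
    def test_single_state_recovery(self):
        cfg = sk.SimulationConfig(states=((1.0, 1.0),), n_days=1,
                                  cells_per_day=25, mean_mols_per_cell=130,
                                  seed=17)
        locs, _ = sk.simulate_smt_dataset(cfg)
        jumps = sk.compute_jumps(locs)
        assert len(jumps) >= 10_000
        spec = infer_spectrum(jumps, fov_size=cfg.fov_size)
        d = spec.grid.values
        mass_near = spec.occupations[(d > 0.5) & (d < 2.0)].sum()
        assert mass_near >= 0.8

    def test_two_state_bound_fraction_recovery(self, two_state_jumps):
        spec = infer_spectrum(two_state_jumps, fov_size=20.0)
        assert bound_fraction(spec) == pytest.approx(0.30, abs=0.03)

    def test_deterministic(self, two_state_jumps):
        jumps = two_state_jumps.iloc[:2000]
        s1 = infer_spectrum(jumps)
        s2 = infer_spectrum(jumps)
        assert np.array_equal(s1.occupations, s2.occupations)

    def test_em_loglikelihood_monotone(self, two_state_jumps):
        grid = DiffusionGrid()
        ll_seg, _, _ = segment_log_likelihoods(two_state_jumps.iloc[:3000],
                                               grid, 3)
        trace = []
        _em(ll_seg, max_iter=200, trace=trace)
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-8)

    def test_empty_jump_table_rejected(self):
        with pytest.raises(ValueError):
            infer_spectrum(pd.DataFrame({"r_um": [], "trajectory": [],
                                         "cell_id": [], "day_id": []}))

    def test_occupations_sum_to_one(self, two_state_jumps):
        for corr in (None, "retention", "observation"):
            spec = infer_spectrum(two_state_jumps.iloc[:5000], correction=corr)
            assert spec.occupations.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(spec.occupations >= 0)

    def test_bound_fraction_increases_with_bound_weight(self):
        estimates = []
        for w in (0.1, 0.3, 0.5, 0.7):
            cfg = sk.SimulationConfig(states=((0.005, w), (2.0, 1.0 - w)),
                                      n_days=1, cells_per_day=25,
                                      mean_mols_per_cell=60, seed=31)
            locs, _ = sk.simulate_smt_dataset(cfg)
            spec = infer_spectrum(sk.compute_jumps(locs), fov_size=cfg.fov_size)
            estimates.append(bound_fraction(spec))
        assert np.all(np.diff(estimates) > 0)


class TestBoundFraction:
    def grid_spectrum(self, occ):
        grid = DiffusionGrid()
        return sk.DiffusionSpectrum(grid=grid, occupations=occ)

    def test_all_mass_slow(self):
        grid = DiffusionGrid()
        occ = np.zeros(100)
        occ[0] = 1.0  # D = 0.01
        assert bound_fraction(self.grid_spectrum(occ)) == 1.0

    def test_uniform_occupations_default_grid(self):
        occ = np.full(100, 0.01)
        # 25 of the 100 log-spaced points over [0.01, 100] lie below 0.1
        assert bound_fraction(self.grid_spectrum(occ)) == pytest.approx(0.25)

    def test_all_mass_fast(self):
        grid = DiffusionGrid()
        occ = np.zeros(100)
        occ[np.argmin(np.abs(grid.values - 10.0))] = 1.0
        assert bound_fraction(self.grid_spectrum(occ)) == 0.0


@pytest.fixture(scope="module")
def half_bound_jumps():
    # 50/50 mixture without a detection slab (no defocalization)
    cfg = sk.SimulationConfig(states=((0.005, 0.5), (2.0, 0.5)),
                              focal_depth=1e6, n_days=1, cells_per_day=20,
                              mean_mols_per_cell=150, seed=23)
    locs, _ = sk.simulate_smt_dataset(cfg)
    return sk.compute_jumps(locs)


class TestTwoStateFit:
    def test_even_mixture_recovery(self, half_bound_jumps):
        fit = two_state_jumplength_fit(half_bound_jumps, focal_depth=1e6)
        assert fit.f_bound == pytest.approx(0.50, abs=0.03)
        assert fit.d_bound < fit.d_free

    def test_single_state_collapses(self):
        cfg = sk.SimulationConfig(states=((2.0, 1.0),), focal_depth=1e6,
                                  n_days=1, cells_per_day=8,
                                  mean_mols_per_cell=80, seed=29)
        locs, _ = sk.simulate_smt_dataset(cfg)
        fit = two_state_jumplength_fit(sk.compute_jumps(locs), focal_depth=1e6)
        assert fit.f_bound <= 0.05

    def test_cross_validates_spectrum(self, two_state_jumps):
        # kinetic-model fit and grid spectrum agree on the bound fraction
        fit = two_state_jumplength_fit(two_state_jumps)
        spec = infer_spectrum(two_state_jumps, fov_size=20.0)
        assert fit.f_bound_corrected == pytest.approx(bound_fraction(spec),
                                                      abs=0.05)

    def test_too_few_jumps_rejected(self):
        jumps = pd.DataFrame({"r_um": np.full(10, 0.1)})
        with pytest.raises(ValueError):
            two_state_jumplength_fit(jumps)
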