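"""Forward binding model, grid resampling, and the LPM fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import epstitrate as ep
from epstitrate.chemistry import ChargeExcessSeries, DataError

from conftest import make_spectrum


def series_from(pH, Q, **kw):
    defaults = dict(sample_id="s", replicate_id="r1", direction="forward")
    defaults.update(kw)
    return ChargeExcessSeries(pH=np.asarray(pH, float), Q=np.asarray(Q, float), **defaults)


def lattice_min_objective(pH, q, pka, l_values, s_values):
    """Exhaustive lattice search oracle for the L1 objective (3 sites)."""
    a = ep.design_matrix(np.asarray(pka), np.asarray(pH))
    grids = np.meshgrid(*([l_values] * len(pka)), indexing="ij")
    combos = np.stack([g.ravel() for g in grids], axis=1)  # (n_combos, 3)
    preds = combos @ a.T  # (n_combos, n_points)
    best = np.inf
    for s in s_values:
        obj = np.abs(np.asarray(q)[None, :] - preds - s).sum(axis=1).min()
        best = min(best, obj)
    return best


class TestForwardModel:
    def test_half_occupancy_at_pKa(self):
        spec = make_spectrum({6.0: 0.10})
        assert ep.forward_model(spec, [6.0])[0] == pytest.approx(0.05, rel=1e-12)

    def test_fully_protonated_limit_returns_intercept(self):
        spec = make_spectrum({6.0: 0.10}, intercept=0.0)
        assert ep.forward_model(spec, [2.0])[0] == pytest.approx(0.0, abs=1e-5)

    def test_two_site_hand_value(self):
        # 0.01 + 0.2*Ka5/(Ka5+10^-6.5) + 0.4*Ka8/(Ka8+10^-6.5), hand-evaluated
        spec = make_spectrum({5.0: 0.2, 8.0: 0.4}, intercept=0.01)
        assert ep.forward_model(spec, [6.5])[0] == pytest.approx(0.2161307, rel=1e-6)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_monotone_nondecreasing_in_pH(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 6)
        spec = ep.LigandSpectrum(
            pka=np.sort(rng.uniform(3, 11, n)) + np.arange(n) * 1e-6,
            ligand_totals=rng.uniform(0, 0.5, n),
            intercept=rng.uniform(-0.1, 0.1),
        )
        pH = np.linspace(2, 12, 60)
        q = ep.forward_model(spec, pH)
        assert np.all(np.diff(q) >= -1e-15)


class TestResampling:
    def test_linear_midpoint(self):
        s = series_from([5.9, 6.1], [1.0, 2.0])
        out = ep.resample_to_fit_grid(s, ep.PKaGrid())
        assert list(out.pH) == [6.0]
        assert out.Q[0] == pytest.approx(1.5)

    def test_outside_span_omitted(self):
        s = series_from([5.5, 7.5], [0.0, 1.0])
        out = ep.resample_to_fit_grid(s, ep.PKaGrid())
        assert out.pH.min() >= 5.5 and out.pH.max() <= 7.5

    def test_on_grid_input_is_identity(self):
        grid = ep.PKaGrid()
        pH = grid.pka_values
        q = np.linspace(0, 1, pH.size)
        out = ep.resample_to_fit_grid(series_from(pH, q), grid)
        np.testing.assert_allclose(out.pH, pH)
        np.testing.assert_allclose(out.Q, q, rtol=1e-12)

    def test_duplicate_pH_collapsed_to_mean(self):
        s = series_from([5.9, 6.1, 6.1], [1.0, 1.0, 3.0])
        out = ep.resample_to_fit_grid(s, ep.PKaGrid())
        assert out.Q[0] == pytest.approx((1.0 + 2.0) / 2)

    def test_no_overlap_is_error(self):
        with pytest.raises(DataError):
            ep.resample_to_fit_grid(series_from([1.0, 2.0], [0.0, 1.0]), ep.PKaGrid())


class TestFitLpm:
    def test_noise_free_on_grid_round_trip(self):
        grid = ep.PKaGrid()
        truth = make_spectrum({5.0: 0.2, 8.4: 0.4}, intercept=0.01)
        q = ep.forward_model(truth, grid.pka_values)
        fitted, diag = ep.fit_lpm(series_from(grid.pka_values, q), grid,
                                  report_threshold=1e-9)
        assert diag.solver_status == "optimal"
        assert diag.objective_value <= 1e-9
        assert fitted.intercept == pytest.approx(0.01, abs=1e-6)
        by_pka = dict(zip(np.round(fitted.pka, 6), fitted.ligand_totals))
        assert by_pka[5.0] == pytest.approx(0.2, abs=1e-6)
        assert by_pka[8.4] == pytest.approx(0.4, abs=1e-6)

    def test_zero_input_gives_zero_spectrum(self):
        grid = ep.PKaGrid()
        fitted, diag = ep.fit_lpm(series_from(grid.pka_values, np.zeros(grid.n_sites)), grid)
        assert fitted.total_LT == 0.0
        assert fitted.intercept == pytest.approx(0.0, abs=1e-9)
        assert diag.objective_value == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_objective_beats_lattice_oracle(self, seed):
        """On tiny instances the LP matches/beats exhaustive lattice search."""
        rng = np.random.default_rng(seed)
        pka = np.array([4.5, 6.5, 8.5])
        pH = np.sort(rng.uniform(4.5, 8.5, 5))
        l_values = np.round(np.arange(0, 0.51, 0.01), 2)
        s_values = np.round(np.arange(-0.1, 0.101, 0.01), 2)
        truth_l = rng.choice(l_values, 3)
        truth_s = rng.choice(s_values)
        q = ep.design_matrix(pka, pH) @ truth_l + truth_s + rng.normal(0, 0.01, 5)
        grid = ep.PKaGrid(start=4.5, stop=8.5, step=2.0)
        fitted, diag = ep.fit_lpm(series_from(pH, q), grid, resample=False,
                                  report_threshold=0.0)
        oracle = lattice_min_objective(pH, q, pka, l_values, s_values)
        assert diag.objective_value <= oracle + 1e-9

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_optimality_against_random_feasible_proposals(self, seed):
        rng = np.random.default_rng(seed)
        grid = ep.PKaGrid(start=4.0, stop=10.0, step=1.0)
        pH = np.linspace(4, 10, 13)
        q = rng.normal(0, 0.2, pH.size)
        fitted, diag = ep.fit_lpm(series_from(pH, q), grid, resample=False,
                                  report_threshold=0.0)
        a = ep.design_matrix(grid.pka_values, pH)
        for _ in range(5):
            l_prop = rng.uniform(0, 0.5, grid.n_sites)
            s_prop = rng.uniform(-0.2, 0.2)
            obj_prop = np.abs(q - a @ l_prop - s_prop).sum()
            assert diag.objective_value <= obj_prop + 1e-7

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        grid = ep.PKaGrid()
        truth = make_spectrum({4.8: 0.15, 7.2: 0.3}, intercept=0.02)
        q = ep.forward_model(truth, grid.pka_values) + rng.normal(0, 0.005, grid.n_sites)
        s1, _ = ep.fit_lpm(series_from(grid.pka_values, q), grid, report_threshold=0.0)
        c = 3.7
        s2, _ = ep.fit_lpm(series_from(grid.pka_values, c * q), grid, report_threshold=0.0)
        assert s2.total_LT == pytest.approx(c * s1.total_LT, rel=1e-6, abs=1e-9)
        assert s2.intercept == pytest.approx(c * s1.intercept, rel=1e-6, abs=1e-9)

    @pytest.mark.parametrize("seed", [11, 12, 13, 14])
    def test_exact_recovery_of_class_totals(self, seed):
        """Noise-free on-grid mixtures are recovered per functional-group class."""
        rng = np.random.default_rng(seed)
        grid = ep.PKaGrid()
        n_sites = rng.integers(1, 6)
        idx = rng.choice(grid.n_sites, n_sites, replace=False)
        lt = np.zeros(grid.n_sites)
        lt[idx] = rng.uniform(0.01, 0.5, n_sites)
        truth = ep.LigandSpectrum(pka=grid.pka_values, ligand_totals=lt,
                                  intercept=rng.uniform(-0.05, 0.05))
        q = ep.forward_model(truth, grid.pka_values)
        fitted, _ = ep.fit_lpm(series_from(grid.pka_values, q), grid,
                               report_threshold=1e-9)
        t_truth = ep.bin_functional_groups(truth)
        t_fit = ep.bin_functional_groups(fitted)
        for k in t_truth:
            assert t_fit[k] == pytest.approx(t_truth[k], abs=1e-6)
        assert fitted.intercept == pytest.approx(truth.intercept, abs=1e-6)

    def test_grid_validation(self):
        with pytest.raises(Exception):
            ep.PKaGrid(start=4.0, stop=10.0, step=0.23)
        grid = ep.PKaGrid()
        assert grid.n_sites == 31
        np.testing.assert_allclose(grid.pka_values[:3], [4.0, 4.2, 4.4])
        assert grid.pka_values[-1] == pytest.approx(10.0)
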