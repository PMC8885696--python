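"""Double Cole-Cole model: forward evaluation, R^2, fitting, order comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drsviab.colecole import (
    ColeColeModel,
    ColeColeParams,
    compare_dispersion_orders,
    evaluate_model,
    fit_model,
    goodness_of_fit,
    r_squared_stacked,
)
from drsviab.simulate import NoiseModel, simulate_spectrum
from drsviab.spectra import FrequencyGrid, PermittivitySpectrum, SpectrumError, default_grid

from conftest import noiseless_spectrum


def params_strategy():
    """Random valid double Cole-Cole parameter sets (well-separated taus)."""
    return st.builds(
        lambda eps_inf, d1, d2, t2, ratio, a1, a2: ColeColeParams(
            eps_inf=eps_inf,
            delta_eps1=d1,
            delta_eps2=d2,
            tau1=t2 * ratio,
            tau2=t2,
            alpha1=a1,
            alpha2=a2,
        ),
        eps_inf=st.floats(2, 10),
        d1=st.floats(5, 60),
        d2=st.floats(5, 60),
        t2=st.floats(1e-12, 2e-11),
        ratio=st.floats(20, 500),
        a1=st.floats(0, 0.3),
        a2=st.floats(0, 0.3),
    )


class TestForwardModel:
    def test_static_limit(self, control_params):
        g = FrequencyGrid(np.array([1e-3, 2e-3]))  # quasi-static
        eps = evaluate_model(control_params, g)
        assert eps.real[0] == pytest.approx(control_params.eps_static, rel=1e-6)
        assert -eps.imag[0] == pytest.approx(0.0, abs=1e-4)

    def test_debye_point_at_omega_tau_one(self):
        # single Debye dispersion evaluated at w*tau = 1: 1/(1+j) = (1-j)/2
        tau1 = 1e-9
        p = ColeColeParams(
            eps_inf=5.0, delta_eps1=20.0, delta_eps2=1e-9 * 1e12, tau1=tau1,
            tau2=1e-14, alpha1=0.0, alpha2=0.0,
        )
        # make the second term negligible by a vanishing strength
        p = ColeColeParams(5.0, 20.0, 1e-6, tau1, 1e-14, 0.0, 0.0)
        f = 1.0 / (2 * np.pi * tau1)
        g = FrequencyGrid(np.array([f, 2 * f]))
        eps = evaluate_model(p, g)
        assert eps.real[0] == pytest.approx(5.0 + 10.0, abs=1e-5)
        assert -eps.imag[0] == pytest.approx(10.0, abs=1e-5)

    def test_against_arbitrary_precision_oracle(self, control_params):
        sympy = pytest.importorskip("sympy")
        w = 2 * sympy.pi * sympy.Integer(10) ** 9
        p = control_params
        expr = (
            sympy.Float(p.eps_inf, 30)
            + sympy.Float(p.delta_eps1, 30)
            / (1 + (sympy.I * w * sympy.Float(p.tau1, 30)) ** sympy.Float(1 - p.alpha1, 30))
            + sympy.Float(p.delta_eps2, 30)
            / (1 + (sympy.I * w * sympy.Float(p.tau2, 30)) ** sympy.Float(1 - p.alpha2, 30))
        )
        val = complex(sympy.N(expr, 30))
        g = FrequencyGrid(np.array([1e9, 2e9]))
        eps = evaluate_model(p, g)[0]
        assert abs(eps - val) / abs(val) < 1e-10

    @given(p=params_strategy())
    @settings(max_examples=50, deadline=None)
    def test_eps_real_strictly_decreasing(self, p):
        g = default_grid(n_points=60)
        eps = evaluate_model(p, g)
        assert np.all(np.diff(eps.real) < 0)
        assert np.all(-eps.imag >= 0)


class TestRSquared:
    def test_perfect_reproduction(self, control_spectrum, control_params):
        eps = evaluate_model(control_params, control_spectrum.grid)
        assert r_squared_stacked(eps, control_spectrum) == pytest.approx(1.0)

    def test_grand_mean_gives_zero(self, control_spectrum):
        data = np.concatenate([control_spectrum.eps_real, control_spectrum.eps_imag])
        mean = data.mean()
        pred = np.full(len(control_spectrum.grid), mean) * (1 - 1j)
        assert r_squared_stacked(pred, control_spectrum) == pytest.approx(0.0, abs=1e-12)

    def test_five_point_toy_value(self):
        # hand-assigned predictions; R^2 computed independently from the
        # definition 1 - SS_res/SS_tot on the stacked vector
        g = FrequencyGrid(np.array([1e9, 2e9, 3e9, 4e9, 5e9]))
        er = np.array([50.0, 45.0, 40.0, 35.0, 30.0])
        ei = np.array([5.0, 6.0, 7.0, 6.0, 5.0])
        s = PermittivitySpectrum(g, er, ei)
        pr = er + np.array([0.5, -0.5, 0.2, 0.0, -0.2])
        pi = ei + np.array([-0.1, 0.1, 0.0, 0.2, -0.2])
        data = np.concatenate([er, ei])
        pred = np.concatenate([pr, pi])
        expected = 1 - np.sum((data - pred) ** 2) / np.sum((data - data.mean()) ** 2)
        assert r_squared_stacked(pr - 1j * pi, s) == pytest.approx(expected)

    def test_constant_spectrum_undefined(self):
        g = FrequencyGrid(np.array([1e9, 2e9]))
        s = PermittivitySpectrum(g, np.array([5.0, 5.0]), np.array([5.0, 5.0]))
        with pytest.raises(SpectrumError, match="undefined"):
            r_squared_stacked(np.array([5.0 - 5.0j] * 2), s)


class TestFit:
    @pytest.mark.parametrize("label", ["Control", "I-4h-R-3h", "I-6h"])
    def test_noiseless_recovery_of_printed_parameters(self, library, grid167, label):
        true = library[label]
        s = noiseless_spectrum(true, grid167)
        res = ColeColeModel(s).fit(seed=0)
        assert res.converged
        for name in ("delta_eps1", "delta_eps2", "tau1", "tau2"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(true, name), rel=1e-3
            )

    def test_debye_input_with_two_dispersions_converges_perfectly(self):
        p = ColeColeParams(5.0, 30.0, 1e-6, 1e-10, 1e-13, 0.0, 0.0)
        g = default_grid(n_points=80)
        s = noiseless_spectrum(p, g)
        res = fit_model(s, n_dispersions=2, seed=0)
        assert res.converged
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_brute_force_lattice_oracle(self, control_params):
        """The fitter never does worse than exhaustive search on a coarse
        bounded lattice of parameter values."""
        g = default_grid(n_points=20)
        s = noiseless_spectrum(control_params, g)
        data = np.concatenate([s.eps_real, s.eps_imag])
        w = g.omega

        d_vals = np.linspace(5, 60, 6)
        lt1 = np.linspace(np.log10(1e-10), np.log10(2e-9), 6)
        lt2 = np.linspace(np.log10(1e-12), np.log10(2e-11), 6)
        einf = np.array([3.0, 7.0, 11.0])
        alph = np.array([0.0, 0.1, 0.2])
        best = np.inf
        for e0 in einf:
            for a1 in alph:
                for a2 in alph:
                    # vectorize over the 6^4 strength/time lattice
                    D1, D2, T1, T2 = np.meshgrid(
                        d_vals, d_vals, 10.0**lt1, 10.0**lt2, indexing="ij"
                    )
                    pred = (
                        e0
                        + D1[..., None] / (1 + (1j * w * T1[..., None]) ** (1 - a1))
                        + D2[..., None] / (1 + (1j * w * T2[..., None]) ** (1 - a2))
                    )
                    stacked = np.concatenate([pred.real, -pred.imag], axis=-1)
                    ss = np.sum((stacked - data) ** 2, axis=-1)
                    best = min(best, float(ss.min()))
        res = fit_model(s, n_dispersions=2, seed=0)
        assert res.residual_norm**2 <= best + 1e-9

    def test_deterministic_given_seed(self, library, grid167):
        s = simulate_spectrum(
            library["I-1h"], grid167, NoiseModel(), np.random.default_rng(5)
        )
        r1 = fit_model(s, seed=42)
        r2 = fit_model(s, seed=42)
        assert r1.params == r2.params
        assert r1.r_squared == r2.r_squared

    def test_nonfinite_input_rejected(self, grid167):
        er = np.full(len(grid167), 50.0)
        ei = np.full(len(grid167), 5.0)
        s = PermittivitySpectrum(grid167, er, ei)
        object.__setattr__(s, "eps_real", er * np.where(np.arange(167) == 0, np.nan, 1))
        with pytest.raises(SpectrumError):
            fit_model(s)

    def test_short_spectrum_rejected(self, control_params):
        g = FrequencyGrid(np.linspace(1e9, 2e9, 5))
        s = noiseless_spectrum(control_params, g)
        with pytest.raises(SpectrumError, match="at least 10"):
            fit_model(s)

    @staticmethod
    def _random_params(rng):
        t2 = rng.uniform(1e-12, 2e-11)
        return ColeColeParams(
            eps_inf=rng.uniform(2, 10),
            delta_eps1=rng.uniform(5, 60),
            delta_eps2=rng.uniform(5, 60),
            tau1=t2 * rng.uniform(30, 300),
            tau2=t2,
            alpha1=rng.uniform(0, 0.3),
            alpha2=rng.uniform(0, 0.3),
        )

    def test_noiseless_recovery_of_random_parameters(self, grid167):
        """Noiseless spectra identify all seven parameters: scale parameters
        within 0.5 % relative, broadening exponents within 0.005 absolute."""
        rng = np.random.default_rng(2024)
        for k in range(25):
            p = self._random_params(rng)
            res = fit_model(noiseless_spectrum(p, grid167), seed=k)
            assert res.converged
            rel = np.abs(res.params.as_array() - p.as_array()) / np.abs(p.as_array())
            assert np.max(rel[:5]) < 0.005
            assert np.max(np.abs(res.params.as_array()[5:] - p.as_array()[5:])) < 0.005

    def test_noisy_fit_never_loses_to_true_parameters(self, grid167):
        """Under the measurement-noise model the residual at the fitted
        optimum is never above the residual at the generating parameters:
        any remaining parameter error is identifiability, not optimisation."""
        from drsviab.colecole import _pack, _residuals

        rng = np.random.default_rng(11)
        for k in range(8):
            p = self._random_params(rng)
            s = simulate_spectrum(p, grid167, NoiseModel(), rng)
            res = fit_model(s, seed=k)
            data = np.concatenate([s.eps_real, s.eps_imag])
            th = _pack(
                p.eps_inf,
                [(p.delta_eps1, p.tau1, p.alpha1), (p.delta_eps2, p.tau2, p.alpha2)],
            )
            true_ss = np.sum(_residuals(th, grid167.omega, data, 2) ** 2)
            assert res.residual_norm**2 <= true_ss * (1 + 1e-9)

    def test_replicate_averaged_recovery_under_noise(self, grid167):
        """Averaging 20 noisy replicates (the per-condition fits average many
        measurements) brings the median parameter error below 5 %."""
        rng = np.random.default_rng(2024)
        meds = []
        for k in range(10):
            p = self._random_params(rng)
            reps = [simulate_spectrum(p, grid167, NoiseModel(), rng) for _ in range(20)]
            s = PermittivitySpectrum(
                grid167,
                np.mean([r.eps_real for r in reps], axis=0),
                np.mean([r.eps_imag for r in reps], axis=0),
            )
            res = fit_model(s, seed=k)
            rel = np.abs(res.params.as_array() - p.as_array()) / np.abs(p.as_array())
            meds.append(np.median(rel))
        assert np.median(meds) < 0.05


class TestDispersionOrders:
    def test_two_dispersion_data_selects_order_two(self, library, grid167):
        s = simulate_spectrum(
            library["Control"], grid167, NoiseModel(), np.random.default_rng(0)
        )
        cmp = compare_dispersion_orders(s, seed=0)
        # optimizer tolerance on the monotonicity of R^2 with order
        assert cmp.fits[1].r_squared >= cmp.fits[0].r_squared - 1e-6
        assert cmp.fits[2].r_squared >= cmp.fits[1].r_squared - 1e-6
        assert cmp.selected_order == 2
        assert cmp.flags[2] == "minimal improvement"

    def test_single_debye_adequate_at_order_one(self, grid167):
        p = ColeColeParams(5.0, 30.0, 1e-6, 1e-10, 1e-13, 0.0, 0.0)
        s = noiseless_spectrum(p, grid167)
        cmp = compare_dispersion_orders(s, seed=0)
        assert cmp.selected_order == 1

    def test_majority_of_noisy_control_runs_select_order_two(self, library, grid167):
        chosen = []
        for seed in range(7):
            s = simulate_spectrum(
                library["Control"], grid167, NoiseModel(), np.random.default_rng(100 + seed)
            )
            chosen.append(compare_dispersion_orders(s, seed=seed).selected_order)
        assert sum(c == 2 for c in chosen) > len(chosen) / 2


class TestModelResultsInterface:
    def test_summary_contains_estimates(self, control_spectrum):
        res = ColeColeModel(control_spectrum).fit(seed=0)
        text = res.summary()
        assert "R^2" in text and "tau1 [ps]" in text
        assert f"{res.params.delta_eps1:.4f}"[:6] in text

    def test_from_dataframe_roundtrip(self, control_spectrum):
        import pandas as pd

        df = pd.DataFrame(
            {
                "frequency_hz": control_spectrum.grid.points,
                "eps_real": control_spectrum.eps_real,
                "eps_imag": control_spectrum.eps_imag,
            }
        )
        res = ColeColeModel.from_dataframe(df).fit(seed=0)
        assert res.rsquared == pytest.approx(1.0, abs=1e-9)

    def test_goodness_of_fit_matches_results(self, control_spectrum):
        res = ColeColeModel(control_spectrum).fit(seed=0)
        assert goodness_of_fit(res.fit_result, control_spectrum) == pytest.approx(
            res.rsquared
        )
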