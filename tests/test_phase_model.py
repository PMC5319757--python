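"""Order parameter, parameter estimation, noise coefficients, PRC, SDE dynamics."""

import numpy as np
import pytest

from neuroloop.phase_model import (
    PhaseModelParams,
    StimulusSettings,
    StimulusTrain,
    colored_noise_coefficients,
    default_phase_grid,
    estimate_model_params,
    estimate_order_parameter,
    periodic_interp,
    prc_lookup,
    sample_stimulus_train,
    simulate_phase_ensemble,
    simulate_phase_sde,
)
from neuroloop.synthetic_signals import (
    generate_model_params,
    synthesize_paired_recording,
)


def noise_free_params(**kw):
    defaults = dict(omega=6.0, K=0.0, r=0.5, psi=0.2, sigma_I=0.0, sigma_C=0.0)
    defaults.update(kw)
    return PhaseModelParams(**defaults)


class TestOrderParameter:
    def test_aligned_phases(self):
        r, psi = estimate_order_parameter(np.full(50, 0.3))
        assert r == pytest.approx(1.0)
        assert psi == pytest.approx(0.3)

    def test_antipodal_phases_cancel(self):
        r, _ = estimate_order_parameter([0.0, 0.5])
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_uniform_phases_near_zero(self, rng):
        r, _ = estimate_order_parameter(rng.uniform(size=10_000))
        assert r <= 0.03

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_order_parameter([])


class TestParameterEstimation:
    def test_recovery_from_synthetic_recording(self):
        truth = generate_model_params("pd_bursting", seed=3)
        lfp, spikes = synthesize_paired_recording(truth, duration=60.0, seed=3)
        est = estimate_model_params(lfp, spikes)
        assert est.omega == pytest.approx(truth.omega, rel=0.10)
        assert abs(est.r - truth.r) <= 0.10
        assert 0.0 <= est.r <= 1.0
        assert est.sigma_I > 0 and est.sigma_C > 0

    def test_non_bursting_recording_refused(self, rng):
        from neuroloop.signals import SampledSignal

        lfp = SampledSignal(rng.standard_normal(5000), 1000.0)
        regular_spikes = np.arange(1, 200) * 0.02
        with pytest.raises(ValueError, match="bursting"):
            estimate_model_params(lfp, regular_spikes)

    def test_too_few_spikes_refused(self, rng):
        from neuroloop.signals import SampledSignal

        lfp = SampledSignal(rng.standard_normal(5000), 1000.0)
        with pytest.raises(ValueError, match="spikes"):
            estimate_model_params(lfp, [0.1, 0.2])


class TestColoredNoiseCoefficients:
    def test_zero_sensitivity_gives_zero_coefficients(self):
        v, D = colored_noise_coefficients(
            np.zeros(64), {"form": "exp", "tau": 0.02}, 6.0, 0.3
        )
        assert v == 0.0 and D == 0.0

    def test_sinusoidal_sensitivity_matches_closed_form(self):
        omega, sigma_C, tau = 6.0, 0.3, 0.02
        grid = default_phase_grid(128)
        v, D = colored_noise_coefficients(
            np.sin(2 * np.pi * grid), {"form": "exp", "tau": tau}, omega, sigma_C
        )
        denom = 1.0 + (2 * np.pi * omega * tau) ** 2
        assert D == pytest.approx(sigma_C**2 * tau / denom, rel=1e-6)
        assert v == pytest.approx(
            -sigma_C**2 * 2 * np.pi**2 * omega * tau**2 / denom, rel=1e-6
        )

    def test_diffusion_coefficient_non_negative_for_random_curves(self, rng):
        grid = default_phase_grid(64)
        for _ in range(10):
            coeffs = rng.standard_normal(5)
            r_c = sum(
                c * np.sin(2 * np.pi * (k + 1) * grid + rng.uniform(0, 2 * np.pi))
                for k, c in enumerate(coeffs)
            )
            _, D = colored_noise_coefficients(
                r_c, {"form": "exp", "tau": 0.02}, rng.uniform(2, 10), 0.2
            )
            assert D >= -1e-15

    def test_divergent_correlation_rejected(self):
        with pytest.raises(ValueError):
            colored_noise_coefficients(
                np.sin(2 * np.pi * default_phase_grid(64)),
                {"form": "exp", "tau": np.inf}, 6.0, 0.3,
            )


class TestPRC:
    def test_table_value_at_grid_node(self, pd_params):
        node = pd_params.phase_grid[10]
        val = prc_lookup(pd_params, node, pd_params.beta_ref)
        assert val == pytest.approx(pd_params.prc[10])

    def test_linear_scaling_in_beta(self, pd_params):
        v1 = prc_lookup(pd_params, 0.33, pd_params.beta_ref)
        v2 = prc_lookup(pd_params, 0.33, 2 * pd_params.beta_ref)
        assert v2 == pytest.approx(2 * v1)

    def test_nonpositive_beta_rejected(self, pd_params):
        with pytest.raises(ValueError):
            prc_lookup(pd_params, 0.2, 0.0)

    def test_reconstruction_by_perturb_and_measure(self):
        """Simulating a noise-free oscillator, kicking it at a chosen phase
        and measuring the asymptotic shift reconstructs the PRC table."""
        params = noise_free_params()
        beta = params.beta_ref
        for phi0 in (0.1, 0.4, 0.75):
            # place a single impulse when the oscillator sits at phi0
            tau = phi0 / params.omega + 3.0 / params.omega  # 3 full cycles first
            train = StimulusTrain(tau_k=np.array([tau]), beta=beta)
            kicked = simulate_phase_sde(params, train, 1.0, dt=1e-4, seed=0)
            free = simulate_phase_sde(params, None, 1.0, dt=1e-4, seed=0)
            shift = kicked.phi_unwrapped[-1] - free.phi_unwrapped[-1]
            expected = prc_lookup(params, phi0, beta)
            assert shift == pytest.approx(expected, abs=2.0 / params.phase_grid.size)


class TestStimulusTrain:
    def test_mean_rate_recovered(self):
        settings = StimulusSettings(60.0, 0.001, 130.0, 30.0)
        train = sample_stimulus_train(settings, 100.0, seed=0)
        rate = train.tau_k.size / 100.0
        se = 130.0 / np.sqrt(train.tau_k.size)
        assert abs(rate - 130.0) < 3 * se

    def test_ipi_cv_matches_poisson_parameter(self):
        settings = StimulusSettings(60.0, 0.001, 130.0, 30.0)
        train = sample_stimulus_train(settings, 200.0, seed=1)
        ipi = np.diff(train.tau_k)
        cv = np.std(ipi) / np.mean(ipi)
        assert cv == pytest.approx(1 / np.sqrt(30.0), rel=0.15)

    def test_regular_surrogate_has_zero_cv(self):
        settings = StimulusSettings.regular_surrogate(60.0, 0.0025, 130.0)
        train = sample_stimulus_train(settings, 10.0, seed=0)
        assert np.allclose(np.diff(train.tau_k), 1.0 / 130.0)

    def test_beta_follows_pulse_parameters(self):
        settings = StimulusSettings(60.0, 0.001, 130.0, 30.0)
        train = sample_stimulus_train(settings, 1.0, seed=0)
        assert train.beta == pytest.approx(60.0 * 0.001)

    def test_short_duration_warns_and_may_be_empty(self):
        settings = StimulusSettings(60.0, 0.001, 20.0, 30.0)
        with pytest.warns(RuntimeWarning, match="empty"):
            train = sample_stimulus_train(settings, 0.01, seed=0)
        assert train.tau_k.size == 0

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            StimulusSettings(w=10.0, I0=0.001, f=130.0, lam=30.0)
        with pytest.raises(ValueError):
            StimulusSettings(w=60.0, I0=0.01, f=130.0, lam=30.0)


class TestPhaseSDE:
    def test_pure_rotation_exact(self):
        params = noise_free_params()
        traj = simulate_phase_sde(params, None, 2.0, dt=1e-3, seed=0, phi0=0.1)
        assert traj.phi_unwrapped[-1] == pytest.approx(0.1 + 6.0 * 2.0, abs=1e-10)
        assert np.all((traj.phi >= 0) & (traj.phi < 1))

    def test_single_impulse_jump_equals_prc(self):
        params = noise_free_params()
        train = StimulusTrain(tau_k=np.array([0.50037]), beta=params.beta_ref)
        traj = simulate_phase_sde(params, train, 1.0, dt=1e-3, seed=0, phi0=0.0)
        free = simulate_phase_sde(params, None, 1.0, dt=1e-3, seed=0, phi0=0.0)
        phi_pre = (params.omega * 0.50037) % 1.0
        observed = traj.phi_unwrapped[-1] - free.phi_unwrapped[-1]
        assert observed == pytest.approx(
            prc_lookup(params, phi_pre, params.beta_ref), abs=1e-9
        )

    def test_brownian_variance_growth(self):
        grid = default_phase_grid()
        params = PhaseModelParams(
            omega=6.0, K=0.0, r=0.5, psi=0.2, sigma_I=0.3, sigma_C=0.0,
            R_I=np.ones(grid.size), R_C=np.zeros(grid.size),
        )
        t_end = 0.5
        ens = simulate_phase_ensemble(params, 1000, t_end, dt=1e-3, seed=4)
        # R_I constant => additive noise, Var(phi_t) = sigma_I^2 t
        assert np.var(ens[-1]) == pytest.approx(0.3**2 * t_end, rel=0.15)

    def test_same_seed_identical_trajectory(self, pd_params):
        a = simulate_phase_sde(pd_params, None, 0.5, dt=1e-3, seed=7)
        b = simulate_phase_sde(pd_params, None, 0.5, dt=1e-3, seed=7)
        assert np.array_equal(a.phi, b.phi)

    def test_halving_dt_noise_free_terminal_phase(self):
        params = noise_free_params(K=0.4)
        a = simulate_phase_sde(params, None, 1.0, dt=1e-3, seed=0)
        b = simulate_phase_sde(params, None, 1.0, dt=5e-4, seed=0)
        assert abs(a.phi_unwrapped[-1] - b.phi_unwrapped[-1]) <= 1e-3

    def test_drift_correction_vanishes_for_constant_sensitivity(self):
        from neuroloop.phase_model import _drift_diffusion

        grid = default_phase_grid()
        params = PhaseModelParams(
            omega=6.0, K=0.0, r=0.5, psi=0.2, sigma_I=0.4, sigma_C=0.0,
            R_I=np.ones(grid.size), R_C=np.zeros(grid.size),
        )
        drift, g = _drift_diffusion(params, np.linspace(0, 1, 50, endpoint=False), False)
        assert np.allclose(drift, params.omega, atol=1e-10)
        assert np.allclose(g, 0.4)

    def test_too_coarse_dt_rejected(self, pd_params):
        with pytest.raises(ValueError, match="dt"):
            simulate_phase_sde(pd_params, None, 1.0, dt=0.5, seed=0)


class TestPeriodicInterp:
    def test_node_identity_and_wraparound(self):
        table = np.array([1.0, 2.0, 4.0, 0.0])
        assert periodic_interp(table, 0.25) == pytest.approx(2.0)
        assert periodic_interp(table, 0.875) == pytest.approx(0.5)  # between 0 and 1
        assert periodic_interp(table, 1.25) == periodic_interp(table, 0.25)


class TestRoundTrip:
    def test_params_json_roundtrip(self, pd_params, tmp_path):
        import json

        d = pd_params.to_dict()
        path = tmp_path / "p.json"
        path.write_text(json.dumps(d))
        back = PhaseModelParams.from_dict(json.loads(path.read_text()))
        assert back.omega == pd_params.omega
        assert np.allclose(back.prc, pd_params.prc)
        assert back.v_C == pytest.approx(pd_params.noise_coefficients()[0])
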