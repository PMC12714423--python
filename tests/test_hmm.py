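"""Movement HMM: likelihood machinery, fitting, decoding, AIC selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from collarbehavior.hmm import (
    HmmFit,
    HmmSpec,
    compare_aic,
    default_spec,
    fit_hmm,
    forward_loglik,
    hourly_activity_means,
    movement_observations,
    simulate_from_spec,
    steps_and_angles,
    viterbi,
    wrapped_cauchy_pdf,
)
from collarbehavior.label import GPSTrack

from _oracles import (
    brute_force_forward,
    brute_force_steps_angles,
    brute_force_viterbi,
)

T0 = pd.Timestamp("2022-06-01")


def toy_spec(**overrides):
    params = dict(
        streams=("step", "angle"),
        emissions={
            "step": {"mean": np.array([10.0, 80.0, 500.0]),
                     "sd": np.array([8.0, 50.0, 200.0])},
            "angle": {"mean": np.zeros(3), "rho": np.array([0.0, 0.3, 0.8])},
        },
        tmat=np.array([[0.85, 0.10, 0.05], [0.10, 0.80, 0.10], [0.05, 0.15, 0.80]]),
        delta=np.array([0.4, 0.4, 0.2]),
    )
    params.update(overrides)
    return HmmSpec(**params)


def track_from_xy(xy, minutes=10):
    times = pd.DatetimeIndex(
        [T0 + pd.Timedelta(minutes=minutes * i) for i in range(len(xy))]
    )
    return GPSTrack(animal_id="t", times=times, xy=np.asarray(xy, dtype=float))


class TestStepsAndAngles:
    def test_collinear_fixes_have_zero_angles(self):
        sa = steps_and_angles(track_from_xy([[0, 0], [10, 0], [20, 0], [30, 0]]))
        assert np.allclose(sa["step"], 10.0)
        assert np.isnan(sa["angle"].iloc[0])
        assert np.allclose(sa["angle"].iloc[1:], 0.0)

    def test_left_turn_is_positive_half_pi(self):
        sa = steps_and_angles(track_from_xy([[0, 0], [10, 0], [10, 10]]))
        assert sa["angle"].iloc[1] == pytest.approx(np.pi / 2)

    def test_matches_brute_force_reference(self, rng):
        xy = rng.normal(0, 100, size=(50, 2))
        sa = steps_and_angles(track_from_xy(xy))
        steps, angles = brute_force_steps_angles(xy)
        assert np.allclose(sa["step"], steps)
        assert np.allclose(sa["angle"].iloc[1:], angles[1:])

    def test_too_few_fixes_rejected(self):
        with pytest.raises(ValueError, match="2 fixes"):
            steps_and_angles(track_from_xy([[0, 0]]))


class TestWrappedCauchy:
    def test_zero_concentration_is_circular_uniform(self):
        theta = np.linspace(-np.pi, np.pi, 50)
        assert np.allclose(wrapped_cauchy_pdf(theta, 0.0, 0.0), 1 / (2 * np.pi))

    def test_integrates_to_one(self):
        val, _ = quad(lambda t: wrapped_cauchy_pdf(t, 0.0, 0.7), -np.pi, np.pi)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_mode_at_location(self):
        m = 0.8
        dens_mode = wrapped_cauchy_pdf(m, m, 0.6)
        for offset in (0.3, 1.0, 2.5):
            assert dens_mode > wrapped_cauchy_pdf(m + offset, m, 0.6)
            assert dens_mode > wrapped_cauchy_pdf(m - offset, m, 0.6)

    def test_invalid_concentration_rejected(self):
        with pytest.raises(ValueError):
            wrapped_cauchy_pdf(0.0, 0.0, 1.0)


class TestForwardLoglik:
    def test_degenerate_identical_states_reduce_to_iid(self, rng):
        """With identical emissions in every state the hidden structure is
        irrelevant: loglik equals the iid sum of log densities."""
        spec = toy_spec(
            emissions={
                "step": {"mean": np.array([50.0] * 3), "sd": np.array([20.0] * 3)},
                "angle": {"mean": np.zeros(3), "rho": np.array([0.4] * 3)},
            }
        )
        obs, _ = simulate_from_spec(spec, 30, rng)
        from scipy.stats import gamma

        shape, scale = (50 / 20) ** 2, 20**2 / 50
        iid = gamma.logpdf(obs["step"], a=shape, scale=scale).sum()
        a = obs["angle"][~np.isnan(obs["angle"])]
        iid += np.log(wrapped_cauchy_pdf(a, 0.0, 0.4)).sum()
        assert forward_loglik(obs, spec) == pytest.approx(iid)

    @pytest.mark.parametrize("T", [2, 4, 6])
    def test_matches_exhaustive_path_enumeration(self, T, rng):
        spec = toy_spec()
        obs, _ = simulate_from_spec(spec, T, rng)
        assert forward_loglik(obs, spec) == pytest.approx(
            brute_force_forward(obs, spec), rel=1e-10
        )

    def test_state_relabeling_invariance(self, rng):
        spec = toy_spec()
        obs, _ = simulate_from_spec(spec, 50, rng)
        perm = [2, 0, 1]
        relabeled = HmmSpec(
            streams=spec.streams,
            emissions={
                "step": {k: np.asarray(v)[perm] for k, v in spec.emissions["step"].items()},
                "angle": {k: np.asarray(v)[perm] for k, v in spec.emissions["angle"].items()},
            },
            tmat=spec.tmat[np.ix_(perm, perm)],
            delta=spec.delta[perm],
        )
        assert forward_loglik(obs, relabeled) == pytest.approx(
            forward_loglik(obs, spec)
        )

    def test_all_missing_step_rejected(self):
        spec = toy_spec()
        obs = {"step": np.array([10.0, np.nan]), "angle": np.array([np.nan, np.nan])}
        with pytest.raises(ValueError, match="every stream missing"):
            forward_loglik(obs, spec)

    def test_missing_first_angle_contributes_unit_likelihood(self, rng):
        spec = toy_spec()
        obs, _ = simulate_from_spec(spec, 10, rng)
        assert np.isnan(obs["angle"][0])
        assert np.isfinite(forward_loglik(obs, spec))


class TestFit:
    def test_start_at_truth_cannot_worsen(self, rng):
        spec = toy_spec()
        obs, _ = simulate_from_spec(spec, 300, rng)
        fit = fit_hmm(obs, spec, n_restarts=1, seed=0)
        assert fit.loglik >= forward_loglik(obs, spec) - 1e-6

    def test_more_restarts_never_lower_loglik(self, rng):
        spec = toy_spec()
        obs, _ = simulate_from_spec(spec, 200, rng)
        fit2 = fit_hmm(obs, default_spec(), n_restarts=2, seed=3)
        fit4 = fit_hmm(obs, default_spec(), n_restarts=4, seed=3)
        assert fit4.loglik >= fit2.loglik - 1e-9

    def test_parameter_recovery_moderate_n(self, rng):
        spec = toy_spec()
        obs, _ = simulate_from_spec(spec, 2000, rng)
        fit = fit_hmm(obs, default_spec(), n_restarts=2, seed=5)
        order = np.argsort(fit.spec.emissions["step"]["mean"])
        means = fit.spec.emissions["step"]["mean"][order]
        assert np.all(np.abs(means - [10, 80, 500]) / [10, 80, 500] < 0.15)

    def test_restart_log_recorded(self, rng):
        obs, _ = simulate_from_spec(toy_spec(), 100, rng)
        fit = fit_hmm(obs, default_spec(), n_restarts=3, seed=1)
        assert len(fit.restarts) == 3
        assert fit.loglik == pytest.approx(fit.restarts["loglik"].max())

    def test_zero_restarts_rejected(self, rng):
        obs, _ = simulate_from_spec(toy_spec(), 10, rng)
        with pytest.raises(ValueError, match="n_restarts"):
            fit_hmm(obs, toy_spec(), n_restarts=0)


class TestAic:
    def test_aic_identity(self, rng):
        obs, _ = simulate_from_spec(toy_spec(), 100, rng)
        fit = fit_hmm(obs, toy_spec(), n_restarts=1, seed=0)
        # 6 transition + 2 initial + 6 step + 3 rho = 17 free parameters
        assert fit.spec.n_params == 17
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * 17)

    def test_aic_arithmetic(self):
        fit = HmmFit(spec=toy_spec(), loglik=-100.0, n_obs=10)
        k = fit.spec.n_params
        assert fit.aic == -2 * -100 + 2 * k
        # textbook check at k = 14
        assert -2 * -100.0 + 2 * 14 == 228.0

    def test_identical_fits_tie_to_simpler(self, rng):
        gps_only = toy_spec(streams=("step",), emissions={
            "step": {"mean": np.array([10.0, 80.0, 500.0]),
                     "sd": np.array([8.0, 50.0, 200.0])}})
        obs, _ = simulate_from_spec(toy_spec(), 50, rng)
        big = toy_spec()
        # logliks chosen so both AICs are exactly equal
        fit_small = HmmFit(spec=gps_only, loglik=-10.0, n_obs=50)
        fit_big = HmmFit(
            spec=big, loglik=-10.0 + (big.n_params - gps_only.n_params), n_obs=50
        )
        chosen, delta = compare_aic(fit_big, fit_small)
        assert chosen is fit_small and delta == 0.0

    def test_mismatched_spans_rejected(self):
        a = HmmFit(spec=toy_spec(), loglik=-1.0, n_obs=10)
        b = HmmFit(spec=toy_spec(), loglik=-1.0, n_obs=20)
        with pytest.raises(ValueError, match="different data spans"):
            compare_aic(a, b)

    def test_uninformative_activity_prefers_gps_only(self, rng):
        """When activity carries no state information, the extra emission
        parameters cost more AIC than they buy likelihood."""
        full = toy_spec(
            streams=("step", "angle", "act_x"),
            emissions={
                "step": {"mean": np.array([10.0, 80.0, 500.0]),
                         "sd": np.array([8.0, 50.0, 200.0])},
                "angle": {"mean": np.zeros(3), "rho": np.array([0.0, 0.3, 0.8])},
                # same activity distribution in every state
                "act_x": {"mean": np.array([30.0] * 3), "sd": np.array([10.0] * 3)},
            },
        )
        obs, _ = simulate_from_spec(full, 800, rng)
        gps_obs = {"step": obs["step"], "angle": obs["angle"]}
        fit_gps = fit_hmm(gps_obs, default_spec(("step", "angle")),
                          n_restarts=2, seed=2)
        fit_full = fit_hmm(obs, default_spec(("step", "angle", "act_x")),
                           n_restarts=2, seed=2)
        chosen, delta = compare_aic(fit_gps, fit_full)
        assert chosen is fit_gps
        assert delta > 0


class TestViterbi:
    def test_identical_emissions_give_constant_lowest_index_path(self, rng):
        spec = toy_spec(
            emissions={
                "step": {"mean": np.array([50.0] * 3), "sd": np.array([20.0] * 3)},
                "angle": {"mean": np.zeros(3), "rho": np.array([0.4] * 3)},
            },
            tmat=np.full((3, 3), 1 / 3),
            delta=np.array([1 / 3, 1 / 3, 1 / 3]),
        )
        obs, _ = simulate_from_spec(spec, 20, rng)
        assert (viterbi(obs, spec) == 0).all()

    @pytest.mark.parametrize("T", [2, 3])
    def test_matches_exhaustive_enumeration(self, T, rng):
        spec = toy_spec()
        for _ in range(10):
            obs, _ = simulate_from_spec(spec, T, rng)
            assert tuple(viterbi(obs, spec)) == brute_force_viterbi(obs, spec)

    def test_decoding_recovers_well_separated_truth(self, rng):
        spec = toy_spec()
        obs, states = simulate_from_spec(spec, 1000, rng)
        agree = np.mean(viterbi(obs, spec) == states)
        assert agree >= 0.95

    def test_relabeling_permutes_decoded_path(self, rng):
        spec = toy_spec()
        obs, _ = simulate_from_spec(spec, 50, rng)
        perm = np.array([2, 0, 1])
        relabeled = HmmSpec(
            streams=spec.streams,
            emissions={
                s: {k: np.asarray(v)[perm] for k, v in p.items()}
                for s, p in spec.emissions.items()
            },
            tmat=spec.tmat[np.ix_(perm, perm)],
            delta=spec.delta[perm],
        )
        inv = np.empty(3, dtype=int)
        inv[perm] = np.arange(3)
        assert (viterbi(obs, relabeled) == inv[viterbi(obs, spec)]).all()


class TestObservationBuilders:
    def test_hourly_means_require_enough_records(self):
        times = [T0 + pd.Timedelta(minutes=5 * i) for i in range(15)]
        frame = pd.DataFrame(
            {"interval_start": times, "act_x": 10, "act_y": 20, "act_z": 30}
        )
        out = hourly_activity_means(frame, min_records=9)
        # first hour has 12 records, second only 3 -> dropped
        assert len(out) == 1
        assert out.iloc[0]["act_x"] == 10

    def test_movement_observations_align_activity(self):
        xy = [[0, 0], [100, 0], [200, 0]]
        times = pd.DatetimeIndex([T0, T0 + pd.Timedelta(hours=1),
                                  T0 + pd.Timedelta(hours=2)])
        track = GPSTrack(animal_id="t", times=times, xy=np.array(xy, dtype=float))
        activity = pd.DataFrame(
            {"hour": [T0], "act_x": [5.0], "act_y": [6.0], "act_z": [7.0]}
        )
        obs = movement_observations(track, activity)
        assert obs["act_x"][0] == 5.0
        assert np.isnan(obs["act_x"][1])
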