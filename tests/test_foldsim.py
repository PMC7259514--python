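"""Fold-transition simulator: fixed points, escape, detrend, controls."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from motionews.ews import WindowSpec, windowed_ar1
from motionews.foldsim import (
    SimConfig,
    Trajectory,
    detrend,
    generate_exp3_ensemble,
    read_trajectory,
    simulate_fold_exp3,
    simulate_fold_minimal,
    simulate_heaviside_control,
    stable_branch,
    write_trajectory,
)


def _minimal_cfg(**kw):
    base = dict(
        a=1.0, gamma=0.0, epsilon=0.0, dt=0.01, duration=5.0,
        tstar_range=(0.0, 0.0), cubic=False, seed=0,
    )
    base.update(kw)
    return SimConfig(**base)


class TestMinimalModel:
    def test_converges_to_stable_root(self):
        # dx/dt = -0.25 + x^2 from x(0)=0 settles at the stable root -0.5
        traj = simulate_fold_minimal(
            _minimal_cfg(duration=20.0), y0=-0.25, x0=0.0
        )
        assert traj.x[-1] == pytest.approx(-0.5, abs=1e-5)
        assert np.all(np.abs(traj.x[-100:] + 0.5) < 1e-3)

    def test_no_fixed_point_when_y_positive(self):
        traj = simulate_fold_minimal(
            _minimal_cfg(duration=1.0), y0=0.1, x0=0.0
        )
        x = traj.x
        if traj.escape_time is not None:
            x = x[traj.t < traj.escape_time]
        assert np.all(np.diff(x) > 0)

    def test_escape_time_matches_dense_ode_oracle(self):
        """Euler escape agrees with a high-accuracy integration of the ODE."""
        cfg = _minimal_cfg(epsilon=0.01, duration=25.0)
        y0 = -0.05
        traj = simulate_fold_minimal(cfg, y0=y0)
        assert traj.escape_time is not None

        bound = cfg.x_bound
        event = lambda t, x: x[0] - bound  # noqa: E731
        event.terminal = True
        sol = solve_ivp(
            lambda t, x: [y0 + cfg.epsilon * t + x[0] ** 2],
            (0, 25.0),
            [-np.sqrt(-y0)],
            events=event,
            rtol=1e-10,
            atol=1e-12,
            max_step=0.01,
        )
        t_oracle = sol.t_events[0][0]
        # slow passage through the bottleneck amplifies the first-order
        # discretization error; the Euler escape sits a few readouts
        # late and converges to the oracle as dt shrinks
        assert abs(traj.escape_time - t_oracle) <= 5 * cfg.dt
        fine = simulate_fold_minimal(
            _minimal_cfg(epsilon=0.01, duration=25.0, dt=0.001), y0=-0.05
        )
        assert abs(fine.escape_time - t_oracle) <= cfg.dt

    def test_halving_dt_moves_escape_toward_oracle(self):
        cfg = _minimal_cfg(epsilon=0.01, duration=25.0)
        t1 = simulate_fold_minimal(cfg, y0=-0.05).escape_time
        cfg2 = _minimal_cfg(epsilon=0.01, duration=25.0, dt=0.005)
        t2 = simulate_fold_minimal(cfg2, y0=-0.05).escape_time
        assert t2 < t1
        assert abs(t1 - t2) <= 3 * cfg.dt

    def test_transition_flagged_where_y_crosses_zero(self):
        cfg = _minimal_cfg(epsilon=0.01, duration=25.0)
        traj = simulate_fold_minimal(cfg, y0=-0.05)
        assert traj.tstar_true == pytest.approx(5.0)
        k = np.searchsorted(traj.t, traj.tstar_true)
        assert traj.y[k] >= 0 > traj.y[k - 2]


class TestSaturatingModel:
    def test_readout_count_matches_configuration(self, exp3_cfg):
        traj = simulate_fold_exp3(exp3_cfg, rng=np.random.default_rng(0))
        assert len(traj.t) == 150  # 1.5 s at 10 ms readouts
        assert exp3_cfg.tstar_range[0] <= traj.tstar_true <= exp3_cfg.tstar_range[1]

    def test_plateau_is_cubic_root_for_small_positive_y(self):
        """Held at y=0.01 the flow settles at the root of 0.01+4x^2-x^3."""
        from motionews.foldsim import _integrate

        cfg = SimConfig(gamma=0.0, duration=30.0, tstar_range=(0.0, 1.0))
        y = np.full(3000, 0.01)
        x, _ = _integrate(0.0, y, cfg, None)
        root = brentq(lambda v: 0.01 + 4 * v**2 - v**3, 3.0, 5.0)
        assert root == pytest.approx(4.000625, abs=1e-4)
        assert x[-1] == pytest.approx(root, abs=1e-3)

    def test_noiseless_monotone_after_transition(self):
        cfg = SimConfig(gamma=0.0, seed=1)
        traj = simulate_fold_exp3(
            cfg, rng=np.random.default_rng(1), tstar=0.5, direction=1
        )
        after = (traj.t >= 0.5) & (traj.t <= traj.t[-1])
        xa = traj.x[after]
        ramp = np.diff(xa)
        # monotone rise until saturation; allow the flat saturated tail
        rising = ramp > -1e-9
        assert rising[: np.argmax(xa[:-1] > 0.99 * xa.max())].all()

    def test_noiseless_bounded_by_final_branch(self):
        cfg = SimConfig(gamma=0.0, seed=1)
        traj = simulate_fold_exp3(
            cfg, rng=np.random.default_rng(1), tstar=0.35, direction=1
        )
        y_end = cfg.epsilon * (cfg.duration - 0.35)
        upper = brentq(lambda v: y_end + 4 * v**2 - v**3, 4.0, 100.0)
        assert np.all(np.abs(traj.x) <= max(np.abs(traj.x[0]), upper + 1.0))

    def test_escape_before_transition_never_happens_noiselessly(self):
        cfg = SimConfig(gamma=0.0, seed=3)
        for tstar in (0.35, 0.5, 0.7):
            traj = simulate_fold_exp3(
                cfg, rng=np.random.default_rng(3), tstar=tstar, direction=1
            )
            pre = traj.t < tstar - cfg.dt
            assert np.all(np.abs(traj.x[pre]) < cfg.a / 2)


class TestDetrend:
    def test_removes_exact_stable_branch(self):
        """A trajectory lying on the branch detrends to zero before t*."""
        cfg = SimConfig(gamma=0.0)
        n = cfg.n_readouts
        t = np.arange(n) * cfg.dt
        tstar = 0.5
        y = cfg.epsilon * (t - tstar)
        x = stable_branch(y, cfg.a, True)
        traj = Trajectory(t=t, x=x, y=y, tstar_true=tstar, cfg=cfg)
        out = detrend(traj)
        assert np.all(np.abs(out.x[t < tstar]) < 1e-10)

    def test_constant_pretransition_becomes_zero(self):
        cfg = SimConfig(gamma=0.0)
        n = cfg.n_readouts
        t = np.arange(n) * cfg.dt
        y = np.full(n, -1.0)  # branch is constant, so is the signal
        x = stable_branch(y, cfg.a, True).copy()
        traj = Trajectory(t=t, x=x, y=y, tstar_true=np.nan, cfg=cfg)
        out = detrend(traj)
        assert np.allclose(out.x, 0.0, atol=1e-12)

    def test_ensemble_pretransition_mean_within_monte_carlo_error(self):
        cfg = SimConfig(seed=5)
        rngs = np.random.SeedSequence(5).spawn(100)
        vals = []
        for c in rngs:
            tr = simulate_fold_exp3(cfg, rng=np.random.default_rng(c), direction=1)
            vals.append(tr.x[tr.pre_transition_mask()])
        means = np.array([v.mean() for v in vals])
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) < 3 * se + 1e-12

    def test_requires_pre_transition_samples(self):
        cfg = SimConfig(gamma=0.0)
        n = cfg.n_readouts
        t = np.arange(n) * cfg.dt
        traj = Trajectory(
            t=t, x=np.zeros(n), y=np.zeros(n), tstar_true=0.0, cfg=cfg
        )
        with pytest.raises(ValueError):
            detrend(traj)


class TestHeavisideControl:
    def test_noiseless_step_is_exact(self):
        cfg = SimConfig(seed=0)
        traj = simulate_heaviside_control(0.5, 4.0, 0.0, cfg, direction=1)
        assert np.all(traj.x[traj.t < 0.5] == 0.0)
        assert np.all(traj.x[traj.t >= 0.5] == 4.0)

    def test_matched_ensemble_shares_transition_times(self):
        cfg = SimConfig(seed=9)
        pairs = generate_exp3_ensemble(cfg, 12)
        for fold, ctrl in pairs:
            assert ctrl.tstar_true == fold.tstar_true
            assert ctrl.kind == "heaviside"

    def test_control_pretransition_ar1_near_iid_bias(self):
        """Step-control windows are i.i.d., so AR(1) centers on -1/(n-1)."""
        cfg = SimConfig(seed=21)
        w = WindowSpec(length_ms=100, rate=100.0)  # 10-sample windows
        ests = []
        for c in np.random.SeedSequence(21).spawn(60):
            tr = simulate_heaviside_control(
                0.7, 4.0, 0.1, cfg, rng=np.random.default_rng(c)
            )
            est = windowed_ar1(tr.x[tr.t < 0.7], w)
            ests.append(np.nanmean(est))
        mean = np.mean(ests)
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert mean == pytest.approx(-1.0 / 9.0, abs=4 * se)

    def test_validation(self):
        cfg = SimConfig()
        with pytest.raises(ValueError):
            simulate_heaviside_control(2.0, 4.0, 0.1, cfg)
        with pytest.raises(ValueError):
            simulate_heaviside_control(0.5, 4.0, -0.1, cfg)


class TestEnsemble:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(seed=33)
        p1 = generate_exp3_ensemble(cfg, 5)
        p2 = generate_exp3_ensemble(cfg, 5)
        for (f1, c1), (f2, c2) in zip(p1, p2):
            np.testing.assert_array_equal(f1.x, f2.x)
            np.testing.assert_array_equal(c1.x, c2.x)
            assert f1.direction == f2.direction

    def test_counts_and_noise_matching(self):
        cfg = SimConfig(seed=2)
        pairs = generate_exp3_ensemble(cfg, 20)
        assert len(pairs) == 20
        # control noise half-width matches the fold arm's fluctuation
        # amplitude: sd * sqrt(3) for a uniform draw
        pre_sd = np.mean(
            [np.std(f.x[f.pre_transition_mask()], ddof=1) for f, _ in pairs]
        )
        amp = pairs[0][1].meta["noise_amp"]
        assert amp == pytest.approx(pre_sd * np.sqrt(3), rel=1e-9)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(dt=-0.01),
            dict(gamma=-1.0),
            dict(epsilon=-5.0),
            dict(tstar_range=(0.8, 0.3)),
            dict(duration=0.5),
            dict(noise_kind="poisson"),
        ],
    )
    def test_bad_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw)


def test_trajectory_roundtrip(tmp_path, exp3_cfg):
    traj = simulate_fold_exp3(exp3_cfg, rng=np.random.default_rng(4))
    path = tmp_path / "traj.csv"
    write_trajectory(traj, path)
    back = read_trajectory(path)
    np.testing.assert_allclose(back.x, traj.x)
    np.testing.assert_allclose(back.y, traj.y)
    assert back.tstar_true == pytest.approx(traj.tstar_true)
    assert back.direction == traj.direction
    assert back.cfg == traj.cfg
    assert back.detrended
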