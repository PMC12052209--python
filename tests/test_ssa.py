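import numpy as np
import pytest

from rcnoise import (
    CircuitParams,
    CountState,
    ResourceMode,
    build_propensities,
    clamped_mean_run,
    dose_sweep,
    find_steady_states,
    gillespie_run,
    spawn_seed,
    steady_state_closed_form,
)
from rcnoise.model import ode_rhs
from rcnoise.ssa import STOICHIOMETRY, _propensities

UNLIM = ResourceMode.UNLIMITED
SHARED = ResourceMode.SHARED


class TestPropensities:
    def test_exactly_eight_channels(self, defaults):
        chans = build_propensities(defaults, SHARED)
        assert len(chans) == 8
        labels = [c.label for c in chans]
        assert labels == [
            "m1_birth", "m1_death", "p1_birth", "p1_death",
            "m2_birth", "m2_death", "p2_birth", "p2_death",
        ]

    def test_each_event_changes_one_species_by_one(self):
        assert STOICHIOMETRY.shape == (8, 4)
        assert np.all(np.abs(STOICHIOMETRY).sum(axis=1) == 1)

    def test_deaths_vanish_at_zero_counts(self, defaults):
        zero = np.zeros(4)
        for mode in ResourceMode:
            chans = build_propensities(defaults, mode)
            for c in chans:
                if c.label.endswith("death"):
                    assert c.propensity(zero) == 0.0

    def test_unlimited_translation_is_kp_times_count(self, defaults):
        chans = build_propensities(defaults, UNLIM)
        X = np.array([7, 0, 3, 0])
        p1_birth = next(c for c in chans if c.label == "p1_birth")
        assert p1_birth.propensity(X) == pytest.approx(defaults.kp1 * 7)

    def test_shared_limits_to_unlimited(self, defaults):
        big = defaults.replace(Jm1=1e9, Jm2=1e9, Jp1=1e9, Jp2=1e9)
        X = np.array([10, 150, 2, 40])
        a = [c.propensity(X) for c in build_propensities(big, SHARED)]
        b = [c.propensity(X) for c in build_propensities(defaults, UNLIM)]
        assert np.allclose(a, b, rtol=1e-5)

    def test_negative_count_rejected(self, defaults):
        chans = build_propensities(defaults, SHARED)
        with pytest.raises(ValueError, match="negative"):
            chans[0].propensity(np.array([-1, 0, 0, 0]))

    def test_clamp_requires_shared(self, defaults):
        with pytest.raises(ValueError, match="shared"):
            build_propensities(defaults, UNLIM, clamp=(5.0, 5.0))

    @pytest.mark.parametrize("mode", list(ResourceMode))
    def test_kernel_matches_python_channels(self, defaults, mode):
        rng = np.random.default_rng(5)
        chans = build_propensities(defaults, mode)
        a = np.zeros(8)
        for _ in range(25):
            X = rng.integers(0, 300, size=4)
            _propensities(
                defaults.theta(), mode.code, -1.0, -1.0,
                int(X[0]), int(X[1]), int(X[2]), int(X[3]), a,
            )
            expected = [c.propensity(X.astype(float)) for c in chans]
            assert np.allclose(a, expected, rtol=1e-12)

    def test_kernel_clamp_matches_python_channels(self, defaults):
        rng = np.random.default_rng(6)
        clamp = (12.5, 3.25)
        chans = build_propensities(defaults, SHARED, clamp=clamp)
        a = np.zeros(8)
        for _ in range(25):
            X = rng.integers(0, 300, size=4)
            _propensities(
                defaults.theta(), SHARED.code, clamp[0], clamp[1],
                int(X[0]), int(X[1]), int(X[2]), int(X[3]), a,
            )
            expected = [c.propensity(X.astype(float)) for c in chans]
            assert np.allclose(a, expected, rtol=1e-12)


class TestGillespie:
    def test_linear_birth_death_is_poisson(self):
        # isolate M1: constant birth Omega*km01, linear death dm1*M1
        p = CircuitParams(km01=20.0, km1=1e-12, km02=1e-6, km2=1e-12,
                          kp1=1e-12, kp2=1e-12, Omega=1.0)
        traj = gillespie_run(p, UNLIM, t_end=5000.0, seed=9, init=[0, 0, 0, 0])
        x = traj.stationary()[:, 0].astype(float)
        lam = p.km01 * p.Omega
        mean_expected = lam / p.dm1
        se = np.sqrt(mean_expected / (len(x) / 20))  # crude ESS correction
        assert abs(x.mean() - mean_expected) < 3 * se
        fano = x.var() / x.mean()
        assert abs(fano - 1.0) < 0.1

    def test_stationary_mean_matches_closed_form(self, unlimited_long_run, defaults):
        ss = steady_state_closed_form(defaults, UNLIM)
        x = unlimited_long_run.stationary()
        # P1: expect Omega * 126 = 189 within MC error
        mean = x[:, 1].mean()
        assert abs(mean - defaults.Omega * ss.p1) < 3.0

    def test_seed_determinism(self, defaults):
        a = gillespie_run(defaults, SHARED, t_end=50.0, seed=77)
        b = gillespie_run(defaults, SHARED, t_end=50.0, seed=77)
        assert np.array_equal(a.counts, b.counts)
        c = gillespie_run(defaults, SHARED, t_end=50.0, seed=78)
        assert not np.array_equal(a.counts, c.counts)

    def test_absorbing_state_terminates_cleanly(self):
        # no production, no initial molecules -> total propensity 0
        p = CircuitParams(km01=0.0, km1=1e-300, km02=0.0, km2=1e-300)
        traj = gillespie_run(p, UNLIM, t_end=10.0, seed=1, init=[0, 0, 0, 0])
        assert np.all(traj.counts == 0)
        assert traj.t[-1] == pytest.approx(10.0, abs=0.1)

    def test_invalid_t_end(self, defaults):
        with pytest.raises(ValueError):
            gillespie_run(defaults, SHARED, t_end=0.0, seed=1)

    def test_ensemble_mean_tracks_ode(self, defaults):
        # monostable shared regime
        params = defaults.replace(I1=0.5)
        from scipy.integrate import solve_ivp

        sol = solve_ivp(
            lambda t, x: ode_rhs(x, params, SHARED), (0, 500), np.zeros(4),
            method="LSODA", rtol=1e-10, atol=1e-12,
        )
        target = sol.y[:, -1] * params.Omega
        finals = np.array([
            gillespie_run(params, SHARED, t_end=400.0, seed=s).stationary().mean(axis=0)
            for s in range(25)
        ])
        mean = finals.mean(axis=0)
        se = finals.std(axis=0, ddof=1) / np.sqrt(len(finals))
        assert np.all(np.abs(mean - target) < 3 * se + 0.05 * target)

    def test_two_inits_hold_their_branches_initially(self, defaults):
        stable = [p for p in find_steady_states(defaults, SHARED) if p.stable]
        runs = []
        for pt in stable:
            init = pt.state.to_counts(defaults)
            tr = gillespie_run(defaults, SHARED, t_end=30.0, seed=5, init=init,
                               burn_in_frac=0.0)
            runs.append(tr.counts[:, 1].mean())
        lo, hi = sorted(runs)
        assert lo < defaults.Omega * stable[1].state.p1 * 0.8
        assert hi > defaults.Omega * stable[0].state.p1 * 1.2

    def test_trajectory_csv_round_trip(self, defaults, tmp_path):
        tr = gillespie_run(defaults, SHARED, t_end=20.0, seed=4)
        path = tmp_path / "run.csv"
        tr.to_csv(path)
        import json

        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == ["t", "M1", "P1", "M2", "P2"]
        meta = json.loads((tmp_path / "run.csv.json").read_text())
        assert meta["mode"] == "shared" and meta["seed"] == 4


class TestClampedRuns:
    def test_clamp_noop_when_partition_inactive(self, defaults):
        # with huge translational capacities the clamped mRNA never matters,
        # so clamped and unclamped runs coincide event-for-event
        p = defaults.replace(Jp1=1e12, Jp2=1e12)
        a = gillespie_run(p, SHARED, t_end=30.0, seed=21)
        b = gillespie_run(p, SHARED, t_end=30.0, seed=21, clamp=(1234.0, 5678.0))
        assert np.array_equal(a.counts, b.counts)

    def test_bistable_requires_branch(self, defaults):
        with pytest.raises(ValueError, match="branch"):
            clamped_mean_run(defaults, t_end=10.0, seed=1, reference="deterministic")

    def test_unknown_reference_rejected(self, defaults):
        with pytest.raises(ValueError, match="reference"):
            clamped_mean_run(defaults, t_end=10.0, seed=1, reference="x")

    def test_clamp_on_unshared_rejected(self, defaults):
        with pytest.raises(ValueError, match="shared"):
            gillespie_run(defaults, UNLIM, t_end=10.0, seed=1, clamp=(1.0, 1.0))

    def test_monostable_clamped_matches_unclamped_mean(self, defaults):
        params = defaults.replace(I1=0.3)
        free = gillespie_run(params, SHARED, t_end=4000.0, seed=31)
        clamped = clamped_mean_run(params, t_end=4000.0, seed=31,
                                   reference="deterministic")
        mu_f = free.stationary()[:, 1].mean()
        mu_c = clamped.stationary()[:, 1].mean()
        assert abs(mu_f - mu_c) / mu_f < 0.05


class TestDoseSweep:
    def test_single_dose_single_rep_equals_one_run(self, defaults):
        sweep = dose_sweep(defaults, SHARED, [0.5], reps=1, t_end=30.0,
                           master_seed=99)
        direct = gillespie_run(defaults.replace(I1=0.5), SHARED, t_end=30.0,
                               seed=spawn_seed(99, 0, 0))
        assert np.array_equal(sweep[0][0].counts, direct.counts)

    def test_seed_schedule_unique(self):
        seeds = {spawn_seed(7, i, r) for i in range(10) for r in range(10)}
        assert len(seeds) == 100

    def test_mean_curves_sigmoidal(self, defaults):
        doses = [0.1, 0.5, 1.0, 1.5, 2.0]
        sweep = dose_sweep(defaults, SHARED, doses, reps=2, t_end=1500.0,
                           master_seed=7)
        gfp = [np.mean([r.stationary()[:, 1].mean() for r in runs]) for runs in sweep]
        rfp = [np.mean([r.stationary()[:, 3].mean() for r in runs]) for runs in sweep]
        assert gfp[-1] > gfp[0]  # increasing overall
        assert rfp[-1] < rfp[0]  # decreasing overall

    def test_unlimited_sweep_matches_closed_form(self, defaults):
        doses = [0.2, 1.0]
        sweep = dose_sweep(defaults, UNLIM, doses, reps=3, t_end=2000.0,
                           master_seed=13)
        for dose, runs in zip(doses, sweep):
            ss = steady_state_closed_form(defaults.replace(I1=dose), UNLIM)
            pooled = np.concatenate([r.stationary() for r in runs])
            assert pooled[:, 1].mean() == pytest.approx(
                defaults.Omega * ss.p1, rel=0.05
            )
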