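"""Generator contracts: cohorts, ground truth, edge values, scans, TACs, GMD."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fcaging import logan, synthetic
from fcaging.synthetic import (
    CohortSpec,
    EffectConfig,
    MotionModel,
    ReferenceCurve,
    make_cohort,
    sample_edge_truth,
    simulate_edge_values,
    simulate_gmd,
    simulate_tac,
    simulate_timeseries,
)


class TestMakeCohort:
    def test_group_sizes_and_age_means(self):
        cohort = make_cohort(CohortSpec(n_young=30, n_old=30, seed=1))
        assert len(cohort) == 60
        young = [r.age for r in cohort if r.group == "younger"]
        old = [r.age for r in cohort if r.group == "older"]
        assert len(young) == len(old) == 30
        # sample means within 2 SE of the group targets
        assert abs(np.mean(young) - 24.2) < 2 * 3.4 / np.sqrt(30)
        assert abs(np.mean(old) - 70.8) < 2 * 2.7 / np.sqrt(30)

    def test_degenerate_sd_gives_exact_ages(self):
        cohort = make_cohort(CohortSpec(young_age_sd=0.0, old_age_sd=0.0, seed=2))
        assert all(r.age == 24.2 for r in cohort if r.group == "younger")
        assert all(r.age == 70.8 for r in cohort if r.group == "older")

    def test_seeded_determinism(self):
        a = make_cohort(CohortSpec(seed=3))
        b = make_cohort(CohortSpec(seed=3))
        assert [(r.subject_id, r.age, r.motion_trait) for r in a] == [
            (r.subject_id, r.age, r.motion_trait) for r in b
        ]

    def test_ages_truncated_above_minimum(self):
        cohort = make_cohort(CohortSpec(young_age_mean=19.0, young_age_sd=4.0, seed=4))
        assert all(r.age > 18.0 for r in cohort)

    @pytest.mark.parametrize("field,value", [("n_young", 1), ("n_old", 0)])
    def test_invalid_spec_names_field(self, field, value):
        spec = CohortSpec(**{field: value})
        with pytest.raises(ValueError, match=field):
            make_cohort(spec)


class TestEdgeTruth:
    @pytest.mark.parametrize("n_nodes,expected", [(261, 33930), (3, 3), (10, 45)])
    def test_edge_count_is_n_choose_2(self, n_nodes, expected):
        assert len(sample_edge_truth(n_nodes, seed=0)) == expected

    def test_small_graph_rejected(self):
        with pytest.raises(ValueError):
            sample_edge_truth(2)

    def test_zero_slope_scales_give_zero_betas(self):
        cfg = EffectConfig(
            beta_mu_mean=0.0, beta_mu_sd=0.0, beta_sigma_mean=0.0, beta_sigma_sd=0.0,
            node_coupling_mu=0.0, node_coupling_sigma=0.0,
        )
        truth = sample_edge_truth(5, cfg, seed=0)
        assert all(e.beta_mu == 0.0 and e.beta_sigma == 0.0 for e in truth)

    def test_ordered_node_indices(self):
        assert all(e.node_i < e.node_j for e in sample_edge_truth(8, seed=1))


def _fixed_age_cohort(n, age, fd=0.0):
    half = n // 2
    return [
        synthetic.SubjectRecord(f"s{i}", age, "younger" if i < half else "older", "F", fd)
        for i in range(n)
    ]


class TestSimulateEdgeValues:
    def test_mean_matches_generative_law(self):
        # beta_mu = -0.002, age 70 -> mean = alpha_mu - 0.1
        truth = [synthetic.EdgeTruth(0, 1, 0.3, -0.002, np.log(0.2), 0.0, 0.0)]
        cohort = _fixed_age_cohort(100_000, 70.0)
        y = simulate_edge_values(cohort, truth, seed=5)[:, 0]
        se = 0.2 / np.sqrt(y.size)
        assert abs(y.mean() - 0.2) < 4 * se

    def test_sd_matches_log_linear_law(self):
        truth = [synthetic.EdgeTruth(0, 1, 0.0, 0.0, np.log(0.1), 0.01, 0.0)]
        cohort = _fixed_age_cohort(100_000, 70.0)
        y = simulate_edge_values(cohort, truth, seed=6)[:, 0]
        expected_sd = 0.1 * np.exp(0.01 * 50)
        assert abs(y.std() / expected_sd - 1) < 0.02

    def test_noiseless_motion_offset(self):
        # sigma -> 0: y = mu + rho * FD exactly
        truth = [synthetic.EdgeTruth(0, 1, 0.3, 0.0, -50.0, 0.0, 0.5)]
        cohort = _fixed_age_cohort(10, 20.0, fd=0.2)
        y = simulate_edge_values(cohort, truth, seed=7)[:, 0]
        assert np.allclose(y, 0.3 + 0.5 * 0.2, atol=1e-6)

    def test_include_motion_flag(self):
        truth = [synthetic.EdgeTruth(0, 1, 0.0, 0.0, -50.0, 0.0, 1.0)]
        cohort = _fixed_age_cohort(6, 30.0, fd=0.3)
        with_m = simulate_edge_values(cohort, truth, seed=8)
        without = simulate_edge_values(cohort, truth, seed=8, include_motion=False)
        assert np.allclose(with_m - without, 0.3, atol=1e-6)


class TestSimulateTimeseries:
    def test_zero_target_gives_independent_series(self, rng):
        scan = simulate_timeseries(
            np.zeros((4, 4)), 20_000, motion=MotionModel(0.0, 0.0), nuisance_gain=0.0,
            seed=9,
        )
        r = np.corrcoef(scan.series, rowvar=False)
        off = r[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.03

    def test_three_node_target_recovered(self):
        z = np.arctanh(np.array([
            [0.0, 0.5, 0.3],
            [0.5, 0.0, 0.2],
            [0.3, 0.2, 0.0],
        ]))
        scan = simulate_timeseries(
            z, 100_000, motion=MotionModel(0.0, 0.0), nuisance_gain=0.0, seed=10
        )
        r = np.corrcoef(scan.series, rowvar=False)
        target = np.array([0.5, 0.3, 0.2])
        got = np.array([r[0, 1], r[0, 2], r[1, 2]])
        assert np.abs(got - target).max() < 0.01

    def test_zero_motion_model(self):
        scan = simulate_timeseries(np.zeros((3, 3)), 60, motion=MotionModel(0.0, 0.0), seed=11)
        assert np.all(scan.motion == 0)

    def test_population_correlation_is_psd(self, rng):
        z = rng.normal(0.3, 0.4, (20, 20))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        scan = simulate_timeseries(z, 60, seed=12)
        assert np.linalg.eigvalsh(scan.target_correlation).min() > -1e-8
        assert scan.projection_distance >= 0

    def test_nonfinite_target_rejected(self):
        z = np.zeros((3, 3))
        z[0, 1] = z[1, 0] = np.inf
        with pytest.raises(ValueError):
            simulate_timeseries(z, 60)

    def test_spikes_raise_framewise_displacement(self):
        from fcaging.pipeline import framewise_displacement

        z = np.zeros((5, 5))
        quiet = simulate_timeseries(z, 400, motion=MotionModel(0.05, 0.0), seed=13)
        spiky = simulate_timeseries(z, 400, motion=MotionModel(0.05, 0.05, 1.0), seed=13)
        assert framewise_displacement(spiky.motion).max() > framewise_displacement(quiet.motion).max()


def _srtm_ode_frame_means(dvr, r1, k2, ref, schedule):
    """Independent oracle: integrate the SRTM ODE numerically."""
    k2a = k2 / dvr
    a, lu, lw = ref.amplitude, ref.uptake, ref.washout
    c_ref = lambda t: a * (np.exp(-lw * t) - np.exp(-lu * t))
    dc_ref = lambda t: a * (-lw * np.exp(-lw * t) + lu * np.exp(-lu * t))
    sol = solve_ivp(
        lambda t, y: [r1 * dc_ref(t) + k2 * c_ref(t) - k2a * y[0]],
        (0, schedule.total_minutes),
        [0.0],
        dense_output=True,
        rtol=1e-10,
        atol=1e-12,
    )
    out = []
    for t0, t1 in zip(schedule.start, schedule.end):
        grid = np.linspace(t0, t1, 2001)
        out.append(np.trapezoid(sol.sol(grid)[0], grid) / (t1 - t0))
    return np.array(out)


class TestSimulateTac:
    def test_unit_dvr_r1_one_gives_identical_curves(self):
        tac, ref = simulate_tac(1.0, r1=1.0, k2=0.15)
        assert np.allclose(tac.activity, ref.activity, rtol=1e-10)

    def test_noiseless_matches_ode_oracle(self):
        refc = ReferenceCurve()
        sched = logan.default_schedule()
        tac, _ = simulate_tac(2.5, r1=1.0, k2=0.15, reference=refc, schedule=sched)
        oracle = _srtm_ode_frame_means(2.5, 1.0, 0.15, refc, sched)
        assert np.allclose(tac.activity, oracle, rtol=1e-5)

    def test_short_schedule_rejected(self):
        sched = logan.FrameSchedule(np.array([0.0, 5.0]), np.array([5.0, 5.0]))
        with pytest.raises(ValueError):
            simulate_tac(1.5, schedule=sched)

    def test_noise_is_seeded(self):
        a, _ = simulate_tac(2.0, noise=0.05, seed=3)
        b, _ = simulate_tac(2.0, noise=0.05, seed=3)
        c, _ = simulate_tac(2.0, noise=0.05, seed=4)
        assert np.array_equal(a.activity, b.activity)
        assert not np.array_equal(a.activity, c.activity)


class TestSimulateGmd:
    def test_zero_slopes_equal_group_means(self, default_cohort):
        truth = synthetic.sample_node_truth(
            5,
            EffectConfig(gmd_beta_mu_mean=0.0, gmd_beta_mu_sd=0.0, gmd_coupling_mu=0.0),
            seed=1,
        )
        vals = simulate_gmd(default_cohort, truth, seed=2)
        young = np.array([r.group == "younger" for r in default_cohort])
        diff = vals[young].mean() - vals[~young].mean()
        assert abs(diff) < 0.05  # sampling error only

    def test_negative_slope_shifts_older_group(self):
        cohort = make_cohort(CohortSpec(n_young=2000, n_old=2000, seed=3))
        truth = synthetic.sample_node_truth(
            3,
            EffectConfig(
                gmd_beta_mu_mean=-0.003, gmd_beta_mu_sd=0.0, gmd_coupling_mu=0.0,
                gmd_alpha_sigma_sd=0.0,
            ),
            seed=4,
        )
        vals = simulate_gmd(cohort, truth, seed=5)
        young = np.array([r.group == "younger" for r in cohort])
        d_age = np.mean([r.age for r in cohort if r.group == "older"]) - np.mean(
            [r.age for r in cohort if r.group == "younger"]
        )
        diff = vals[~young].mean() - vals[young].mean()
        assert abs(diff - (-0.003 * d_age)) < 0.01

    def test_seeded_determinism(self, default_cohort):
        truth = synthetic.sample_node_truth(4, seed=6)
        assert np.array_equal(
            simulate_gmd(default_cohort, truth, seed=7),
            simulate_gmd(default_cohort, truth, seed=7),
        )
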