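"""Synthetic IPD and utility generation, and the state-mean estimator."""

import numpy as np
import pandas as pd
import pytest

from durvacea.simulate import (
    SimConfig,
    SimulationError,
    estimate_state_utilities,
    sample_survival_times,
    simulate_ipd,
    simulate_utilities,
)
from durvacea.survival import SurvivalCurve, survival

from .conftest import PPS, PUBLISHED_CURVES


def sim_config(**kw):
    base = dict(
        n_patients=500,
        ttp=SurvivalCurve("exponential", (0.10,)),
        pfs=SurvivalCurve("exponential", (0.13,)),
        pps=SurvivalCurve("exponential", (0.08,)),
        censor_time=48.0,
        seed=5,
    )
    base.update(kw)
    return SimConfig(**base)


class TestSimulateIpd:
    def test_same_seed_identical_datasets(self):
        r1, p1 = simulate_ipd(sim_config())
        r2, p2 = simulate_ipd(sim_config())
        for role in ("ttp", "pfs", "pps"):
            assert [(x.time, x.event) for x in r1[role]] == [
                (x.time, x.event) for x in r2[role]
            ]
        pd.testing.assert_frame_equal(p1, p2)

    def test_tiny_censor_time_censors_everything(self):
        recs, _ = simulate_ipd(sim_config(censor_time=0.001))
        assert all(r.event == 0 for r in recs["pfs"])

    def test_km_of_simulated_pfs_matches_curve(self):
        # empirical exit-time distribution vs the target PFS survival
        cfg = sim_config(n_patients=5000, censor_time=1e6, seed=11)
        recs, _ = simulate_ipd(cfg)
        times = np.sort([r.time for r in recs["pfs"]])
        s_emp = 1.0 - np.arange(1, len(times) + 1) / len(times)
        s_true = np.atleast_1d(survival(cfg.pfs, times))
        assert np.max(np.abs(s_emp - s_true)) < 0.03

    def test_published_curves_accepted_and_pps_from_progression(self):
        cfg = sim_config(
            n_patients=300,
            ttp=PUBLISHED_CURVES["bsc"]["ttp"],
            pfs=PUBLISHED_CURVES["bsc"]["pfs"],
            pps=PPS,
            censor_time=60.0,
        )
        recs, patients = simulate_ipd(cfg)
        assert len(recs["pps"]) > 0
        assert all(r.time <= 60.0 for r in recs["pps"])

    def test_inconsistent_curves_rejected(self):
        # PFS survival above TTP survival implies a negative death hazard
        bad = sim_config(
            ttp=SurvivalCurve("exponential", (0.2,)),
            pfs=SurvivalCurve("exponential", (0.1,)),
        )
        with pytest.raises(SimulationError, match="t ="):
            simulate_ipd(bad)

    def test_inverse_cdf_sampler_is_calibrated(self):
        rng = np.random.default_rng(3)
        t = sample_survival_times(PPS, 20_000, rng)
        # median of draws near the analytic median e^mu
        assert np.median(t) == pytest.approx(np.exp(3.0448), rel=0.05)


class TestUtilities:
    def test_zero_noise_reproduces_state_means_exactly(self):
        cfg = sim_config(sd_between=0.0, sd_residual=0.0)
        _, patients = simulate_ipd(cfg)
        obs = simulate_utilities(cfg, patients)
        assert set(obs.state) == {"PF", "PD"}
        assert (obs.loc[obs.state == "PF", "value"] == 0.901).all()
        assert (obs.loc[obs.state == "PD", "value"] == 0.863).all()

    def test_patient_without_progression_has_no_pd_observations(self):
        cfg = sim_config()
        _, patients = simulate_ipd(cfg)
        obs = simulate_utilities(cfg, patients)
        never_progressed = patients.loc[~np.isfinite(patients.t_prog), "patient"]
        pd_patients = set(obs.loc[obs.state == "PD", "patient"])
        assert pd_patients.isdisjoint(set(never_progressed))

    def test_observation_times_within_followup(self):
        cfg = sim_config()
        _, patients = simulate_ipd(cfg)
        obs = simulate_utilities(cfg, patients)
        merged = obs.merge(patients, on="patient")
        assert (merged.time <= np.minimum(merged.t_death, merged.censor) + 1e-9).all()


class TestEstimator:
    def test_zero_noise_exact_recovery(self):
        cfg = sim_config(sd_between=0.0, sd_residual=0.0)
        _, patients = simulate_ipd(cfg)
        obs = simulate_utilities(cfg, patients)
        est = estimate_state_utilities(obs)
        assert est.mean_pf == pytest.approx(0.901, abs=1e-12)
        assert est.mean_pd == pytest.approx(0.863, abs=1e-12)

    def test_noisy_recovery_within_three_se(self):
        cfg = sim_config(n_patients=2000, sd_between=0.05, sd_residual=0.05, seed=21)
        _, patients = simulate_ipd(cfg)
        obs = simulate_utilities(cfg, patients)
        est = estimate_state_utilities(obs)
        assert abs(est.mean_pf - 0.901) < 3 * est.se_pf
        assert abs(est.mean_pd - 0.863) < 3 * est.se_pd

    def test_balanced_toy_matches_hand_computed_means(self):
        obs = pd.DataFrame(
            {
                "patient": [0, 0, 1, 1],
                "time": [1.0, 2.0, 1.0, 2.0],
                "state": ["PF", "PD", "PF", "PD"],
                "value": [0.92, 0.88, 0.90, 0.84],
            }
        )
        est = estimate_state_utilities(obs)
        assert est.mean_pf == pytest.approx((0.92 + 0.90) / 2, abs=1e-6)
        assert est.mean_pd == pytest.approx((0.88 + 0.84) / 2, abs=1e-6)

    def test_invariant_to_patient_relabelling(self):
        cfg = sim_config(n_patients=200, seed=9)
        _, patients = simulate_ipd(cfg)
        obs = simulate_utilities(cfg, patients)
        relabelled = obs.copy()
        relabelled["patient"] = relabelled["patient"].max() - relabelled["patient"]
        a = estimate_state_utilities(obs)
        b = estimate_state_utilities(relabelled)
        assert a.mean_pf == pytest.approx(b.mean_pf, abs=1e-8)
        assert a.mean_pd == pytest.approx(b.mean_pd, abs=1e-8)

    def test_single_state_reported_inestimable(self):
        obs = pd.DataFrame(
            {
                "patient": [0, 1, 0, 1],
                "time": [1, 1, 2, 2],
                "state": ["PF"] * 4,
                "value": [0.9, 0.91, 0.89, 0.9],
            }
        )
        est = estimate_state_utilities(obs)
        assert est.mean_pd is None
        assert est.mean_pf is not None


def test_config_validation():
    with pytest.raises(SimulationError):
        SimConfig(n_patients=0)
    with pytest.raises(SimulationError):
        sim_config(censor_time=-1.0)
    with pytest.raises(SimulationError):
        sim_config(sd_between=-0.1)


def test_end_to_end_simulate_fit_run_recovers_outcomes():
    """Simulated IPD, refit by AIC selection, must reproduce the pipeline's
    discounted outcomes from the generating curves within 5%."""
    from durvacea.cohort import ArmSpec, CycleGrid, run_cohort
    from durvacea.survival import FAMILIES, fit_parametric, select_best

    from .conftest import make_arm

    arm = make_arm("bsc")
    cfg = SimConfig(
        n_patients=2000, ttp=arm.ttp, pfs=arm.pfs, pps=arm.pps,
        censor_time=60.0, seed=0,
    )
    recs, _ = simulate_ipd(cfg)
    fitted = {}
    for role in ("ttp", "pfs", "pps"):
        fits = [fit_parametric(recs[role], fam) for fam in FAMILIES]
        fitted[role] = select_best(fits, "aic").curve
    grid = CycleGrid.build()
    _, e_true = run_cohort(arm, grid)
    arm_fit = ArmSpec(
        "bsc_refit", fitted["ttp"], fitted["pfs"], fitted["pps"], 0.901, 0.863
    )
    _, e_fit = run_cohort(arm_fit, grid)
    assert e_fit.ly_total == pytest.approx(e_true.ly_total, rel=0.05)
    assert e_fit.qaly_total == pytest.approx(e_true.qaly_total, rel=0.05)
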