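import numpy as np
import pandas as pd
import pytest

from hrvguide.decision import FULL, RECOVERY, REDUCED
from hrvguide.simulate import (ArmOutcome, OutcomeSpec, TrialConfig,
                               build_timeline, generate_outcomes,
                               null_decision_fractions,
                               null_decision_probabilities,
                               simulate_participant, simulate_trial)


class TestTimeline:
    def test_default_structure(self):
        days = build_timeline(TrialConfig())
        assert len(days) == 77  # 11 weeks
        assert sum(d.training for d in days) == 30
        assert sum(d.training and d.block == 1 for d in days) == 15
        assert sum(d.training and d.block == 2 for d in days) == 15
        phases = [d.phase for d in days[::7]]
        assert phases == ["baseline", "baseline", "pretest", "block", "block",
                          "block", "recalibration", "block", "block", "block",
                          "posttest"]

    def test_weekend_rest_pattern(self):
        days = build_timeline(TrialConfig())
        assert all(not d.training for d in days if d.date.weekday() >= 5)

    def test_block_starts_marked_once(self):
        days = build_timeline(TrialConfig())
        starts = [d for d in days if d.block_start]
        assert [d.block for d in starts] == [1, 2]


class TestSimulateParticipant:
    def test_deterministic_given_seed(self):
        cfg = TrialConfig(n_per_arm=2, seed=5)
        a = simulate_participant("G01", "guided", cfg, 123)
        b = simulate_participant("G01", "guided", cfg, 123)
        assert [r.hrv_daily for r in a[0]] == [r.hrv_daily for r in b[0]]
        assert a[1] == b[1]

    def test_noise_free_null_all_full(self):
        cfg = TrialConfig(daily_sd=0.0, stress_delta_full=0.0,
                          hrv_compliance_prob=1.0)
        readings, sessions, truth = simulate_participant("G01", "guided", cfg, 9)
        assert all(r.hrv_daily == pytest.approx(truth["mu"]) for r in readings)
        assert all(s["decision"] == FULL for s in sessions)

    def test_guided_noise_free_dhi_equals_attended(self):
        cfg = TrialConfig(daily_sd=0.0, stress_delta_full=0.0)
        _, sessions, _ = simulate_participant("G01", "guided", cfg, 10)
        assert sum(s["dhi"] for s in sessions) == sum(s["attended"] for s in sessions)

    def test_unknown_arm_rejected(self):
        with pytest.raises(ValueError):
            simulate_participant("X", "placebo", TrialConfig(), 0)


class TestSimulateTrial:
    def test_reproducible_bit_for_bit(self):
        cfg = TrialConfig(n_per_arm=3, seed=77)
        a, b = simulate_trial(cfg), simulate_trial(cfg)
        pd.testing.assert_frame_equal(a.daily_log, b.daily_log)
        pd.testing.assert_frame_equal(a.session_log, b.session_log)
        pd.testing.assert_frame_equal(a.outcomes, b.outcomes)

    def test_predetermined_never_modulated(self, small_trial):
        pre = small_trial.session_log.query("arm == 'predetermined'")
        assert set(pre["decision"]) == {"NA"}
        assert (pre["volume_multiplier"] == 1.0).all()

    def test_predetermined_dhi_equals_attended(self, small_trial):
        pre = small_trial.session_log.query("arm == 'predetermined'")
        assert (pre["dhi"] == pre["attended"]).all()

    def test_full_adherence_predetermined_dhi_is_30(self):
        ds = simulate_trial(TrialConfig(n_per_arm=2, seed=8, adherence_prob=1.0))
        dhi = (ds.session_log.query("arm == 'predetermined'")
               .groupby("participant_id")["dhi"].sum())
        assert (dhi == 30).all()

    def test_conservation_per_participant(self, small_trial):
        log = small_trial.session_log
        for _, grp in log.groupby("participant_id"):
            attended = grp[grp["attended"]]
            counts = attended["decision"].isin([FULL, REDUCED, RECOVERY, "NA"]).sum()
            missed = (~grp["attended"]).sum()
            assert counts + missed == grp["scheduled"].sum()

    def test_guided_decisions_defined_every_training_day(self, small_trial):
        guided = small_trial.session_log.query("arm == 'guided'")
        assert guided["decision"].isin([FULL, REDUCED, RECOVERY]).all()

    def test_recalibration_produces_two_profiles_per_guided(self, small_trial):
        counts = small_trial.profiles.groupby("participant_id")["block"].count()
        assert (counts == 2).all()
        assert set(small_trial.profiles["block"]) == {1, 2}

    def test_baseline_recovery_within_sampling_error(self, small_trial):
        """Calibration on the simulated baseline recovers each mu_i to 3 sigma/sqrt(n)."""
        truth = {t["participant_id"]: t["mu"]
                 for t in small_trial.truth["participants"]}
        cfg = small_trial.config
        block1 = small_trial.profiles.query("block == 1")
        for _, row in block1.iterrows():
            tol = 3 * cfg.daily_sd / np.sqrt(row["n_days"])
            assert abs(row["mean"] - truth[row["participant_id"]]) < tol

    def test_dhi_monotone_in_stress_delta(self):
        """Stronger stress accumulation cannot raise guided-arm DHI (common seeds)."""
        means = []
        for delta in (0.0, 0.15, 0.40):
            cfg = TrialConfig(n_per_arm=6, seed=99, stress_delta_full=delta)
            ds = simulate_trial(cfg)
            means.append(ds.session_log.query("arm == 'guided'")["dhi"].mean())
        assert means[0] >= means[1] >= means[2]

    def test_day_to_day_cv_in_configured_band(self, null_trial):
        """Default daily noise puts the day-to-day CV of the score near 9-10%."""
        from hrvguide.hrv import cv_of_hrv
        cvs = []
        for _, grp in null_trial.daily_log.groupby("participant_id"):
            scores = grp.sort_values("date")["hrv_daily"].to_numpy()
            cvs.append(cv_of_hrv(scores, window_days=len(scores)))
        assert 7.0 < np.mean(cvs) < 12.0


class TestNullDecisionFractions:
    def test_closed_form_probabilities(self):
        p = null_decision_probabilities()
        assert p[FULL] == pytest.approx(0.814, abs=5e-4)
        assert p[RECOVERY] == pytest.approx(0.0081, abs=5e-4)
        assert sum(p.values()) == pytest.approx(1.0)

    def test_monte_carlo_matches_closed_form(self):
        n = 20000
        frac = null_decision_fractions(n, seed=31)
        p = null_decision_probabilities()
        for tier in (FULL, REDUCED, RECOVERY):
            se = np.sqrt(p[tier] * (1 - p[tier]) / n)
            assert abs(frac[tier] - p[tier]) < 3 * se

    def test_simulated_trial_null_full_fraction_matches_estimated_baseline_oracle(self):
        """Inside a trial the baseline is *estimated* from 14 days, so the
        FULL fraction sits below the known-parameter closed form. Compare the
        pooled trial fractions against an independent Monte-Carlo oracle of
        the estimated-baseline null: deviation = (7-day mean) - (14-day mean),
        threshold from the sampled 14-day SD. Baseline error is shared across
        a participant-block's decisions, so the effective sample size is
        participants x blocks."""
        mu, sigma = 8.5, 0.8
        rng = np.random.default_rng(7)
        m = 200_000
        base_mean = rng.normal(mu, sigma / np.sqrt(14), m)
        sd_hat = sigma * np.sqrt(rng.chisquare(13, m) / 13)
        win_mean = rng.normal(mu, sigma / np.sqrt(7), m)
        dev = np.abs(win_mean - base_mean)
        oracle_full = np.mean(dev <= 0.5 * sd_hat)

        n_arm = 40
        cfg = TrialConfig.null(n_per_arm=n_arm, seed=12, adherence_prob=1.0,
                               hrv_compliance_prob=1.0, baseline_mean_mean=mu,
                               daily_sd=sigma)
        ds = simulate_trial(cfg)
        guided = ds.session_log.query("arm == 'guided'")
        observed = (guided["decision"] == FULL).mean()
        n_eff = n_arm * cfg.n_blocks
        se = np.sqrt(oracle_full * (1 - oracle_full) / n_eff)
        assert abs(observed - oracle_full) < 3 * se


class TestGenerateOutcomes:
    def test_zero_change_perfect_retest_post_equals_pre(self):
        spec = OutcomeSpec("x", ArmOutcome(100.0, 10.0, 100.0),
                           ArmOutcome(100.0, 10.0, 100.0), retest_r=1.0)
        cfg = TrialConfig(n_per_arm=5, outcomes=(spec,))
        participants = pd.DataFrame({"participant_id": ["a", "b"],
                                     "arm": ["guided", "predetermined"]})
        out = generate_outcomes(cfg, participants, np.random.default_rng(0))
        assert np.allclose(out["pre"], out["post"])

    def test_reproducible(self):
        cfg = TrialConfig(n_per_arm=3)
        participants = pd.DataFrame({"participant_id": ["a"], "arm": ["guided"]})
        a = generate_outcomes(cfg, participants, np.random.default_rng(42))
        b = generate_outcomes(cfg, participants, np.random.default_rng(42))
        pd.testing.assert_frame_equal(a, b)

    def test_configured_change_recovered_at_large_n(self):
        spec = OutcomeSpec("x", ArmOutcome(100.0, 10.0, 106.0),
                           ArmOutcome(100.0, 10.0, 106.0))
        cfg = TrialConfig(n_per_arm=1000, outcomes=(spec,))
        participants = pd.DataFrame({
            "participant_id": [f"p{i}" for i in range(2000)],
            "arm": ["guided"] * 1000 + ["predetermined"] * 1000})
        out = generate_outcomes(cfg, participants, np.random.default_rng(3))
        for _, grp in out.groupby("arm"):
            pooled = np.sqrt((grp["pre"].std(ddof=1) ** 2
                              + grp["post"].std(ddof=1) ** 2) / 2)
            d = (grp["post"].mean() - grp["pre"].mean()) / pooled
            assert 0.55 < d < 0.65
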