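"""Generator ground truth, determinism, artifacts, cohort coupling."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats as sp_stats

from motionerp import (
    CohortSpec,
    ComponentParams,
    ConditionSpec,
    NoiseProfile,
    SubjectSpec,
    default_conditions,
    generate_cohort,
    generate_subject,
    inject_artifacts,
)
from motionerp.errors import ConfigError
from motionerp.synth import DEFAULT_BETWEEN_SDS, raised_cosine

from conftest import quiet_profile, zero_noise_conditions


class TestSpecs:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigError):
            ConditionSpec("x", n_trials=0)
        with pytest.raises(ConfigError):
            ConditionSpec("x", isi_range=(6.0, 2.0))
        with pytest.raises(ConfigError):
            NoiseProfile(artifact_fraction=1.5)
        with pytest.raises(ConfigError):
            CohortSpec(n_subjects=1)

    def test_overlapping_isi_rejected_at_generation(self):
        cond = ConditionSpec("x", n_trials=2, isi_range=(1.0, 1.2))
        with pytest.raises(ConfigError, match="overlap"):
            generate_subject(SubjectSpec("S", seed=0), [cond])


class TestGenerateSubject:
    def test_zero_noise_bump_at_exact_latency(self, zero_noise_subject, montage):
        """With all SDs zero the N2 template peak sits at the drawn latency
        on the peak channel, trial for trial."""
        rec, gt = zero_noise_subject
        ipo8 = rec.channel_index("PO8")
        fast = gt.trials[gt.trials["condition"] == "fast"]
        for row in fast.head(5).itertuples():
            seg = rec.data[ipo8, row.stimulus_sample + 120:
                           row.stimulus_sample + 260]
            assert np.argmin(seg) + 120 == round(row.N2_latency)

    def test_button_press_identity_every_trial(self, small_noisy_subject):
        _, gt = small_noisy_subject
        assert np.allclose(
            gt.trials["button_press_ms"],
            gt.trials["emg_onset_ms"] + gt.trials["motor_time_ms"],
        )

    def test_channel_layout(self, small_noisy_subject):
        rec, _ = small_noisy_subject
        assert len(rec.channel_labels) == 65
        assert rec.channel_kinds.count("eeg") == 63
        assert rec.channel_labels[-2:] == ("EOG", "EMG")
        assert rec.srate == 1000.0

    def test_condition_means_match_spec_within_3_sem(self):
        conds = [replace(c, n_trials=80) for c in default_conditions()]
        _, gt = generate_subject(SubjectSpec("M", seed=33), conds)
        for cond in conds:
            g = gt.trials[gt.trials["condition"] == cond.name]
            for col, (mean, sd) in (
                ("emg_onset_ms", cond.emg_delay),
                ("motor_time_ms", cond.motor_time),
            ):
                sem = sd / np.sqrt(len(g)) if sd else 1e-9
                assert abs(g[col].mean() - mean) < 3 * max(sem, 1e-9)

    def test_seed_determinism_bit_identical(self):
        conds = [replace(c, n_trials=6) for c in default_conditions()
                 if c.name == "fast"]
        spec = SubjectSpec("D", seed=99)
        r1, g1 = generate_subject(spec, conds)
        r2, g2 = generate_subject(spec, conds)
        assert np.array_equal(r1.data, r2.data)
        assert g1.trials.equals(g2.trials)
        assert [(e.sample, e.label) for e in r1.events] == [
            (e.sample, e.label) for e in r2.events]

    def test_isi_uniformity(self):
        """Drawn ISIs pass a uniformity test on [2, 6] s at n = 10,000."""
        rng = np.random.default_rng(0)
        from motionerp.synth import _draw_trial_times

        cond = ConditionSpec("u", n_trials=10000)
        samples, _ = _draw_trial_times(rng, cond, 1000.0, 0.0)
        isis = np.diff(samples) / 1000.0
        stat, p = sp_stats.kstest(isis, "uniform", args=(2.0, 4.0))
        assert p > 0.01


class TestInjectArtifacts:
    def test_zero_rates_identity(self, small_noisy_subject):
        rec, _ = small_noisy_subject
        out, log = inject_artifacts(rec, quiet_profile(), 0)
        assert out.data is rec.data or np.array_equal(out.data, rec.data)
        assert log["artifact_trials"] == [] and log["blink_trials"] == []

    def test_artifact_bookkeeping_exact(self):
        """The log lists exactly the injected artifact trials, and the
        downstream rejection flags exactly those trials."""
        from motionerp import PipelineConfig, run_subject

        conds = zero_noise_conditions(("fast",))
        prof = NoiseProfile(broadband_sd=0.0, blink_rate=0.0,
                            artifact_fraction=4 / 80)
        spec = SubjectSpec("A", noise_profile=prof, seed=5)
        rec, gt = generate_subject(spec, conds)
        injected = sorted(gt.trials.loc[gt.trials["artifact"], "trial_id"])
        assert len(injected) == 4
        cfg = PipelineConfig()
        cfg.csd.bypass = True
        res = run_subject(rec, cfg)
        flagged = sorted(
            res.trials.loc[
                res.trials["exclusion_reasons"].str.contains("eeg_artifact"),
                "trial_id",
            ]
        )
        assert flagged == injected

    def test_step_artifact_triggers_rejection(self, montage):
        """An injected 60 uV step between adjacent samples is caught by the
        >50 uV step criterion."""
        from motionerp.preprocess import reject_artifacts, segment
        from motionerp.io import Event, EventList, Recording

        data = np.zeros((2, 5000))
        data[0, 2100:2180] += 60.0          # step at +100 ms
        rec = Recording(data=data, srate=1000.0,
                        channel_labels=("PO7", "PO8"),
                        channel_kinds=("eeg", "eeg"),
                        events=EventList([Event(2000, "stimulus", "fast")]))
        ep = segment(rec)
        ep, _ = reject_artifacts(ep)
        assert ep.flagged(["eeg_artifact"]).tolist() == [True]


class TestCohort:
    def test_deterministic_coupling_corr_one(self):
        spec = CohortSpec(
            n_subjects=12, coupling=(0.0, 1.0, 0.0, 0.0),
            between_subject_sds={"N2r": 0.0}, master_seed=3,
        )
        cohort = generate_cohort(spec)
        g = cohort.subject_truths.query("condition == 'fast'")
        r = np.corrcoef(g["N2_latency"], g["emg_onset"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_generating_r2_recovered(self):
        """Closed-form generating R^2 vs empirical fit on true values."""
        b, c = 0.7, -0.9
        sd_n2, sd_n2r = DEFAULT_BETWEEN_SDS["N2"], DEFAULT_BETWEEN_SDS["N2r"]
        sig = b**2 * sd_n2**2 + c**2 * sd_n2r**2
        resid_sd = np.sqrt(sig * 0.15 / 0.85)
        r2s = []
        import statsmodels.api as sm

        for seed in range(60):
            cohort = generate_cohort(CohortSpec(
                n_subjects=37, coupling=(0.0, b, c, resid_sd),
                master_seed=seed))
            g = cohort.subject_truths.query("condition == 'fast'")
            X = sm.add_constant(g[["N2_latency", "N2r_latency"]])
            r2s.append(sm.OLS(g["emg_onset"], X).fit().rsquared)
        assert abs(np.mean(r2s) - 0.85) < 0.03

    def test_master_seed_reproducible(self):
        a = generate_cohort(CohortSpec(n_subjects=5, master_seed=7))
        b = generate_cohort(CohortSpec(n_subjects=5, master_seed=7))
        assert a.subject_truths.equals(b.subject_truths)
        assert [s.seed for s in a.subjects] == [s.seed for s in b.subjects]

    def test_degenerate_cohort_warns(self):
        sds = {k: 0.0 for k in DEFAULT_BETWEEN_SDS}
        with pytest.warns(UserWarning, match="degenerate"):
            generate_cohort(CohortSpec(
                n_subjects=3, coupling=(0.0, 1.0, 0.0, 0.0),
                between_subject_sds=sds))


class TestTemplates:
    def test_raised_cosine_analytic_maximum(self):
        t = np.linspace(0, 400, 4001)
        bump = raised_cosine(t, 187.0, 120.0)
        assert t[np.argmax(bump)] == pytest.approx(187.0, abs=0.1)
        assert bump.max() == pytest.approx(1.0)
        assert bump[t < 127.0].max() == 0.0
        assert bump[t > 247.1].max() == 0.0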