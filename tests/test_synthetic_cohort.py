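"""Generator invariants: determinism, calibration means, degenerate limits."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evseg.config import (
    AnxietyParams,
    BoundaryParams,
    GeneratorConfig,
    PCLParams,
    PressParams,
    RecallParams,
    VideoSpec,
)
from evseg.segmentation import bin_presses
from evseg.synthetic_cohort import (
    Condition,
    Group,
    SubjectRecord,
    generate_anxiety,
    generate_cohort,
    generate_press_log,
    generate_recall,
    generate_subjects,
    generate_video_truth,
)


def _subject(ability=0.5, group=Group.CONTROL, pcl=20):
    return SubjectRecord("sX", group, pcl, ability, "trauma_first")


class TestSubjects:
    def test_group_sizes_and_invariants(self, default_config):
        subs = generate_subjects(default_config)
        assert len(subs) == 127
        assert sum(s.group is Group.PTSD for s in subs) == 63
        assert all(17 <= s.pcl_total <= 85 for s in subs)
        assert all(0 < s.ability < 1 for s in subs)

    def test_pcl_group_means_match_calibration(self):
        """Sample PCL means land on 54.60 / 20.81 within Monte-Carlo error."""
        means_p, means_c = [], []
        for seed in range(40):
            subs = generate_subjects(GeneratorConfig(seed=seed))
            df = pd.DataFrame([(s.group.value, s.pcl_total) for s in subs],
                              columns=["group", "pcl"])
            g = df.groupby("group")["pcl"].mean()
            means_p.append(g["PTSD"])
            means_c.append(g["CONTROL"])
        # MC error of the mean over 40 cohorts: ~13.7/sqrt(63*40) ~ 0.27
        assert np.mean(means_p) == pytest.approx(54.60, abs=0.8)
        assert np.mean(means_c) == pytest.approx(20.81, abs=0.5)

    def test_zero_pcl_variance_collapses_scores(self):
        cfg = GeneratorConfig(
            seed=3,
            pcl_ptsd=PCLParams(mu=55, sigma=0),
            pcl_control=PCLParams(mu=21, sigma=0),
        )
        subs = generate_subjects(cfg)
        assert {s.pcl_total for s in subs if s.group is Group.PTSD} == {55}
        assert {s.pcl_total for s in subs if s.group is Group.CONTROL} == {21}

    def test_severity_lowers_ability_on_average(self, default_config):
        subs = generate_subjects(default_config)
        ab_p = np.mean([s.ability for s in subs if s.group is Group.PTSD])
        ab_c = np.mean([s.ability for s in subs if s.group is Group.CONTROL])
        assert ab_p < ab_c

    def test_session_order_counterbalanced(self, default_config):
        subs = generate_subjects(default_config)
        orders = [s.session_order for s in subs]
        assert abs(orders.count("trauma_first") - orders.count("positive_first")) <= 1

    def test_invalid_group_sizes_rejected(self):
        with pytest.raises(ValueError, match="group sizes"):
            GeneratorConfig(n_ptsd=0)


class TestVideoTruth:
    def test_renewal_expectation(self, default_config):
        """Boundary count concentrates near duration / mean_gap."""
        counts = [
            len(generate_video_truth("v", 329, default_config, seed=s).boundary_times)
            for s in range(200)
        ]
        expected = 329 / default_config.boundary.mean_gap_s
        assert np.mean(counts) == pytest.approx(expected, rel=0.1)

    def test_fixed_seed_reproducible(self, default_config):
        t1 = generate_video_truth("v", 300, default_config, seed=9)
        t2 = generate_video_truth("v", 300, default_config, seed=9)
        assert np.array_equal(t1.boundary_times, t2.boundary_times)
        assert np.array_equal(t1.salience, t2.salience)

    def test_salience_support(self, default_config):
        """Beta-drawn salience stays in (0, 1] over many draws."""
        sal = np.concatenate(
            [
                generate_video_truth("v", 400, default_config, seed=s).salience
                for s in range(250)
            ]
        )
        assert len(sal) > 10_000
        assert np.all(sal > 0) and np.all(sal <= 1)

    def test_gap_longer_than_video_can_yield_empty(self):
        cfg = GeneratorConfig(boundary=BoundaryParams(mean_gap_s=500.0))
        counts = [
            len(generate_video_truth("v", 60, cfg, seed=s).boundary_times)
            for s in range(30)
        ]
        assert min(counts) == 0  # empty boundary list is permitted


class TestPressLog:
    def test_noiseless_limit_reproduces_boundaries(self, default_config):
        cfg = dataclasses.replace(
            default_config,
            press=PressParams(jitter_sd_s=0.0, false_alarm_rate=0.0),
        )
        truth = generate_video_truth("v", 300, cfg, seed=2)
        subj = _subject(ability=1 - 1e-9)
        log = generate_press_log(subj, truth, Condition.POSITIVE, cfg, seed=4)
        assert np.allclose(np.sort(truth.boundary_times), log.press_times_s)

    def test_zero_ability_yields_poisson_false_alarms(self, default_config):
        cfg = dataclasses.replace(
            default_config, press=PressParams(false_alarm_rate=0.1)
        )
        truth = generate_video_truth("v", 300, cfg, seed=2)
        subj = _subject(ability=1e-9)
        counts = [
            len(generate_press_log(subj, truth, Condition.POSITIVE, cfg, seed=s).press_times_s)
            for s in range(300)
        ]
        assert np.mean(counts) == pytest.approx(0.1 * 300, rel=0.1)

    def test_high_ability_overlaps_truth_more(self, default_config):
        """Binned overlap with true boundary bins increases with ability."""
        truth = generate_video_truth("v", 300, default_config, seed=2)
        true_bins = set(truth.boundary_times.astype(int))
        overlaps = {}
        for ability in (0.1, 0.9):
            subj = _subject(ability=ability)
            log = generate_press_log(subj, truth, Condition.POSITIVE, default_config, seed=7)
            marked = set(np.flatnonzero(bin_presses(log, 300).indicator))
            overlaps[ability] = len(marked & true_bins)
        assert overlaps[0.9] > overlaps[0.1]

    def test_press_times_sorted_and_in_range(self, default_cohort):
        t = default_cohort.press_log.groupby(["subject_id", "video_id"])["time_s"]
        assert (t.apply(lambda s: s.is_monotonic_increasing)).all()
        durations = default_cohort.durations
        for vid, grp in default_cohort.press_log.groupby("video_id"):
            assert grp["time_s"].between(0, durations[vid]).all()


class TestRecall:
    def test_logistic_midpoint(self, default_config):
        cfg = dataclasses.replace(
            default_config,
            recall=RecallParams(
                intercept=0.0, agreement_slope=0.0, group_offset=0.0,
                severity_offset=0.0, condition_offset=0.0,
                subject_noise_sd=0.0, n_units_total=40,
            ),
        )
        props = [
            generate_recall(_subject(), 0.6, "v", Condition.POSITIVE, cfg, seed=s).n_recalled / 40
            for s in range(200)
        ]
        assert np.mean(props) == pytest.approx(0.5, abs=0.02)

    def test_group_deficit_sign_over_seeds(self, default_config):
        """Strongly negative group offset lowers PTSD recall on every seed."""
        cfg = dataclasses.replace(
            default_config,
            recall=dataclasses.replace(default_config.recall, group_offset=-2.0),
        )
        for seed in range(20):
            p = generate_recall(
                _subject(group=Group.PTSD, pcl=38), 0.6, "v", Condition.POSITIVE, cfg, seed=seed
            )
            c = generate_recall(
                _subject(group=Group.CONTROL, pcl=38), 0.6, "v", Condition.POSITIVE, cfg, seed=seed
            )
            assert p.n_recalled < c.n_recalled

    def test_missing_agreement_falls_back_to_midpoint(self, default_config):
        r = generate_recall(_subject(), float("nan"), "v", Condition.POSITIVE,
                            default_config, seed=1)
        assert 0 <= r.n_recalled <= r.n_units_total


class TestAnxiety:
    def test_deterministic_when_noiseless(self, default_config):
        cfg = dataclasses.replace(
            default_config,
            anxiety=AnxietyParams(
                baseline=2.0, group_effect=0.0, condition_effect=0.0,
                interaction=0.0, subject_sd=0.0, residual_sd=0.0,
            ),
        )
        recs = generate_anxiety(_subject(), Condition.TRAUMATIC, cfg, seed=1)
        assert len(recs) == 11
        assert all(r.rating == 2.0 for r in recs)

    def test_ratings_clipped_to_scale(self, default_cohort):
        assert default_cohort.anxiety["rating"].between(1, 10).all()
        assert (default_cohort.anxiety.groupby(["subject_id", "condition"]).size() == 11).all()


class TestCohortAssembly:
    def test_same_seed_identical_tables(self, small_config):
        a = generate_cohort(small_config, score=True)
        b = generate_cohort(small_config, score=True)
        for name in ("subjects", "press_log", "agreement", "recall", "anxiety"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))

    def test_different_seed_differs(self, small_config):
        a = generate_cohort(small_config, score=False)
        b = generate_cohort(dataclasses.replace(small_config, seed=99), score=False)
        assert not a.press_log.equals(b.press_log)

    def test_conditions_counterbalanced_within_subject(self, small_cohort):
        per_subject = small_cohort.roster.groupby("subject_id")["condition"].nunique()
        assert (per_subject == 2).all()

    def test_agreement_monotone_in_ability(self, default_cohort):
        """Expected scaled agreement is nondecreasing in latent ability
        (checked by rank correlation across the cohort)."""
        merged = (
            default_cohort.agreement.groupby("subject_id")["scaled"]
            .mean()
            .reset_index()
            .merge(default_cohort.subjects[["subject_id", "ability"]], on="subject_id")
        )
        rho = merged[["scaled", "ability"]].corr(method="spearman").iloc[0, 1]
        assert rho > 0.6

    @given(
        st.integers(0, 10_000),
        st.integers(2, 5),
        st.integers(2, 5),
        st.floats(0.1, 3.0),
        st.floats(0.0, 2.0),
    )
    @settings(max_examples=15, deadline=None)
    def test_randomised_configs_respect_type_invariants(
        self, seed, n_ptsd, n_control, jitter, noise
    ):
        cfg = GeneratorConfig(
            n_ptsd=n_ptsd,
            n_control=n_control,
            seed=seed,
            videos=[VideoSpec("v1", 60), VideoSpec("v2", 45)],
            press=PressParams(jitter_sd_s=jitter),
            recall=dataclasses.replace(
                GeneratorConfig().recall, subject_noise_sd=noise
            ),
        )
        c = generate_cohort(cfg, score=True)
        assert c.subjects["pcl_total"].between(17, 85).all()
        assert c.subjects["ability"].between(0, 1, inclusive="neither").all()
        assert (c.recall["n_recalled"] <= c.recall["n_units_total"]).all()
        assert c.anxiety["rating"].between(1, 10).all()
        scaled = c.agreement["scaled"].dropna()
        assert scaled.between(0, 1).all()
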