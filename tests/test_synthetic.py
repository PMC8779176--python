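import dataclasses

import numpy as np
import pandas as pd
import pytest

from trichamber import (
    Bout,
    CohortDesign,
    DetectorParams,
    EffectSpec,
    GroundTruth,
    SexEffectSpec,
    SimulationConfig,
    TrialRecord,
    ZoneTimeline,
    assign_zones,
    detect_bouts,
    draw_metric_targets,
    extract_visits,
    human_scorer_oracle,
    internose_distances,
    simulate_cohort,
    simulate_trial,
    study_design_totals,
)
from trichamber.synthetic import PlantedBout
from trichamber.zone_scoring import ArenaGeometry


def _record(phase="sociability", side="left", fps=35.0):
    return TrialRecord("s1", "F", "F1", "NA", "DMSO", "NA", phase, side, fps, "L1")


class TestSimulateTrial:
    def test_same_seed_is_bit_identical(self):
        cfg = SimulationConfig(seed=3, trial_duration_s=30.0)
        a, _ = simulate_trial(cfg, _record())
        b, _ = simulate_trial(cfg, _record())
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_nothing_planted_nothing_true(self):
        cfg = SimulationConfig(seed=4, trial_duration_s=30.0)
        _, truth = simulate_trial(cfg, _record())
        assert truth.true_bouts == []

    def test_planted_bout_recovered_within_one_frame(self):
        cfg = SimulationConfig(
            seed=5, trial_duration_s=60.0,
            planted_bouts=(PlantedBout("left_enclosure", 30.0, 1.0),),
        )
        track, truth = simulate_trial(cfg, _record())
        params = DetectorParams()
        detected = detect_bouts(internose_distances(track, params), params)
        assert len(detected) == 1 and len(truth.true_bouts) == 1
        t, d = truth.true_bouts[0], detected[0]
        assert abs(d.start_frame - t.start_frame) <= 1
        assert abs(d.end_frame_exclusive - t.end_frame_exclusive) <= 1

    def test_planted_bout_frames_stay_inside_contact_distance(self):
        cfg = SimulationConfig(
            seed=6, trial_duration_s=60.0,
            planted_bouts=(PlantedBout("right_enclosure", 25.0, 0.8),),
        )
        track, truth = simulate_trial(cfg, _record(phase="social_novelty"))
        nose = track.xy("nose")
        stim = track.xy("stim_right_nose")
        b = truth.true_bouts[0]
        d = np.linalg.norm(
            nose[b.start_frame : b.end_frame_exclusive]
            - stim[b.start_frame : b.end_frame_exclusive],
            axis=1,
        )
        assert np.all(d < cfg.contact_distance_px)

    def test_habituation_never_leaves_center(self):
        cfg = SimulationConfig(seed=7, trial_duration_s=30.0)
        track, truth = simulate_trial(cfg, _record(phase="habituation"))
        tl = assign_zones(track, ArenaGeometry())
        assert set(tl.labels) == {"center"}
        assert set(truth.true_zone_timeline.labels) == {"center"}

    def test_truth_timeline_matches_scorer_closely(self):
        cfg = SimulationConfig(seed=8, trial_duration_s=90.0)
        track, truth = simulate_trial(cfg, _record())
        tl = assign_zones(track, ArenaGeometry())
        n_transitions = int(np.sum(tl.labels[1:] != tl.labels[:-1])) + 1
        mismatch = int(np.sum(tl.labels != truth.true_zone_timeline.labels))
        assert mismatch <= 2 * n_transitions

    def test_every_frame_lies_in_exactly_one_zone(self):
        cfg = SimulationConfig(
            seed=9, trial_duration_s=60.0,
            confidence_dropout_rate=0.02, teleport_glitch_rate=0.005,
        )
        track, truth = simulate_trial(cfg, _record())
        tl = truth.true_zone_timeline
        assert tl.n_frames == track.n_frames
        assert sum(tl.zone_times_s().values()) == pytest.approx(
            track.duration_s, abs=1 / track.frame_rate_hz
        )

    def test_dropout_frames_have_low_confidence(self):
        cfg = SimulationConfig(seed=10, trial_duration_s=30.0,
                               confidence_dropout_rate=0.2)
        track, _ = simulate_trial(cfg, _record())
        conf = track.confidence("body_center")
        frac_low = np.mean(conf < 0.90)
        assert 0.1 < frac_low < 0.3


class TestSimulateTrialErrors:
    def test_bout_outside_trial(self):
        with pytest.raises(ValueError, match="past the trial end"):
            cfg = SimulationConfig(
                seed=0, trial_duration_s=30.0,
                planted_bouts=(PlantedBout("left_enclosure", 29.5, 1.0),),
            )
            simulate_trial(cfg, _record())

    def test_full_dropout_with_bouts(self):
        cfg = SimulationConfig(
            seed=0, trial_duration_s=30.0, confidence_dropout_rate=1.0,
            planted_bouts=(PlantedBout("left_enclosure", 15.0, 0.5),),
        )
        with pytest.raises(ValueError, match="unverifiable"):
            simulate_trial(cfg, _record())

    def test_bouts_in_habituation(self):
        cfg = SimulationConfig(
            seed=0, trial_duration_s=30.0,
            planted_bouts=(PlantedBout("left_enclosure", 15.0, 0.5),),
        )
        with pytest.raises(ValueError, match="habituation"):
            simulate_trial(cfg, _record(phase="habituation"))

    def test_bout_at_empty_enclosure_in_sociability(self):
        cfg = SimulationConfig(
            seed=0, trial_duration_s=30.0,
            planted_bouts=(PlantedBout("right_enclosure", 15.0, 0.5),),
        )
        with pytest.raises(ValueError, match="no stimulus animal"):
            simulate_trial(cfg, _record(phase="sociability", side="left"))

    def test_overlapping_bouts_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SimulationConfig(
                planted_bouts=(
                    PlantedBout("left_enclosure", 10.0, 2.0),
                    PlantedBout("right_enclosure", 11.0, 2.0),
                )
            )


def test_dwell_means_converge_to_configuration():
    """Empirical mean dwell per zone approaches the configured exponential
    mean once several hundred entries accumulate (transit frames at the run
    edges add a small positive bias, kept below the tolerance by a fast
    travel speed)."""
    dwell = 30.0
    cfg = SimulationConfig(
        seed=12,
        frame_rate_hz=5.0,
        trial_duration_s=26000.0,
        dwell_means_s={"center": dwell, "left_distal": dwell},
        zone_transition_bias={"center": 1.0, "left_distal": 1.0},
        step_speed_cm_s=50.0,
    )
    _, truth = simulate_trial(cfg, _record(fps=5.0))
    visits = extract_visits(truth.true_zone_timeline)
    for zone in ("center", "left_distal"):
        runs = [v.duration_s for v in visits if v.target == zone]
        assert len(runs) >= 200
        assert np.mean(runs) == pytest.approx(dwell, rel=0.15)


class TestHumanScorerOracle:
    def _truth(self, n_bouts=20, fps=35.0, seed=0):
        rng = np.random.default_rng(seed)
        bouts, t = [], 5.0
        for _ in range(n_bouts):
            d = rng.uniform(0.3, 2.0)
            s = int(t * fps)
            e = s + max(1, int(d * fps))
            bouts.append(Bout("left_enclosure", s, e, (e - s) / fps))
            t += d + rng.uniform(2, 6)
        tl = ZoneTimeline(["center"] * int(t * fps + fps), fps)
        return GroundTruth(tl, bouts)

    def test_noiseless_scorer_equals_truth(self):
        truth = self._truth()
        assert human_scorer_oracle(truth, 0.0, 0.0, seed=1) == truth.true_bouts

    def test_full_miss_rate_empty(self):
        assert human_scorer_oracle(self._truth(), 0.0, 1.0, seed=1) == []

    def test_rerating_noise_is_seconds_scale(self):
        """Two independent jittered re-scorings of 16 trials differ by a
        per-trial total-time RMSE on the order of seconds, matching human
        test-retest variability."""
        from trichamber import rmse_vs_human

        truths = {i: self._truth(seed=i) for i in range(16)}
        a = {i: human_scorer_oracle(t, 0.5, 0.0, seed=100 + i) for i, t in truths.items()}
        b = {i: human_scorer_oracle(t, 0.5, 0.0, seed=200 + i) for i, t in truths.items()}
        rmse = rmse_vs_human(a, b).rmse_s
        assert 0.5 < rmse < 20.0


class TestCohort:
    def test_study_design_totals(self):
        totals = study_design_totals()
        assert totals["litters"] == 306
        assert totals["animals"] == 1209

    def test_null_design_has_no_spurious_effects(self):
        """With no planted effect the between-cell standardized differences
        average to zero.  Any single pair carries sampling noise with
        SD(d-hat) ~ sqrt(2/n) ~ 0.32 at n = 20, so the check is on the mean
        across replicate draws plus a loose per-pair tail bound."""
        from trichamber import cohens_d

        design = CohortDesign(generations=("F3",), lineages=("paternal",), n_per_cell=20)
        all_ds = []
        for rep in range(10):
            tab = draw_metric_targets(design, seed=70 + rep, phases=("sociability",))
            sub = tab[tab.sex == "F"]
            groups = {
                t: g["social_preference_score"].to_numpy()
                for t, g in sub.groupby("treatment")
            }
            labels = list(groups)
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    all_ds.append(cohens_d(groups[labels[i]], groups[labels[j]]))
        assert abs(np.mean(all_ds)) < 0.3
        assert np.max(np.abs(all_ds)) < 1.3  # ~4 sigma tail bound

    def test_effect_spec_recovers_planted_d(self):
        """A planted standardized shift of -0.8 on the preference score is
        recovered within a broad Monte-Carlo band over replicate cohorts."""
        from trichamber import cohens_d

        cell = {"generation": "F3", "lineage": "paternal", "sex": "F",
                "treatment": "VIN"}
        design = CohortDesign(
            generations=("F3",), lineages=("paternal",), n_per_cell=20,
            effect_specs=(EffectSpec("social_preference_score", cell, -0.8),),
        )
        ds = []
        for rep in range(20):
            tab = draw_metric_targets(design, seed=700 + rep)
            sub = tab[(tab.phase == "sociability") & (tab.sex == "F")]
            vin = sub.loc[sub.treatment == "VIN", "social_preference_score"]
            ctrl = sub.loc[sub.treatment == "DMSO", "social_preference_score"]
            ds.append(cohens_d(vin.to_numpy(), ctrl.to_numpy()))
        assert -1.2 < np.mean(ds) < -0.4

    def test_sex_effect_spec_is_detectable(self):
        """A planted between-sex shift of d=1.7 on distance traveled drives
        the Kruskal-Wallis test significant in nearly every replicate."""
        from scipy import stats as sps

        design = CohortDesign(
            generations=("F1",), n_per_cell=100,
            sex_effect_specs=(SexEffectSpec("distance_traveled_m", 1.7),),
        )
        hits = 0
        reps = 20
        for rep in range(reps):
            tab = draw_metric_targets(
                design, seed=900 + rep, phases=("sociability",)
            )
            f = tab.loc[tab.sex == "F", "distance_traveled_m"]
            m = tab.loc[tab.sex == "M", "distance_traveled_m"]
            hits += sps.kruskal(f, m).pvalue < 0.05
        assert hits / reps >= 0.95

    def test_unknown_metric_in_effect_spec(self):
        with pytest.raises(ValueError, match="unknown metric"):
            EffectSpec("not_a_metric", {"sex": "F"}, 0.5)

    def test_simulated_cohort_metrics_track_targets(self):
        """Rendered trials approximately realize the drawn metric targets."""
        from trichamber import ArenaGeometry, score_trials

        design = CohortDesign(generations=("F1",), treatments=("DMSO",), n_per_cell=3)
        cfg = SimulationConfig(seed=80, trial_duration_s=300.0)
        trials, targets = simulate_cohort(design, cfg, phases=("sociability",))
        table, _, _ = score_trials(
            [(tr, rec) for tr, rec, _ in trials], ArenaGeometry()
        )
        merged = table.merge(
            targets, on=["animal_id", "phase"], suffixes=("", "_target")
        )
        # preference score is ratio-based and should land near its target
        err = (
            merged["social_preference_score"]
            - merged["social_preference_score_target"]
        ).abs()
        assert err.median() < 0.25
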