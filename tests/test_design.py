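"""Trial lists, boundary aggregation and run-schedule arithmetic."""

import numpy as np
import pandas as pd
import pytest

from facespace import design


class TestBehaviouralTrialList:
    def test_canonical_counts(self):
        trials = design.behavioural_trial_list(seed=0)
        assert len(trials) == 120  # 2 classes x 5 components x 2 directions x 6
        counts = trials.groupby(["class", "component", "direction"]).size()
        assert (counts == 6).all()

    def test_product_rule(self):
        trials = design.behavioural_trial_list(1, 2, 2, 3, seed=0)
        assert len(trials) == 12

    def test_shuffle_is_seeded_and_caricature_bounds_respected(self):
        a = design.behavioural_trial_list(seed=4)
        b = design.behavioural_trial_list(seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert a["max_caricature_sd"].between(8, 14).all()


class TestAggregateBoundaries:
    @staticmethod
    def _table(values_by_participant, reps=6):
        rows = []
        for part, v in values_by_participant.items():
            for _ in range(reps):
                rows.append(
                    {
                        "participant": part,
                        "class": "m",
                        "component": 1,
                        "direction": 1,
                        "transition_sd": v,
                    }
                )
        return pd.DataFrame(rows)

    def test_constant_responses(self):
        out = design.aggregate_boundaries(self._table({"p1": 4.0, "p2": 4.0}))
        assert out.loc[0, "group_mean"] == 4.0
        assert out.loc[0, "group_sd"] == 0.0

    def test_two_participant_hand_arithmetic(self):
        out = design.aggregate_boundaries(self._table({"p1": 3.0, "p2": 5.0}))
        assert out.loc[0, "group_mean"] == pytest.approx(4.0)
        assert out.loc[0, "group_sd"] == pytest.approx(np.sqrt(2))

    def test_single_participant_flagged(self):
        out = design.aggregate_boundaries(self._table({"p1": 4.0}))
        assert "single_participant" in out.loc[0, "flags"]
        assert np.isnan(out.loc[0, "group_sd"])

    def test_missing_repetitions_flagged(self):
        out = design.aggregate_boundaries(self._table({"p1": 4.0, "p2": 4.0}, reps=5))
        assert "missing_repetitions" in out.loc[0, "flags"]

    def test_negative_transitions_rejected(self):
        t = self._table({"p1": 4.0})
        t.loc[0, "transition_sd"] = -1.0
        with pytest.raises(ValueError):
            design.aggregate_boundaries(t)


class TestConditionSet:
    def test_canonical_21_conditions(self, condition_set):
        assert len(condition_set) == 21
        assert (condition_set["orientation"] == "upright").sum() == 15
        assert (condition_set["orientation"] == "inverted").sum() == 6
        inv = condition_set[condition_set["orientation"] == "inverted"]
        assert set(inv["level_offset"]) == {-1, 6}

    def test_single_component_gives_7(self):
        cs = design.caricature_condition_set(4.0, 1.0, components=1)
        assert len(cs) == 7

    def test_absolute_positions(self):
        cs = design.caricature_condition_set(4.0, 1.0, components=1)
        up = cs[cs["orientation"] == "upright"]
        assert sorted(up["level_sd"]) == [3.0, 4.0, 5.0, 7.0, 10.0]

    def test_negative_positions_clipped_and_flagged(self):
        cs = design.caricature_condition_set(0.5, 1.0, components=1)
        row = cs[(cs["level_offset"] == -1) & (cs["orientation"] == "upright")].iloc[0]
        assert row["level_sd"] == 0.0 and row["clipped"]

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            design.caricature_condition_set(4.0, 0.0)


class TestEventRelatedSchedule:
    def test_canonical_duration_and_volumes(self, canonical_schedules):
        s = canonical_schedules[0]
        assert s.total_duration == 394.0
        assert s.n_volumes == 197
        assert len(s.events) == 63

    def test_isi_histogram_balanced(self, canonical_schedules):
        isis = canonical_schedules[0].events["isi"].value_counts()
        assert isis.to_dict() == {3.0: 21, 5.0: 21, 7.0: 21}

    def test_zero_trials_boundary_case(self, condition_set):
        s = design.event_related_schedule(condition_set.iloc[:0], seed=0)
        assert s.total_duration == 16.0
        assert len(s.events) == 0

    def test_onsets_increasing_and_nonoverlapping(self, canonical_schedules):
        for s in canonical_schedules:
            on = s.events["onset"].to_numpy()
            assert np.all(np.diff(on) > 0)
            assert np.all(on[:-1] + s.events["duration"].to_numpy()[:-1] <= on[1:])

    def test_seed_permutes_but_preserves_counts(self, condition_set):
        a = design.event_related_schedule(condition_set, seed=1)
        b = design.event_related_schedule(condition_set, seed=2)
        assert a.total_duration == b.total_duration
        assert sorted(a.events["trial_type"]) == sorted(b.events["trial_type"])
        assert not a.events["trial_type"].tolist() == b.events["trial_type"].tolist()

    def test_determinism_under_seed(self, condition_set):
        a = design.event_related_schedule(condition_set, seed=9)
        b = design.event_related_schedule(condition_set, seed=9)
        pd.testing.assert_frame_equal(a.events, b.events)
        assert np.array_equal(a.attention_onsets, b.attention_onsets)

    def test_indivisible_trial_count_rejected(self, condition_set):
        with pytest.raises(ValueError, match="divisible"):
            design.event_related_schedule(condition_set.iloc[:20], repeats=1, seed=0)

    def test_duration_closed_form_over_random_configs(self, condition_set):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n_cond = int(rng.integers(1, 8)) * 3
            reps = int(rng.integers(1, 3))
            menu = tuple(sorted(rng.choice([2.0, 3.0, 4.0, 5.0, 7.0], 3, replace=False)))
            sub = condition_set.sample(n_cond, replace=True, random_state=1).reset_index(drop=True)
            s = design.event_related_schedule(
                sub, repeats=1, isi_menu=menu, n_attention=3, seed=int(rng.integers(2**31))
            )
            expected = 8 + (1 + np.mean(menu)) * n_cond + 8
            assert s.total_duration == pytest.approx(expected)

    def test_attention_events_counted_and_spaced(self, canonical_schedules):
        att = canonical_schedules[0].attention_onsets
        assert len(att) == 42
        assert np.diff(att).min() >= 1.0

    def test_tsv_round_trip(self, canonical_schedules, tmp_path):
        s = canonical_schedules[0]
        s.to_tsv(tmp_path / "run.tsv")
        back = design.RunSchedule.from_tsv(tmp_path / "run.tsv", s.total_duration, s.tr)
        assert back.n_volumes == s.n_volumes
        assert back.events["trial_type"].tolist() == s.events["trial_type"].tolist()


class TestLevelPooling:
    def test_pooled_schedule_has_7_conditions(self, canonical_schedules):
        pooled = design.pool_by_level(canonical_schedules[0])
        assert len(set(pooled.events["trial_type"])) == 7
        ups = pooled.events[pooled.events["orientation"] == "upright"]
        assert len(set(ups["trial_type"])) == 5

    def test_pooling_preserves_timing(self, canonical_schedules):
        s = canonical_schedules[0]
        pooled = design.pool_by_level(s)
        assert np.array_equal(pooled.events["onset"], s.events["onset"])
        assert pooled.total_duration == s.total_duration


class TestLocaliserSchedule:
    def test_canonical_duration(self):
        s = design.localiser_schedule(seed=0)
        assert s.total_duration == 392.0
        assert s.n_volumes == 196
        assert len(s.attention_onsets) == 130

    def test_single_block_formula(self):
        s = design.localiser_schedule(("faces",), blocks_per_category=1, n_attention=2, seed=0)
        assert s.total_duration == 24.0  # 8 OFF + 8 ON + 8 OFF

    def test_blocks_contain_eight_one_second_images(self):
        s = design.localiser_schedule(seed=1)
        blocks = design.block_onsets(s)
        assert len(blocks) == 24
        assert np.allclose(blocks["duration"], 8.0)
        assert len(s.events) == 24 * 8
        assert np.allclose(s.events["duration"], 1.0)

    def test_block_order_seeded_shuffle(self):
        a = design.localiser_schedule(seed=1)
        b = design.localiser_schedule(seed=2)
        assert not a.events["trial_type"].tolist() == b.events["trial_type"].tolist()
        assert sorted(a.events["trial_type"]) == sorted(b.events["trial_type"])


class TestScheduleInvariants:
    def test_overlapping_events_rejected(self):
        ev = pd.DataFrame(
            {
                "onset": [0.0, 0.5],
                "duration": [1.0, 1.0],
                "trial_type": ["a", "b"],
            }
        )
        with pytest.raises(ValueError, match="overlap"):
            design.RunSchedule(events=ev, total_duration=10.0)

    def test_nonmonotonic_onsets_rejected(self):
        ev = pd.DataFrame(
            {
                "onset": [2.0, 1.0],
                "duration": [0.5, 0.5],
                "trial_type": ["a", "b"],
            }
        )
        with pytest.raises(ValueError, match="increasing"):
            design.RunSchedule(events=ev, total_duration=10.0)
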