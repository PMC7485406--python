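import numpy as np
import pandas as pd
import pytest

import pepsim
from pepsim.experiment import (
    CONDITIONS,
    TaskDesign,
    classify_congruency,
    classify_transition,
    code_conditions,
    compute_effects,
    records_to_frame,
    run_experiment,
    run_participant,
    run_trial,
    sample_trials,
    summarize,
    _make_record,
)
from pepsim.fixtures import SIM1_ERROR_PCTS, SIM1_RT_MEANS, TABLE1_PAIRS, make_fixture


class TestSampling:
    def test_sequence_length_and_determinism(self, design):
        a = sample_trials(design, 800, np.random.default_rng(4))
        b = sample_trials(design, 800, np.random.default_rng(4))
        assert len(a) == 800
        assert a == b

    def test_tasks_equiprobable(self, design):
        trials = sample_trials(design, 100_000, np.random.default_rng(0))
        p_parity = np.mean([design.cue_task(c) == "parity" for c, _ in trials])
        assert p_parity == pytest.approx(0.5, abs=0.01)

    def test_task_repetition_frequency_near_half(self, design):
        trials = sample_trials(design, 100_000, np.random.default_rng(1))
        tasks = [design.cue_task(c) for c, _ in trials]
        reps = np.mean([a == b for a, b in zip(tasks, tasks[1:])])
        assert reps == pytest.approx(0.5, abs=0.01)

    def test_invalid_count_rejected(self, design):
        with pytest.raises(ValueError):
            sample_trials(design, 0)


class TestTransitionCoding:
    @pytest.mark.parametrize("condition", list(TABLE1_PAIRS))
    def test_printed_example_pairs_classify_correctly(self, condition, design):
        (pc, pd_), (cc, cd) = TABLE1_PAIRS[condition]
        prev = _make_record(0, pc, pd_, design)
        cur = _make_record(1, cc, cd, design)
        assert classify_transition(prev, cur) == condition

    def test_first_trial_unclassified(self, design):
        assert classify_transition(None, _make_record(0, "blue", 3, design)) == "first"

    def test_impossible_combination_rejected(self, design):
        prev = _make_record(0, "blue", 3, design)
        cur = _make_record(1, "red", 3, design)
        cur.correct_response = "right"  # corrupt: repeated stimulus, same task, new response
        with pytest.raises(ValueError):
            classify_transition(prev, cur)


class TestCongruency:
    def test_printed_examples(self, design):
        assert classify_congruency(7, design) == "incongruent"
        assert classify_congruency(3, design) == "congruent"

    def test_small_digits_congruent_iff_odd_left(self):
        # under odd->left, digits <5 need left for magnitude; odd small
        # digits also need left for parity
        design = TaskDesign(odd_left=True)
        assert {classify_congruency(d, design) for d in (1, 3)} == {"congruent"}
        assert {classify_congruency(d, design) for d in (6, 8)} == {"congruent"}
        assert {classify_congruency(d, design) for d in (7, 9, 2, 4)} == {"incongruent"}

    def test_alt_rr_only_congruent_alt_ra_only_incongruent(self, small_experiment):
        df = small_experiment
        rr = df.loc[df["condition"] == "alt-RR", "congruency"]
        ra = df.loc[df["condition"] == "alt-RA", "congruency"]
        assert set(rr) == {"congruent"}
        assert set(ra) == {"incongruent"}


class TestRunTrial:
    def test_noise_free_instruction_driven_responses_are_correct(self, quiet_params):
        # exhaustive oracle over every (cue, digit) pair on a fresh store
        for design in (TaskDesign(odd_left=True), TaskDesign(odd_left=False)):
            for cue in design.cues:
                for digit in design.digits:
                    rec = run_participant(
                        quiet_params, design, seed=0, trials=[(cue, digit)]
                    )[0]
                    assert not rec.omission, (cue, digit)
                    assert rec.response == rec.correct_response, (cue, digit)
                    assert rec.rt_cycles > 0

    def test_reference_engine_matches_fast_engine(self, design):
        trials = sample_trials(design, 12, np.random.default_rng(42))
        params = pepsim.PEPParameters()
        fast = run_participant(params, design, seed=1, trials=trials, engine="fast")
        ref = run_participant(params, design, seed=1, trials=trials, engine="reference")
        assert [(r.rt_cycles, r.response, r.decision) for r in fast] == [
            (r.rt_cycles, r.response, r.decision) for r in ref
        ]

    def test_unknown_engine_rejected(self, default_params, design):
        with pytest.raises(ValueError):
            run_participant(default_params, design, seed=0, n_trials=2, engine="magic")


class TestSummaries:
    def _toy_frame(self):
        # hand-built six-trial dataset, means checked by hand
        return pd.DataFrame(
            {
                "participant": 0,
                "trial": range(6),
                "cue": ["blue"] * 6,
                "digit": [3] * 6,
                "task": ["parity"] * 6,
                "condition": ["first", "cue-RR", "cue-RR", "cue-AR", "cue-AR", "cue-AA"],
                "congruency": ["congruent"] * 6,
                "response": ["left"] * 6,
                "correct": [1, 1, 1, 0, 1, 1],
                "omission": [0, 0, 0, 0, 0, 1],
                "rt_cycles": [100.0, 200.0, 300.0, 400.0, 500.0, np.nan],
            }
        )

    def test_toy_dataset_means_match_hand_computation(self):
        df = self._toy_frame()
        df = pd.concat(
            [df]
            + [
                df.assign(condition=c, trial=range(6 * (i + 1), 6 * (i + 2)))
                for i, c in enumerate(
                    ["cue-AA", "rep-RR", "rep-AR", "rep-AA", "alt-RR", "alt-RA", "alt-AR", "alt-AA"]
                )
            ],
            ignore_index=True,
        )
        s = summarize(df)
        assert s.rt("cue-RR") == pytest.approx(250.0)  # mean(200, 300)
        assert s.rt("cue-AR") == pytest.approx(500.0)  # error trial excluded
        assert s.error_pct("cue-AR") == pytest.approx(50.0)

    def test_all_correct_dataset_has_zero_errors(self, small_experiment):
        df = small_experiment.copy()
        df["correct"] = np.where(df["omission"] == 1, 0, 1)
        s = summarize(df)
        assert (s.table["error_pct"] == 0).all()

    def test_omissions_excluded_from_error_denominator(self):
        # one correct trial plus one omission per condition: the omission
        # must not count as an error
        df = self._toy_frame().iloc[[1, 5]].copy()  # one correct, one omission
        frames = []
        for i, c in enumerate(CONDITIONS):
            sub = df.copy()
            sub["condition"] = c
            sub["trial"] = [2 * i, 2 * i + 1]
            frames.append(sub)
        full = pd.concat(frames, ignore_index=True)
        s = summarize(full)
        assert (s.table["error_pct"] == 0).all()
        assert (s.table["n"] == 1).all()
        assert s.omission_pct == pytest.approx(50.0)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame())


class TestEffects:
    def _summary_from_printed_means(self):
        rows = [
            {"condition": c, "mean_rt": SIM1_RT_MEANS[c], "error_pct": SIM1_ERROR_PCTS[c], "n": 100}
            for c in CONDITIONS
        ]
        table = pd.DataFrame(rows)
        from pepsim.experiment import ConditionSummary

        return ConditionSummary(
            table=table,
            by_congruency=table.assign(congruency="congruent"),
            congruency=pd.DataFrame(
                {"congruency": ["congruent", "incongruent"], "mean_rt": [801.0, 849.0],
                 "error_pct": [0.0, 8.9], "n": [50, 50]}
            ),
            omission_pct=1.7,
            n_trials=800,
        )

    def test_true_switch_cost_from_printed_means(self):
        effects = compute_effects(self._summary_from_printed_means())
        e = effects.set_index("effect")["cycles"]
        assert e["true_switch_cost"] == pytest.approx(905 - 809)

    def test_pooled_cue_mean_matches_printed_value(self):
        effects = compute_effects(self._summary_from_printed_means())
        e = effects.set_index("effect")["cycles"]
        assert e["cue_pooled_rt"] == pytest.approx(603.67, abs=0.01)
        assert e["congruency_effect"] == pytest.approx(48.0)

    def test_identical_means_give_zero_effects(self):
        s = self._summary_from_printed_means()
        s.table["mean_rt"] = 700.0
        s.congruency["mean_rt"] = 700.0
        effects = compute_effects(s).set_index("effect")["cycles"]
        for name in ("switch_cost", "true_switch_cost", "cue_repetition_benefit",
                     "congruency_effect"):
            assert effects[name] == pytest.approx(0.0)

    def test_effects_invariant_to_participant_order(self, small_experiment):
        df = small_experiment
        shuffled = df.sort_values(["trial", "participant"], kind="stable").reset_index(drop=True)
        a = compute_effects(summarize(df), df).set_index("effect")["cycles"]
        b = compute_effects(summarize(shuffled), shuffled).set_index("effect")["cycles"]
        pd.testing.assert_series_equal(a, b)


class TestExperimentLevel:
    def test_counterbalance_alternates_with_participant_parity(self, small_experiment):
        # participants 0/2 use odd->left, 1/3 odd->right: digit 7 in the
        # parity task then maps to different keys
        df = small_experiment
        rows = df[(df["digit"] == 7) & (df["task"] == "parity")]
        assert set(rows.loc[rows["participant"] % 2 == 0, "congruency"]) == {"incongruent"}
        assert set(rows.loc[rows["participant"] % 2 == 1, "congruency"]) == {"congruent"}

    def test_code_conditions_matches_simulated_labels(self, small_experiment):
        df = small_experiment[small_experiment["participant"] < 2]
        coded = code_conditions(df[["participant", "trial", "cue", "digit"]])
        merged = df.merge(coded, on=["participant", "trial"], suffixes=("", "_coded"))
        assert (merged["condition"] == merged["condition_coded"]).all()
        assert (merged["congruency"] == merged["congruency_coded"]).all()

    def test_invalid_participant_count_rejected(self, default_params):
        with pytest.raises(ValueError):
            run_experiment(default_params, n_participants=0)
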