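import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pepsim
from pepsim.episodic_store import (
    MemoryStore,
    N_INSTRUCTIONS,
    SearchStrengths,
    decay_episodes,
    encode_instructions,
    encode_trial_episode,
    maintain_instructions,
    retrieve,
    schedule_search,
    weaken_on_retrieval,
)
from pepsim.experiment import TaskDesign, run_participant
from pepsim.layout import N_NODES, cue_node, decision_node, digit_node, goal_node, response_node


@pytest.fixture
def instructed_store(design):
    store = MemoryStore()
    encode_instructions(store, design)
    return store


class TestEncoding:
    def test_instructions_are_eight_two_feature_episodes(self, instructed_store):
        assert len(instructed_store) == 8
        for ep in instructed_store:
            assert ep.is_instruction
            assert len(ep.bound_nodes) == 2

    def test_magnitude_keys_are_fixed(self, instructed_store):
        bound = [set(ep.bound_nodes) for ep in instructed_store]
        assert {"decision:lt5", "response:left"} in bound
        assert {"decision:gt5", "response:right"} in bound

    def test_counterbalance_flips_parity_keys_only(self, design):
        store = MemoryStore()
        encode_instructions(store, TaskDesign(odd_left=False))
        bound = [set(ep.bound_nodes) for ep in store]
        assert {"decision:odd", "response:right"} in bound
        assert {"decision:lt5", "response:left"} in bound

    def test_instructions_require_empty_store(self, instructed_store, design):
        with pytest.raises(ValueError):
            encode_instructions(instructed_store, design)

    def test_trial_episode_binds_five_identities(self, instructed_store, default_params):
        encode_trial_episode(
            instructed_store, cue="blue", digit=3, goal="parity",
            decision="odd", response="left", params=default_params,
        )
        assert len(instructed_store) == 9
        ep = instructed_store.episode(8)
        assert set(ep.bound_nodes) == {
            "cue:blue", "digit:3", "goal:parity", "decision:odd",
            "response:left", "response:right",
        }
        assert ep.bound_nodes["response:right"] == default_params.negative_weights_episode

    def test_omission_trial_encoded_without_response(self, instructed_store, default_params):
        encode_trial_episode(
            instructed_store, cue="red", digit=7, goal="parity",
            decision="odd", response=None, params=default_params,
        )
        assert len(instructed_store) == 9
        ep = instructed_store.episode(8)
        assert not any(k.startswith("response") for k in ep.bound_nodes)

    def test_store_size_is_instructions_plus_trials(self, default_params, design):
        records, store = run_participant(
            default_params, design, seed=2, n_trials=60, return_store=True
        )
        assert len(store) == N_INSTRUCTIONS + 60


class TestRetrieve:
    def test_empty_store_zero_drive(self, default_params):
        search = schedule_search("in_trial", False, False, default_params)
        drive = retrieve(MemoryStore(), np.zeros(N_NODES), search, default_params)
        np.testing.assert_array_equal(drive, 0.0)

    def test_cue_probe_drives_only_bound_goal(self, default_params):
        store = MemoryStore()
        w = np.zeros(N_NODES)
        w[cue_node("blue")] = 1.0
        w[goal_node("parity")] = 1.0
        store.add(w, 1.0)
        probe = np.zeros(N_NODES)
        probe[cue_node("blue")] = 1.0
        search = schedule_search("in_trial", False, False, default_params)
        drive = retrieve(store, probe, search, default_params)
        assert drive[goal_node("parity")] > 0
        assert drive[goal_node("magnitude")] == 0
        assert np.all(drive[12:18] == 0)

    def test_equal_episodes_give_equal_response_drive(self, default_params):
        store = MemoryStore()
        for resp in ("left", "right"):
            w = np.zeros(N_NODES)
            w[decision_node("odd")] = 1.0
            w[response_node(resp)] = 1.0
            store.add(w, 1.0)
        probe = np.zeros(N_NODES)
        probe[decision_node("odd")] = 0.8
        search = schedule_search("in_trial", True, True, default_params)
        drive = retrieve(store, probe, search, default_params)
        assert drive[response_node("left")] == pytest.approx(drive[response_node("right")])
        assert drive[response_node("left")] > 0

    def test_recency_dominance_newer_episode_drives_more(self, default_params):
        # identical bindings except the response; the newer (stronger) one
        # contributes strictly more drive -- the engine of binding effects
        store = MemoryStore()
        for resp, strength in (("left", 0.4), ("right", 1.0)):
            w = np.zeros(N_NODES)
            w[digit_node(7)] = 1.0
            w[response_node(resp)] = 1.0
            store.add(w, strength)
        probe = np.zeros(N_NODES)
        probe[digit_node(7)] = 1.0
        search = schedule_search("in_trial", True, True, default_params)
        drive = retrieve(store, probe, search, default_params)
        assert drive[response_node("right")] > drive[response_node("left")]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_layerwise_retrieval_budget_bounded(self, seed):
        rng = np.random.default_rng(seed)
        params = pepsim.PEPParameters()
        store = MemoryStore()
        for _ in range(rng.integers(1, 40)):
            w = np.zeros(N_NODES)
            idx = rng.choice(N_NODES, size=rng.integers(1, 7), replace=False)
            w[idx] = rng.uniform(-0.2, 1.0, size=len(idx))
            store.add(w, float(rng.uniform(0, 1)))
        probe = rng.uniform(0, 1, N_NODES)
        search = schedule_search("in_trial", True, True, params)
        drive = retrieve(store, probe, search, params)
        assert np.all(np.isfinite(drive))
        for lo, hi in ((0, 4), (4, 12), (12, 16), (16, 18), (18, 20)):
            layer = drive[lo:hi]
            assert layer[layer > 0].sum() < 1.0

    def test_congruency_emerges_after_training(self, default_params, design):
        # after substantial training, response retrieval under the correct
        # goal favours the correct response more for a congruent digit than
        # for an incongruent one
        _, store = run_participant(
            default_params, design, seed=13, n_trials=200, return_store=True
        )
        search = schedule_search("in_trial", True, True, default_params)

        def correct_share(digit):
            task = "parity"
            probe = np.zeros(N_NODES)
            probe[digit_node(digit)] = 1.0
            probe[goal_node(task)] = 0.8
            probe[decision_node(design.correct_decision(digit, task))] = 0.6
            drive = retrieve(store, probe, search, default_params)
            correct = drive[response_node(design.correct_response(digit, task))]
            other = drive[response_node("left") if design.correct_response(digit, task) == "right" else response_node("right")]
            return correct - other

        congruent = np.mean([correct_share(d) for d in (1, 3, 6, 8)])
        incongruent = np.mean([correct_share(d) for d in (2, 4, 7, 9)])
        assert congruent > incongruent


class TestMaintenance:
    def test_zero_loss_weakening_is_identity(self, instructed_store, default_params):
        params = default_params.replace(loss_episode_connection=0.0)
        before = instructed_store.strengths[:8].copy()
        probe = np.ones(N_NODES)
        search = schedule_search("in_trial", True, True, params)
        weaken_on_retrieval(instructed_store, probe, search, params)
        np.testing.assert_array_equal(instructed_store.strengths[:8], before)

    def test_zero_similarity_episode_unchanged(self, default_params):
        store = MemoryStore()
        w = np.zeros(N_NODES)
        w[cue_node("blue")] = 1.0
        w[goal_node("parity")] = 1.0
        store.add(w, 0.9)
        search = schedule_search("in_trial", True, True, default_params)
        weaken_on_retrieval(store, np.zeros(N_NODES), search, default_params)
        assert store.strengths[0] == 0.9

    def test_repeated_weakening_matches_iterated_rule(self, default_params):
        store = MemoryStore()
        w = np.zeros(N_NODES)
        w[digit_node(3)] = 1.0
        w[response_node("left")] = 1.0
        store.add(w, 1.0)
        probe = np.zeros(N_NODES)
        probe[digit_node(3)] = 1.0
        probe[response_node("left")] = 0.5
        search = schedule_search("in_trial", True, True, default_params)
        # independent oracle: apply the stated weakening formula k times
        pw_digit = search.target_to_decision
        pw_resp = search.response_coding
        sim = pw_digit * 1.0 + pw_resp * 0.5
        loss, sat = default_params.loss_episode_connection, default_params.weaken_saturation
        expected = 1.0
        history = []
        for _ in range(6):
            expected *= 1.0 - loss * sim / (1.0 + sim / sat)
            weaken_on_retrieval(store, probe, search, default_params)
            history.append(store.strengths[0])
        assert store.strengths[0] == pytest.approx(expected, rel=1e-12)
        assert all(x > y for x, y in zip([1.0] + history, history))

    def test_decay_identity_and_power_law(self, instructed_store, default_params):
        none = default_params.replace(decay_episode=0.0)
        before = instructed_store.strengths[:8].copy()
        decay_episodes(instructed_store, none)
        np.testing.assert_array_equal(instructed_store.strengths[:8], before)
        n = 25
        for _ in range(n):
            decay_episodes(instructed_store, default_params)
        expected = before * (1 - default_params.decay_episode) ** n
        np.testing.assert_allclose(instructed_store.strengths[:8], expected, rtol=1e-10)
        assert np.all(instructed_store.strengths >= 0)

    def test_restore_zero_is_identity_and_capped_at_initial(self, instructed_store, default_params):
        none = default_params.replace(restore_instruction_episode=0.0)
        instructed_store.strengths[:8] = 0.5
        maintain_instructions(instructed_store, none)
        np.testing.assert_array_equal(instructed_store.strengths[:8], 0.5)
        for _ in range(200):
            maintain_instructions(instructed_store, default_params)
        assert np.all(instructed_store.strengths[:8] <= 1.0 + 1e-12)

    def test_weaken_restore_cycle_converges_to_positive_fixed_point(
        self, instructed_store, default_params
    ):
        probe = np.zeros(N_NODES)
        probe[decision_node("odd")] = 0.8
        probe[response_node("left")] = 0.8
        search = schedule_search("in_trial", True, True, default_params)
        values = []
        for _ in range(1000):
            weaken_on_retrieval(instructed_store, probe, search, default_params)
            maintain_instructions(instructed_store, default_params)
            values.append(instructed_store.strengths[:8].copy())
        final = values[-1]
        assert np.all(final > 0.1)
        np.testing.assert_allclose(values[-1], values[-2], rtol=1e-6)

    def test_error_only_restoration_flag(self, instructed_store, default_params):
        params = default_params.replace(restore_after_errors_only=True)
        instructed_store.strengths[:8] = 0.5
        maintain_instructions(instructed_store, params, error_occurred=False)
        np.testing.assert_array_equal(instructed_store.strengths[:8], 0.5)
        maintain_instructions(instructed_store, params, error_occurred=True)
        assert np.all(instructed_store.strengths[:8] > 0.5)


class TestScheduleSearch:
    def test_trial_start_uses_full_cue_search(self, default_params):
        s = schedule_search("in_trial", False, False, default_params)
        assert s.cue_to_goal == pytest.approx(1.14)

    def test_goal_selection_damps_cue_search(self, default_params):
        s = schedule_search("in_trial", True, False, default_params)
        assert s.cue_to_goal == pytest.approx(1.14 * 0.1)
        assert s.target_to_decision == pytest.approx(3.4)

    def test_post_trial_damps_every_search(self, default_params):
        during = schedule_search("in_trial", True, True, default_params)
        after = schedule_search("post_trial", True, True, default_params)
        for f in ("cue_to_goal", "target_to_decision", "decision_to_response", "response_coding"):
            assert getattr(after, f) < getattr(during, f)

    def test_inconsistent_flags_rejected(self, default_params):
        with pytest.raises(ValueError):
            schedule_search("in_trial", False, True, default_params)

    def test_negative_strengths_rejected(self):
        with pytest.raises(ValueError):
            SearchStrengths(-1.0, 1.0, 1.0, 1.0)
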