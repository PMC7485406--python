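"""The cued task-switching paradigm and its analysis.

Implements the digit task-switching design (digits 1-9 without 5, parity
vs. magnitude, four colour cues, left/right keys), the per-trial
cue -> target -> response loop, participant- and experiment-level
simulation, the ten-way transition taxonomy (cue-RR ... alt-AA),
task-rule congruency coding, condition summaries and derived effects
(switch cost, true switch cost, cue- and response-repetition benefits,
congruency effect and its interaction with switching).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels, episodic_store, network_core
from .episodic_store import MemoryStore, N_INSTRUCTIONS, schedule_search
from .layout import (
    CUES,
    CUE_GOAL,
    DECISIONS,
    DIGITS,
    DIGIT_DECISIONS,
    GOALS,
    N_NODES,
    RESPONSES,
    cue_node,
    digit_node,
)
from .network_core import NetworkState, TrialPhase, init_network
from .params import PEPParameters

__all__ = [
    "TaskDesign",
    "TrialRecord",
    "ConditionSummary",
    "CONDITIONS",
    "sample_trials",
    "run_trial",
    "run_participant",
    "run_experiment",
    "classify_transition",
    "classify_congruency",
    "code_conditions",
    "summarize",
    "compute_effects",
]

#: the ten transition conditions, in conventional (figure) order
CONDITIONS = (
    "cue-RR", "cue-AR", "cue-AA",
    "rep-RR", "rep-AR", "rep-AA",
    "alt-RR", "alt-RA", "alt-AR", "alt-AA",
)


@dataclass(frozen=True)
class TaskDesign:
    """The cued task-switching design.

    ``odd_left`` is the per-participant counterbalance of the parity keys
    (odd->left/even->right when True, swapped when False); lt5/gt5 are
    always assigned to left/right.
    """

    odd_left: bool = True

    digits: tuple[int, ...] = DIGITS
    cues: tuple[str, ...] = CUES
    tasks: tuple[str, ...] = GOALS

    def cue_task(self, cue: str) -> str:
        return GOALS[CUE_GOAL[CUES.index(cue)]]

    def decision_response(self, decision: str) -> str:
        if decision == "lt5":
            return "left"
        if decision == "gt5":
            return "right"
        if decision == "odd":
            return "left" if self.odd_left else "right"
        if decision == "even":
            return "right" if self.odd_left else "left"
        raise ValueError(decision)

    def correct_decision(self, digit: int, task: str) -> str:
        parity_dec, magnitude_dec = DIGIT_DECISIONS[DIGITS.index(digit)]
        return DECISIONS[parity_dec if task == "parity" else magnitude_dec]

    def correct_response(self, digit: int, task: str) -> str:
        return self.decision_response(self.correct_decision(digit, task))


@dataclass
class TrialRecord:
    """One simulated trial."""

    index: int
    cue: str
    digit: int
    task: str
    correct_decision: str
    correct_response: str
    response: str | None = None
    decision: str | None = None
    rt_cycles: int | None = None
    omission: bool = False
    error: bool = False
    condition: str = "first"
    congruent: bool | None = None


def sample_trials(
    design: TaskDesign,
    n: int = 800,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, int]]:
    """Sample ``n`` (cue, digit) trials randomly with replacement.

    Cues are uniform over the four colours (hence tasks equiprobable) and
    digits uniform over the eight digits; there are no sequential
    constraints.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng or np.random.default_rng()
    cue_idx = rng.integers(0, len(design.cues), size=n)
    digit_idx = rng.integers(0, len(design.digits), size=n)
    return [(design.cues[c], design.digits[d]) for c, d in zip(cue_idx, digit_idx)]


def classify_congruency(digit: int, design: TaskDesign) -> str:
    """'congruent' if the parity and magnitude tasks map the digit to the
    same key under the participant's mapping, else 'incongruent'."""
    same = design.correct_response(digit, "parity") == design.correct_response(digit, "magnitude")
    return "congruent" if same else "incongruent"


def classify_transition(prev: TrialRecord | None, cur: TrialRecord) -> str:
    """Ten-way transition label from the previous trial.

    Built from (cue repeat, task repeat, stimulus repeat, correct-response
    repeat); impossible combinations (a task repetition with a repeated
    stimulus but alternated response) signal corrupted records.
    """
    if prev is None:
        return "first"
    cue_rep = prev.cue == cur.cue
    task_rep = prev.task == cur.task
    stim_rep = prev.digit == cur.digit
    resp_rep = prev.correct_response == cur.correct_response
    if cue_rep and not task_rep:
        raise ValueError("corrupted record: cue repetition implies task repetition")
    if task_rep and stim_rep and not resp_rep:
        raise ValueError("corrupted record: repeated stimulus in a repeated task must repeat the response")
    if task_rep:
        prefix = "cue" if cue_rep else "rep"
    else:
        prefix = "alt"
    return f"{prefix}-{'R' if stim_rep else 'A'}{'R' if resp_rep else 'A'}"


def _make_record(index: int, cue: str, digit: int, design: TaskDesign) -> TrialRecord:
    task = design.cue_task(cue)
    return TrialRecord(
        index=index,
        cue=cue,
        digit=digit,
        task=task,
        correct_decision=design.correct_decision(digit, task),
        correct_response=design.correct_response(digit, task),
        congruent=classify_congruency(digit, design) == "congruent",
    )


def run_trial(
    state: NetworkState,
    store: MemoryStore,
    trial: tuple[str, int],
    params: PEPParameters,
    design: TaskDesign,
    rng: np.random.Generator,
    index: int = 0,
    ablate_goal_inertia: bool = False,
) -> TrialRecord:
    """Reference (op-level) implementation of one trial.

    The cue drives its input node for ``cue_lead_cycles`` with cue->goal
    search; the target digit then drives its node for up to
    ``deadline_cycles`` or until a response node crosses threshold
    (otherwise the trial is an omission).  The trial is encoded as a new
    episode, memory is weakened/decayed/maintained, and the response-cue
    interval is run.  The fast driver in :mod:`pepsim._kernels` replicates
    this loop exactly.
    """
    cue, digit = trial
    rec = _make_record(index, cue, digit, design)
    if store.size < N_INSTRUCTIONS:
        raise ValueError("instruction episodes must be encoded before running trials")

    pv = params.to_vector()
    a = state.activations
    state.start_trial()
    ext = np.zeros(N_NODES)
    refresh = params.retrieval_refresh

    def current_retrieval() -> np.ndarray:
        search = schedule_search(
            "in_trial", state.goal_selected, state.decision_made, params
        )
        return episodic_store.retrieve(store, a, search, params)

    # cue phase
    ext[cue_node(cue)] = 1.0
    retrieval = current_retrieval()
    need, since = False, 0
    for _ in range(params.cue_lead_cycles):
        if need or since >= refresh:
            retrieval = current_retrieval()
            since, need = 0, False
        was_sel, was_made = state.goal_selected, state.decision_made
        network_core.step_cycle(state, ext, retrieval, params, rng)
        since += 1
        if state.goal_selected != was_sel or state.decision_made != was_made:
            need = True

    # target phase (the cue stays on with the target)
    state.advance_phase(TrialPhase.TARGET_SEARCH)
    ext[digit_node(digit)] = 1.0
    need, since = True, 0
    response = None
    rt = None
    afforded = [
        12 + j for j in DIGIT_DECISIONS[list(DIGITS).index(digit)]
    ]  # the digit's own two decision nodes
    latched_decision = -1
    for c in range(params.deadline_cycles):
        if need or since >= (3 if state.decision_made else refresh):
            retrieval = current_retrieval()
            since, need = 0, False
        was_sel = state.goal_selected
        network_core.step_cycle(state, ext, retrieval, params, rng)
        since += 1
        if state.goal_selected != was_sel:
            need = True
        # decision latch: requires target-consistent evidence on the
        # dimension the system is set for -- the presented digit's decision
        # belonging to the held goal (either afforded decision if no goal
        # has been committed yet)
        if not state.decision_made:
            if state.held_goal in (0, 1):
                cand = afforded[state.held_goal]
            else:
                cand = max(afforded, key=lambda j: a[j])
            if a[cand] >= params.decision_threshold:
                state.decision_made = True
                latched_decision = cand - 12
                need = True
        response = network_core.detect_response(state, params.response_threshold)
        if response is not None:
            rt = c + 1
            break

    dec_idx = latched_decision if latched_decision >= 0 else int(np.argmax(a[12:16]))
    goal_idx = state.held_goal if state.held_goal >= 0 else int(np.argmax(a[18:20]))
    rec.decision = DECISIONS[dec_idx]
    rec.response = response
    rec.rt_cycles = rt
    rec.omission = response is None
    rec.error = (response is not None) and response != rec.correct_response

    # encode / weaken / decay / maintain
    search = schedule_search("in_trial", state.goal_selected, state.decision_made, params)
    episodic_store.weaken_on_retrieval(store, a, search, params)
    episodic_store.encode_trial_episode(
        store,
        cue=cue,
        digit=digit,
        goal=GOALS[goal_idx],
        decision=rec.decision,
        response=response,
        params=params,
    )
    episodic_store.decay_episodes(store, params)
    episodic_store.maintain_instructions(store, params, error_occurred=rec.error or rec.omission)

    # response-cue interval
    state.advance_phase(TrialPhase.POST_TRIAL)
    network_core.run_intertrial_interval(state, params, ablate_goal_inertia)
    return rec


def run_participant(
    params: PEPParameters,
    design: TaskDesign,
    seed: int,
    n_trials: int = 800,
    ablate_goal_inertia: bool = False,
    engine: str = "fast",
    trials: list[tuple[str, int]] | None = None,
    return_store: bool = False,
) -> list[TrialRecord]:
    """Simulate one participant: instruction encoding then ``n_trials``
    trials with a persistent store and network state.

    ``engine='fast'`` uses the compiled whole-sequence driver;
    ``engine='reference'`` loops over the op-level API (identical
    numerics, used in tests and for inspection).
    """
    rng = np.random.default_rng(seed)
    if trials is None:
        trials = sample_trials(design, n_trials, rng)
    records = [_make_record(i, c, d, design) for i, (c, d) in enumerate(trials)]

    if engine == "reference":
        store = MemoryStore()
        episodic_store.encode_instructions(store, design)
        state = init_network()
        out = []
        for i, trial in enumerate(trials):
            out.append(
                run_trial(
                    state, store, trial, params, design, rng,
                    index=i, ablate_goal_inertia=ablate_goal_inertia,
                )
            )
        records = out
    elif engine == "fast":
        n = len(trials)
        store = MemoryStore(capacity=N_INSTRUCTIONS + n)
        episodic_store.encode_instructions(store, design)
        cue_nodes = np.array([cue_node(c) for c, _ in trials], dtype=np.int64)
        digit_nodes = np.array([digit_node(d) for _, d in trials], dtype=np.int64)
        correct_resp = np.array(
            [RESPONSES.index(r.correct_response) for r in records], dtype=np.int64
        )
        out_resp = np.empty(n, dtype=np.int64)
        out_rt = np.empty(n, dtype=np.int64)
        out_dec = np.empty(n, dtype=np.int64)
        out_goal = np.empty(n, dtype=np.int64)
        n_epi = _kernels.run_participant_core(
            cue_nodes, digit_nodes, correct_resp,
            params.to_vector(), ablate_goal_inertia, rng,
            store.weights, store.strengths, N_INSTRUCTIONS,
            out_resp, out_rt, out_dec, out_goal,
        )
        store.size = int(n_epi)
        for i, rec in enumerate(records):
            rec.decision = DECISIONS[out_dec[i]]
            rec.omission = out_resp[i] < 0
            rec.response = None if rec.omission else RESPONSES[out_resp[i]]
            rec.rt_cycles = None if rec.omission else int(out_rt[i])
            rec.error = (not rec.omission) and rec.response != rec.correct_response
    else:
        raise ValueError(f"unknown engine {engine!r}")

    prev = None
    for rec in records:
        rec.condition = classify_transition(prev, rec)
        prev = rec
    if return_store:
        return records, store
    return records


def records_to_frame(records: list[TrialRecord], participant: int = 0) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "participant": participant,
            "trial": [r.index for r in records],
            "cue": [r.cue for r in records],
            "digit": [r.digit for r in records],
            "task": [r.task for r in records],
            "condition": [r.condition for r in records],
            "congruency": ["congruent" if r.congruent else "incongruent" for r in records],
            "response": [r.response if r.response is not None else "" for r in records],
            "correct": [int(not r.error and not r.omission) for r in records],
            "omission": [int(r.omission) for r in records],
            "rt_cycles": [r.rt_cycles if r.rt_cycles is not None else np.nan for r in records],
        }
    )
    return df


def run_experiment(
    params: PEPParameters,
    n_participants: int = 50,
    base_seed: int = 0,
    ablate_goal_inertia: bool = False,
    n_trials: int = 800,
    engine: str = "fast",
) -> pd.DataFrame:
    """Run a sample of simulated participants and concatenate their trials.

    Participant ``i`` uses seed ``base_seed + i`` and the odd/even key
    counterbalance alternates with participant parity.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    frames = []
    for i in range(n_participants):
        design = TaskDesign(odd_left=(i % 2 == 0))
        records = run_participant(
            params, design, seed=base_seed + i, n_trials=n_trials,
            ablate_goal_inertia=ablate_goal_inertia, engine=engine,
        )
        frames.append(records_to_frame(records, participant=i))
    return pd.concat(frames, ignore_index=True)


def code_conditions(df: pd.DataFrame, design_by_participant: bool = True) -> pd.DataFrame:
    """Condition-code an externally produced trial-level table.

    Expects columns participant, trial, cue, digit and (optionally) an
    odd_left column; fills in task, condition and congruency using the
    same taxonomy as the simulator.
    """
    out = []
    for pid, grp in df.groupby("participant", sort=True):
        grp = grp.sort_values("trial")
        odd_left = bool(grp["odd_left"].iloc[0]) if "odd_left" in grp else (int(pid) % 2 == 0)
        design = TaskDesign(odd_left=odd_left)
        prev = None
        for _, row in grp.iterrows():
            rec = _make_record(int(row["trial"]), str(row["cue"]), int(row["digit"]), design)
            rec.condition = classify_transition(prev, rec)
            prev = rec
            out.append(
                {
                    "participant": pid,
                    "trial": rec.index,
                    "cue": rec.cue,
                    "digit": rec.digit,
                    "task": rec.task,
                    "condition": rec.condition,
                    "congruency": "congruent" if rec.congruent else "incongruent",
                }
            )
    return pd.DataFrame(out)


@dataclass
class ConditionSummary:
    """Per-condition means plus overall omission statistics.

    ``table`` has one row per condition (and one per condition x congruency
    cell in ``by_congruency``): mean cycle time over correct non-omitted
    trials, error percentage over non-omitted trials, and trial counts.
    First trials are excluded from all transition-conditioned statistics;
    omissions are excluded from both RT and error denominators.
    """

    table: pd.DataFrame
    by_congruency: pd.DataFrame
    congruency: pd.DataFrame
    omission_pct: float
    n_trials: int

    def _row(self, condition: str) -> pd.Series:
        """Look up a condition row; ``'cue-AR/incongruent'`` addresses a
        condition x congruency cell."""
        if "/" in condition:
            cond, cong = condition.split("/", 1)
            row = self.by_congruency.loc[
                (self.by_congruency["condition"] == cond)
                & (self.by_congruency["congruency"] == cong)
            ]
        else:
            row = self.table.loc[self.table["condition"] == condition]
        if row.empty:
            raise KeyError(f"condition {condition!r} empty")
        return row.iloc[0]

    def rt(self, condition: str) -> float:
        row = self._row(condition)
        if not np.isfinite(row["mean_rt"]):
            raise KeyError(f"condition {condition!r} has no correct responses")
        return float(row["mean_rt"])

    def error_pct(self, condition: str) -> float:
        return float(self._row(condition)["error_pct"])


def summarize(df: pd.DataFrame) -> ConditionSummary:
    """Condition means: RT over correct non-omitted trials, error rates
    over non-omitted trials, omissions excluded from both."""
    if df.empty:
        raise ValueError("empty dataset")
    omission_pct = 100.0 * df["omission"].mean()
    coded = df[df["condition"] != "first"]
    nonom = coded[coded["omission"] == 0]
    if nonom.empty:
        raise ValueError("no non-omitted trials to summarize")

    def _agg(group_cols: list[str], frame: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for key, grp in frame.groupby(group_cols, sort=False):
            key = (key,) if not isinstance(key, tuple) else key
            correct = grp[grp["correct"] == 1]
            rows.append(
                dict(zip(group_cols, key))
                | {
                    "mean_rt": float(correct["rt_cycles"].mean()) if len(correct) else np.nan,
                    "error_pct": 100.0 * (1.0 - grp["correct"].mean()),
                    "n": int(len(grp)),
                }
            )
        return pd.DataFrame(rows)

    table = _agg(["condition"], nonom)
    table["condition"] = pd.Categorical(table["condition"], categories=CONDITIONS, ordered=True)
    table = table.sort_values("condition").reset_index(drop=True)
    table["condition"] = table["condition"].astype(str)
    missing = set(CONDITIONS) - set(table["condition"])
    if missing:
        raise ValueError(f"empty conditions in dataset: {sorted(missing)}")

    by_cc = _agg(["condition", "congruency"], nonom)
    cong = _agg(["congruency"], nonom)
    return ConditionSummary(
        table=table,
        by_congruency=by_cc.sort_values(["condition", "congruency"]).reset_index(drop=True),
        congruency=cong.sort_values("congruency").reset_index(drop=True),
        omission_pct=float(omission_pct),
        n_trials=int(len(df)),
    )


def compute_effects(summary: ConditionSummary, df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Derived task-switching effects, in cycles (RT based).

    Pooled transition-type means are unweighted means of their condition
    means; where a trial-weighted aggregate is also conventional both are
    reported (suffix ``_weighted``), computed from the trial-level data.
    """
    rt = {c: summary.rt(c) for c in CONDITIONS}
    cue_pool = np.mean([rt["cue-RR"], rt["cue-AR"], rt["cue-AA"]])
    rep_pool = np.mean([rt["rep-RR"], rt["rep-AR"], rt["rep-AA"]])
    alt_pool = np.mean([rt["alt-RR"], rt["alt-RA"], rt["alt-AR"], rt["alt-AA"]])
    taskrep_pool = np.mean([cue_pool, rep_pool])

    effects = {
        "cue_pooled_rt": cue_pool,
        "rep_pooled_rt": rep_pool,
        "alt_pooled_rt": alt_pool,
        "switch_cost": alt_pool - taskrep_pool,
        "true_switch_cost": rt["alt-AA"] - rt["rep-AA"],
        "cue_repetition_benefit": rep_pool - cue_pool,
        "response_repetition_benefit_taskrep": np.mean(
            [rt["cue-RR"], rt["cue-AR"], rt["rep-RR"], rt["rep-AR"]]
        )
        - np.mean([rt["cue-AA"], rt["rep-AA"]]),
        "response_repetition_benefit_alt": np.mean([rt["alt-RA"], rt["alt-AA"]])
        - np.mean([rt["alt-RR"], rt["alt-AR"]]),
    }

    cong_tab = summary.congruency.set_index("congruency")
    if {"congruent", "incongruent"} <= set(cong_tab.index):
        effects["congruency_effect"] = float(
            cong_tab.loc["incongruent", "mean_rt"] - cong_tab.loc["congruent", "mean_rt"]
        )

    if df is not None:
        ok = df[(df["condition"] != "first") & (df["omission"] == 0) & (df["correct"] == 1)]
        is_alt = ok["condition"].str.startswith("alt")
        alt_w = ok.loc[is_alt, "rt_cycles"].mean()
        taskrep_w = ok.loc[~is_alt, "rt_cycles"].mean()
        cue_w = ok.loc[ok["condition"].str.startswith("cue"), "rt_cycles"].mean()
        rep_w = ok.loc[ok["condition"].str.startswith("rep"), "rt_cycles"].mean()
        effects["switch_cost_weighted"] = float(alt_w - taskrep_w)
        effects["cue_repetition_benefit_weighted"] = float(rep_w - cue_w)
        resp_rep = ok["condition"].str.endswith("R")
        tr = ~is_alt
        effects["response_repetition_benefit_taskrep_weighted"] = float(
            ok.loc[tr & ~resp_rep, "rt_cycles"].mean() - ok.loc[tr & resp_rep, "rt_cycles"].mean()
        )
        effects["response_repetition_benefit_alt_weighted"] = float(
            ok.loc[is_alt & ~resp_rep, "rt_cycles"].mean()
            - ok.loc[is_alt & resp_rep, "rt_cycles"].mean()
        )
        # congruency x switch interaction
        cong = ok["congruency"] == "congruent"
        sc_cong = ok.loc[is_alt & cong, "rt_cycles"].mean() - ok.loc[tr & cong, "rt_cycles"].mean()
        sc_incong = (
            ok.loc[is_alt & ~cong, "rt_cycles"].mean() - ok.loc[tr & ~cong, "rt_cycles"].mean()
        )
        effects["switch_cost_congruent"] = float(sc_cong)
        effects["switch_cost_incongruent"] = float(sc_incong)
        effects["congruency_switch_interaction"] = float(sc_incong - sc_cong)

    return pd.DataFrame({"effect": list(effects), "cycles": [float(v) for v in effects.values()]})
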