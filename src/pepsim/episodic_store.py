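"""The exemplar memory store.

Every experienced (or instructed) event becomes one episode: a sparse
vector of connection weights over the 20 network nodes plus a decayable
retrieval strength.  Retrieval is similarity-based, recency-weighted (via
retrieval-induced weakening of older episodes) and proportional within
each layer, and is scheduled in two stages over a trial: cue->goal search
first, then target/decision/response search once a goal is selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .layout import (
    CUES,
    DECISIONS,
    DIGITS,
    GOALS,
    N_NODES,
    RESPONSES,
    cue_node,
    decision_node,
    digit_node,
    goal_node,
    response_node,
)
from .params import PEPParameters

__all__ = [
    "Episode",
    "MemoryStore",
    "SearchStrengths",
    "encode_instructions",
    "encode_trial_episode",
    "retrieve",
    "weaken_on_retrieval",
    "decay_episodes",
    "maintain_instructions",
    "schedule_search",
]

N_INSTRUCTIONS = 8

_NODE_NAMES = (
    [f"cue:{c}" for c in CUES]
    + [f"digit:{d}" for d in DIGITS]
    + [f"decision:{d}" for d in DECISIONS]
    + [f"response:{r}" for r in RESPONSES]
    + [f"goal:{g}" for g in GOALS]
)


@dataclass(frozen=True)
class Episode:
    """Read-only view of one memory trace."""

    trial_index: int
    is_instruction: bool
    strength: float
    bound_nodes: dict[str, float]


@dataclass(frozen=True)
class SearchStrengths:
    """Stage-dependent memory search strengths (all nonnegative)."""

    cue_to_goal: float
    target_to_decision: float
    decision_to_response: float
    response_coding: float

    def __post_init__(self) -> None:
        for f in ("cue_to_goal", "target_to_decision", "decision_to_response", "response_coding"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be nonnegative")


class MemoryStore:
    """Ordered collection of episodes backed by preallocated arrays.

    The backing arrays (``weights``, ``strengths``) are shared with the
    compiled kernels; ``size`` episodes are live.  Instruction episodes
    always occupy the first :data:`N_INSTRUCTIONS` rows.
    """

    def __init__(self, capacity: int = 16) -> None:
        self.weights = np.zeros((capacity, N_NODES))
        self.strengths = np.zeros(capacity)
        self.is_instruction = np.zeros(capacity, dtype=bool)
        self.size = 0

    def _ensure_capacity(self, n: int) -> None:
        if n <= self.weights.shape[0]:
            return
        new_cap = max(n, 2 * self.weights.shape[0])
        for name in ("weights", "strengths", "is_instruction"):
            old = getattr(self, name)
            shape = (new_cap,) + old.shape[1:]
            new = np.zeros(shape, dtype=old.dtype)
            new[: old.shape[0]] = old
            setattr(self, name, new)

    def add(self, weights: np.ndarray, strength: float = 1.0, instruction: bool = False) -> int:
        self._ensure_capacity(self.size + 1)
        self.weights[self.size] = weights
        self.strengths[self.size] = strength
        self.is_instruction[self.size] = instruction
        self.size += 1
        return self.size - 1

    @property
    def n_instructions(self) -> int:
        return int(self.is_instruction[: self.size].sum())

    def episode(self, i: int) -> Episode:
        if not 0 <= i < self.size:
            raise IndexError(i)
        bound = {
            _NODE_NAMES[k]: float(w)
            for k, w in enumerate(self.weights[i])
            if w != 0.0
        }
        return Episode(
            trial_index=i,
            is_instruction=bool(self.is_instruction[i]),
            strength=float(self.strengths[i]),
            bound_nodes=bound,
        )

    def __len__(self) -> int:
        return self.size

    def __iter__(self):
        return (self.episode(i) for i in range(self.size))

    def to_frame(self) -> pd.DataFrame:
        """Debug dump: one row per episode (CSV-friendly)."""
        rows = []
        for i in range(self.size):
            ep = self.episode(i)
            rows.append(
                {
                    "trial_index": ep.trial_index,
                    "is_instruction": ep.is_instruction,
                    "strength": ep.strength,
                    "bound": ";".join(f"{k}={v:g}" for k, v in sorted(ep.bound_nodes.items())),
                }
            )
        return pd.DataFrame(rows, columns=["trial_index", "is_instruction", "strength", "bound"])


def encode_instructions(store: MemoryStore, design) -> MemoryStore:
    """Encode the 8 instruction episodes: 4 cue-goal and 4 decision-response.

    Blue and red are instructed to cue parity, green and yellow magnitude;
    lt5/gt5 always map to left/right while the odd/even key assignment
    follows the design's counterbalance flag.
    """
    if store.size != 0:
        raise ValueError("instructions must be encoded into an empty store")
    for cue, goal in zip(CUES, ("parity", "parity", "magnitude", "magnitude")):
        w = np.zeros(N_NODES)
        w[cue_node(cue)] = 1.0
        w[goal_node(goal)] = 1.0
        store.add(w, 1.0, instruction=True)
    for decision in DECISIONS:
        w = np.zeros(N_NODES)
        w[decision_node(decision)] = 1.0
        w[response_node(design.decision_response(decision))] = 1.0
        store.add(w, 1.0, instruction=True)
    return store


def encode_trial_episode(
    store: MemoryStore,
    *,
    cue: str,
    digit: int,
    goal: str,
    decision: str,
    response: str | None,
    params: PEPParameters,
) -> MemoryStore:
    """Append one trace binding the trial's cue, digit, goal, decision and
    response; the unchosen response receives the negative episode weight.
    Omission trials (``response=None``) are encoded with no response
    binding."""
    w = np.zeros(N_NODES)
    w[cue_node(cue)] = 1.0
    w[digit_node(digit)] = 1.0
    w[goal_node(goal)] = 1.0
    w[decision_node(decision)] = 1.0
    if response is not None:
        w[response_node(response)] = 1.0
        other = RESPONSES[1 - RESPONSES.index(response)]
        w[response_node(other)] = params.negative_weights_episode
    store.add(w, 1.0, instruction=False)
    return store


def _probe_weight_vector(search: SearchStrengths, goal_weight: float = 1.0) -> np.ndarray:
    pw = np.empty(N_NODES)
    pw[0:4] = search.cue_to_goal
    pw[4:12] = search.target_to_decision
    pw[12:16] = search.decision_to_response
    pw[16:18] = search.response_coding
    pw[18:20] = goal_weight
    return pw


def retrieve(
    store: MemoryStore,
    probe: np.ndarray,
    search: SearchStrengths,
    params: PEPParameters | None = None,
) -> np.ndarray:
    """Per-node retrieval drive for a probe activation vector.

    Each episode contributes drive to its bound nodes in proportion to
    (similarity x strength x search strength); within each layer the summed
    positive drive is normalized to a bounded budget so competing options
    share it (proportional retrieval).  An empty store yields zero drive.
    """
    probe = np.asarray(probe, dtype=float)
    if probe.shape != (N_NODES,):
        raise ValueError("probe must be a length-20 activation vector")
    pw = _probe_weight_vector(search)
    par = params or PEPParameters()
    return _kernels.compute_retrieval(
        probe, store.weights, store.strengths, store.size, pw,
        par.goal_search_weight, par.stimulus_response_weight,
    )


def episode_similarities(store: MemoryStore, probe: np.ndarray, search: SearchStrengths) -> np.ndarray:
    """Rectified search-weighted similarity of every episode to the probe."""
    pw = _probe_weight_vector(search)
    return _kernels.episode_similarities(
        np.asarray(probe, dtype=float), store.weights, store.strengths, store.size, pw
    )


def weaken_on_retrieval(
    store: MemoryStore,
    probe: np.ndarray,
    search: SearchStrengths,
    params: PEPParameters,
) -> MemoryStore:
    """Weaken existing episodes in proportion to their similarity to the
    just-processed event (recency weighting: the most similar old episodes
    lose the most strength)."""
    pw = _probe_weight_vector(search)
    _kernels.weaken_episodes(
        store.weights,
        store.strengths,
        store.size,
        np.asarray(probe, dtype=float),
        pw,
        params.loss_episode_connection,
        params.weaken_saturation,
    )
    return store


def decay_episodes(store: MemoryStore, params: PEPParameters) -> MemoryStore:
    """Multiplicative per-trial strength decay of every episode."""
    _kernels.decay_episode_strengths(store.strengths, store.size, params.decay_episode)
    return store


def maintain_instructions(
    store: MemoryStore,
    params: PEPParameters,
    error_occurred: bool = False,
) -> MemoryStore:
    """Restore instruction episodes toward their initial strength (1.0).

    By default runs every trial; with ``params.restore_after_errors_only``
    restoration is triggered only by errors/omissions.
    """
    if params.restore_after_errors_only and not error_occurred:
        return store
    _kernels.restore_instruction_strengths(
        store.strengths, N_INSTRUCTIONS if store.size >= N_INSTRUCTIONS else store.size,
        params.restore_instruction_episode,
    )
    return store


def schedule_search(
    phase: str,
    goal_selected: bool,
    decision_made: bool,
    params: PEPParameters,
) -> SearchStrengths:
    """Two-stage search-strength schedule.

    Cue->goal search is strong at trial start; once a goal is selected it
    is damped by ``search_goal_after_selected`` while the target, decision
    and response searches come up to full strength (before that they sit at
    a damped base).  After a decision the stimulus search is additionally
    scaled by ``search_stimulus_after_decision``; post trial everything is
    damped by ``post_trial_damp``.
    """
    if decision_made and not goal_selected:
        raise ValueError("inconsistent flags: decision_made requires goal_selected")
    damp = params.search_goal_after_selected
    cs = params.strength_cue_search
    ts = params.strength_target_search
    ds = params.strength_decision_search
    rs = params.strength_response_search
    if goal_selected:
        cs *= damp
    else:
        ts *= damp
        ds *= damp
    if decision_made:
        ts *= params.search_stimulus_after_decision
    else:
        rs *= damp
    if phase == "post_trial":
        pd_ = params.post_trial_damp
        cs, ts, ds, rs = cs * pd_, ts * pd_, ds * pd_, rs * pd_
    return SearchStrengths(cs, ts, ds, rs)
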