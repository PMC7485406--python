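"""Node layers and per-cycle activation dynamics.

This module exposes the cycle-level network operations as an object API:
initialisation, a single processing cycle (roughly one simulated
millisecond), response-threshold detection, and the response-cue interval.
The arithmetic is delegated to the compiled kernels in
:mod:`pepsim._kernels`, which the fast per-participant driver shares, so
both paths are numerically identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from . import _kernels
from .layout import (
    DECISION_SLICE,
    GOAL_SLICE,
    N_NODES,
    NodeLayout,
    RESPONSE_SLICE,
    RESPONSES,
)
from .params import PEPParameters

__all__ = [
    "TrialPhase",
    "NetworkState",
    "init_network",
    "step_cycle",
    "detect_response",
    "run_intertrial_interval",
]


class TrialPhase(str, Enum):
    """Forward-only phase of a trial."""

    CUE_SEARCH = "cue_search"
    TARGET_SEARCH = "target_search"
    POST_TRIAL = "post_trial"


_PHASE_ORDER = [TrialPhase.CUE_SEARCH, TrialPhase.TARGET_SEARCH, TrialPhase.POST_TRIAL]


@dataclass
class NetworkState:
    """Activations plus the trial-stage bookkeeping of the network.

    ``goal_selected`` latches once a goal node has stayed above
    ``threshold_goal`` for ``goal_confirm_cycles`` consecutive cycles (the
    winner becomes the held goal); ``decision_made`` latches when the trial
    driver sees target-consistent evidence cross ``decision_threshold``.
    Both gate the staged memory-search scheduling.
    """

    activations: np.ndarray = field(default_factory=lambda: np.zeros(N_NODES))
    phase: TrialPhase = TrialPhase.CUE_SEARCH
    goal_selected: bool = False
    decision_made: bool = False
    held_goal: int = -1  # index of the actively maintained goal (-1: none)
    goal_confirm_count: int = 0
    cycle_counter: int = 0

    def decision_sensitivities(self, params: PEPParameters) -> np.ndarray:
        """Current input sensitivity of each decision node."""
        from .layout import DECISION_GOAL

        goals = self.activations[GOAL_SLICE]
        return params.preparation_base + params.weight_goal_decision * goals[DECISION_GOAL]

    def advance_phase(self, phase: TrialPhase) -> None:
        if _PHASE_ORDER.index(phase) < _PHASE_ORDER.index(self.phase):
            raise ValueError(f"phase may only move forward, not {self.phase} -> {phase}")
        self.phase = phase

    def start_trial(self) -> None:
        self.phase = TrialPhase.CUE_SEARCH
        self.goal_selected = False
        self.decision_made = False
        self.held_goal = -1
        self.goal_confirm_count = 0


def init_network(layout: NodeLayout | None = None, params: PEPParameters | None = None) -> NetworkState:
    """Fresh network: every activation at the rest level (0), cue-search phase."""
    layout = layout or NodeLayout()
    if layout.n_nodes != N_NODES:
        raise ValueError("malformed layout")
    params = params or PEPParameters()
    return NetworkState()


def step_cycle(
    state: NetworkState,
    external_drive: np.ndarray,
    retrieval_drive: np.ndarray,
    params: PEPParameters,
    noise_source: np.random.Generator | None = None,
) -> NetworkState:
    """Advance the network by one processing cycle (in place).

    Driven nodes (positive deterministic drive) move toward their drive at
    ``change_toward_stimulus`` (scaled by decision sensitivity for decision
    nodes); undriven nodes decay (``decay_node``, goals ``decay_goal``);
    layer-specific Gaussian drive noise is added; goal nodes compete
    laterally and sensitize their decisions via ``weight_goal_decision``.
    """
    external_drive = np.asarray(external_drive, dtype=float)
    retrieval_drive = np.asarray(retrieval_drive, dtype=float)
    if not (np.all(np.isfinite(external_drive)) and np.all(np.isfinite(retrieval_drive))):
        raise ValueError("drives must be finite")
    if noise_source is not None:
        eps = noise_source.standard_normal(N_NODES)
    else:
        eps = np.zeros(N_NODES)
    pv = params.to_vector()
    _kernels.step_nodes(
        state.activations,
        retrieval_drive,
        external_drive,
        pv,
        eps,
        state.phase is TrialPhase.TARGET_SEARCH,
        state.decision_made,
        state.held_goal,
    )
    if not np.all(np.isfinite(state.activations)):
        raise FloatingPointError("activation blow-up: non-finite activation")
    state.cycle_counter += 1
    if not state.goal_selected:
        if np.max(state.activations[GOAL_SLICE]) >= params.threshold_goal:
            state.goal_confirm_count += 1
        else:
            state.goal_confirm_count = 0
        if state.goal_confirm_count >= params.goal_confirm_cycles:
            state.goal_selected = True
            state.held_goal = int(np.argmax(state.activations[GOAL_SLICE]))
    # the decision latch needs target-consistent evidence, which only the
    # trial driver can judge (it knows which decisions the digit affords),
    # so it is not advanced here
    return state


def detect_response(state: NetworkState, threshold: float) -> str | None:
    """Response whose activation has crossed ``threshold``, if any.

    If both responses cross on the same cycle the more active one wins;
    exact ties break by fixed layout order (left before right).
    """
    if threshold <= 0:
        raise ValueError("threshold must exceed the rest activation")
    acts = state.activations[RESPONSE_SLICE]
    crossed = acts >= threshold
    if not crossed.any():
        return None
    if crossed.all():
        winner = int(np.argmax(acts))  # argmax keeps the first (left) on ties
    else:
        winner = int(np.flatnonzero(crossed)[0])
    return RESPONSES[winner]


def run_intertrial_interval(
    state: NetworkState,
    params: PEPParameters,
    ablate_goal_inertia: bool = False,
) -> NetworkState:
    """Run the response-cue interval: ``rci_cycles`` of pure decay.

    With ``ablate_goal_inertia`` the two goal activations are set to their
    arithmetic mean on every cycle of the interval, removing any carryover
    asymmetry between the previous and the upcoming task goal.  The phase
    is reset to cue search afterwards.
    """
    pv = params.to_vector()
    for _ in range(params.rci_cycles):
        _kernels.rci_decay_cycle(state.activations, pv, ablate_goal_inertia)
    state.cycle_counter += params.rci_cycles
    state.start_trial()
    return state
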