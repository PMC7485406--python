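"""Model parameters.

The tunable parameters carry the published "Original" values of the cued
task-switching parameterization as defaults, together with their a-priori
ranges (used both for validation and as mutation bounds during evolutionary
fitting).  A handful of quantities are fixed constants of the paradigm or of
the model definition (cue lead, response deadline, response-cue interval,
response threshold, ...) and are not part of the fitted parameter space.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = ["PEPParameters", "PARAM_RANGES", "load_params", "save_params"]

#: a-priori range per tunable parameter; ``None`` marks an unbounded end.
PARAM_RANGES: dict[str, tuple[float | None, float | None]] = {
    "change_toward_stimulus": (0.0, 1.0),
    "strength_target_search": (0.0, None),
    "strength_cue_search": (0.0, None),
    "noise_input": (0.0, None),
    "strength_decision_search": (0.0, None),
    "noise_decision": (0.0, None),
    "preparation_base": (0.0, None),
    "strength_response_search": (0.0, None),
    "noise_response": (0.0, None),
    "decay_goal": (0.0, 1.0),
    "threshold_goal": (0.0, 1.0),
    "strength_goal": (0.0, None),
    "noise_goal": (0.0, None),
    "weight_goal_decision": (0.0, None),
    "decay_node": (0.0, 1.0),
    "decay_episode": (0.0, 1.0),
    "loss_episode_connection": (0.0, 1.0),
    "negative_weights_episode": (None, 0.0),
    "restore_instruction_episode": (0.0, 1.0),
    "search_goal_after_selected": (0.0, 1.0),
    "search_stimulus_after_decision": (0.0, 1.0),
    "search_response_coding": (0.0, None),
}

# Indices of the packed parameter/constant vector consumed by the kernels.
P_CHANGE = 0
P_STRENGTH_TARGET = 1
P_STRENGTH_CUE = 2
P_NOISE_INPUT = 3
P_STRENGTH_DECISION = 4
P_NOISE_DECISION = 5
P_PREP_BASE = 6
P_STRENGTH_RESPONSE = 7
P_NOISE_RESPONSE = 8
P_DECAY_GOAL = 9
P_THRESHOLD_GOAL = 10
P_STRENGTH_GOAL = 11
P_NOISE_GOAL = 12
P_WEIGHT_GOAL_DECISION = 13
P_DECAY_NODE = 14
P_DECAY_EPISODE = 15
P_LOSS_EPISODE = 16
P_NEGATIVE_WEIGHTS = 17
P_RESTORE_INSTRUCTION = 18
P_SEARCH_GOAL_AFTER = 19
P_SEARCH_STIM_AFTER = 20
P_RESPONSE_CODING = 21
P_RESPONSE_THRESHOLD = 22
P_DECISION_THRESHOLD = 23
P_GOAL_COMPETITION = 24
P_HARDWIRED_WEIGHT = 25
P_POST_TRIAL_DAMP = 26
P_CUE_LEAD = 27
P_DEADLINE = 28
P_RCI = 29
P_RETRIEVAL_REFRESH = 30
P_RESTORE_ERRORS_ONLY = 31
P_RESPONSE_COMPETITION = 32
P_GOAL_CONFIRM = 33
P_GOAL_SEARCH_WEIGHT = 34
P_RATE_SCALE = 35
P_SR_WEIGHT = 36
P_WEAKEN_SAT = 37
P_RESP_GAIN = 38
N_PACKED = 39

_TUNABLE_ORDER = list(PARAM_RANGES)


@dataclass
class PEPParameters:
    """Full parameter set of the episodic task-switching simulator.

    Tunable parameters (with their fitted a-priori ranges) come first;
    the remaining fields are fixed constants of the paradigm and of the
    model definition.
    """

    # -- tunables ----------------------------------------------------------
    change_toward_stimulus: float = 0.034
    strength_target_search: float = 3.4
    strength_cue_search: float = 1.14
    noise_input: float = 0.012
    strength_decision_search: float = 3.2
    noise_decision: float = 0.25
    preparation_base: float = 0.4
    strength_response_search: float = 3.5
    noise_response: float = 0.0026
    decay_goal: float = 0.007
    threshold_goal: float = 0.1
    strength_goal: float = 1.37
    noise_goal: float = 0.66
    weight_goal_decision: float = 0.88
    decay_node: float = 0.086
    decay_episode: float = 0.0022
    loss_episode_connection: float = 0.045
    negative_weights_episode: float = -0.11
    restore_instruction_episode: float = 0.285
    search_goal_after_selected: float = 0.1
    search_stimulus_after_decision: float = 0.95
    search_response_coding: float = 4.0

    # -- fixed paradigm constants -----------------------------------------
    cue_lead_cycles: int = 200
    deadline_cycles: int = 3000
    rci_cycles: int = 500

    # -- fixed model-definition constants ---------------------------------
    # A response is emitted when a response node crosses this activation.
    response_threshold: float = 0.85
    # A decision counts as made (gating the late search stage) here.
    decision_threshold: float = 0.55
    # Lateral inhibition weight between the two goal nodes.
    goal_competition: float = 1.0
    # Lateral inhibition between the two response accumulators.
    response_competition: float = 1.5
    # Goal selection requires this many consecutive cycles above
    # threshold_goal, so noise spikes cannot commit the wrong task.
    goal_confirm_cycles: int = 20
    # Participation of goal-node activation in memory search: how strongly
    # the current task goal favours task-consistent episodes at retrieval.
    goal_search_weight: float = 1.0
    # Decision, response and goal nodes integrate this much slower than
    # input nodes: central evidence accumulation is sluggish (a ~250-cycle
    # time constant) relative to stimulus encoding, which is what puts
    # simulated response times in the hundreds of cycles and lets
    # preparation differences survive into the target period.
    central_rate_scale: float = 0.12
    # Weight of the stimulus (digit) probe in response-directed memory
    # search, relative to the decision probe: stimulus-response binding is
    # a bias on response retrieval rather than its main route.
    stimulus_response_weight: float = 0.5
    # Retrieval-induced weakening saturates at this multiple of the nominal
    # loss rate for highly similar episodes; larger values mean repeated
    # events erode their older duplicates faster (stronger recency).
    weaken_saturation: float = 8.0
    # Gain from normalized response retrieval to response-accumulator
    # drive; sized so the winning drive sits near the response threshold
    # and crossing times stay sensitive to the retrieval mix.
    response_gain: float = 0.45
    # Hardwired digit->decision connection weight (pre-existing knowledge).
    hardwired_weight: float = 0.55
    # Damping applied to every memory search outside the active trial.
    post_trial_damp: float = 0.1
    # Retrieval drive is refreshed every this many cycles (central
    # activations move with a ~600-cycle time constant, so a few cycles of
    # staleness is negligible but cuts simulation cost several-fold);
    # during the response race the drive refreshes every 3 cycles.
    retrieval_refresh: int = 8
    # Restore instruction memories on every trial (False) or only after an
    # error (True).
    restore_after_errors_only: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        for name, (lo, hi) in PARAM_RANGES.items():
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
            if lo is not None and value < lo:
                raise ValueError(f"{name}={value} below a-priori range (min {lo})")
            if hi is not None and value > hi:
                raise ValueError(f"{name}={value} above a-priori range (max {hi})")
        if self.response_threshold <= 0:
            raise ValueError("response_threshold must exceed the rest activation (0)")
        for name in ("cue_lead_cycles", "deadline_cycles", "rci_cycles", "retrieval_refresh"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive integer")

    # -- conversions -------------------------------------------------------
    def tunables(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in _TUNABLE_ORDER}

    def replace(self, **overrides) -> "PEPParameters":
        return dataclasses.replace(self, **overrides)

    def to_vector(self) -> np.ndarray:
        """Pack parameters and constants into the flat kernel vector."""
        v = np.empty(N_PACKED)
        for i, name in enumerate(_TUNABLE_ORDER):
            v[i] = getattr(self, name)
        v[P_RESPONSE_THRESHOLD] = self.response_threshold
        v[P_DECISION_THRESHOLD] = self.decision_threshold
        v[P_GOAL_COMPETITION] = self.goal_competition
        v[P_HARDWIRED_WEIGHT] = self.hardwired_weight
        v[P_POST_TRIAL_DAMP] = self.post_trial_damp
        v[P_CUE_LEAD] = float(self.cue_lead_cycles)
        v[P_DEADLINE] = float(self.deadline_cycles)
        v[P_RCI] = float(self.rci_cycles)
        v[P_RETRIEVAL_REFRESH] = float(self.retrieval_refresh)
        v[P_RESTORE_ERRORS_ONLY] = 1.0 if self.restore_after_errors_only else 0.0
        v[P_RESPONSE_COMPETITION] = self.response_competition
        v[P_GOAL_CONFIRM] = float(self.goal_confirm_cycles)
        v[P_GOAL_SEARCH_WEIGHT] = self.goal_search_weight
        v[P_RATE_SCALE] = self.central_rate_scale
        v[P_SR_WEIGHT] = self.stimulus_response_weight
        v[P_WEAKEN_SAT] = self.weaken_saturation
        v[P_RESP_GAIN] = self.response_gain
        return v

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def load_params(path: str | Path | None = None, **overrides) -> PEPParameters:
    """Load a parameter file (flat YAML or JSON) on top of the defaults.

    Keys must be parameter names of :class:`PEPParameters`; unknown keys are
    rejected, and tunables are validated against their a-priori ranges.
    An empty file (or ``None``) yields the default parameterization.
    """
    data: dict = {}
    if path is not None:
        path = Path(path)
        text = path.read_text()
        if text.strip():
            if path.suffix.lower() == ".json":
                data = json.loads(text)
            else:
                data = yaml.safe_load(text)
            if data is None:
                data = {}
            if not isinstance(data, dict):
                raise ValueError(f"parameter file {path} must contain a flat mapping")
    data.update(overrides)
    known = {f.name for f in dataclasses.fields(PEPParameters)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return PEPParameters(**data)


def save_params(params: PEPParameters, path: str | Path) -> None:
    """Write the full parameter set as flat YAML."""
    d = {k: (float(v) if isinstance(v, (int, float)) and not isinstance(v, bool) else v)
         for k, v in params.to_dict().items()}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
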