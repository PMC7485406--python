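"""Node layout of the task-switching network.

The network contains five layers, flattened into a single activation vector
of 20 nodes in a fixed order:

====================  =======  ==========================================
layer                 indices  identities
====================  =======  ==========================================
cue inputs            0-3      blue, red, green, yellow
digit inputs          4-11     1, 2, 3, 4, 6, 7, 8, 9  (no 5)
decisions             12-15    odd, even, lt5, gt5
responses             16-17    left, right
goals                 18-19    parity, magnitude
====================  =======  ==========================================

Blue and red cue the parity task; green and yellow cue the magnitude task.
Each decision belongs to exactly one goal (odd/even -> parity,
lt5/gt5 -> magnitude) while the two response keys are shared between goals.
Digit-to-decision links (e.g. 3 -> odd and 3 -> lt5) are treated as
pre-existing knowledge and hardwired; cue-to-goal and decision-to-response
links are instructed and live only in episodic memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CUES: tuple[str, ...] = ("blue", "red", "green", "yellow")
DIGITS: tuple[int, ...] = (1, 2, 3, 4, 6, 7, 8, 9)
DECISIONS: tuple[str, ...] = ("odd", "even", "lt5", "gt5")
RESPONSES: tuple[str, ...] = ("left", "right")
GOALS: tuple[str, ...] = ("parity", "magnitude")

N_CUES = len(CUES)
N_DIGITS = len(DIGITS)
N_DECISIONS = len(DECISIONS)
N_RESPONSES = len(RESPONSES)
N_GOALS = len(GOALS)
N_NODES = N_CUES + N_DIGITS + N_DECISIONS + N_RESPONSES + N_GOALS  # 20

CUE_SLICE = slice(0, 4)
DIGIT_SLICE = slice(4, 12)
DECISION_SLICE = slice(12, 16)
RESPONSE_SLICE = slice(16, 18)
GOAL_SLICE = slice(18, 20)

CUE_OFFSET = 0
DIGIT_OFFSET = 4
DECISION_OFFSET = 12
RESPONSE_OFFSET = 16
GOAL_OFFSET = 18

#: goal index cued by each colour (blue, red -> parity; green, yellow -> magnitude)
CUE_GOAL = np.array([0, 0, 1, 1], dtype=np.int64)

#: goal index owning each decision (odd, even -> parity; lt5, gt5 -> magnitude)
DECISION_GOAL = np.array([0, 0, 1, 1], dtype=np.int64)

#: for each digit (layout order), its parity decision and magnitude decision
DIGIT_DECISIONS = np.array(
    [
        [0, 2],  # 1: odd, lt5
        [1, 2],  # 2: even, lt5
        [0, 2],  # 3: odd, lt5
        [1, 2],  # 4: even, lt5
        [1, 3],  # 6: even, gt5
        [0, 3],  # 7: odd, gt5
        [1, 3],  # 8: even, gt5
        [0, 3],  # 9: odd, gt5
    ],
    dtype=np.int64,
)

#: hardwired digit->decision connection matrix (decision x digit), 0/1
HARDWIRED_DIGIT_DECISION = np.zeros((N_DECISIONS, N_DIGITS))
for _d, (_p, _m) in enumerate(DIGIT_DECISIONS):
    HARDWIRED_DIGIT_DECISION[_p, _d] = 1.0
    HARDWIRED_DIGIT_DECISION[_m, _d] = 1.0

#: node index -> layer id (0 cues, 1 digits, 2 decisions, 3 responses, 4 goals)
NODE_LAYER = np.array([0] * 4 + [1] * 8 + [2] * 4 + [3] * 2 + [4] * 2, dtype=np.int64)


def cue_node(cue: str | int) -> int:
    """Flat node index of a colour cue (by name or cue index)."""
    idx = cue if isinstance(cue, (int, np.integer)) else CUES.index(cue)
    return CUE_OFFSET + int(idx)


def digit_node(digit: int) -> int:
    """Flat node index of a target digit (the digit itself, not its index)."""
    return DIGIT_OFFSET + DIGITS.index(digit)


def decision_node(decision: str | int) -> int:
    idx = decision if isinstance(decision, (int, np.integer)) else DECISIONS.index(decision)
    return DECISION_OFFSET + int(idx)


def response_node(response: str | int) -> int:
    idx = response if isinstance(response, (int, np.integer)) else RESPONSES.index(response)
    return RESPONSE_OFFSET + int(idx)


def goal_node(goal: str | int) -> int:
    idx = goal if isinstance(goal, (int, np.integer)) else GOALS.index(goal)
    return GOAL_OFFSET + int(idx)


@dataclass(frozen=True)
class NodeLayout:
    """The fixed node inventory of the cued task-switching network.

    The default layout is the only one the simulator supports; the class
    exists so that malformed layouts are caught early and so that code can
    speak in terms of identities rather than raw indices.
    """

    cue_inputs: tuple[str, ...] = CUES
    digit_inputs: tuple[int, ...] = DIGITS
    decisions: tuple[str, ...] = DECISIONS
    responses: tuple[str, ...] = RESPONSES
    goals: tuple[str, ...] = GOALS

    def __post_init__(self) -> None:
        if (
            len(self.cue_inputs) != 4
            or len(self.digit_inputs) != 8
            or len(self.decisions) != 4
            or len(self.responses) != 2
            or len(self.goals) != 2
        ):
            raise ValueError(
                "malformed layout: expected 4 cues, 8 digits, 4 decisions, "
                "2 responses and 2 goals"
            )
        if 5 in self.digit_inputs:
            raise ValueError("digit 5 is excluded from the design")

    @property
    def n_nodes(self) -> int:
        return (
            len(self.cue_inputs)
            + len(self.digit_inputs)
            + len(self.decisions)
            + len(self.responses)
            + len(self.goals)
        )


DEFAULT_LAYOUT = NodeLayout()
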