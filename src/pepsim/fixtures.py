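"""Deterministic fixtures: published worked examples and toy sequences.

These are inputs printed in the source study's tables (example transition
pairs and the simulated condition means), used as test oracles and as fit
targets; plus a small reproducible trial sequence for hand checking.
"""

from __future__ import annotations

import numpy as np

from .experiment import CONDITIONS, TaskDesign, sample_trials
from .fitting import FitTarget

__all__ = ["make_fixture", "SIM1_RT_MEANS", "SIM1_ERROR_PCTS", "TABLE1_PAIRS"]

#: published simulated condition mean cycle times (figure order)
SIM1_RT_MEANS: dict[str, float] = {
    "cue-RR": 505.0,
    "cue-AR": 635.0,
    "cue-AA": 671.0,
    "rep-RR": 693.0,
    "rep-AR": 780.0,
    "rep-AA": 809.0,
    "alt-RR": 845.0,
    "alt-RA": 896.0,
    "alt-AR": 936.0,
    "alt-AA": 905.0,
}

#: published simulated error percentages (same order, omissions excluded)
SIM1_ERROR_PCTS: dict[str, float] = {
    "cue-RR": 0.5,
    "cue-AR": 1.7,
    "cue-AA": 5.1,
    "rep-RR": 1.0,
    "rep-AR": 3.2,
    "rep-AA": 4.4,
    "alt-RR": 0.0,
    "alt-RA": 29.0,
    "alt-AR": 6.3,
    "alt-AA": 5.1,
}

#: example preceding/current trial pairs, one per condition
#: (cue, digit) tuples under the odd->left mapping
TABLE1_PAIRS: dict[str, tuple[tuple[str, int], tuple[str, int]]] = {
    "cue-RR": (("blue", 3), ("blue", 3)),
    "cue-AR": (("blue", 3), ("blue", 1)),
    "cue-AA": (("blue", 3), ("blue", 2)),
    "rep-RR": (("blue", 3), ("red", 3)),
    "rep-AR": (("blue", 3), ("red", 1)),
    "rep-AA": (("blue", 3), ("red", 2)),
    "alt-RR": (("blue", 3), ("green", 3)),
    "alt-RA": (("blue", 7), ("green", 7)),
    "alt-AR": (("blue", 3), ("green", 2)),
    "alt-AA": (("blue", 3), ("green", 6)),
}


def make_fixture(kind: str):
    """Deterministic fixtures.

    ``toy_sequence``
        a 20-trial (cue, digit) sequence from a fixed seed.
    ``printed_table1_pairs``
        the labelled example transitions, one per condition.
    ``printed_sim1_means``
        the published simulated condition means as a :class:`FitTarget`.
    """
    if kind == "toy_sequence":
        return sample_trials(TaskDesign(), n=20, rng=np.random.default_rng(1234))
    if kind == "printed_table1_pairs":
        return dict(TABLE1_PAIRS)
    if kind == "printed_sim1_means":
        return FitTarget(rt=dict(SIM1_RT_MEANS), errors=dict(SIM1_ERROR_PCTS))
    raise ValueError(f"unknown fixture kind {kind!r}")
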