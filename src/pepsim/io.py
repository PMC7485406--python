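"""Summary serialization and the run manifest."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .experiment import ConditionSummary, run_experiment, summarize
from .params import PEPParameters

__all__ = ["write_summary", "read_summary", "RunManifest"]

_SUMMARY_COLUMNS = [
    "condition",
    "congruency",
    "mean_rt",
    "error_pct",
    "n",
    "omission_pct",
    "n_trials",
]


def write_summary(summary: ConditionSummary, path: str | Path) -> None:
    """Write a condition summary as CSV, one row per condition x congruency
    cell (congruency ``any`` for pooled rows, condition ``any`` for the
    overall congruency means).  The column order is fixed; the overall
    omission percentage and trial count are carried on every row so the
    file round-trips losslessly."""
    frames = [
        summary.table.assign(congruency="any"),
        summary.by_congruency,
        summary.congruency.assign(condition="any"),
    ]
    out = pd.concat(frames, ignore_index=True)
    out["omission_pct"] = summary.omission_pct
    out["n_trials"] = summary.n_trials
    out = out[_SUMMARY_COLUMNS]
    out.to_csv(path, index=False)


def read_summary(path: str | Path) -> ConditionSummary:
    df = pd.read_csv(path)
    if list(df.columns) != _SUMMARY_COLUMNS:
        raise ValueError(f"unexpected summary header in {path}")
    pooled = df[(df["congruency"] == "any") & (df["condition"] != "any")]
    cells = df[(df["congruency"] != "any") & (df["condition"] != "any")]
    overall = df[df["condition"] == "any"]
    base = ["mean_rt", "error_pct", "n"]
    return ConditionSummary(
        table=pooled[["condition"] + base].reset_index(drop=True),
        by_congruency=cells[["condition", "congruency"] + base].reset_index(drop=True),
        congruency=overall[["congruency"] + base].reset_index(drop=True),
        omission_pct=float(df["omission_pct"].iloc[0]),
        n_trials=int(df["n_trials"].iloc[0]),
    )


@dataclass
class RunManifest:
    """Everything needed to bit-reproduce an experiment run."""

    params: dict
    n_participants: int
    base_seed: int
    n_trials: int = 800
    ablate_goal_inertia: bool = False
    engine: str = "fast"
    version: str = "unknown"

    @classmethod
    def create(
        cls,
        params: PEPParameters,
        n_participants: int,
        base_seed: int,
        n_trials: int = 800,
        ablate_goal_inertia: bool = False,
        engine: str = "fast",
    ) -> "RunManifest":
        from . import __version__

        return cls(
            params=params.to_dict(),
            n_participants=n_participants,
            base_seed=base_seed,
            n_trials=n_trials,
            ablate_goal_inertia=ablate_goal_inertia,
            engine=engine,
            version=__version__,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))

    def rerun(self) -> pd.DataFrame:
        """Re-execute the run this manifest describes."""
        params = PEPParameters(**self.params)
        return run_experiment(
            params,
            n_participants=self.n_participants,
            base_seed=self.base_seed,
            ablate_goal_inertia=self.ablate_goal_inertia,
            n_trials=self.n_trials,
            engine=self.engine,
        )
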