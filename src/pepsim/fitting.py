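"""Evolutionary parameter fitting and the reverse-target sensitivity test.

A steady-state evolutionary algorithm: each child is a mutated copy of a
random parent, evaluated by simulating a small sample of participants, and
replaces the worst parent when it fits better.  The reverse-target
construction (each condition mean reflected about the grand mean of
condition means) asks the model to produce opposite-direction effects with
unchanged mean and spread — a falsifiability probe: a model with fixed
qualitative predictions can only approach null effects, never reversed
ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .experiment import CONDITIONS, ConditionSummary, compute_effects, run_experiment, summarize
from .params import PARAM_RANGES, PEPParameters

__all__ = [
    "EvolutionConfig",
    "FitTarget",
    "loss",
    "mutate",
    "evolve",
    "reverse_targets",
    "evaluate_params",
]

#: practical mutation ceiling for parameters whose a-priori range is
#: unbounded above: 10x the default ("Original") value.
_UNBOUNDED_CEILING_FACTOR = 10.0


def mutation_bounds() -> dict[str, tuple[float, float]]:
    """Finite per-parameter mutation bounds derived from the a-priori ranges."""
    defaults = PEPParameters()
    bounds = {}
    for name, (lo, hi) in PARAM_RANGES.items():
        d = abs(getattr(defaults, name))
        if lo is None:
            lo = -_UNBOUNDED_CEILING_FACTOR * max(d, 1.0)
        if hi is None:
            hi = _UNBOUNDED_CEILING_FACTOR * max(d, 1.0)
        bounds[name] = (float(lo), float(hi))
    return bounds


@dataclass
class EvolutionConfig:
    """Settings of the steady-state evolutionary search."""

    mutation_rate: float = 0.3
    mutation_extremity: float = 0.3
    parent_population: int = 40
    n_children: int = 1000
    eval_participants: int = 50
    n_trials: int = 800
    seed: int = 0
    bounds: dict[str, tuple[float, float]] = field(default_factory=mutation_bounds)

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if not 0.0 <= self.mutation_extremity <= 1.0:
            raise ValueError("mutation_extremity must lie in [0, 1]")
        if self.parent_population < 1 or self.eval_participants < 1:
            raise ValueError("population sizes must be positive")


@dataclass
class FitTarget:
    """Condition means (cycle times and error percentages) to fit.

    ``rt`` and ``errors`` map condition labels (optionally condition x
    congruency labels such as ``'cue-AR/incongruent'``) to target values.
    """

    rt: dict[str, float]
    errors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d in (self.rt, self.errors):
            for k, v in d.items():
                if not np.isfinite(v):
                    raise ValueError(f"non-finite target for {k!r}")


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd == 0.0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def loss(simulated: ConditionSummary, target: FitTarget) -> float:
    """Root-mean-square deviation over standardized RT and error means.

    Cycle times and error percentages are z-scored separately (against the
    target's own spread) and weighted equally.
    """
    devs = []
    for attr, sim_getter in (("rt", simulated.rt), ("errors", simulated.error_pct)):
        tgt = getattr(target, attr)
        if not tgt:
            continue
        conds = sorted(tgt)
        try:
            sim_vals = np.array([sim_getter(c) for c in conds])
        except KeyError as exc:
            raise ValueError(f"simulated summary lacks target condition {exc}") from exc
        tgt_vals = np.array([tgt[c] for c in conds])
        mu, sd = tgt_vals.mean(), tgt_vals.std()
        if sd == 0.0:
            sd = 1.0
        devs.append((sim_vals - mu) / sd - (tgt_vals - mu) / sd)
    if not devs:
        raise ValueError("empty fit target")
    all_devs = np.concatenate(devs)
    return float(np.sqrt(np.mean(all_devs**2)))


def mutate(
    params: PEPParameters,
    config: EvolutionConfig,
    rng: np.random.Generator,
) -> PEPParameters:
    """Mutate each tunable independently with probability ``mutation_rate``.

    Perturbations are Gaussian with scale ``mutation_extremity`` times the
    parameter's (finite) mutation range, reflected back into bounds.
    """
    overrides = {}
    for name, (lo, hi) in config.bounds.items():
        if rng.random() >= config.mutation_rate:
            continue
        width = hi - lo
        value = getattr(params, name) + rng.normal(0.0, config.mutation_extremity * width)
        # reflect into [lo, hi]
        for _ in range(64):
            if value < lo:
                value = lo + (lo - value)
            elif value > hi:
                value = hi - (value - hi)
            else:
                break
        value = float(np.clip(value, lo, hi))
        overrides[name] = value
    return params.replace(**overrides) if overrides else params


def evaluate_params(
    params: PEPParameters,
    target: FitTarget,
    config: EvolutionConfig,
    seed: int,
) -> float:
    """Fit loss of one candidate, from a fresh simulated sample.

    A candidate whose simulation blows up (non-finite activations or an
    empty condition) receives infinite loss.
    """
    try:
        df = run_experiment(
            params,
            n_participants=config.eval_participants,
            base_seed=seed,
            n_trials=config.n_trials,
        )
        return loss(summarize(df), target)
    except (FloatingPointError, ValueError, KeyError):
        return float("inf")


@dataclass
class EvolutionResult:
    best_params: PEPParameters
    best_loss: float
    population: list[PEPParameters]
    population_losses: list[float]
    trace: pd.DataFrame  # child index, child loss, population minimum


def evolve(
    start: PEPParameters,
    target: FitTarget,
    config: EvolutionConfig,
) -> EvolutionResult:
    """Steady-state evolution from ``start``.

    The initial parent population is ``start`` plus mutated copies; each
    child is a mutated copy of a uniformly chosen parent and replaces the
    current worst parent if its loss is lower.  The population minimum is
    non-increasing over children by construction.
    """
    rng = np.random.default_rng(config.seed)
    eval_seed = int(rng.integers(0, 2**31 - 1))

    parents = [start]
    while len(parents) < config.parent_population:
        parents.append(mutate(start, config, rng))
    losses = [evaluate_params(p, target, config, eval_seed + i) for i, p in enumerate(parents)]

    rows = []
    for child_i in range(config.n_children):
        parent = parents[int(rng.integers(len(parents)))]
        child = mutate(parent, config, rng)
        child_loss = evaluate_params(
            child, target, config, eval_seed + config.parent_population + child_i
        )
        worst = int(np.argmax(losses))
        if child_loss < losses[worst]:
            parents[worst] = child
            losses[worst] = child_loss
        rows.append(
            {"child": child_i, "child_loss": child_loss, "population_min": float(np.min(losses))}
        )
    best = int(np.argmin(losses))
    return EvolutionResult(
        best_params=parents[best],
        best_loss=float(losses[best]),
        population=parents,
        population_losses=[float(x) for x in losses],
        trace=pd.DataFrame(rows, columns=["child", "child_loss", "population_min"]),
    )


def reverse_targets(target: FitTarget) -> FitTarget:
    """Reflect every condition mean about the grand mean of condition means
    (``2 * mean-of-means - mean``); grand mean and spread are preserved."""
    if not target.rt and not target.errors:
        raise ValueError("empty fit target")

    def _reflect(d: dict[str, float]) -> dict[str, float]:
        if not d:
            return {}
        grand = float(np.mean(list(d.values())))
        return {k: 2.0 * grand - v for k, v in d.items()}

    return FitTarget(rt=_reflect(target.rt), errors=_reflect(target.errors))
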