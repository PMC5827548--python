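"""Transformed up-down luminance staircase.

A fixed-step adaptive procedure: a single hit lowers target luminance by
``step_down``; three consecutive misses raise it by ``step_up``.  Catch
trials and trials without a valid response never touch the staircase.

The counter of consecutive misses forms a three-state Markov chain, so at a
stationary hit probability p (miss probability q = 1 - p) the expected
down-drift per trial is p * step_down and the expected up-drift is
step_up * q^3 / (1 + q + q^2).  Setting the two equal at p = 0.5 gives
step_up / step_down = 7 exactly — the shipped default ratio, which makes the
procedure hover where the observer detects about half the targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StaircaseState",
    "update",
    "converged_level",
    "run_staircase",
    "equilibrium_hit_rate",
    "DEFAULT_STEP_RATIO",
]

#: step_up / step_down ratio whose equilibrium hit rate is exactly 0.5.
DEFAULT_STEP_RATIO = 7.0


@dataclass(frozen=True)
class StaircaseState:
    level: float
    step_down: float = 0.05
    step_up: float = 0.05 * DEFAULT_STEP_RATIO
    floor: float = 0.0
    ceiling: float = 10.0
    run_counter: int = 0
    last_direction: str = "none"  # {"up", "down", "none"}
    reversals: tuple[float, ...] = field(default_factory=tuple)
    levels: tuple[float, ...] = field(default_factory=tuple)  # trajectory

    def __post_init__(self) -> None:
        if self.step_down <= 0 or self.step_up <= 0:
            raise ValueError("step sizes must be > 0")
        if not (self.floor <= self.level <= self.ceiling):
            raise ValueError(
                f"level {self.level} outside [{self.floor}, {self.ceiling}]"
            )
        if self.run_counter < 0:
            raise ValueError("run_counter must be >= 0")


def update(state: StaircaseState, hit: bool) -> StaircaseState:
    """Advance the staircase by one scored (target-present) trial."""
    level = state.level
    run = state.run_counter
    direction = state.last_direction
    reversals = state.reversals
    if hit:
        new_level = max(state.floor, level - state.step_down)
        if direction == "up":
            reversals = reversals + (level,)
        direction = "down"
        run = 0
    else:
        run += 1
        new_level = level
        if run >= 3:
            new_level = min(state.ceiling, level + state.step_up)
            if direction == "down":
                reversals = reversals + (level,)
            direction = "up"
            run = 0
    return replace(
        state,
        level=new_level,
        run_counter=run,
        last_direction=direction,
        reversals=reversals,
        levels=state.levels + (new_level,),
    )


def converged_level(
    state: StaircaseState,
    n_last_reversals: int | None = 6,
    trailing_trials: int | None = None,
) -> float:
    """Converged luminance estimate.

    By default the mean of the last ``n_last_reversals`` reversal levels;
    pass ``trailing_trials`` instead to average the level over a trailing
    trial window (the mode matching a 'mean over the final blocks' rule).
    """
    if trailing_trials is not None:
        if len(state.levels) < trailing_trials:
            raise ValueError(
                f"trajectory has {len(state.levels)} trials, "
                f"need {trailing_trials}"
            )
        return float(np.mean(state.levels[-trailing_trials:]))
    if n_last_reversals is None:
        raise ValueError("one of n_last_reversals / trailing_trials required")
    if len(state.reversals) < n_last_reversals:
        raise ValueError(
            f"only {len(state.reversals)} reversals recorded, "
            f"need {n_last_reversals}"
        )
    return float(np.mean(state.reversals[-n_last_reversals:]))


def run_staircase(
    p_hit,
    n_trials: int,
    initial: StaircaseState,
    seed: int,
) -> tuple[StaircaseState, np.ndarray]:
    """Drive a staircase against a stochastic observer.

    ``p_hit`` maps a luminance level to a detection probability.  Returns the
    final state and the boolean hit vector.  Deterministic given
    (initial state, seed, observer).
    """
    rng = np.random.default_rng(seed)
    u = rng.random(n_trials)
    state = initial
    hits = np.empty(n_trials, dtype=bool)
    for i in range(n_trials):
        hit = u[i] < p_hit(state.level)
        hits[i] = hit
        state = update(state, hit)
    return state, hits


def trajectory_frame(initial: StaircaseState, hits) -> "pd.DataFrame":
    """Replay a hit sequence into a per-trial trajectory table.

    Columns: trial, level (after the update), response, reversal flag.
    Write with ``df.to_csv(path, index=False)`` for a delimited export.
    """
    import pandas as pd

    state = initial
    rows = []
    for i, h in enumerate(np.asarray(hits, dtype=bool)):
        n_rev = len(state.reversals)
        state = update(state, bool(h))
        rows.append(
            {
                "trial": i,
                "level": state.level,
                "response": "hit" if h else "miss",
                "reversal": len(state.reversals) > n_rev,
            }
        )
    return pd.DataFrame(rows)


def equilibrium_hit_rate(step_ratio: float) -> float:
    """Stationary hit rate implied by a given step_up/step_down ratio.

    Solves p = ratio * (1-p)^3 / (1 + (1-p) + (1-p)^2) on (0, 1) by
    bisection.  Assumes a locally flat psychometric function (steps small
    relative to its spread).
    """
    def drift(p: float) -> float:
        q = 1.0 - p
        return p - step_ratio * q**3 / (1.0 + q + q**2)

    lo, hi = 1e-9, 1 - 1e-9
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if drift(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
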