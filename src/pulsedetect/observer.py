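"""Parametric observers and cohort simulation.

The generative model behind every synthetic dataset: a participant detects a
near-threshold target with probability given by a lapse-scaled logistic in
luminance, shifted on the log-odds scale by (a) an optional sinusoidal
entrainment term locked to the stimulation pulse train, (b) a linear fatigue
drift across the trials of a block, and (c) a sequence bonus in whichever
condition the participant performs second.  Catch trials produce false
alarms at a fixed guess rate; a small fraction of trials carry no valid
response at all.

Entrainment enters on the log-odds scale so probabilities stay inside (0, 1)
for any amplitude.  The downstream sinusoid is nevertheless fit on the
standardized rate scale — the same mismatch any real experiment has between
its generative physiology and its descriptive model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import SessionPlan, TRIAL_COLUMNS, build_schedule

__all__ = [
    "ObserverParams",
    "PopulationSpec",
    "p_hit",
    "hit_probability",
    "simulate_cohort",
    "staircased_luminance",
]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class ObserverParams:
    """One participant's generative detection model.

    Luminance is in arbitrary units on [0, 1]; ``threshold`` is the
    luminance of the logistic inflection and ``slope`` its steepness per
    luminance unit.  ``entrain_amp`` (A) and ``entrain_phase`` define the
    phase-locked modulation A*sin(2*pi*soa/period + phase) on log-odds;
    ``fatigue_slope`` is log-odds per trial within a block;
    ``condition_offset`` is the log-odds bonus in the second-performed
    condition.
    """

    threshold: float = 0.5
    slope: float = 10.0
    lapse: float = 0.02
    guess_fa: float = 0.05
    entrain_amp: float = 0.0
    entrain_phase: float = 0.0
    fatigue_slope: float = 0.0
    condition_offset: float = 0.0
    no_response_rate: float = 0.02

    def __post_init__(self) -> None:
        for name in ("lapse", "guess_fa", "no_response_rate"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must lie in [0, 1), got {v!r}")
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if self.entrain_amp < 0:
            raise ValueError("entrain_amp must be >= 0")
        if not (-np.pi < self.entrain_phase <= np.pi):
            raise ValueError("entrain_phase must lie in (-pi, pi]")


@dataclass(frozen=True)
class PopulationSpec:
    """Distribution of observer parameters across a cohort.

    Thresholds are jittered per participant (normal, truncated to keep the
    psychometric function inside the luminance range); entrainment phase is
    drawn uniformly on (-pi, pi] — there is no a-priori reason participants
    would share a preferred phase.  The remaining parameters are shared.

    Defaults emulate the study conditions: detection staircased to ~50%,
    a fatigue drift that loses roughly ten percentage points over a 128-trial
    block, and a sequence bonus of about five percentage points in the
    second-performed condition.
    """

    threshold_mean: float = 0.5
    threshold_sd: float = 0.05
    slope: float = 10.0
    lapse: float = 0.02
    guess_fa: float = 0.05
    fatigue_slope: float = -0.004
    condition_offset: float = 0.2
    no_response_rate: float = 0.02
    entrain_phase_random: bool = True

    def draw(self, entrain_amp: float, rng: np.random.Generator) -> ObserverParams:
        thr = float(np.clip(
            rng.normal(self.threshold_mean, self.threshold_sd), 0.15, 0.85
        ))
        if self.entrain_phase_random:
            phase = float(rng.uniform(-np.pi, np.pi))
            if phase == -np.pi:  # keep inside (-pi, pi]
                phase = np.pi
        else:
            phase = 0.0
        return ObserverParams(
            threshold=thr,
            slope=self.slope,
            lapse=self.lapse,
            guess_fa=self.guess_fa,
            entrain_amp=entrain_amp,
            entrain_phase=phase,
            fatigue_slope=self.fatigue_slope,
            condition_offset=self.condition_offset,
            no_response_rate=self.no_response_rate,
        )


def hit_probability(
    luminance,
    pulse_soa,
    trial_index,
    params: ObserverParams,
    entrain_on: bool,
    is_second_condition: bool,
    period: float = 100.0,
):
    """Vectorised detection probability for target-present trials."""
    x = params.slope * (np.asarray(luminance, dtype=float) - params.threshold)
    if entrain_on and params.entrain_amp > 0:
        x = x + params.entrain_amp * np.sin(
            2 * np.pi * np.asarray(pulse_soa, dtype=float) / period
            + params.entrain_phase
        )
    x = x + params.fatigue_slope * np.asarray(trial_index, dtype=float)
    if is_second_condition:
        x = x + params.condition_offset
    return (1.0 - params.lapse) * _sigmoid(x)


def p_hit(
    trial: pd.Series,
    params: ObserverParams,
    entrain_on: bool,
    period: float = 100.0,
    is_second_condition: bool = False,
) -> float:
    """Detection probability for a single target-present trial row."""
    if bool(trial["catch"]):
        raise ValueError(
            "p_hit is defined for target-present trials only; "
            "catch trials use guess_fa directly"
        )
    return float(
        hit_probability(
            trial["luminance"], trial["pulse_soa"], trial["trial"],
            params, entrain_on, is_second_condition, period,
        )
    )


def staircased_luminance(
    params: ObserverParams,
    plan: SessionPlan,
    rng: np.random.Generator,
    n_blocks: int = 2,
) -> float:
    """Luminance a pre-session staircase run would settle on.

    Runs the 3-miss-up / 1-hit-down staircase (default step ratio 7:1)
    against the observer's plain logistic for ``n_blocks`` blocks of target
    trials and returns the mean level over the final block — the rule of
    fixing luminance at the average over the last staircased blocks.
    """
    n_targets = n_blocks * (plan.trials_per_block - plan.catch_per_block)
    step_down = 0.01
    step_up = 7.0 * step_down
    level = 0.8
    u = rng.random(n_targets)
    levels = np.empty(n_targets)
    run = 0
    for i in range(n_targets):
        p = (1.0 - params.lapse) * _sigmoid(params.slope * (level - params.threshold))
        if u[i] < p:
            level = max(0.0, level - step_down)
            run = 0
        else:
            run += 1
            if run == 3:
                level = min(1.0, level + step_up)
                run = 0
        levels[i] = level
    tail = n_targets // n_blocks
    return float(np.mean(levels[-tail:]))


def _draw_responses(
    sched: pd.DataFrame,
    params: ObserverParams,
    entrain_on: bool,
    is_second: bool,
    period: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(sched)
    catch = sched["catch"].to_numpy(bool)
    p = np.empty(n)
    p[~catch] = hit_probability(
        sched.loc[~catch, "luminance"].to_numpy(),
        sched.loc[~catch, "pulse_soa"].to_numpy(),
        sched.loc[~catch, "trial"].to_numpy(),
        params, entrain_on, is_second, period,
    )
    p[catch] = params.guess_fa
    press = rng.random(n) < p
    response = np.where(
        catch,
        np.where(press, "false_alarm", "correct_rejection"),
        np.where(press, "hit", "miss"),
    )
    no_resp = rng.random(n) < params.no_response_rate
    response = np.where(no_resp, "no_response", response)
    rt = np.where(
        press & ~no_resp,
        250.0 + rng.lognormal(np.log(150.0), 0.4, size=n),
        np.nan,
    )
    out = sched.copy()
    out["response"] = response
    out["rt"] = rt
    return out


def simulate_cohort(
    n_participants: int,
    plan: SessionPlan | None = None,
    population: PopulationSpec | None = None,
    entrain_amp: float = 0.0,
    seed: int = 0,
    allow_odd: bool = False,
) -> pd.DataFrame:
    """Simulate a counterbalanced two-condition cohort.

    Each participant performs both conditions (sham then otCS or the
    reverse; exactly half in each order).  Sham always has entrainment
    amplitude 0; otCS has ``entrain_amp``.  Luminance is fixed per
    participant at the level a simulated pre-session staircase settles on.
    Fully reproducible from ``seed``.
    """
    if n_participants % 2 != 0 and not allow_odd:
        raise ValueError(
            "n_participants must be even for exact counterbalancing "
            "(pass allow_odd=True to override)"
        )
    plan = plan or SessionPlan()
    population = population or PopulationSpec()
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_participants)
    tables = []
    for i in range(n_participants):
        rng = np.random.default_rng(child[i])
        params = population.draw(entrain_amp, rng)
        order = "sham_first" if i % 2 == 0 else "otcs_first"
        lum = staircased_luminance(params, plan, rng)
        pid = f"p{i:02d}"
        for cond in ("sham", "otcs"):
            sched = build_schedule(plan, seed=int(rng.integers(2**31)))
            sched["participant_id"] = pid
            sched["condition"] = cond
            sched["order"] = order
            sched["luminance"] = lum
            is_second = (cond == "otcs") == (order == "sham_first")
            entrain_on = cond == "otcs"
            tables.append(
                _draw_responses(
                    sched, params, entrain_on, is_second,
                    plan.pulse_period, rng,
                )
            )
    return pd.concat(tables, ignore_index=True)[TRIAL_COLUMNS]
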