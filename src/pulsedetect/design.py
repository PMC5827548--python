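"""Experiment schedule construction and pulse-train timing.

The task is a backward-masked visual detection paradigm run under a
continuous 10-Hz train of stimulation pulses.  Each trial shows a fixation
cross, a blank of variable duration (the target SOA, tSOA), a brief target,
and a mask; on a fraction of trials the target is omitted (catch trials).
Because the pulse train runs continuously, each target onset falls at some
latency within the 100-ms inter-pulse cycle — the pulse-to-target SOA — and
that latency is the phase proxy every downstream analysis is built on.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SessionPlan",
    "DEFAULT_TSOA_SET",
    "build_schedule",
    "pulse_to_target_soa",
    "read_trials",
    "write_trials",
    "TRIAL_COLUMNS",
]

#: Blank-screen durations (ms) between fixation offset and target onset.
DEFAULT_TSOA_SET = (200.0, 225.0, 266.66, 283.33, 300.0, 341.66, 374.99, 408.33)

#: Column order of the canonical trial table.
TRIAL_COLUMNS = [
    "participant_id",
    "condition",
    "order",
    "block",
    "trial",
    "tsoa",
    "catch",
    "pulse_soa",
    "luminance",
    "response",
    "rt",
]

CONDITIONS = ("sham", "otcs")
ORDERS = ("sham_first", "otcs_first")
RESPONSES = ("hit", "miss", "false_alarm", "correct_rejection", "no_response")


class PlanError(ValueError):
    """A SessionPlan field violates its constraints."""


@dataclass(frozen=True)
class SessionPlan:
    """Timing and composition of one experimental session (one condition).

    Durations are in milliseconds.  Defaults reproduce the study design:
    three blocks of 128 trials, 20% catch trials, eight tSOAs, an 8.33-ms
    target with a fixed 41.7-ms target-to-mask SOA, and 2.5-ms stimulation
    pulses every 100 ms.
    """

    n_blocks: int = 3
    trials_per_block: int = 128
    catch_fraction: float = 0.2
    tsoa_set: tuple[float, ...] = DEFAULT_TSOA_SET
    fixation_dur: float = 400.0
    target_dur: float = 8.33
    mask_soa: float = 41.7
    mask_dur: float = 8.33
    response_window: float = 1000.0
    pulse_period: float = 100.0
    pulse_width: float = 2.5

    def __post_init__(self) -> None:
        positive = (
            "n_blocks", "trials_per_block", "fixation_dur", "target_dur",
            "mask_soa", "mask_dur", "response_window", "pulse_period",
            "pulse_width",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise PlanError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if not (0 <= self.catch_fraction < 1):
            raise PlanError(
                f"catch_fraction must lie in [0, 1), got {self.catch_fraction!r}"
            )
        if len(self.tsoa_set) == 0:
            raise PlanError("tsoa_set must be non-empty")
        if any(t <= 0 for t in self.tsoa_set):
            raise PlanError("tsoa_set entries must be > 0")
        if self.pulse_period <= self.pulse_width:
            raise PlanError(
                f"pulse_period ({self.pulse_period}) must exceed "
                f"pulse_width ({self.pulse_width})"
            )

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def catch_per_block(self) -> int:
        # Fixed count per block rather than per-trial Bernoulli: stabilises
        # the detection-rate denominators.
        return round(self.catch_fraction * self.trials_per_block)

    def trial_duration(self, tsoa: float) -> float:
        """Total duration of one trial given its tSOA."""
        return (
            self.fixation_dur + tsoa + self.mask_soa + self.mask_dur
            + self.response_window
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tsoa_set"] = list(self.tsoa_set)
        return d


def pulse_to_target_soa(
    target_onset: float | np.ndarray,
    pulse_phase0: float,
    period: float,
) -> float | np.ndarray:
    """Latency from the most recent stimulation pulse to target onset.

    Pulses occur at ``pulse_phase0 + k * period``; the returned SOA is
    ``(target_onset - pulse_phase0) mod period`` on the half-open interval
    ``[0, period)`` — a target coincident with a pulse has SOA 0.
    """
    if period <= 0:
        raise ValueError(f"period must be > 0, got {period!r}")
    soa = np.mod(np.asarray(target_onset, dtype=float) - pulse_phase0, period)
    # mod can return `period` itself through floating-point rounding
    soa = np.where(soa >= period, soa - period, soa)
    if np.ndim(target_onset) == 0:
        return float(soa)
    return soa


def build_schedule(plan: SessionPlan, seed: int) -> pd.DataFrame:
    """Lay out every trial of a session and compute its pulse-to-target SOA.

    Per block, exactly ``round(catch_fraction * trials_per_block)`` trials
    are catch trials at seed-randomised positions; tSOAs are drawn uniformly
    with replacement from ``plan.tsoa_set``.  The pulse train is phase-locked
    to block onset (first pulse at block time 0) and runs continuously, so
    target onsets accumulate across the trials of a block.

    Returns a DataFrame with the canonical trial columns; ``luminance``,
    ``response`` and ``rt`` are left unset (NaN / empty).
    """
    rng = np.random.default_rng(seed)
    tsoas = np.asarray(plan.tsoa_set, dtype=float)
    cols = {"block": [], "trial": [], "tsoa": [], "catch": [], "pulse_soa": []}
    for block in range(plan.n_blocks):
        n = plan.trials_per_block
        tsoa = tsoas[rng.integers(0, len(tsoas), size=n)]
        catch = np.zeros(n, dtype=bool)
        catch[rng.choice(n, size=plan.catch_per_block, replace=False)] = True
        # continuous pulse train, phase 0 at block onset
        durations = plan.fixation_dur + tsoa + plan.mask_soa + plan.mask_dur \
            + plan.response_window
        starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        onsets = starts + plan.fixation_dur + tsoa
        soa = pulse_to_target_soa(onsets, 0.0, plan.pulse_period)
        cols["block"].append(np.full(n, block))
        cols["trial"].append(np.arange(n))
        cols["tsoa"].append(tsoa)
        cols["catch"].append(catch)
        cols["pulse_soa"].append(soa)
    df = pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})
    df["participant_id"] = ""
    df["condition"] = ""
    df["order"] = ""
    df["luminance"] = np.nan
    df["response"] = ""
    df["rt"] = np.nan
    return df[TRIAL_COLUMNS]


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial table as comma-separated text (missing rt = empty)."""
    df.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def read_trials(path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trials`."""
    df = pd.read_csv(path, dtype={"participant_id": str, "condition": str,
                                  "order": str, "response": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    df["catch"] = df["catch"].astype(bool)
    return df[TRIAL_COLUMNS]


def validate_trials(df: pd.DataFrame, period: float = 100.0) -> list[str]:
    """Schema checks for a trial table; returns a list of problems (empty = ok)."""
    problems = []
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        return [f"missing columns: {missing}"]
    bad_cond = set(df["condition"].unique()) - set(CONDITIONS)
    if bad_cond:
        problems.append(f"unknown condition labels: {sorted(bad_cond)}")
    bad_order = set(df["order"].unique()) - set(ORDERS)
    if bad_order:
        problems.append(f"unknown order labels: {sorted(bad_order)}")
    bad_resp = set(df["response"].unique()) - set(RESPONSES)
    if bad_resp:
        problems.append(f"unknown response labels: {sorted(bad_resp)}")
    soa = df["pulse_soa"].to_numpy(dtype=float)
    if np.any((soa < 0) | (soa >= period)):
        problems.append(f"pulse_soa outside [0, {period})")
    catch = df["catch"].to_numpy(dtype=bool)
    resp = df["response"].to_numpy()
    if np.any(catch & np.isin(resp, ["hit", "miss"])):
        problems.append("catch trials carry hit/miss responses")
    if np.any(~catch & np.isin(resp, ["false_alarm", "correct_rejection"])):
        problems.append("target trials carry catch-trial responses")
    return problems
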