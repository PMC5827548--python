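"""Phase bins and time-course bins of detection rate.

Trials are grouped by pulse-to-target SOA into half-open 10-ms bins over the
100-ms stimulation cycle (ten bins), separately per participant and
condition.  Catch trials and trials without a valid response are excluded
before any rate is formed.  Rates can be standardized (z-scored across the
ten bins within participant x condition) to strip mean-level differences
such as sequence effects.  A second, orthogonal view bins consecutive trials
(12 bins of 32) to expose drifts over the course of a condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CONDITIONS

__all__ = [
    "BinnedRates",
    "bin_index",
    "detection_rates",
    "standardize",
    "timecourse_bins",
    "rates_to_frame",
    "frame_to_rates",
]


@dataclass
class BinnedRates:
    """Per participant x condition detection rates over the phase bins.

    ``rates[b]`` is hits / (hits + misses) among included trials of bin b,
    NaN where a bin received no included trial.  ``standardized`` (when set)
    is the z-score of ``rates`` across the bins (sample SD).
    """

    participant_id: str
    condition: str
    rates: np.ndarray
    counts: np.ndarray
    standardized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        ok = self.rates[~np.isnan(self.rates)]
        if np.any((ok < 0) | (ok > 1)):
            raise ValueError("rates must lie in [0, 1]")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @property
    def n_bins(self) -> int:
        return len(self.rates)


def bin_index(pulse_soa, width: float = 10.0, period: float = 100.0):
    """Half-open phase-bin index: floor(soa / width), in 0 .. period/width - 1."""
    n_bins = period / width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"width {width} does not divide period {period}")
    soa = np.asarray(pulse_soa, dtype=float)
    if np.any((soa < 0) | (soa >= period)):
        raise ValueError(f"pulse_soa must lie in [0, {period})")
    idx = np.floor(soa / width).astype(int)
    # float division can nudge an soa just below a bin edge over it
    idx = np.minimum(idx, int(round(n_bins)) - 1)
    if np.ndim(pulse_soa) == 0:
        return int(idx)
    return idx


def _included(trials: pd.DataFrame) -> pd.DataFrame:
    """Scored target trials: no catch, no missing response."""
    return trials[~trials["catch"] & trials["response"].isin(["hit", "miss"])]


def detection_rates(
    trials: pd.DataFrame,
    width: float = 10.0,
    period: float = 100.0,
) -> list[BinnedRates]:
    """Phase-binned detection rates per participant x condition.

    Catch trials and trials without a valid response are excluded; empty
    bins carry NaN and count 0.
    """
    unknown = set(trials["condition"].unique()) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown condition labels: {sorted(unknown)}")
    n_bins = int(round(period / width))
    inc = _included(trials).copy()
    inc["bin"] = bin_index(inc["pulse_soa"].to_numpy(), width, period)
    inc["is_hit"] = (inc["response"] == "hit").astype(int)
    out = []
    for (pid, cond), grp in inc.groupby(["participant_id", "condition"], sort=True):
        counts = np.bincount(grp["bin"], minlength=n_bins)
        hits = np.bincount(grp["bin"], weights=grp["is_hit"], minlength=n_bins)
        with np.errstate(invalid="ignore"):
            rates = np.where(counts > 0, hits / np.maximum(counts, 1), np.nan)
        out.append(BinnedRates(str(pid), str(cond), rates, counts))
    return out


def standardize(binned: BinnedRates, mode: str = "z") -> BinnedRates:
    """Standardize rates across bins within one participant x condition.

    mode "z": subtract the mean and divide by the sample SD (ddof=1);
    mode "center": subtract the mean only.  NaN bins stay NaN.
    """
    if mode not in ("z", "center"):
        raise ValueError(f"unknown mode {mode!r}")
    r = binned.rates
    ok = ~np.isnan(r)
    if ok.sum() < 2:
        raise ValueError("need >= 2 non-missing bins to standardize")
    mu = r[ok].mean()
    z = r - mu
    if mode == "z":
        sd = r[ok].std(ddof=1)
        if sd == 0:
            raise ValueError(
                "constant rate vector has zero variance; exclude this "
                "participant x condition from standardized analyses"
            )
        z = z / sd
    return BinnedRates(
        binned.participant_id, binned.condition,
        binned.rates, binned.counts, standardized=z,
    )


def timecourse_bins(
    trials: pd.DataFrame,
    bin_size: int = 32,
) -> pd.DataFrame:
    """Detection rate in consecutive-trial bins per participant x condition.

    Trials are taken in presentation order (block, then trial); exclusions
    (catch, no valid response) remove trials from the rate's numerator and
    denominator but not from the consecutive-position count, so bin b always
    spans presentation positions [b*bin_size, (b+1)*bin_size).

    Returns a long DataFrame (participant_id, condition, tbin, rate, count).
    """
    rows = []
    for (pid, cond), grp in trials.groupby(
        ["participant_id", "condition"], sort=True
    ):
        grp = grp.sort_values(["block", "trial"], kind="stable")
        n = len(grp)
        if n % bin_size != 0:
            raise ValueError(
                f"{pid}/{cond}: {n} trials not divisible by bin_size {bin_size}"
            )
        tbin = np.arange(n) // bin_size
        scored = (~grp["catch"].to_numpy()) & grp["response"].isin(
            ["hit", "miss"]
        ).to_numpy()
        hit = (grp["response"] == "hit").to_numpy()
        for b in range(n // bin_size):
            m = (tbin == b) & scored
            cnt = int(m.sum())
            rate = float(hit[m].sum() / cnt) if cnt else np.nan
            rows.append(
                {"participant_id": pid, "condition": cond, "tbin": b,
                 "rate": rate, "count": cnt}
            )
    return pd.DataFrame(rows)


def rates_to_frame(binned: list[BinnedRates]) -> pd.DataFrame:
    """Long-format table (participant, condition, bin, rate, count, z)."""
    rows = []
    for br in binned:
        z = br.standardized
        for b in range(br.n_bins):
            rows.append(
                {
                    "participant_id": br.participant_id,
                    "condition": br.condition,
                    "bin": b,
                    "rate": br.rates[b],
                    "count": int(br.counts[b]),
                    "z": np.nan if z is None else z[b],
                }
            )
    return pd.DataFrame(rows)


def frame_to_rates(df: pd.DataFrame) -> list[BinnedRates]:
    """Inverse of :func:`rates_to_frame`."""
    out = []
    for (pid, cond), grp in df.groupby(["participant_id", "condition"], sort=True):
        grp = grp.sort_values("bin")
        z = grp["z"].to_numpy(float)
        out.append(
            BinnedRates(
                str(pid), str(cond),
                grp["rate"].to_numpy(float),
                grp["count"].to_numpy(int),
                standardized=None if np.all(np.isnan(z)) else z,
            )
        )
    return out
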