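"""End-to-end analysis pipeline and operating-characteristic evaluation.

``run_pipeline`` takes a trial table through the complete analysis: phase
binning, standardization, the mixed condition x bin x order ANOVA in both
error modes (on raw and standardized rates), per-participant sinusoidal
fits with the paired amplitude and goodness-of-fit comparisons, and the
condition x time-course repeated-measures ANOVA with Greenhouse-Geisser
correction and Holm-corrected post-hoc tests against the first trial bin.

``operating_characteristics`` establishes what the pipeline can and cannot
detect: it simulates cohorts across a grid of entrainment amplitudes and
records the rejection rate of the amplitude t-test (type-I error at A = 0,
power elsewhere) together with amplitude-recovery error, using the exact
least-squares fits on the bulk path.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import anova, binning, config as cfgmod, inference, sinefit
from .design import SessionPlan, validate_trials
from .observer import PopulationSpec, hit_probability, ObserverParams, simulate_cohort

__all__ = ["run_pipeline", "operating_characteristics", "expected_alpha1"]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _anova_long(binned, order_of, standardized):
    rows = []
    for br in binned:
        vals = br.standardized if standardized else br.rates
        for b, v in enumerate(vals):
            rows.append(
                {
                    "participant_id": br.participant_id,
                    "order": order_of[br.participant_id],
                    "condition": br.condition,
                    "bin": b,
                    "value": v,
                }
            )
    return pd.DataFrame(rows)


def _posthoc_vs_first(tc: pd.DataFrame) -> pd.DataFrame:
    """Paired t of time bin 0 against every later bin, Holm-adjusted.

    Rates are averaged over conditions per participant first (the post-hoc
    follows the time-bin main effect).
    """
    wide = (
        tc.groupby(["participant_id", "tbin"])["rate"].mean().unstack("tbin")
    )
    first = wide[0]
    rows = []
    for b in wide.columns[1:]:
        t, df, p = inference.paired_t(first, wide[b])
        rows.append({"bin": int(b), "t": t, "df": df, "p": p,
                     "mean_first": float(first.mean()),
                     "mean_bin": float(wide[b].mean())})
    out = pd.DataFrame(rows)
    out["p_holm"] = inference.holm(out["p"].to_numpy())
    return out


def run_pipeline(
    trials: pd.DataFrame,
    cfg: dict | None = None,
    seed: int = 0,
    out_dir=None,
    make_figures: bool = False,
) -> dict:
    """Full behavioral analysis of a trial table; returns a results dict.

    With ``out_dir`` set, writes ``results.json`` (every statistic plus the
    config snapshot and its hash) and, if ``make_figures``, the bin-profile
    and time-course figures.
    """
    cfg = dict(cfg or cfgmod.default_config())
    problems = validate_trials(trials, period=cfg.get("pulse_period", 100.0))
    if problems:
        raise ValueError(
            "trial table failed validation:\n- " + "\n- ".join(problems)
        )
    order_of = (
        trials.groupby("participant_id")["order"].first().to_dict()
    )

    binned = binning.detection_rates(
        trials, width=cfg["bin_width"], period=cfg["pulse_period"]
    )
    norm = cfg.get("normalize", "z")
    if norm != "none":
        binned = [binning.standardize(br, mode=norm) for br in binned]

    results: dict = {
        "config": cfg,
        "config_hash": cfgmod.config_hash(cfg),
        "seed": seed,
        "n_participants": len(order_of),
    }

    long_raw = _anova_long(binned, order_of, standardized=False)
    results["mixed_anova_raw"] = {
        mode: anova.mixed_anova(long_raw, error_mode=mode)
        for mode in ("stratified", "pooled")
    }
    if norm != "none":
        long_std = _anova_long(binned, order_of, standardized=True)
        results["mixed_anova_standardized"] = {
            mode: anova.mixed_anova(long_std, error_mode=mode)
            for mode in ("stratified", "pooled")
        }

    # per-participant sinusoidal fits on the (standardized) bin rates
    fits: dict[str, dict[str, sinefit.SineFit]] = {"sham": {}, "otcs": {}}
    rng = np.random.default_rng(seed)
    for br in binned:
        y = br.standardized if norm != "none" else br.rates
        fits[br.condition][br.participant_id] = sinefit.fit_sine(
            y,
            n_starts=cfg["n_starts"],
            seed=int(rng.integers(2**31)),
            method=cfg.get("fit_method", "multistart"),
        )
    pids = sorted(fits["sham"])
    fits_sham = [fits["sham"][p] for p in pids]
    fits_otcs = [fits["otcs"][p] for p in pids]
    results["sine_fits"] = {
        cond: {
            p: {k: getattr(f, k) for k in
                ("alpha0", "alpha1", "phi", "sse", "r2", "adj_r2", "converged")}
            for p, f in fits[cond].items()
        }
        for cond in fits
    }
    results["amplitude_comparison"] = sinefit.compare_conditions(
        fits_sham, fits_otcs, prior_scale=cfg["prior_scale"],
        dp_seed=int(rng.integers(2**31)),
    )

    # time-course: condition x consecutive-trial bins
    tc = binning.timecourse_bins(trials, bin_size=cfg["timecourse_bin_size"])
    tc_long = tc.rename(columns={"tbin": "bin", "rate": "value"})
    results["timecourse_anova"] = anova.rm_anova(
        tc_long, within=("condition", "bin")
    )
    results["timecourse_posthoc"] = _posthoc_vs_first(tc)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "results.json", "w") as fh:
            json.dump(_serialize_results(results), fh, indent=1)
        binning.rates_to_frame(binned).to_csv(
            out_dir / "binned_rates.csv", index=False
        )
        fit_rows = [
            {"participant_id": p, "condition": cond,
             **{k: getattr(f, k) for k in
                ("alpha0", "alpha1", "phi", "sse", "r2", "adj_r2",
                 "converged")}}
            for cond in fits for p, f in sorted(fits[cond].items())
        ]
        pd.DataFrame(fit_rows).to_csv(out_dir / "sine_fits.csv", index=False)
        if make_figures:
            _figures(binned, fits, tc, out_dir, norm)
    return results


def _serialize_results(results: dict) -> dict:
    out = {}
    for k, v in results.items():
        if isinstance(v, pd.DataFrame):
            out[k] = _jsonable(v)
        elif isinstance(v, dict) and any(
            isinstance(x, pd.DataFrame) for x in v.values()
        ):
            out[k] = {kk: _jsonable(vv) for kk, vv in v.items()}
        else:
            out[k] = _jsonable(v)
    return out


def _figures(binned, fits, tc, out_dir, norm):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t_dense = np.linspace(0, 100, 200)
    centers = sinefit.bin_centers()
    fig, ax = plt.subplots(figsize=(6, 4))
    for cond, color in (("sham", "tab:red"), ("otcs", "tab:blue")):
        mats = np.array([
            (br.standardized if norm != "none" else br.rates)
            for br in binned if br.condition == cond
        ])
        mean = np.nanmean(mats, axis=0)
        se = np.nanstd(mats, axis=0, ddof=1) / np.sqrt(mats.shape[0])
        ax.errorbar(centers, mean, yerr=se, fmt="o", color=color, label=cond)
        group_fit = sinefit.fit_sine(mean, method="analytic")
        ax.plot(t_dense, group_fit.predict(t_dense), color=color, alpha=0.7)
    ax.set_xlabel("pulse-to-target SOA (ms)")
    ax.set_ylabel("standardized detection rate" if norm != "none"
                  else "detection rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "bin_profile.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    for cond, color in (("sham", "tab:red"), ("otcs", "tab:blue")):
        sub = tc[tc["condition"] == cond]
        g = sub.groupby("tbin")["rate"]
        mean, se = g.mean(), g.std(ddof=1) / np.sqrt(g.count())
        ax.errorbar(mean.index + 1, mean, yerr=se, fmt="o-", color=color,
                    label=cond)
    ax.set_xlabel("bin of 32 consecutive trials")
    ax.set_ylabel("detection rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "timecourse.png", dpi=120)
    plt.close(fig)


def _amplitude_test_fast(trials: pd.DataFrame, bin_width=10.0, period=100.0):
    """Paired t on fitted amplitudes, exact-fit bulk path.

    Returns (t, df, p, mean alpha1 sham, mean alpha1 otcs).  Participants
    with an empty or constant bin profile in either condition are dropped
    pairwise (rare at the default trial counts).
    """
    binned = binning.detection_rates(trials, width=bin_width, period=period)
    prof: dict[str, dict[str, np.ndarray]] = {}
    for br in binned:
        ok = ~np.isnan(br.rates)
        if ok.sum() == len(br.rates) and np.ptp(br.rates) > 0:
            z = (br.rates - br.rates.mean()) / br.rates.std(ddof=1)
            prof.setdefault(br.participant_id, {})[br.condition] = z
    pids = [p for p, d in prof.items() if len(d) == 2]
    Y_sham = np.array([prof[p]["sham"] for p in pids])
    Y_otcs = np.array([prof[p]["otcs"] for p in pids])
    f_sham = sinefit.batch_fit(Y_sham)
    f_otcs = sinefit.batch_fit(Y_otcs)
    t, df, p = inference.paired_t(f_otcs["alpha1"], f_sham["alpha1"])
    return t, df, p, float(f_sham["alpha1"].mean()), float(f_otcs["alpha1"].mean())


def expected_alpha1(
    entrain_amp: float,
    params: ObserverParams | None = None,
    period: float = 100.0,
    n_bins: int = 10,
) -> float:
    """Amplitude the sine fit would recover from the noise-free profile.

    Evaluates the generative hit probability at the bin centers for an
    observer at threshold luminance with the given entrainment amplitude,
    standardizes the profile, and fits the sinusoid exactly.  This is the
    recovery target on the standardized-rate scale (the generative
    amplitude lives on log-odds, so the two are not directly comparable).
    """
    if entrain_amp == 0:
        return 0.0
    params = params or ObserverParams()
    centers = sinefit.bin_centers(n_bins, period / n_bins)
    p = hit_probability(
        params.threshold, centers, 0.0,
        ObserverParams(
            threshold=params.threshold, slope=params.slope, lapse=params.lapse,
            entrain_amp=entrain_amp, entrain_phase=0.0,
        ),
        entrain_on=True, is_second_condition=False, period=period,
    )
    z = (p - p.mean()) / p.std(ddof=1)
    return float(sinefit.fit_sine(z, method="analytic").alpha1)


def operating_characteristics(
    amps,
    n_sims: int = 200,
    n_participants: int = 36,
    plan: SessionPlan | None = None,
    population: PopulationSpec | None = None,
    seed: int = 0,
    alpha: float = 0.05,
    progress: bool = False,
) -> pd.DataFrame:
    """Type-I error / power / amplitude recovery across entrainment amplitudes.

    For each amplitude A, simulates ``n_sims`` cohorts, runs the amplitude
    analysis (phase binning, z-scoring, exact sinusoid fits, paired t-test)
    and tabulates the rejection rate at the given alpha with its Monte-Carlo
    standard error, plus the bias and RMSE of the fitted otCS amplitude
    against the noise-free expectation from :func:`expected_alpha1`.
    """
    if n_sims < 2:
        raise ValueError("need n_sims >= 2")
    plan = plan or SessionPlan()
    population = population or PopulationSpec()
    ss = np.random.SeedSequence(seed)
    rows = []
    for a_i, A in enumerate(amps):
        target = expected_alpha1(A)
        rej = np.empty(n_sims, dtype=bool)
        amp_otcs = np.empty(n_sims)
        amp_excess = np.empty(n_sims)
        child = ss.spawn(n_sims)
        for s in range(n_sims):
            sim_seed = int(child[s].generate_state(1)[0] % (2**31))
            trials = simulate_cohort(
                n_participants, plan, population, entrain_amp=A,
                seed=sim_seed,
            )
            t, df, p, m_sham, m_otcs = _amplitude_test_fast(
                trials, plan.pulse_period / 10, plan.pulse_period
            )
            rej[s] = p < alpha
            amp_otcs[s] = m_otcs
            amp_excess[s] = m_otcs - m_sham
            if progress and (s + 1) % 50 == 0:
                print(f"A={A}: {s + 1}/{n_sims}", flush=True)
        rate = float(rej.mean())
        rows.append(
            {
                "entrain_amp": float(A),
                "rejection_rate": rate,
                "rejection_mc_se": float(
                    np.sqrt(max(rate * (1 - rate), 1e-12) / n_sims)
                ),
                "expected_alpha1": target,
                "mean_alpha1_otcs": float(amp_otcs.mean()),
                "mean_alpha1_excess": float(amp_excess.mean()),
                "alpha1_bias": float(amp_otcs.mean() - target),
                "alpha1_rmse": float(
                    np.sqrt(np.mean((amp_otcs - target) ** 2))
                ),
                "n_sims": n_sims,
            }
        )
    return pd.DataFrame(rows)
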