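"""Balanced repeated-measures and split-plot ANOVA with sphericity machinery.

Handles the two designs the detection analysis needs:

* a three-factor mixed (split-plot) ANOVA — two crossed within-subject
  factors (stimulation condition, phase bin) and one between-subject factor
  (condition order), subjects nested in order; and
* pure within-subject ANOVA with one or two factors (e.g. condition x
  12 time-course bins), with Mauchly's sphericity test and
  Greenhouse-Geisser corrected degrees of freedom per within effect.

All sums of squares are the classical balanced-design decompositions
computed from marginal means; in a balanced complete layout the effect
arrays are mutually orthogonal so they sum exactly to the total SS.

Two error modes are provided for the mixed design.  ``stratified`` is the
textbook split-plot analysis: every within effect is tested against its own
subject-interaction stratum (e.g. condition x order on df (1, 34) with 36
subjects in 2 groups).  ``pooled`` instead enters the participant as a
single additive blocking factor and pools all remaining subject-by-within
variation into one residual — for the 36 x 2 x 10 design that residual has
720 - 74 = 646 degrees of freedom.  The pooled mode exists because some
published analyses report exactly this df structure; stratified is the
statistically conventional default.

Mauchly's W is computed from the pooled within-group covariance of
orthonormal contrast scores, with the standard chi-square approximation
chi2 = -(1 - (2d^2 + d + 2) / (6 d n_r)) * n_r * ln W on
d(d+1)/2 - 1 degrees of freedom (d = contrast dimension, n_r = residual
subject df) plus Box's second-order correction term, matching the ezANOVA /
SPSS convention; epsilon is (sum lambda)^2 / (d sum lambda^2) over the
eigenvalues of the contrast covariance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import helmert

__all__ = ["mixed_anova", "rm_anova", "ANOVA_COLUMNS"]

ANOVA_COLUMNS = [
    "effect", "ss", "df_num", "df_den", "F", "p",
    "mauchly_w", "mauchly_p", "gg_epsilon", "df_num_gg", "df_den_gg", "p_gg",
]


class DesignError(ValueError):
    """The data do not form a balanced complete design."""


def _pivot(data, dv, subject, within, between):
    """Reshape the long table to Y[subject, w1, w2] plus group labels."""
    factors = [subject, *within] + ([between] if between else [])
    counts = data.groupby(factors, sort=True).size()
    bad = counts[counts != 1]
    if len(bad):
        cell = dict(zip(factors, np.atleast_1d(bad.index[0])))
        raise DesignError(
            f"design not balanced/complete: cell {cell} has "
            f"{int(bad.iloc[0])} observations (expected 1)"
        )
    w1 = within[0]
    w2 = within[1] if len(within) > 1 else None
    subjects = np.sort(data[subject].unique())
    lv1 = np.sort(data[w1].unique())
    lv2 = np.sort(data[w2].unique()) if w2 else np.array([0])
    idx = [subject, w1] + ([w2] if w2 else [])
    wide = data.set_index(idx)[dv]
    shape = (len(subjects), len(lv1), len(lv2))
    Y = np.full(shape, np.nan)
    try:
        for si, s in enumerate(subjects):
            for i, a in enumerate(lv1):
                if w2:
                    for j, b in enumerate(lv2):
                        Y[si, i, j] = wide.loc[(s, a, b)]
                else:
                    Y[si, i, 0] = wide.loc[(s, a)]
    except KeyError as exc:
        raise DesignError(f"missing cell in the design: {exc.args[0]}") from exc
    if np.any(np.isnan(Y)):
        raise DesignError("missing cells in the design")
    if between:
        gmap = data.groupby(subject, sort=True)[between].agg(
            lambda x: x.unique()[0] if x.nunique() == 1 else np.nan
        )
        if gmap.isna().any():
            raise DesignError("a subject appears in more than one group")
        groups = np.sort(gmap.unique())
        go = np.searchsorted(groups, gmap.loc[subjects].to_numpy())
        sizes = np.bincount(go)
        if len(set(sizes)) != 1:
            raise DesignError(
                f"unequal group sizes {dict(zip(groups, sizes))}; "
                "balanced design required"
            )
    else:
        groups = np.array(["all"])
        go = np.zeros(len(subjects), dtype=int)
    return Y, go, groups, lv1, lv2, subjects


def _group_mean(Y, go, g):
    """Means over subjects per group, broadcast back to subject axis."""
    out = np.empty_like(Y)
    for k in range(g):
        out[go == k] = Y[go == k].mean(axis=0, keepdims=True)
    return out


def _decompose(Y, go, g):
    """Orthogonal effect arrays for the balanced split-plot layout."""
    n, a, b = Y.shape
    m = Y.mean()
    mg = _group_mean(Y, go, g)                       # [s,i,j] group cell means
    G = mg.mean(axis=(1, 2), keepdims=True)          # group grand mean per subj
    ms = Y.mean(axis=(1, 2), keepdims=True)          # subject means
    mi = Y.mean(axis=(0, 2), keepdims=True)          # w1 means
    mj = Y.mean(axis=(0, 1), keepdims=True)          # w2 means
    mij = Y.mean(axis=0, keepdims=True)              # w1 x w2 means
    mgi = mg.mean(axis=2, keepdims=True)             # group x w1
    mgj = mg.mean(axis=1, keepdims=True)             # group x w2
    msi = Y.mean(axis=2, keepdims=True)              # subject x w1
    msj = Y.mean(axis=1, keepdims=True)              # subject x w2

    eff = {
        "O": G - m,
        "S(O)": ms - G,
        "A": mi - m,
        "B": mj - m,
        "OA": mgi - G - mi + m,
        "OB": mgj - G - mj + m,
        "AB": mij - mi - mj + m,
        "OAB": mg - mgi - mgj - mij + G + mi + mj - m,
        "AS(O)": msi - ms - mgi + G,
        "BS(O)": msj - ms - mgj + G,
        "ABS(O)": None,  # residual, filled below
    }
    total = np.zeros_like(Y)
    for k, v in eff.items():
        if v is not None:
            total = total + v
    eff["ABS(O)"] = Y - m - total
    ss = {k: float(np.sum(np.broadcast_to(v, Y.shape) ** 2))
          for k, v in eff.items()}
    n_per = n // g
    df = {
        "O": g - 1,
        "S(O)": n - g,
        "A": a - 1,
        "B": b - 1,
        "OA": (g - 1) * (a - 1),
        "OB": (g - 1) * (b - 1),
        "AB": (a - 1) * (b - 1),
        "OAB": (g - 1) * (a - 1) * (b - 1),
        "AS(O)": (a - 1) * (n - g),
        "BS(O)": (b - 1) * (n - g),
        "ABS(O)": (a - 1) * (b - 1) * (n - g),
    }
    return ss, df


def _contrast(levels: int) -> np.ndarray:
    """Orthonormal (levels-1, levels) contrast rows summing to zero."""
    return helmert(levels, full=False)


def _sphericity(Ycells, go, g, M):
    """Mauchly W, its chi-square p, and GG epsilon for one within effect.

    Ycells: subjects x within-cells matrix; M: contrast rows for the effect.
    Covariance pooled within groups (residual subject df n - g).
    """
    n = Ycells.shape[0]
    nr = n - g
    d = M.shape[0]
    centered = Ycells - _group_mean(
        Ycells[:, :, None], go, g
    )[:, :, 0]
    scores = centered @ M.T
    S = scores.T @ scores / nr
    lam = np.linalg.eigvalsh(S)
    lam = np.clip(lam, 0, None)
    tr = lam.sum()
    if tr <= 0:
        return np.nan, np.nan, 1.0
    eps = float(tr**2 / (d * np.sum(lam**2)))
    eps = float(np.clip(eps, 1.0 / d, 1.0))
    det = float(np.prod(lam))
    W = det / (tr / d) ** d
    if W <= 0 or nr <= d:        # singular covariance: W degenerate
        return (0.0 if W <= 0 else W), np.nan, eps
    # chi-square approximation with Box's second-order term (as in ezANOVA)
    f = 1.0 - (2 * d * d + d + 2) / (6.0 * d * nr)
    k = d + 1
    w2 = (
        (d + 2) * (d - 1) * (d - 2) * (2 * d**3 + 6 * d**2 + 3 * k + 2)
        / (288.0 * (nr * d * f) ** 2)
    )
    chi2 = -nr * f * np.log(W)
    ddof = d * (d + 1) // 2 - 1
    p1 = stats.chi2.sf(chi2, ddof)
    p2 = stats.chi2.sf(chi2, ddof + 4)
    p = float(p1 + w2 * (p2 - p1))
    return float(W), p, eps


def _row(effect, ss_e, df_e, ss_err, df_err, sph=None):
    ms_e = ss_e / df_e if df_e > 0 else np.nan
    ms_err = ss_err / df_err if df_err > 0 else np.nan
    F = ms_e / ms_err if (df_e > 0 and ms_err > 0) else np.nan
    p = float(stats.f.sf(F, df_e, df_err)) if np.isfinite(F) else np.nan
    row = {
        "effect": effect, "ss": ss_e, "df_num": df_e, "df_den": df_err,
        "F": F, "p": p,
        "mauchly_w": np.nan, "mauchly_p": np.nan, "gg_epsilon": np.nan,
        "df_num_gg": np.nan, "df_den_gg": np.nan, "p_gg": np.nan,
    }
    if sph is not None:
        W, wp, eps = sph
        row.update(
            mauchly_w=W, mauchly_p=wp, gg_epsilon=eps,
            df_num_gg=eps * df_e, df_den_gg=eps * df_err,
            p_gg=float(stats.f.sf(F, eps * df_e, eps * df_err))
            if np.isfinite(F) else np.nan,
        )
    return row


def _anova(data, dv, subject, within, between, error_mode, sphericity):
    if error_mode not in ("stratified", "pooled"):
        raise ValueError(f"unknown error_mode {error_mode!r}")
    within = tuple(within)
    if not 1 <= len(within) <= 2:
        raise ValueError("one or two within factors supported")
    Y, go, groups, lv1, lv2, _ = _pivot(data, dv, subject, within, between)
    g = len(groups)
    n, a, b = Y.shape
    if a < 2:
        raise ValueError(f"within factor {within[0]!r} needs >= 2 levels")
    ss, df = _decompose(Y, go, g)

    name = {
        "A": within[0], "B": within[1] if len(within) > 1 else None,
        "O": between,
    }

    def label(key):
        parts = []
        for sym in key:
            parts.append(name[sym])
        return " x ".join(parts)

    # sphericity contrasts on flattened within cells (order: w1 major, w2 minor)
    Ycells = Y.reshape(n, a * b)
    Ca, Cb = _contrast(a), (None if b == 1 else _contrast(b))
    ones_a, ones_b = np.full((1, a), 1.0 / a), np.full((1, b), 1.0 / b)
    contrasts = {"A": np.kron(Ca, ones_b)}
    if b > 1:
        contrasts["B"] = np.kron(ones_a, Cb)
        contrasts["AB"] = np.kron(Ca, Cb)

    strata = {"A": "AS(O)", "OA": "AS(O)", "B": "BS(O)", "OB": "BS(O)",
              "AB": "ABS(O)", "OAB": "ABS(O)"}
    fixed = ["A"] + (["OA"] if g > 1 else [])
    if b > 1:
        fixed += ["B"] + (["OB"] if g > 1 else [])
        fixed += ["AB"] + (["OAB"] if g > 1 else [])

    rows = []
    if g > 1:
        rows.append(_row(label("O"), ss["O"], df["O"], ss["S(O)"], df["S(O)"]))
    if error_mode == "pooled":
        ss_res = ss["AS(O)"] + ss["BS(O)"] + ss["ABS(O)"]
        df_res = df["AS(O)"] + df["BS(O)"] + df["ABS(O)"]
    for key in fixed:
        if error_mode == "pooled":
            ss_err, df_err = ss_res, df_res
            sph = None
        else:
            err = strata[key]
            ss_err, df_err = ss[err], df[err]
            base = key.lstrip("O") or key
            sph = None
            if sphericity and base in contrasts:
                if df[base] == 1:
                    sph = (1.0, 1.0, 1.0)  # two levels: sphericity trivial
                else:
                    sph = _sphericity(Ycells, go, g, contrasts[base])
        rows.append(_row(label(key), ss[key], df[key], ss_err, df_err, sph))
    table = pd.DataFrame(rows, columns=ANOVA_COLUMNS)
    table.attrs["ss_total"] = float(np.sum((Y - Y.mean()) ** 2))
    table.attrs["ss_components"] = ss
    table.attrs["df_components"] = df
    table.attrs["error_mode"] = error_mode
    return table


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "participant_id",
    within: tuple[str, ...] = ("condition", "bin"),
    between: str = "order",
    error_mode: str = "stratified",
    sphericity: bool = True,
) -> pd.DataFrame:
    """Split-plot ANOVA: within factors crossed with a between-subject factor.

    Returns a table with one row per effect (ss, df, F, p and — for within
    effects with more than one numerator df in stratified mode — Mauchly's
    W, Greenhouse-Geisser epsilon and the corrected test).
    """
    if between is None:
        raise ValueError("between factor required; use rm_anova otherwise")
    return _anova(data, dv, subject, within, between, error_mode, sphericity)


def rm_anova(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "participant_id",
    within: tuple[str, ...] = ("bin",),
    sphericity: bool = True,
) -> pd.DataFrame:
    """Pure within-subject ANOVA (one or two factors), stratified errors."""
    return _anova(data, dv, subject, within, None, "stratified", sphericity)
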