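"""Per-subject behavioural analysis: filtering, type-I/type-II SDT, bias betas.

The analysis chain mirrors a standard metacognition psychophysics pipeline:

1. discard the first block (staircase stabilization), drop non-responses,
   reject trials with RT < 100 ms or |RT - mean| > 3 SD (single pass);
2. rank-bin raw 0-100 confidence into 4 equal-count quartile bins;
3. type-I signal detection: d' = z(H) - z(F), c = -(z(H)+z(F))/2 treating
   RIGHT as signal, with the 1/(2N) adjustment for extreme rates;
4. type-II AROC: area under the piecewise-linear ROC through the cumulative
   confidence-conditional hit/false-alarm rates P(conf >= k | correct) and
   P(conf >= k | incorrect), k = 2..4, anchored at (0,0) and (1,1).  0.5 means
   confidence carries no information about accuracy, 1.0 perfect insight;
5. within-subject OLS of confidence on standardized trial mean angle,
   direction SD, accuracy and RT — the SD weight is the variance-induced
   confidence bias;
6. a two-way repeated-measures ANOVA (8 within-session time bins x condition)
   on accuracy as a staircase-stability check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .behaviour import MU, SIGMA, CONDITIONS, NONE

N_CONF_BINS = 4


@dataclass
class FilterReport:
    n_input: int
    n_dropped_first_block: int
    n_dropped_no_response: int
    n_dropped_rt_fast: int
    n_dropped_rt_outlier: int
    n_retained: int

    def __post_init__(self):
        drops = (self.n_dropped_first_block + self.n_dropped_no_response
                 + self.n_dropped_rt_fast + self.n_dropped_rt_outlier)
        if self.n_retained != self.n_input - drops:
            raise ValueError("FilterReport counts do not reconcile")

    def to_dict(self):
        return dict(vars(self))


def filter_trials(trials: pd.DataFrame, rt_floor_ms: float = 100.0,
                  rt_sd_cut: float = 3.0):
    """Apply the trial-rejection rules; returns (retained, FilterReport).

    Order: drop block 1, drop non-responses, drop RT < ``rt_floor_ms``, then
    drop trials with |RT - mean| > ``rt_sd_cut`` * SD where mean and SD are
    computed once on the surviving set (no re-iteration, so re-applying the
    filter to its own output may drop further trials).
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    t = trials
    first_block = t["block"].min()
    keep = t["block"] != first_block
    n_block = int((~keep).sum())
    t = t[keep]
    responded = t["response"] != NONE
    n_none = int((~responded).sum())
    t = t[responded]
    fast = t["rt_ms"] < rt_floor_ms
    n_fast = int(fast.sum())
    t = t[~fast]
    if len(t):
        mu, sd = t["rt_ms"].mean(), t["rt_ms"].std(ddof=1)
        if np.isnan(sd):
            sd = 0.0
        outlier = (t["rt_ms"] - mu).abs() > rt_sd_cut * sd
    else:
        outlier = pd.Series(False, index=t.index)
    n_out = int(outlier.sum())
    t = t[~outlier].copy()
    report = FilterReport(len(trials), n_block, n_none, n_fast, n_out, len(t))
    return t, report


def bin_confidence_quartiles(trials: pd.DataFrame) -> pd.DataFrame:
    """Fill ``confidence_bin`` by rank-based quartile assignment (1..4).

    Ties are broken by ascending trial index, so the split is deterministic
    and bin sizes differ by at most one even under heavy ties.  Because the
    binning is purely rank-based, any strictly monotone transform of the raw
    confidence yields identical bins (and hence identical AROC).
    """
    n = len(trials)
    if n < N_CONF_BINS:
        raise ValueError(f"need >= {N_CONF_BINS} trials to quartile-bin, got {n}")
    t = trials.copy()
    conf = t["confidence_raw"].to_numpy(dtype=float)
    tidx = t["trial_index"].to_numpy()
    order = np.lexsort((tidx, conf))
    bins = np.empty(n, dtype=int)
    bins[order] = np.arange(n) * N_CONF_BINS // n + 1
    t["confidence_bin"] = bins
    return t


def compute_sdt(trials: pd.DataFrame):
    """Type-I sensitivity and criterion, treating RIGHT as the signal class.

    Hit rate H = P(resp RIGHT | RIGHT), false-alarm rate F =
    P(resp RIGHT | LEFT); d' = z(H) - z(F), c = -(z(H) + z(F))/2.  Rates of
    exactly 0 or 1 are replaced by 1/(2N) and 1 - 1/(2N) to keep d' finite.
    """
    right = trials[trials["true_side"] == "RIGHT"]
    left = trials[trials["true_side"] == "LEFT"]
    if len(right) == 0 or len(left) == 0:
        raise ValueError("need trials of both stimulus classes for d'/c")

    def _rate(sub):
        n = len(sub)
        r = (sub["response"] == "RIGHT").mean()
        if r == 0.0:
            r = 1.0 / (2 * n)
        elif r == 1.0:
            r = 1.0 - 1.0 / (2 * n)
        return r

    zH, zF = sps.norm.ppf(_rate(right)), sps.norm.ppf(_rate(left))
    return float(zH - zF), float(-(zH + zF) / 2.0)


@dataclass
class Type2ROC:
    """Cumulative type-II ROC over 4 confidence bins and its area."""

    bin_counts_correct: np.ndarray
    bin_counts_incorrect: np.ndarray
    cumulative_hit: np.ndarray   # P(conf >= k | correct), k = 2..4
    cumulative_fa: np.ndarray    # P(conf >= k | incorrect), k = 2..4
    aroc: float

    def __post_init__(self):
        if np.any(np.diff(self.cumulative_hit) > 1e-12) or \
           np.any(np.diff(self.cumulative_fa) > 1e-12):
            raise ValueError("cumulative ROC series must be non-increasing in k")
        if not 0.0 <= self.aroc <= 1.0:
            raise ValueError("AROC outside [0, 1]")


def aroc_from_counts(counts_correct, counts_incorrect) -> Type2ROC:
    """Type-II AROC from per-bin confidence counts (bin 1 = lowest)."""
    cc = np.asarray(counts_correct, dtype=float)
    ic = np.asarray(counts_incorrect, dtype=float)
    if cc.shape != (N_CONF_BINS,) or ic.shape != (N_CONF_BINS,):
        raise ValueError(f"expected {N_CONF_BINS} confidence-bin counts")
    if cc.sum() == 0:
        raise ValueError("no correct trials: type-II AROC undefined")
    if ic.sum() == 0:
        raise ValueError("no incorrect trials: type-II AROC undefined")
    h = cc / cc.sum()
    f = ic / ic.sum()
    # interior criteria conf >= k for k = 4, 3, 2 (strict to lax)
    hit = np.array([h[k:].sum() for k in range(N_CONF_BINS - 1, 0, -1)])
    fa = np.array([f[k:].sum() for k in range(N_CONF_BINS - 1, 0, -1)])
    x = np.concatenate(([0.0], fa, [1.0]))
    y = np.concatenate(([0.0], hit, [1.0]))
    area = 0.0
    for i in range(len(x) - 1):
        area += (x[i + 1] - x[i]) * (y[i] + y[i + 1]) / 2.0
    return Type2ROC(cc, ic, hit[::-1], fa[::-1], float(area))


def compute_aroc(trials: pd.DataFrame) -> Type2ROC:
    """Type-II AROC of a binned trial table (``confidence_bin`` filled)."""
    if trials["confidence_bin"].isna().any():
        raise ValueError("confidence_bin not filled; run bin_confidence_quartiles")
    bins = trials["confidence_bin"].to_numpy(dtype=int)
    correct = trials["correct"].to_numpy(dtype=bool)
    cc = np.bincount(bins[correct], minlength=N_CONF_BINS + 1)[1:]
    ic = np.bincount(bins[~correct], minlength=N_CONF_BINS + 1)[1:]
    return aroc_from_counts(cc, ic)


BIAS_PREDICTORS = {"mean": "mean_angle", "variance": "sd_angle",
                   "accuracy": "correct", "rt": "rt_ms"}


def confidence_bias_betas(trials: pd.DataFrame, min_trials: int = 20) -> dict:
    """Within-subject OLS of raw confidence on trial stimulus statistics.

    Predictors (z-standardized within subject): trial mean angle, direction
    SD, accuracy and RT; the SD weight is the variance-induced confidence
    bias.  Constant predictors are dropped (beta NaN) and listed under
    ``dropped``.  Returns betas, their standard errors, and the intercept.
    """
    import statsmodels.api as sm

    if len(trials) < min_trials:
        raise ValueError(f"need >= {min_trials} trials for the bias regression")
    y = trials["confidence_raw"].to_numpy(dtype=float)
    cols, names, dropped = [], [], []
    for name, col in BIAS_PREDICTORS.items():
        x = trials[col].to_numpy(dtype=float)
        s = x.std(ddof=0)
        if s == 0:
            dropped.append(name)
            continue
        cols.append((x - x.mean()) / s)
        names.append(name)
    X = sm.add_constant(np.column_stack(cols) if cols else np.empty((len(y), 0)))
    fit = sm.OLS(y, X).fit()
    out = {"intercept": float(fit.params[0]),
           "se_intercept": float(fit.bse[0]), "dropped": dropped}
    for i, name in enumerate(names, start=1):
        out[name] = float(fit.params[i])
        out[f"se_{name}"] = float(fit.bse[i])
    for name in dropped:
        out[name] = np.nan
        out[f"se_{name}"] = np.nan
    return out


def _rebin_accuracy(trials: pd.DataFrame, subject: int, n_bins: int = 8):
    rows = []
    for cond in CONDITIONS:
        sub = trials[trials["condition"] == cond].sort_values("trial_index")
        if len(sub) < n_bins:
            raise ValueError(
                f"subject {subject}: only {len(sub)} {cond} trials, "
                f"cannot form {n_bins} bins")
        for b, chunk in enumerate(np.array_split(sub["correct"].to_numpy(), n_bins)):
            rows.append(dict(subject=subject, condition=cond, time_bin=b + 1,
                             accuracy=float(np.mean(chunk))))
    return rows


def staircase_stability_anova(trial_tables, n_bins: int = 8) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA of accuracy on time bin x condition.

    Each subject's retained trials are re-binned per condition into
    ``n_bins`` equal-count bins of consecutive trials; per-cell accuracy
    enters a two-way within-subject ANOVA (subject as random factor).
    Returns a table with F, df, uncorrected and Greenhouse-Geisser-adjusted
    p-values for both main effects and the interaction.  A stable staircase
    shows no time-bin main effect or interaction.
    """
    import pingouin as pg

    rows = []
    for subject, trials in enumerate(trial_tables):
        rows.extend(_rebin_accuracy(trials, subject, n_bins))
    cells = pd.DataFrame(rows)
    if cells["accuracy"].nunique() == 1:
        # no variance anywhere: all effect and error sums of squares are 0
        src = ["time_bin", "condition", "time_bin * condition"]
        return pd.DataFrame({"Source": src, "F": 0.0, "p_unc": 1.0,
                             "p_GG_corr": 1.0, "eps": 1.0})
    table = pg.rm_anova(dv="accuracy", within=["time_bin", "condition"],
                        subject="subject", data=cells, detailed=True)
    keep = ["Source", "SS", "ddof1", "ddof2", "MS", "F", "p_unc",
            "p_GG_corr", "eps"]
    out = table[[c for c in keep if c in table.columns]].copy()
    out[["F", "p_unc"]] = out[["F", "p_unc"]].fillna({"F": 0.0, "p_unc": 1.0})
    return out


def _condition_summary(trials: pd.DataFrame, condition: str) -> dict:
    sub = trials[trials["condition"] == condition]
    if len(sub) == 0:
        raise ValueError(f"no retained trials in condition {condition}")
    d_prime, criterion = compute_sdt(sub)
    roc = compute_aroc(sub)
    level_col = "mean_angle" if condition == MU else "sd_angle"
    return dict(
        d_prime=d_prime, criterion=criterion,
        accuracy=float(sub["correct"].mean()),
        confidence_100=float(sub["confidence_raw"].mean()),
        confidence_bin=float(sub["confidence_bin"].mean()),
        aroc=roc.aroc,
        rt_ms=float(sub["rt_ms"].mean()),
        median_level=float(sub[level_col].median()),
        n_trials=int(len(sub)),
    )


SUMMARY_STATS = ["d_prime", "criterion", "accuracy", "confidence_100",
                 "confidence_bin", "aroc", "rt_ms"]


def summarise_subject(trials: pd.DataFrame, covariates: dict | None = None,
                      fixed_mean_angle: float = 15.0) -> pd.Series:
    """Per-subject summary: every statistic per condition plus the average.

    Expects filtered, quartile-binned trials.  Condition statistics carry
    ``_mu`` / ``_sigma`` suffixes; ``_avg`` is the mean of the two (AROC and
    d' are computed per condition first, then averaged).  Also includes the
    within-subject bias betas and the staircase mean-signal difference
    (median adaptive mean angle minus the fixed mean of the variance
    staircase).
    """
    out = {}
    per = {c: _condition_summary(trials, c) for c in CONDITIONS}
    for stat in SUMMARY_STATS + ["median_level", "n_trials"]:
        out[f"{stat}_mu"] = per[MU][stat]
        out[f"{stat}_sigma"] = per[SIGMA][stat]
    for stat in SUMMARY_STATS:
        out[f"{stat}_avg"] = (per[MU][stat] + per[SIGMA][stat]) / 2.0
    betas = confidence_bias_betas(trials)
    for name in ["intercept", *BIAS_PREDICTORS]:
        out[f"bias_{name}"] = betas[name]
        out[f"bias_se_{name}"] = betas[f"se_{name}"]
    out["staircase_mean_signal_diff"] = per[MU]["median_level"] - fixed_mean_angle
    if covariates:
        out.update({k: covariates[k] for k in ("age", "gender", "tiv")
                    if k in covariates})
    return pd.Series(out)


def summarise_cohort(sessions, truth: pd.DataFrame | None = None,
                     rt_floor_ms: float = 100.0, rt_sd_cut: float = 3.0):
    """Filter, bin and summarise every session of a cohort.

    ``sessions`` may be Session objects or raw trial DataFrames.  Returns
    ``(summaries, filtered_tables, reports)`` where ``summaries`` has one row
    per subject (covariates merged in from ``truth`` when given).
    """
    summaries, tables, reports = [], [], []
    for i, s in enumerate(sessions):
        trials = s.trials if hasattr(s, "trials") else s
        kept, rep = filter_trials(trials, rt_floor_ms, rt_sd_cut)
        kept = bin_confidence_quartiles(kept)
        cov = None
        if truth is not None:
            row = truth.iloc[i]
            cov = {k: row[k] for k in ("age", "gender", "tiv") if k in truth.columns}
        summary = summarise_subject(kept, covariates=cov)
        summary["subject"] = i
        summaries.append(summary)
        tables.append(kept)
        reports.append(rep)
    df = pd.DataFrame(summaries)
    df["subject"] = df["subject"].astype(int)
    return df.set_index("subject"), tables, reports
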