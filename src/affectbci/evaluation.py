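"""Offline and closed-loop evaluation statistics.

* repeated stratified k-fold cross-validation of the calibration model on
  1-s non-overlapping windows, with the binomial chance-level threshold;
* modulation statistics — resting mean (RM), action mean (AM), total
  deviation (TD), and the trial-averaged score difference — with
  one-tailed paired t-tests (right-tailed for the → happy task,
  left-tailed for → sad), marginal significance at p < 0.1;
* per-feature band-power contrasts (action minus rest, one observation
  per trial) with Bonferroni-corrected t-tests;
* Pearson correlations between performance measures and mood
  self-assessment items;
* pairwise (bivariate) Granger causality between the feedback score and
  each feature, fixed lag order, OLS F-tests, Bonferroni-corrected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .decoder import (
    EEGRecording,
    SigmoidLDA,
    compute_baseline,
    feature_index,
    segment_stream,
    _segment_features,
    DEFAULT_BANDS,
)
from .loop import SessionRecord

__all__ = [
    "CVResult",
    "ModulationStats",
    "TaskModulation",
    "GrangerResult",
    "cross_validate",
    "chance_threshold",
    "modulation_stats",
    "bandpower_contrast",
    "mood_correlations",
    "granger_pairwise",
    "action_series",
    "session_summary_table",
]

TASKS = ("to_happy", "to_sad")

MARGINAL_P = 0.1


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Repeated k-fold cross-validation summary (percentages in [0, 100])."""

    acc: float
    per_class: dict[str, float]
    auc: float
    n_obs: int
    table: pd.DataFrame = field(repr=False, default=None)


def cross_validate(
    calib_rec: EEGRecording,
    repeats: int = 100,
    folds: int = 10,
    seed: int = 0,
    window_s: float = 1.0,
    ridge: float | str = "auto",
    alpha: float = 2.0,
    bands: Sequence[tuple[str, float, float]] = DEFAULT_BANDS,
) -> CVResult:
    """Repeated stratified k-fold CV of the decoding pipeline.

    The two-class calibration data are partitioned into non-overlapping
    ``window_s`` windows (two 20-s presentations per class at 1 s → 80
    observations, 40 per class).  The baseline vector comes from the idle
    periods; feature standardization and the LDA are re-fit on the
    training folds of every split, so no statistics leak from the test
    fold.  Accuracy is reported overall and per class, AUC from the
    continuous discriminant on the test folds.
    """
    segs = segment_stream(
        calib_rec,
        window_s=window_s,
        step_s=window_s,
        labels={"happy", "sad", "idle"},
    )
    idle = [s for s in segs if s.label == "idle"]
    cls = [s for s in segs if s.label != "idle"]
    X_raw = np.asarray(
        [
            _segment_features(s.data, calib_rec.fs, bands)
            for s in cls
        ]
    )
    y = np.asarray([1 if s.label == "happy" else 0 for s in cls])
    baseline = compute_baseline(
        [_segment_features(s.data, calib_rec.fs, bands) for s in idle]
    )
    X = X_raw - baseline
    n_obs = len(y)
    if n_obs < folds:
        raise ValueError(
            f"{n_obs} observations cannot be split into {folds} folds"
        )

    rng = np.random.default_rng(seed)
    rows = []
    aucs = []
    acc_happy = []
    acc_sad = []
    acc_all = []
    for rep in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds,
            shuffle=True,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        dec_all = np.empty(n_obs)
        pred_all = np.empty(n_obs, dtype=int)
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            scaler = StandardScaler().fit(X[tr])
            model = SigmoidLDA(ridge=ridge, alpha=alpha).fit(
                scaler.transform(X[tr]), y[tr]
            )
            Z_te = scaler.transform(X[te])
            dec_all[te] = model.decision_function(Z_te)
            pred_all[te] = model.predict(Z_te)
            rows.append(
                {
                    "repeat": rep,
                    "fold": fold,
                    "acc": float(np.mean(pred_all[te] == y[te])) * 100.0,
                }
            )
        aucs.append(roc_auc_score(y, dec_all))
        acc_happy.append(np.mean(pred_all[y == 1] == 1) * 100.0)
        acc_sad.append(np.mean(pred_all[y == 0] == 0) * 100.0)
        acc_all.append(np.mean(pred_all == y) * 100.0)
    return CVResult(
        acc=float(np.mean(acc_all)),
        per_class={
            "happy": float(np.mean(acc_happy)),
            "sad": float(np.mean(acc_sad)),
        },
        auc=float(np.mean(aucs)),
        n_obs=n_obs,
        table=pd.DataFrame(rows),
    )


def chance_threshold(n_obs: int, p_sig: float = 0.05) -> float:
    """Binomial chance-level accuracy threshold, as a percentage.

    The inverse binomial CDF convention standard in BCI decoding: the
    smallest correct-classification count k with
    ``P(Binomial(n, 0.5) <= k) >= 1 - p_sig``, expressed as 100·k/n.
    For n = 80 at p < 0.05 this is 58.75 %.
    """
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    k = int(stats.binom.ppf(1.0 - p_sig, n_obs, 0.5))
    return 100.0 * k / n_obs


# ---------------------------------------------------------------------------
# modulation statistics
# ---------------------------------------------------------------------------

@dataclass
class TaskModulation:
    """Per-task modulation summary over trials."""

    task: str
    n_trials: int
    rm: float = math.nan  # resting mean
    am: float = math.nan  # action mean
    td: float = math.nan  # total deviation, task-signed
    s_diff: float = math.nan  # mean (action - rest) over trials
    t_stat: float = math.nan
    p_value: float = math.nan
    significant: bool = False
    available: bool = False


@dataclass
class ModulationStats:
    """Modulation statistics for both tasks of one session."""

    by_task: dict[str, TaskModulation]

    def __getitem__(self, task: str) -> TaskModulation:
        return self.by_task[task]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(v) for v in self.by_task.values()])


def _one_tailed_paired_t(
    action: np.ndarray, rest: np.ndarray, tail: str
) -> tuple[float, float]:
    diff = action - rest
    if np.allclose(diff, 0.0):
        return 0.0, 0.5  # no deviation at all: exactly the null midpoint
    alt = "greater" if tail == "right" else "less"
    res = stats.ttest_rel(action, rest, alternative=alt)
    return float(res.statistic), float(res.pvalue)


def modulation_stats(
    session: SessionRecord, marginal_p: float = MARGINAL_P
) -> ModulationStats:
    """RM/AM/TD and the trial-averaged score difference per task.

    For each task the per-trial rest and action score means are averaged
    into the resting mean RM and action mean AM; the total deviation is
    task-signed (TD_happy = AM − RM, TD_sad = RM − AM) so that positive
    TD always means modulation in the instructed direction.  A paired
    one-tailed t-test (right-tailed for → happy, left-tailed for → sad)
    over the per-trial means tests the modulation; a task with fewer than
    two trials is marked unavailable, mirroring the imbalanced-task
    situation that arises when a responder is strongly biased.
    """
    out: dict[str, TaskModulation] = {}
    for task in TASKS:
        trials = session.trials_of(task)
        tm = TaskModulation(task=task, n_trials=len(trials))
        if len(trials) >= 2:
            rest = np.asarray([t.rest_mean for t in trials])
            action = np.asarray([t.action_mean for t in trials])
            tm.rm = float(rest.mean())
            tm.am = float(action.mean())
            tm.td = tm.am - tm.rm if task == "to_happy" else tm.rm - tm.am
            tm.s_diff = float(np.mean(action - rest))
            tail = "right" if task == "to_happy" else "left"
            tm.t_stat, tm.p_value = _one_tailed_paired_t(action, rest, tail)
            tm.significant = tm.p_value < marginal_p
            tm.available = True
        out[task] = tm
    return ModulationStats(by_task=out)


# ---------------------------------------------------------------------------
# band-power contrast
# ---------------------------------------------------------------------------

def bandpower_contrast(
    sessions: Sequence[SessionRecord],
    task: str,
    p_sig: float = 0.05,
) -> pd.DataFrame:
    """Per-feature action-minus-rest band-power t-table.

    For every trial of the given task, the mean feature vector over the
    action-period segments minus the mean over the rest-period segments
    forms one observation.  Observations are scale-normalized within each
    session (divided by the per-feature SD across that session's trials,
    leaving the effect's sign and mean intact), pooled, and tested
    feature-wise against zero; the significance column applies the
    Bonferroni threshold ``p_sig / n_features``.
    """
    obs_all = []
    for sess in sessions:
        trials = sess.trials_of(task)
        obs = []
        for t in trials:
            if "action" not in t.segments or "rest" not in t.segments:
                continue
            obs.append(
                t.segments["action"].mean(axis=0)
                - t.segments["rest"].mean(axis=0)
            )
        if len(obs) == 0:
            continue
        obs = np.asarray(obs)
        sd = obs.std(axis=0, ddof=1) if len(obs) > 1 else np.ones(obs.shape[1])
        sd = np.where(sd > 0, sd, 1.0)
        obs_all.append(obs / sd)
    if not obs_all:
        raise ValueError(f"no trials of task {task!r} in the sessions")
    pooled = np.vstack(obs_all)
    if pooled.shape[0] < 2:
        raise ValueError("need at least 2 observations for the t-tests")

    n_feat = pooled.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_1samp(pooled, 0.0, axis=0)
    t_vals = np.nan_to_num(res.statistic, nan=0.0)
    p_vals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)

    model = sessions[0].model
    idx = feature_index(model.channel_names, model.band_defs)
    return pd.DataFrame(
        {
            "channel": [c for c, _ in idx],
            "band": [b for _, b in idx],
            "mean_diff": pooled.mean(axis=0),
            "t": t_vals,
            "p": p_vals,
            "significant": p_vals < (p_sig / n_feat),
        }
    )


# ---------------------------------------------------------------------------
# mood correlations
# ---------------------------------------------------------------------------

def session_summary_table(
    sessions: Sequence[SessionRecord],
) -> pd.DataFrame:
    """One row per session: the six performance measures plus mood items."""
    rows = []
    for sess in sessions:
        ms = modulation_stats(sess)
        row: dict = {"participant": sess.participant}
        for task in TASKS:
            tm = ms[task]
            suffix = task.removeprefix("to_")
            row[f"RM_{suffix}"] = tm.rm
            row[f"AM_{suffix}"] = tm.am
            row[f"TD_{suffix}"] = tm.td
        if sess.mood_ratings is not None:
            for i, v in enumerate(sess.mood_ratings):
                row[f"mood_{i + 1:02d}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def mood_correlations(
    sessions: Sequence[SessionRecord] | pd.DataFrame,
    p_sig: float = 0.05,
    marginal_p: float = MARGINAL_P,
) -> pd.DataFrame:
    """Pearson correlations: performance measures × mood items.

    Accepts session records (summarized via
    :func:`session_summary_table`) or a prebuilt table whose columns are
    the six measures (RM/AM/TD per task) and ``mood_*`` items.  Pairs
    with a zero-variance column get an undefined (NaN) correlation and
    are flagged.
    """
    if isinstance(sessions, pd.DataFrame):
        table = sessions
    else:
        table = session_summary_table(sessions)
    if len(table) < 3:
        raise ValueError("need at least 3 session rows")
    measures = [
        c
        for c in table.columns
        if c.split("_")[0] in ("RM", "AM", "TD")
    ]
    moods = [c for c in table.columns if c.startswith("mood_")]
    rows = []
    for m in measures:
        for item in moods:
            sub = table[[m, item]].dropna()
            x = sub[m].to_numpy(dtype=float)
            z = sub[item].to_numpy(dtype=float)
            if len(x) < 3 or np.std(x) == 0 or np.std(z) == 0:
                r, p, undef = math.nan, math.nan, True
            else:
                r, p = stats.pearsonr(x, z)
                undef = False
            rows.append(
                {
                    "measure": m,
                    "mood_item": item,
                    "r": r,
                    "p": p,
                    "n": len(x),
                    "undefined": undef,
                    "marginal": (not undef) and p < marginal_p,
                    "significant": (not undef) and p < p_sig,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Granger causality
# ---------------------------------------------------------------------------

def _lag_matrix(series: np.ndarray, nlags: int) -> np.ndarray:
    n = len(series) - nlags
    return np.column_stack(
        [series[nlags - k - 1 : nlags - k - 1 + n] for k in range(nlags)]
    )


def _granger_f(
    target: np.ndarray, predictor: np.ndarray, nlags: int
) -> tuple[float, float]:
    """F-test: do the predictor's lags improve an AR model of the target?

    Fixed lag order; OLS with intercept.  Restricted model: target on its
    own ``nlags`` lags.  Full model: plus the predictor's ``nlags`` lags.
    """
    n = len(target) - nlags
    if n <= 2 * nlags + 1:
        raise ValueError("series too short for the requested lag order")
    y = target[nlags:]
    self_lags = _lag_matrix(target, nlags)
    cross_lags = _lag_matrix(predictor, nlags)
    ones = np.ones((n, 1))
    X_r = np.hstack([ones, self_lags])
    X_f = np.hstack([ones, self_lags, cross_lags])
    rss_r = np.sum((y - X_r @ np.linalg.lstsq(X_r, y, rcond=None)[0]) ** 2)
    rss_f = np.sum((y - X_f @ np.linalg.lstsq(X_f, y, rcond=None)[0]) ** 2)
    df_num = nlags
    df_den = n - 2 * nlags - 1
    if rss_f <= 0:
        return math.inf, 0.0
    F = ((rss_r - rss_f) / df_num) / (rss_f / df_den)
    p = float(stats.f.sf(F, df_num, df_den))
    return float(F), p


@dataclass
class GrangerResult:
    """Directed score↔feature causality table plus test metadata."""

    table: pd.DataFrame
    nlags: int
    n_tests: int
    p_thresh: float

    def significant(self, direction: str) -> pd.DataFrame:
        col = {"f->s": "sig_f_to_s", "s->f": "sig_s_to_f"}[direction]
        return self.table[self.table[col]]


def granger_pairwise(
    score_series: np.ndarray,
    feature_matrix: np.ndarray,
    nlags: int = 10,
    p_thresh: float = 0.01,
    feature_names: Sequence[str] | None = None,
) -> GrangerResult:
    """Bivariate Granger causality between the score and every feature.

    For each feature, two OLS F-tests at fixed lag order ``nlags``:
    feature → score (do the feature's lags improve prediction of the
    score beyond the score's own lags?) and score → feature.  The
    significance flags apply a Bonferroni threshold over all tests
    actually performed (2 × n_features).  Constant or non-finite series
    are flagged and skipped.
    """
    s = np.asarray(score_series, dtype=float)
    Fm = np.atleast_2d(np.asarray(feature_matrix, dtype=float))
    if Fm.shape[0] == len(s) and Fm.shape[1] != len(s):
        Fm = Fm.T  # accept observations-in-rows
    n_feat = Fm.shape[0]
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(n_feat)]
    n_tests = 2 * n_feat
    thr = p_thresh / n_tests

    s_ok = np.isfinite(s).all() and np.std(s) > 0
    rows = []
    for i in range(n_feat):
        f = Fm[i]
        f_ok = np.isfinite(f).all() and np.std(f) > 0
        if s_ok and f_ok:
            F_fs, p_fs = _granger_f(s, f, nlags)
            F_sf, p_sf = _granger_f(f, s, nlags)
            skipped = False
        else:
            F_fs = p_fs = F_sf = p_sf = math.nan
            skipped = True
        rows.append(
            {
                "feature": feature_names[i],
                "F_f_to_s": F_fs,
                "p_f_to_s": p_fs,
                "sig_f_to_s": (not skipped) and p_fs < thr,
                "F_s_to_f": F_sf,
                "p_s_to_f": p_sf,
                "sig_s_to_f": (not skipped) and p_sf < thr,
                "skipped": skipped,
            }
        )
    return GrangerResult(
        table=pd.DataFrame(rows),
        nlags=nlags,
        n_tests=n_tests,
        p_thresh=p_thresh,
    )


def action_series(
    session: SessionRecord, task: str = "to_happy"
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated action-period observations for causality analysis.

    Returns (score series, features matrix with observations in rows):
    the 60 action-period score updates and the 60 window observations of
    every valid trial of the task, concatenated across trials.
    """
    scores = []
    feats = []
    for t in session.trials_of(task):
        if "action" not in t.segments:
            continue
        scores.extend(s.value for s in t.action_scores)
        feats.append(t.segments["action"])
    if not feats:
        raise ValueError(f"no trials of task {task!r} with stored segments")
    return np.asarray(scores), np.vstack(feats)
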