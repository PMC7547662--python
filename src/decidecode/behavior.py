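"""Behavioral analyses: reverse-correlation kernels and choice models.

The central statistic is the psychophysical kernel: for each of the ten
sample positions, the ROC area (AUC) comparing single-trial sample
contrasts between the two choices *within* each stimulus category (hits vs
misses for stronger-category trials, false alarms vs correct rejects for
weaker-category trials), with the two category-specific AUCs averaged.
Conditioning on category factors the physical stimulus out, so AUC > 0.5
means that contrast fluctuations above the category mean push the observer
toward "stronger" choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .trials import SAMPLE_COLUMNS

__all__ = [
    "roc_auc",
    "categorize_sdt",
    "psychophysical_kernel",
    "kernel_slope",
    "ChoiceModelFit",
    "fit_choice_logreg",
    "fit_confidence_logreg",
    "exclude_fast_rts",
    "contamination_free_boundary",
    "RT_EXCLUSION_THRESHOLD",
]

RT_EXCLUSION_THRESHOLD = 1.225  # s; trials faster than this are excluded


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney U statistic.

    ``labels`` are boolean (True = "stronger" choice / positive class).
    Ties contribute 0.5 per pair.  AUC > 0.5 means larger scores associate
    with the positive class.  Raises if only one class is present.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_auc requires both classes to be present")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def categorize_sdt(trials: pd.DataFrame) -> pd.Series:
    """Signal-detection labels per trial.

    stronger category + stronger choice -> hit; stronger + weaker -> miss;
    weaker + stronger -> false_alarm; weaker + weaker -> correct_reject.
    Trials with missing choice are dropped (count retained in attrs).
    """
    ok = trials["choice"].notna()
    t = trials[ok]
    stronger_cat = t["stimulus_category"] == "stronger"
    stronger_choice = t["choice"] == "stronger"
    labels = np.where(
        stronger_cat,
        np.where(stronger_choice, "hit", "miss"),
        np.where(stronger_choice, "false_alarm", "correct_reject"),
    )
    out = pd.Series(labels, index=t.index, name="sdt_label")
    out.attrs["n_excluded_missing_choice"] = int((~ok).sum())
    return out


def _cell_auc(values: np.ndarray, choices_stronger: np.ndarray) -> float:
    """AUC within one stimulus category; NaN if a choice cell is empty."""
    if choices_stronger.all() or (~choices_stronger).all():
        return np.nan
    return roc_auc(values, choices_stronger)


def psychophysical_kernel(
    trials: pd.DataFrame, value_columns: list | None = None
) -> np.ndarray:
    """AUC per sample position, category-balanced.

    For each position: AUC(hit vs miss) and AUC(false_alarm vs
    correct_reject) are computed separately and averaged.  Empty cells
    propagate as NaN (never imputed).  ``value_columns`` defaults to the
    contrast sample columns; passing other columns (e.g. band power per
    sample) yields neural-activity kernels.
    """
    cols = value_columns or SAMPLE_COLUMNS
    stronger_cat = (trials["stimulus_category"] == "stronger").to_numpy()
    stronger_choice = (trials["choice"] == "stronger").to_numpy()
    out = np.empty(len(cols))
    for i, col in enumerate(cols):
        v = trials[col].to_numpy(float)
        auc_hm = _cell_auc(v[stronger_cat], stronger_choice[stronger_cat])
        auc_fc = _cell_auc(v[~stronger_cat], stronger_choice[~stronger_cat])
        out[i] = np.nanmean([auc_hm, auc_fc]) if not (
            np.isnan(auc_hm) and np.isnan(auc_fc)) else np.nan
    return out


def kernel_slope(series: np.ndarray, positions: np.ndarray | None = None) -> float:
    """OLS slope of kernel values against sample position (1-based index)."""
    series = np.asarray(series, float)
    pos = np.arange(1, series.size + 1) if positions is None else np.asarray(positions, float)
    ok = np.isfinite(series)
    if ok.sum() < 2:
        raise ValueError("kernel_slope needs at least two non-missing positions")
    return float(np.polyfit(pos[ok], series[ok], 1)[0])


@dataclass
class ChoiceModelFit:
    """Cross-validated logistic regression of a binary report on the samples."""

    coefficients: np.ndarray   # intercept followed by the 10 sample weights
    cv_accuracy: float
    fold_assignments: np.ndarray
    separation_flagged: bool = False


def _logreg_cv(X: np.ndarray, y: np.ndarray, n_folds: int) -> ChoiceModelFit:
    if len(y) < 50:
        raise ValueError("need at least 50 trials for a cross-validated fit")
    if y.all() or (~y).all():
        raise ValueError("both response classes must be present")
    # tiny L2 penalty on z-scored predictors keeps fits finite under separation
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - mu) / sd
    model = LogisticRegression(C=1e6, solver="lbfgs", max_iter=2000)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=0)
    folds = np.empty(len(y), dtype=int)
    accs = []
    for k, (tr, te) in enumerate(skf.split(Xz, y)):
        folds[te] = k
        m = LogisticRegression(C=1e6, solver="lbfgs", max_iter=2000).fit(Xz[tr], y[tr])
        accs.append(float((m.predict(Xz[te]) == y[te]).mean()))
    model.fit(Xz, y)
    # map coefficients back to the raw contrast scale
    beta = model.coef_[0] / sd
    beta0 = float(model.intercept_[0] - (beta * mu).sum())
    flagged = bool(np.any(np.abs(model.coef_) > 50))
    return ChoiceModelFit(np.concatenate([[beta0], beta]), float(np.mean(accs)),
                          folds, flagged)


def fit_choice_logreg(trials: pd.DataFrame, n_folds: int = 5) -> ChoiceModelFit:
    """Predict choice from the ten sample contrasts (stratified 5-fold CV)."""
    X = trials[SAMPLE_COLUMNS].to_numpy(float)
    y = (trials["choice"] == "stronger").to_numpy()
    return _logreg_cv(X, y, n_folds)


def fit_confidence_logreg(trials: pd.DataFrame, n_folds: int = 5) -> dict:
    """Predict high-vs-low confidence from the samples, per choice separately."""
    out = {}
    for ch in ("stronger", "weaker"):
        sub = trials[trials["choice"] == ch]
        X = sub[SAMPLE_COLUMNS].to_numpy(float)
        y = (sub["confidence"] == "high").to_numpy()
        out[ch] = _logreg_cv(X, y, n_folds)
    return out


def exclude_fast_rts(
    trials: pd.DataFrame, threshold: float = RT_EXCLUSION_THRESHOLD
) -> pd.DataFrame:
    """Drop trials with rt strictly below threshold (boundary kept)."""
    keep = trials["rt"] >= threshold
    out = trials[keep].reset_index(drop=True)
    out.attrs["n_excluded_fast_rt"] = int((~keep).sum())
    return out


def contamination_free_boundary(
    rt_threshold: float = RT_EXCLUSION_THRESHOLD, spectral_window: float = 0.25
) -> float:
    """Latest time point free of movement contamination.

    Spectral estimates at time t draw on +/- window/2 around t, so with all
    reaction times >= rt_threshold the analysis is movement-free up to
    rt_threshold - window/2 (1.1 s for the default 1.225 s cut and 0.25 s
    window).
    """
    return rt_threshold - spectral_window / 2.0
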