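"""Regionally specific decoding of choice and contrast from spectral power.

Choice decoding trains linear SVMs on the spectral pattern (1-145 Hz, both
hemispheres) of one ROI at one time bin, separately per stimulus category
(so the decoder separates choices *within* category, i.e. correct from
error trials), with 10-fold stratified cross-validation, train-fold-only
z-scoring, and minority-class upsampling in the training set.  Performance
is the ROC area of the SVM decision values on the held-out fold, averaged
over folds and then categories.

Contrast decoding predicts the contrast of sample i (or the running mean
up to i — the accumulated evidence) from the same features via ridge
regression, with the penalty chosen over {0.1, 1, 10} by nested 3-fold
cross-validation; the score is the Pearson correlation between held-out
predictions and true targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.decomposition import PCA
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import LinearSVC

from ._rng import require_rng
from .behavior import roc_auc
from .trials import SAMPLE_COLUMNS

__all__ = [
    "DecodingTimecourse",
    "decode_choice_spectral",
    "decode_choice_finegrained",
    "remove_region_leakage",
    "decode_contrast",
    "envelope",
    "encoding_regression",
    "accumulated_contrast",
]


@dataclass
class DecodingTimecourse:
    """Per-time decoding scores with cross-validation bookkeeping."""

    times: np.ndarray
    score: np.ndarray                 # AUC (choice) or Pearson r (contrast)
    fold_scores: np.ndarray           # (time, fold), NaN for skipped folds
    scheme: str
    target: str
    roi: str = ""
    n_folds: int = 10
    notes: dict = field(default_factory=dict)


def _zscore_train_apply(train: np.ndarray, test: np.ndarray):
    mu, sd = train.mean(axis=0), train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _upsample_to_parity(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Randomly repeat minority-class rows until the classes are equal."""
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == n0:
        return X, y
    minority = y if n1 < n0 else ~y
    need = abs(n0 - n1)
    idx = np.flatnonzero(minority)
    extra = rng.choice(idx, size=need, replace=True)
    return np.vstack([X, X[extra]]), np.concatenate([y, y[extra]])


def _choice_auc_folds(
    X: np.ndarray, y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """AUC per fold for one feature matrix / label vector."""
    scores = np.full(n_folds, np.nan)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=int(rng.integers(2**31)))
    for k, (tr, te) in enumerate(skf.split(X, y)):
        if y[tr].all() or (~y[tr]).all() or y[te].all() or (~y[te]).all():
            continue  # class absent in this fold: skip, leave NaN
        Xtr, Xte = _zscore_train_apply(X[tr], X[te])
        Xtr, ytr = _upsample_to_parity(Xtr, y[tr], rng)
        clf = LinearSVC(C=1.0, dual=False).fit(Xtr, ytr)
        scores[k] = roc_auc(clf.decision_function(Xte), y[te])
    return scores


def _roi_features(power: xr.DataArray, roi: str, freq_range=(1.0, 145.0)) -> xr.DataArray:
    """Both-hemisphere spectral features of one ROI: dims (trial, feature, time)."""
    p = power.sel(roi=roi) if "roi" in power.dims else power
    f = np.asarray(p["freq"].values, float)
    p = p.isel(freq=(f >= freq_range[0]) & (f <= freq_range[1]))
    if "hemi" in p.dims:
        p = p.stack(feature=("hemi", "freq"))
    else:
        p = p.rename({"freq": "feature"})
    return p.transpose("trial", "feature", "time")


def decode_choice_spectral(
    power: xr.DataArray,
    trials: pd.DataFrame,
    roi: str,
    rng: np.random.Generator,
    per_category: bool = True,
    n_folds: int = 10,
    times: np.ndarray | None = None,
) -> DecodingTimecourse:
    """Choice decoding from an ROI's spectral pattern, per time bin.

    ``power`` must be percent-change units with dims (trial, [roi,] hemi,
    freq, time) aligned with ``trials``.  Requires >= 20 trials per class.
    """
    require_rng(rng)
    feats = _roi_features(power, roi)
    if times is None:
        times = np.asarray(feats["time"].values, float)
    y = (trials["choice"] == "stronger").to_numpy()
    cat = (trials["stimulus_category"] == "stronger").to_numpy()
    groups = [cat, ~cat] if per_category else [np.ones(len(y), bool)]
    for g in groups:
        counts = [int(y[g].sum()), int((~y[g]).sum())]
        if min(counts) < 20:
            raise ValueError(f"need >= 20 trials per class, got {counts}")
    t_all = np.asarray(feats["time"].values, float)
    score = np.full(times.size, np.nan)
    fold_scores = np.full((times.size, n_folds), np.nan)
    X_all = feats.values  # (trial, feature, time)
    for ti, t in enumerate(times):
        col = int(np.argmin(np.abs(t_all - t)))
        cat_scores = []
        per_fold = []
        for g in groups:
            fs = _choice_auc_folds(X_all[g, :, col], y[g], n_folds, rng)
            cat_scores.append(np.nanmean(fs))
            per_fold.append(fs)
        score[ti] = float(np.mean(cat_scores))
        fold_scores[ti] = np.nanmean(per_fold, axis=0)
    return DecodingTimecourse(
        times=times, score=score, fold_scores=fold_scores,
        scheme="spectral_per_category" if per_category else "spectral_pooled",
        target="choice", roi=roi, n_folds=n_folds,
    )


def decode_choice_finegrained(
    features: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator,
    n_folds: int = 10,
) -> tuple[float, dict]:
    """Fine-grained choice decoding with PCA + L1 feature selection.

    Per fold: z-score -> PCA keeping components to 95% cumulative variance
    -> L1 linear SVM (C = 10/n_features) -> discard components with
    |weight| < 1e-5 -> L2 linear SVM (C = 1/2) -> AUC on the held-out fold.
    All reductions are fitted on training data only.  One decoder across
    both stimulus categories.  Returns (mean AUC, diagnostics).
    """
    require_rng(rng)
    X = np.asarray(features, float)
    y = np.asarray(labels, bool)
    aucs, kept_counts, fallbacks = [], [], 0
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=int(rng.integers(2**31)))
    for tr, te in skf.split(X, y):
        Xtr, Xte = _zscore_train_apply(X[tr], X[te])
        pca = PCA(n_components=0.95, svd_solver="full").fit(Xtr)
        Ztr, Zte = pca.transform(Xtr), pca.transform(Xte)
        l1 = LinearSVC(C=10.0 / Ztr.shape[1], penalty="l1", dual=False,
                       max_iter=5000).fit(Ztr, y[tr])
        keep = np.abs(l1.coef_[0]) >= 1e-5
        if not keep.any():
            keep = np.ones(Ztr.shape[1], bool)  # fall back to all PCA features
            fallbacks += 1
        clf = LinearSVC(C=0.5, dual=False).fit(Ztr[:, keep], y[tr])
        aucs.append(roc_auc(clf.decision_function(Zte[:, keep]), y[te]))
        kept_counts.append(int(keep.sum()))
    return float(np.mean(aucs)), {
        "n_kept_features": kept_counts, "n_pruning_fallbacks": fallbacks}


def remove_region_leakage(
    target_power: xr.DataArray, source_power: xr.DataArray
) -> xr.DataArray:
    """Residualize a target region's power on a source region's, per frequency.

    For each frequency (and time bin, if present) an OLS regression across
    trials predicts the target from the source; the prediction is
    subtracted.  The residual is exactly orthogonal to the source on the
    fitting set.  A constant source yields the centered target.
    """
    tgt = target_power.transpose("trial", ...)
    src = source_power.transpose("trial", ...).values.reshape(tgt.sizes["trial"], -1)
    out = tgt.values.reshape(tgt.sizes["trial"], -1).copy()
    xm = src - src.mean(axis=0)
    ym = out - out.mean(axis=0)
    var = (xm**2).sum(axis=0)
    slope = np.where(var > 0, (xm * ym).sum(axis=0) / np.where(var > 0, var, 1.0), 0.0)
    resid = ym - slope * xm
    res = tgt.copy(data=resid.reshape(tgt.shape))
    res.attrs.update(target_power.attrs)
    return res


def accumulated_contrast(trials: pd.DataFrame, i: int) -> np.ndarray:
    """Running mean of the true contrasts of samples 1..i (1-based)."""
    if not 1 <= i <= 10:
        raise ValueError("sample index must be in 1..10")
    return trials[SAMPLE_COLUMNS[:i]].to_numpy(float).mean(axis=1)


def decode_contrast(
    power: xr.DataArray,
    targets: np.ndarray,
    rng: np.random.Generator,
    n_folds: int = 10,
    alphas: tuple = (0.1, 1.0, 10.0),
    times: np.ndarray | None = None,
) -> DecodingTimecourse:
    """Ridge decoding of a continuous target from spectral features, per time bin.

    ``power`` should already be hemisphere-averaged or lateralized (dims
    (trial, freq, time)); ``targets`` is the per-trial contrast of one
    sample or its running mean.  Nested cross-validation: outer ``n_folds``
    folds score Pearson r between held-out predictions and targets, an
    inner 3-fold loop on each training set picks the ridge penalty.
    """
    require_rng(rng)
    targets = np.asarray(targets, float)
    if np.std(targets) == 0:
        raise ValueError("constant decoding target: correlation undefined")
    feats = power.transpose("trial", "freq", "time").values
    t_all = np.asarray(power["time"].values, float)
    if times is None:
        times = t_all
    score = np.full(times.size, np.nan)
    fold_scores = np.full((times.size, n_folds), np.nan)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31)))
    splits = list(kf.split(targets))
    for ti, t in enumerate(times):
        X = feats[:, :, int(np.argmin(np.abs(t_all - t)))]
        for k, (tr, te) in enumerate(splits):
            Xtr, Xte = _zscore_train_apply(X[tr], X[te])
            best_alpha, best_r = alphas[0], -np.inf
            inner = KFold(n_splits=3, shuffle=True, random_state=0)
            for a in alphas:
                rs = []
                for itr, ite in inner.split(tr):
                    m = Ridge(alpha=a).fit(Xtr[itr], targets[tr][itr])
                    pred = m.predict(Xtr[ite])
                    if np.std(pred) == 0 or np.std(targets[tr][ite]) == 0:
                        rs.append(0.0)
                    else:
                        rs.append(np.corrcoef(pred, targets[tr][ite])[0, 1])
                r = float(np.mean(rs))
                if r > best_r:
                    best_alpha, best_r = a, r
            pred = Ridge(alpha=best_alpha).fit(Xtr, targets[tr]).predict(Xte)
            if np.std(pred) > 0:
                fold_scores[ti, k] = np.corrcoef(pred, targets[te])[0, 1]
            else:
                fold_scores[ti, k] = 0.0
        score[ti] = float(np.nanmean(fold_scores[ti]))
    return DecodingTimecourse(
        times=times, score=score, fold_scores=fold_scores,
        scheme="ridge", target="contrast", n_folds=n_folds,
    )


def envelope(curves: np.ndarray) -> np.ndarray:
    """Pointwise upper envelope across decoding curves on a common grid.

    This is the summary drawn across the ten sample-specific decoding
    curves ("convex hull across decoding peaks"): the maximum at each time
    bin, which dominates every individual curve.
    """
    curves = np.atleast_2d(np.asarray(curves, float))
    if curves.shape[0] < 2:
        raise ValueError("envelope needs at least two curves")
    return np.nanmax(curves, axis=0)


def encoding_regression(
    power: xr.DataArray,
    trials: pd.DataFrame,
    latency: float = 0.190,
) -> xr.DataArray:
    """Frequency-resolved contrast-encoding weights.

    For each frequency f and sample position i, power at the sample's
    encoding latency (onset + 190 ms, nearest bin) and the sample contrast
    are z-scored and regressed; the slope then equals their Pearson
    correlation.  Returns a (freq, sample) map of standardized betas; a
    zero-variance power bin yields NaN.
    """
    p = power.transpose("trial", "freq", "time")
    t_all = np.asarray(p["time"].values, float)
    freqs = np.asarray(p["freq"].values, float)
    betas = np.full((freqs.size, 10), np.nan)
    for i in range(10):
        onset = i * 0.1 + latency
        col = int(np.argmin(np.abs(t_all - onset)))
        c = trials[SAMPLE_COLUMNS[i]].to_numpy(float)
        cz = (c - c.mean()) / c.std()
        P = p.values[:, :, col]
        mu, sd = P.mean(axis=0), P.std(axis=0)
        ok = sd > 0
        Pz = (P[:, ok] - mu[ok]) / sd[ok]
        betas[ok, i] = Pz.T @ cz / len(cz)
    return xr.DataArray(
        betas, dims=("freq", "sample"),
        coords={"freq": freqs, "sample": np.arange(1, 11)},
        name="encoding_beta",
    )
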