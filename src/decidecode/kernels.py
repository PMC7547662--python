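"""Decision-related activity kernels and their coupling across regions.

Neural-activity kernels apply the psychophysical-kernel recipe (two SDT
cells, ROC-AUC, averaged) to band-limited power instead of contrast: for
each sample position, hemisphere-averaged band power extracted 190 ms
after sample onset is compared between choices within each stimulus
category.  The *residual* variant first regresses power on the same
sample's contrast and uses the residuals, isolating the endogenous
(non-stimulus-driven) component of choice-predictive activity.

The cross-correlation analysis relates the build-up of choice-predictive
activity in M1-hand (decoder AUC time course, 0-0.8 s) to time-shifted
visual-cortex low-frequency kernels (lags -215..215 ms; positive lag =
M1 leads).  The zero-lag correlation between the two statistics computed
from M1 itself serves as a conservative reference for source leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.linear_model import LogisticRegression

from .behavior import psychophysical_kernel, kernel_slope
from .spectral import BandDefinition, band_power
from .trials import SAMPLE_COLUMNS

__all__ = [
    "band_power_by_sample",
    "neural_kernel",
    "frequency_resolved_kernels",
    "correlate_kernels",
    "InteractionFit",
    "interaction_logreg",
    "highres_kernel",
    "CrossCorrelationResult",
    "crosscorr_choice_feedback",
    "group_crosscorr",
    "leakage_reference",
    "SAMPLE_LATENCY",
]

SAMPLE_LATENCY = 0.190  # s, peak of sample-contrast encoding after sample onset


def band_power_by_sample(
    power: xr.DataArray, band: BandDefinition, latency: float = SAMPLE_LATENCY
) -> np.ndarray:
    """(trial, 10) band power at each sample's encoding latency.

    ``power`` must be hemisphere-collapsed: dims (trial, freq, time).
    """
    cols = [band_power(power, band, i * 0.1 + latency).values for i in range(10)]
    return np.column_stack(cols)


def _residualize_on_contrast(values: np.ndarray, trials: pd.DataFrame) -> np.ndarray:
    """Per sample position, remove the OLS prediction from that sample's contrast."""
    out = np.empty_like(values)
    for i in range(values.shape[1]):
        c = trials[SAMPLE_COLUMNS[i]].to_numpy(float)
        cm = c - c.mean()
        v = values[:, i]
        denom = (cm**2).sum()
        slope = (cm * (v - v.mean())).sum() / denom if denom > 0 else 0.0
        out[:, i] = v - (v.mean() + slope * cm)
    return out


def neural_kernel(
    power: xr.DataArray,
    trials: pd.DataFrame,
    band: BandDefinition,
    variant: str = "overall",
    latency: float = SAMPLE_LATENCY,
) -> np.ndarray:
    """Choice-predictive kernel of band power, per sample position.

    variant="overall" uses raw band power at each sample's latency;
    variant="residual" first removes the linear contrast contribution per
    sample position.
    """
    if variant not in ("overall", "residual"):
        raise ValueError("variant must be 'overall' or 'residual'")
    values = band_power_by_sample(power, band, latency)
    if variant == "residual":
        values = _residualize_on_contrast(values, trials)
    df = trials[["stimulus_category", "choice"]].copy()
    cols = []
    for i in range(10):
        col = f"bp{i + 1:02d}"
        df[col] = values[:, i]
        cols.append(col)
    return psychophysical_kernel(df, value_columns=cols)


def frequency_resolved_kernels(
    power: xr.DataArray, trials: pd.DataFrame, latency: float = SAMPLE_LATENCY
) -> xr.Dataset:
    """Time-collapsed kernel mean (AUC - 0.5) and kernel slope per frequency bin."""
    freqs = np.asarray(power["freq"].values, float)
    mean_dev = np.full(freqs.size, np.nan)
    slope = np.full(freqs.size, np.nan)
    for fi, f in enumerate(freqs):
        single = BandDefinition(f"f{f:g}", (f, f), (f, f))
        k = neural_kernel(power, trials, single, latency=latency)
        if np.isfinite(k).sum() >= 2:
            mean_dev[fi] = np.nanmean(k) - 0.5
            slope[fi] = kernel_slope(k)
    return xr.Dataset(
        {"kernel_mean": ("freq", mean_dev), "kernel_slope": ("freq", slope)},
        coords={"freq": freqs},
    )


def correlate_kernels(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two kernels over common positions."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need at least 3 common positions")
    if np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
        return np.nan
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


@dataclass
class InteractionFit:
    """Choice regression on low-frequency and gamma power in trial halves.

    Coefficient order: [beta0, alpha_h1, alpha_h2, gamma_h1, gamma_h2,
    interaction_h1, interaction_h2] with inputs z-scored before products.
    Temporal asymmetry per term = beta_{n,2} - beta_{n,1}.
    """

    coefficients: np.ndarray
    asymmetry: dict
    separation_flagged: bool = False


def interaction_logreg(
    trials: pd.DataFrame,
    low_power: np.ndarray,
    gamma_power: np.ndarray,
) -> InteractionFit:
    """Logistic choice model with alpha x gamma interaction per trial half.

    ``low_power`` and ``gamma_power`` are (trial, 10) band-power arrays at
    the sample encoding latency; they are averaged over samples 1-5 (first
    half) and 6-10 (second half), z-scored, and entered with their product.
    """
    y = (trials["choice"] == "stronger").to_numpy()
    if y.all() or (~y).all():
        raise ValueError("both choices must be present")

    def _halves(v):
        h = np.column_stack([v[:, :5].mean(axis=1), v[:, 5:].mean(axis=1)])
        return (h - h.mean(axis=0)) / h.std(axis=0)

    a, g = _halves(np.asarray(low_power, float)), _halves(np.asarray(gamma_power, float))
    X = np.column_stack([a, g, a * g])
    model = LogisticRegression(C=1e6, solver="lbfgs", max_iter=2000).fit(X, y)
    beta = model.coef_[0]
    coeffs = np.concatenate([[model.intercept_[0]], beta])
    asym = {
        "low_frequency": float(beta[1] - beta[0]),
        "gamma": float(beta[3] - beta[2]),
        "interaction": float(beta[5] - beta[4]),
    }
    return InteractionFit(coeffs, asym, bool(np.any(np.abs(beta) > 50)))


def highres_kernel(
    power: xr.DataArray,
    trials: pd.DataFrame,
    band: BandDefinition,
    times: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-resolved kernel: choice AUC of band power at every time bin."""
    t_all = np.asarray(power["time"].values, float)
    if times is None:
        times = t_all
    df = trials[["stimulus_category", "choice"]].copy()
    cols = []
    for ti, t in enumerate(times):
        col = f"t{ti}"
        df[col] = band_power(power, band, t).values
        cols.append(col)
    return times, psychophysical_kernel(df, value_columns=cols)


@dataclass
class CrossCorrelationResult:
    """Lagged correlation between M1 choice decoding and a visual kernel."""

    lags: np.ndarray          # s; positive = M1 leads
    r: np.ndarray             # (subject, lag)
    group_r: np.ndarray       # mean across subjects per lag
    peak_lag: float           # argmax of the group-mean correlation
    reference_r: float | None = None


def crosscorr_choice_feedback(
    m1_times: np.ndarray,
    m1_auc: np.ndarray,
    kernel_times: np.ndarray,
    kernel_auc: np.ndarray,
    lags: np.ndarray,
    window: tuple = (0.0, 0.8),
) -> np.ndarray:
    """Single-subject lagged correlations.

    For each lag l, the Pearson correlation between the M1 AUC time course
    on ``window`` and the visual kernel on [window + l].  Kernel values are
    matched by nearest time bin; where the shifted window leaves the kernel
    support the overlap is truncated (no padding), and a lag with fewer
    than 3 overlapping bins is NaN.
    """
    m1_times = np.asarray(m1_times, float)
    kernel_times = np.asarray(kernel_times, float)
    lags = np.asarray(lags, float)
    dt = np.median(np.diff(kernel_times))
    sel = (m1_times >= window[0] - 1e-9) & (m1_times <= window[1] + 1e-9)
    t_win = m1_times[sel]
    a = np.asarray(m1_auc, float)[sel]
    out = np.full(lags.size, np.nan)
    for li, lag in enumerate(lags):
        target = t_win + lag
        ok = (target >= kernel_times[0] - dt / 2) & (target <= kernel_times[-1] + dt / 2)
        idx = np.clip(np.round((target[ok] - kernel_times[0]) / dt).astype(int),
                      0, kernel_times.size - 1)
        b = np.asarray(kernel_auc, float)[idx]
        av = a[ok]
        good = np.isfinite(av) & np.isfinite(b)
        if good.sum() < 3 or np.std(av[good]) == 0 or np.std(b[good]) == 0:
            continue
        out[li] = np.corrcoef(av[good], b[good])[0, 1]
    return out


def group_crosscorr(
    per_subject_r: np.ndarray, lags: np.ndarray, reference_r: float | None = None
) -> CrossCorrelationResult:
    """Collapse per-subject lagged correlations; peak lag from the group mean."""
    r = np.atleast_2d(np.asarray(per_subject_r, float))
    lags = np.asarray(lags, float)
    group = np.nanmean(r, axis=0)
    peak = float(lags[np.nanargmax(group)])
    return CrossCorrelationResult(lags, r, group, peak, reference_r)


def leakage_reference(
    m1_times: np.ndarray,
    m1_auc: np.ndarray,
    m1_kernel_times: np.ndarray,
    m1_kernel_auc: np.ndarray,
    window: tuple = (0.0, 0.8),
) -> float:
    """Zero-lag correlation of M1 decoding AUC with the M1 low-frequency kernel.

    Both statistics come from the same ROI, so this bounds the correlation
    attainable through source leakage alone.
    """
    r = crosscorr_choice_feedback(
        m1_times, m1_auc, m1_kernel_times, m1_kernel_auc,
        lags=np.array([0.0]), window=window)
    return float(r[0])
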