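"""Spectral estimation and power-tensor arithmetic.

Time-frequency representations use sliding-window DPSS multitapers: 1-9 Hz
(step 1) with a 0.25-s window and 8 Hz spectral smoothing, 10-150 Hz
(step 5) with a 0.1-s window and 20 Hz smoothing; the smoothing is the
one-sided half-bandwidth W, and the taper count follows the concentration
rule K = round(2 T W - 1) = 3 for both window x smoothing products.  Power is converted to percent change relative to a
condition-independent pre-stimulus baseline (-250 to 0 ms), and analyses
use either the hemisphere average (stimulus-driven signals; the grating
spans both hemifields) or the hemispheric lateralization relative to the
hand reporting "stronger" (motor choice signals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.signal.windows import dpss

__all__ = [
    "FrequencyGrid",
    "BandDefinition",
    "GAMMA_BAND",
    "LOW_FREQUENCY_BAND",
    "multitaper_tfr",
    "baseline_normalize",
    "lateralize",
    "hemi_average",
    "band_power",
    "condition_tfr_contrast",
]


@dataclass(frozen=True)
class FrequencyGrid:
    """TFR frequency grid with window lengths and smoothing per sub-band."""

    low_freqs: np.ndarray = field(default_factory=lambda: np.arange(1.0, 10.0, 1.0))
    high_freqs: np.ndarray = field(default_factory=lambda: np.arange(10.0, 151.0, 5.0))
    low_window: float = 0.25       # s
    low_smoothing: float = 8.0     # Hz (total)
    high_window: float = 0.1
    high_smoothing: float = 20.0
    decoding_range: tuple = (1.0, 145.0)

    @property
    def freqs(self) -> np.ndarray:
        return np.concatenate([self.low_freqs, self.high_freqs])

    def decoding_freqs(self) -> np.ndarray:
        f = self.freqs
        return f[(f >= self.decoding_range[0]) & (f <= self.decoding_range[1])]


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band given by its center-frequency range on the TFR grid."""

    name: str
    center_range: tuple      # inclusive range of center frequencies to average
    effective_range: tuple   # range actually covered given spectral smoothing

    def select(self, freqs: np.ndarray) -> np.ndarray:
        lo, hi = self.center_range
        sel = (np.asarray(freqs) >= lo) & (np.asarray(freqs) <= hi)
        if not sel.any():
            raise ValueError(f"no grid bins inside band {self.name} {self.center_range}")
        return sel


GAMMA_BAND = BandDefinition("gamma", (50.0, 65.0), (40.0, 75.0))
LOW_FREQUENCY_BAND = BandDefinition("low_frequency", (10.0, 10.0), (0.0, 20.0))


def _taper_count(window: float, smoothing: float) -> int:
    # smoothing is the one-sided half-bandwidth W; K = round(2 T W - 1)
    return max(1, int(round(2 * window * smoothing - 1)))


def multitaper_tfr(
    data: np.ndarray,
    times_in: np.ndarray,
    grid: FrequencyGrid | None = None,
    hop: float = 1.0 / 60.0,
) -> xr.DataArray:
    """Sliding-window multitaper power of trial x time series.

    Power at frequency f and center time t is the taper-averaged squared
    magnitude of the tapered DFT of the window centred on t, evaluated at
    exactly f.  Centres whose window would extend beyond the epoch are
    returned as NaN.
    """
    grid = grid or FrequencyGrid()
    data = np.atleast_2d(np.asarray(data, float))
    times_in = np.asarray(times_in, float)
    fs = 1.0 / np.median(np.diff(times_in))
    fmax = grid.freqs.max()
    if fs < 2 * fmax:
        raise ValueError(f"sampling rate {fs:.1f} Hz below Nyquist for {fmax:.0f} Hz")
    centers = np.arange(times_in[0], times_in[-1] + hop / 2, hop)
    out = np.full((data.shape[0], grid.freqs.size, centers.size), np.nan)
    row = 0
    for freqs, window, smoothing in (
        (grid.low_freqs, grid.low_window, grid.low_smoothing),
        (grid.high_freqs, grid.high_window, grid.high_smoothing),
    ):
        n_w = int(round(window * fs))
        k = _taper_count(window, smoothing)
        tapers = np.atleast_2d(dpss(n_w, window * smoothing, k))
        t_rel = np.arange(n_w) / fs
        # DFT vectors at the exact analysis frequencies
        basis = np.exp(-2j * np.pi * freqs[:, None] * t_rel[None, :])
        for c, tc in enumerate(centers):
            start = int(round((tc - times_in[0]) * fs)) - n_w // 2
            if start < 0 or start + n_w > times_in.size:
                continue
            seg = data[:, start:start + n_w]
            tapered = seg[:, None, :] * tapers[None, :, :]          # trial, taper, n
            spec = np.einsum("atn,fn->atf", tapered, basis)
            out[:, row:row + freqs.size, c] = (np.abs(spec) ** 2).mean(axis=1) * (2.0 / fs / n_w)
        row += freqs.size
    return xr.DataArray(
        out,
        dims=("trial", "freq", "time"),
        coords={"trial": np.arange(data.shape[0]), "freq": grid.freqs, "time": centers},
        attrs={"units": "raw"},
        name="power",
    )


def baseline_normalize(
    power: xr.DataArray, window: tuple = (-0.25, 0.0)
) -> xr.DataArray:
    """Percent power change relative to a condition-independent baseline.

    The baseline is the mean over trials and over time bins in
    [window[0], window[1]) — computed per frequency (and per ROI/hemisphere
    if those dims are present); output = 100 * (power - baseline)/baseline.
    """
    if power.attrs.get("units") == "pct_change":
        raise ValueError("power is already baseline-normalized")
    t = power["time"]
    sel = (t >= window[0]) & (t < window[1])
    if not bool(sel.any()):
        raise ValueError("baseline window lies outside the epoch")
    baseline = power.isel(time=sel.values).mean(dim=("trial", "time"))
    if bool((baseline <= 0).any()):
        raise ValueError("baseline power must be strictly positive")
    out = 100.0 * (power - baseline) / baseline
    out.attrs.update(power.attrs)
    out.attrs["units"] = "pct_change"
    return out


def hemi_average(power: xr.DataArray) -> xr.DataArray:
    """Average the two hemispheres (stimulus-driven analyses)."""
    out = power.mean(dim="hemi")
    out.attrs.update(power.attrs)
    return out


def lateralize(power: xr.DataArray, stronger_hand: str) -> xr.DataArray:
    """Contralateral minus ipsilateral power relative to the "stronger" hand.

    ``stronger_hand`` is the hand this subject uses to report "stronger"
    choices; the hemisphere contralateral to it carries the positive sign.
    Swapping hemisphere labels flips the sign exactly.
    """
    if stronger_hand not in ("left", "right"):
        raise ValueError("stronger_hand must be 'left' or 'right'")
    hemis = list(np.asarray(power["hemi"].values))
    if set(hemis) != {"left", "right"}:
        raise ValueError("both hemispheres must be present")
    contra = "left" if stronger_hand == "right" else "right"
    ipsi = "right" if contra == "left" else "left"
    out = power.sel(hemi=contra, drop=True) - power.sel(hemi=ipsi, drop=True)
    out.attrs.update(power.attrs)
    return out


def band_power(
    power: xr.DataArray, band: BandDefinition, at_time: float
) -> xr.DataArray:
    """Mean power over a band's center bins at the nearest time bin.

    Ties in the nearest-bin lookup resolve toward the earlier bin.
    """
    t = np.asarray(power["time"].values, float)
    if at_time < t.min() - 1e-9 or at_time > t.max() + 1e-9:
        raise ValueError(f"time {at_time} outside epoch [{t.min()}, {t.max()}]")
    dist = np.abs(t - at_time)
    idx = int(np.flatnonzero(dist <= dist.min() + 1e-12)[0])  # earlier bin on ties
    sel = band.select(np.asarray(power["freq"].values, float))
    out = power.isel(time=idx, freq=sel).mean(dim="freq")
    out.attrs.update(power.attrs)
    return out


def condition_tfr_contrast(
    power: xr.DataArray, trials: pd.DataFrame, mode: str
) -> xr.DataArray:
    """Balanced condition-contrast map over the trial dimension.

    choice_specific: (stronger - weaker choice) computed within each
    stimulus category, averaged across categories (factors the stimulus
    out).  stimulus_specific: (stronger - weaker category) within each
    choice, averaged across choices (factors the choice out).  Pass
    lateralized input for choice maps and hemisphere-averaged input for
    stimulus maps.  Any empty cell yields an all-NaN map.
    """
    if mode not in ("choice_specific", "stimulus_specific"):
        raise ValueError("mode must be 'choice_specific' or 'stimulus_specific'")
    cat = (trials["stimulus_category"] == "stronger").to_numpy()
    cho = (trials["choice"] == "stronger").to_numpy()
    inner, outer = (cho, cat) if mode == "choice_specific" else (cat, cho)
    diffs = []
    for level in (True, False):
        a = power.isel(trial=np.flatnonzero((outer == level) & inner))
        b = power.isel(trial=np.flatnonzero((outer == level) & ~inner))
        if a.sizes["trial"] == 0 or b.sizes["trial"] == 0:
            return xr.full_like(power.isel(trial=0, drop=True), np.nan)
        diffs.append(a.mean(dim="trial") - b.mean(dim="trial"))
    out = (diffs[0] + diffs[1]) / 2.0
    out.attrs.update(power.attrs)
    return out
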