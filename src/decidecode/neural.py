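"""Synthetic ROI-level spectro-temporal power.

Generates a trial x ROI x hemisphere x frequency x time power tensor with
the statistical structure the analysis pipeline assumes:

* **Visual ROIs, gamma band (40-75 Hz):** power is linear in the contrast of
  each 100-ms sample, attenuated by variance-dependent adaptation
  (``exp(-rate * (i-1))`` with rate depending on the trial's sample SD), and
  smeared in time by a gamma-shaped impulse response peaking
  ``response_latency`` (190 ms) after sample onset.  Identical in both
  hemispheres (the stimulus spans both hemifields).
* **Visual ROIs, low-frequency band (<= 20 Hz):** an endogenous,
  choice-signed component ``alpha_feedback_gain * sign(choice) *
  R(t - feedback_lag)`` where R is the normalized motor build-up shape —
  i.e. a delayed copy of the decision signal fed back to visual cortex.
* **Motor ROIs (M1-hand, IPS/PostCeS, aIPS), low-frequency band:**
  hemisphere-lateralized build-up proportional to the normalized cumulative
  evidence ``C(t) = sum_{i: onset_i + latency <= t} w_i (c_i - 0.5)``, with
  the hemisphere contralateral to the hand mapped to "stronger" carrying
  the positive sign.
* Multiplicative lognormal noise per trial/bin (mean-corrected so expected
  power equals the deterministic profile); the baseline interval
  [-0.25, 0) s contains baseline + noise only.

The shared build-up shape R(t) (the choice-predictive SNR profile of the
motor signal) is what makes the M1 -> visual-cortex delay identifiable by
lagged cross-correlation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from ._rng import require_rng
from .observer import ObserverParams
from .trials import SAMPLE_COLUMNS

__all__ = [
    "NeuralGenParams",
    "default_frequency_grid",
    "generate_power_tensor",
    "buildup_shape",
    "VISUAL_ROIS",
    "MOTOR_ROIS",
]

VISUAL_ROIS = ("V1", "V2-V4")
MOTOR_ROIS = ("IPS/PostCeS", "M1-hand")

EPOCH = (-0.25, 1.35)        # s, relative to test-stimulus onset
SAMPLE_DURATION = 0.1        # s
N_SAMPLES = 10


def default_frequency_grid(coarse: bool = False) -> np.ndarray:
    """The analysis frequency grid: 1-9 Hz step 1, then 10-145 Hz step 5.

    ``coarse=True`` returns a reduced grid (same coverage, fewer bins) for
    fast simulation studies.
    """
    if coarse:
        return np.concatenate([np.arange(1.0, 10.0, 2.0), np.arange(10.0, 146.0, 15.0)])
    return np.concatenate([np.arange(1.0, 10.0, 1.0), np.arange(10.0, 146.0, 5.0)])


@dataclass(frozen=True)
class NeuralGenParams:
    """Gains, latencies and noise levels of the synthetic power generator."""

    gamma_gain: float = 1.0                 # power modulation per unit contrast
    gamma_offset: float = 0.5               # contrast-independent stimulus response
    adaptation_rate_per_sd: tuple = ((0.05, 0.05), (0.1, 0.1), (0.15, 0.15))
    response_latency: float = 0.190         # s, peak of the impulse response
    alpha_feedback_gain: float = 0.03       # choice-signed low-frequency feedback
    feedback_lag: float = 0.150             # s, delay of the fed-back decision signal
    motor_buildup_gain: float = 0.25        # lateralized motor build-up amplitude
    noise_sd: float = 0.2                   # lognormal sigma per trial/bin
    baseline_level: float = 10.0            # raw power units (per frequency)
    time_step: float = 1.0 / 60.0           # s
    frequency_grid: np.ndarray = field(default_factory=default_frequency_grid)
    gamma_band: tuple = (40.0, 75.0)        # effective range carrying contrast
    low_band: tuple = (0.0, 20.0)           # effective range carrying choice signals

    def __post_init__(self):
        object.__setattr__(self, "frequency_grid", np.asarray(self.frequency_grid, float))
        if self.response_latency < 0 or self.feedback_lag < 0:
            raise ValueError("latency and lag must be non-negative")
        if self.noise_sd < 0 or self.baseline_level <= 0:
            raise ValueError("noise_sd must be >= 0 and baseline_level > 0")
        n_steps = (EPOCH[1] - EPOCH[0]) / self.time_step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("time_step must divide the epoch length")

    @property
    def times(self) -> np.ndarray:
        n = int(round((EPOCH[1] - EPOCH[0]) / self.time_step))
        return EPOCH[0] + np.arange(n + 1) * self.time_step

    def adaptation_rate(self, sd_level: float) -> float:
        for sd, rate in self.adaptation_rate_per_sd:
            if np.isclose(sd, sd_level):
                return rate
        raise KeyError(f"no adaptation rate configured for sd_level {sd_level}")


def _impulse_response(times: np.ndarray, latency: float) -> np.ndarray:
    """Gamma-shaped (shape 2) impulse response, unit peak at ``latency``."""
    tau = np.maximum(times, 0.0)
    if latency == 0:
        return (times >= 0).astype(float)
    return (tau / latency) * np.exp(1.0 - tau / latency) * (times > 0)


def buildup_shape(times: np.ndarray, weights: np.ndarray, latency: float) -> np.ndarray:
    """Normalized build-up R(t): the choice-predictive SNR profile of the motor signal.

    R(t) = sum_{i: onset_i + latency <= t} w_i^2 / sum_i w_i^2 — a step ramp
    rising from the first sample's response latency to the last's.
    """
    w2 = np.asarray(weights, float) ** 2
    onsets = np.arange(N_SAMPLES) * SAMPLE_DURATION + latency
    steps = (times[:, None] >= onsets[None, :]).astype(float)
    return steps @ w2 / w2.sum()


def generate_power_tensor(
    trials: pd.DataFrame,
    params: NeuralGenParams | None = None,
    roi_set: tuple = VISUAL_ROIS + MOTOR_ROIS,
    rng: np.random.Generator | None = None,
    observer: ObserverParams | None = None,
) -> xr.DataArray:
    """Generate raw power for one subject's trials.

    Returns an :class:`xarray.DataArray` with dims (trial, roi, hemi, freq,
    time), strictly positive values and attrs ``units='raw'``.  ``trials``
    must be a single subject's rows of a trial table.
    """
    require_rng(rng)
    params = params or NeuralGenParams()
    observer = observer or ObserverParams()
    if len(roi_set) == 0:
        raise ValueError("roi_set must not be empty")
    times = params.times
    if times[-1] < params.response_latency + (N_SAMPLES - 1) * SAMPLE_DURATION:
        raise ValueError("epoch too short for the response to the last sample")
    freqs = params.frequency_grid
    n_trials = len(trials)
    contrasts = trials[SAMPLE_COLUMNS].to_numpy(float)
    sd_level = trials["sd_level"].to_numpy(float)
    s_choice = np.where(trials["choice"].to_numpy() == "stronger", 1.0, -1.0)
    # hand mapped to "stronger" (constant within subject): recover from any trial
    mask = trials["choice"].to_numpy() == "stronger"
    if mask.any():
        stronger_hand = trials["response_hand"].to_numpy()[mask][0]
    else:
        weaker_hand = trials["response_hand"].to_numpy()[0]
        stronger_hand = "left" if weaker_hand == "right" else "right"

    gamma_bins = (freqs >= params.gamma_band[0]) & (freqs <= params.gamma_band[1])
    low_bins = (freqs >= params.low_band[0]) & (freqs <= params.low_band[1])

    # stimulus-driven gamma drive: per-sample amplitude convolved with the
    # impulse response (vectorized over trials and samples)
    onsets = np.arange(N_SAMPLES) * SAMPLE_DURATION
    kernels = np.stack([_impulse_response(times - o, params.response_latency)
                        for o in onsets])                      # (sample, time)
    rates = np.array([params.adaptation_rate(s) for s in sd_level])
    decay = np.exp(-rates[:, None] * np.arange(N_SAMPLES)[None, :])   # (trial, sample)
    amp = params.gamma_offset + params.gamma_gain * contrasts * decay
    gamma_drive = amp @ kernels                                 # (trial, time)

    # choice-signed feedback into visual low-frequency power
    ramp = buildup_shape(times - params.feedback_lag, observer.weights,
                         params.response_latency)
    feedback = params.alpha_feedback_gain * s_choice[:, None] * ramp[None, :]

    # lateralized cumulative-evidence build-up for motor ROIs
    evid = observer.weights[None, :] * (contrasts - 0.5)        # (trial, sample)
    step = (times[None, None, :] >= (onsets + params.response_latency)[None, :, None])
    cum_evid = (evid[:, :, None] * step).sum(axis=1)            # (trial, time)
    sigma_c = np.sqrt((observer.weights**2).sum()) * 0.1        # nominal mid sd level
    cum_evid = cum_evid / sigma_c
    hemi_sign = {"left": 1.0, "right": -1.0} if stronger_hand == "right" \
        else {"left": -1.0, "right": 1.0}   # contra to the stronger hand is positive

    data = np.empty((n_trials, len(roi_set), 2, freqs.size, times.size))
    hemis = ("left", "right")
    for r, roi in enumerate(roi_set):
        for h, hemi in enumerate(hemis):
            mod = np.zeros((n_trials, freqs.size, times.size))
            if roi in VISUAL_ROIS:
                mod[:, gamma_bins, :] += gamma_drive[:, None, :]
                mod[:, low_bins, :] += feedback[:, None, :]
            else:
                lat = 0.5 * params.motor_buildup_gain * hemi_sign[hemi] * cum_evid
                mod[:, low_bins, :] += lat[:, None, :]
            data[:, r, h] = params.baseline_level * (1.0 + mod)
    if np.any(data <= 0):
        raise ValueError(
            "deterministic power profile became non-positive; reduce gains")
    if params.noise_sd > 0:
        z = rng.normal(0.0, params.noise_sd, size=data.shape)
        data = data * np.exp(z - params.noise_sd**2 / 2.0)

    return xr.DataArray(
        data,
        dims=("trial", "roi", "hemi", "freq", "time"),
        coords={
            "trial": trials["trial"].to_numpy(),
            "roi": list(roi_set),
            "hemi": list(hemis),
            "freq": freqs,
            "time": times,
        },
        attrs={"units": "raw", "epoch": EPOCH},
        name="power",
    )
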