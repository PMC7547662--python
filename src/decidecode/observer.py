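"""Simulated observer: noisy weighted evidence accumulator.

The observer forms a decision variable from the ten contrast samples,

    DV = sum_i w_i * (c_i - 0.5) + N(0, internal_noise_sd),

chooses "stronger" iff DV > 0 (with occasional lapses that flip the
choice), reports high confidence iff |DV| exceeds a criterion, and produces
a reaction time from a shifted lognormal that is independent of the
decision.  The default weights decay exponentially over sample position
(primacy), which is the minimal generative account of psychophysical
kernels that decline over the trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from ._rng import require_rng

__all__ = ["ObserverParams", "simulate_observer", "calibrate_internal_noise"]


def primacy_weights(n: int = 10, decay: float = 0.15) -> np.ndarray:
    return np.exp(-decay * np.arange(n))


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of the accumulator observer (decision-variable units)."""

    weights: np.ndarray = field(default_factory=primacy_weights)
    internal_noise_sd: float = 0.15
    confidence_criterion: float = 0.25
    lapse_rate: float = 0.0
    # shifted lognormal RT from test offset: shift + LogNormal(log_mean, log_sd)
    rt_shift: float = 0.4
    rt_log_mean: float = 0.383
    rt_log_sd: float = 0.35

    def __post_init__(self):
        object.__setattr__(self, "weights", np.asarray(self.weights, float))
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if self.internal_noise_sd <= 0:
            raise ValueError("internal_noise_sd must be positive")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must lie in [0, 0.1]")


def simulate_observer(
    contrasts: np.ndarray, params: ObserverParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Simulate choices for one or many trials.

    Parameters
    ----------
    contrasts : array (..., 10) of Michelson contrasts in [0, 1].

    Returns
    -------
    choice : array of {"stronger", "weaker"}
    confidence : array of {"high", "low"}
    rt : reaction times in seconds from test offset
    dv : the realized decision variables (useful for diagnostics)
    """
    require_rng(rng)
    c = np.atleast_2d(np.asarray(contrasts, float))
    if c.shape[-1] != params.weights.size:
        raise ValueError(f"expected {params.weights.size} samples per trial, got {c.shape[-1]}")
    if np.any((c < 0) | (c > 1)):
        raise ValueError("contrasts must lie in [0, 1]")
    n = c.shape[0]
    dv = (c - 0.5) @ params.weights + rng.normal(0.0, params.internal_noise_sd, size=n)
    stronger = dv > 0
    if params.lapse_rate > 0:
        lapse = rng.random(n) < params.lapse_rate
        stronger = np.where(lapse, ~stronger, stronger)
    choice = np.where(stronger, "stronger", "weaker")
    confidence = np.where(np.abs(dv) >= params.confidence_criterion, "high", "low")
    rt = params.rt_shift + rng.lognormal(params.rt_log_mean, params.rt_log_sd, size=n)
    if np.asarray(contrasts).ndim == 1:
        return choice[0], confidence[0], rt[0], dv[0]
    return choice, confidence, rt, dv


def accuracy_closed_form(
    offset: float, sd_level: float, params: ObserverParams
) -> float:
    """Expected accuracy of the accumulator at a given mean contrast offset.

    For samples ~ N(0.5 +/- offset, sd) the DV is Gaussian with mean
    +/- offset*sum(w) and variance sd^2*sum(w^2) + noise^2, so accuracy is
    Phi(offset*sum(w)/sqrt(sd^2*sum(w^2)+noise^2)), lapse-corrected.
    """
    w = params.weights
    z = offset * w.sum() / np.hypot(sd_level * np.sqrt((w**2).sum()), params.internal_noise_sd)
    p = norm.cdf(z)
    return float((1 - params.lapse_rate) * p + params.lapse_rate * (1 - p))


def calibrate_internal_noise(
    offset: float, sd_level: float, weights: np.ndarray, target_accuracy: float = 0.75,
    lapse_rate: float = 0.0,
) -> float:
    """Internal noise SD at which the accumulator hits ``target_accuracy``.

    Closed-form inversion of the Gaussian accuracy formula; raises if the
    target is unreachable even with zero internal noise (stimulus too weak).
    """
    w = np.asarray(weights, float)
    p = (target_accuracy - lapse_rate / 2.0) / (1.0 - lapse_rate)
    z = norm.ppf(p)
    total_var = (offset * w.sum() / z) ** 2
    stim_var = sd_level**2 * (w**2).sum()
    if total_var <= stim_var:
        raise ValueError("target accuracy unreachable: stimulus noise alone exceeds the budget")
    return float(np.sqrt(total_var - stim_var))
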