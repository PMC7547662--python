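"""QUEST adaptive staircase.

A Bayesian adaptive procedure that keeps a posterior over the observer's
(log10) contrast-offset threshold and places each trial at the posterior
mean (the QUEST "mean" placement rule).  The assumed psychometric function
is a Weibull in log10 units, anchored so that an observer tested exactly at
threshold answers correctly with probability ``target_accuracy`` (0.75 for
a two-alternative contrast discrimination):

    p(correct | x, T) = g + (1 - g - lam) * (1 - exp(-10**(beta*(x-T) + c0)))

with guess rate g, lapse rate lam, slope beta, and the anchoring constant
c0 chosen so p(T | T) = target_accuracy.  After each trial the posterior is
multiplied by the likelihood of the observed outcome at the shown offset and
renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._rng import require_rng

__all__ = ["StaircaseState", "quest_propose_and_update", "weibull_p_correct", "run_staircase"]


def _anchor_constant(guess: float, lapse: float, target: float) -> float:
    # c0 such that the Weibull CDF term evaluates to the target accuracy at x == T
    q = (target - guess) / (1.0 - guess - lapse)
    return float(np.log10(-np.log1p(-q)))


def weibull_p_correct(
    x: np.ndarray | float,
    threshold: np.ndarray | float,
    slope: float = 3.5,
    guess_rate: float = 0.5,
    lapse_rate: float = 0.02,
    target_accuracy: float = 0.75,
) -> np.ndarray:
    """Probability of a correct response at log10 offset ``x`` for threshold ``threshold``."""
    c0 = _anchor_constant(guess_rate, lapse_rate, target_accuracy)
    u = np.power(10.0, slope * (np.asarray(x, float) - np.asarray(threshold, float)) + c0)
    return guess_rate + (1.0 - guess_rate - lapse_rate) * (1.0 - np.exp(-u))


@dataclass
class StaircaseState:
    """Posterior over the log10 contrast-offset threshold."""

    log_intensity_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(-3.0, -0.3, 271)
    )
    posterior: np.ndarray | None = None
    assumed_slope: float = 3.5
    guess_rate: float = 0.5
    lapse_rate: float = 0.02
    target_accuracy: float = 0.75
    degenerate: bool = False  # warning flag: posterior mass piled at a grid edge

    def __post_init__(self):
        self.log_intensity_grid = np.asarray(self.log_intensity_grid, float)
        if self.posterior is None:
            # weak Gaussian prior centred mid-grid, per the original QUEST recipe
            g = self.log_intensity_grid
            self.posterior = np.exp(-0.5 * ((g - g.mean()) / (0.5 * np.ptp(g))) ** 2)
            self.posterior /= self.posterior.sum()
        self.posterior = np.asarray(self.posterior, float)
        if np.any(self.posterior < 0) or abs(self.posterior.sum() - 1.0) > 1e-9:
            raise ValueError("posterior must be non-negative and sum to 1")
        if not (self.guess_rate < self.target_accuracy < 1.0 - self.lapse_rate):
            raise ValueError("target_accuracy must lie in (guess_rate, 1 - lapse_rate)")

    @property
    def proposed_offset(self) -> float:
        """Next log10 contrast offset: the posterior mean (QUEST mean rule)."""
        return float(np.dot(self.posterior, self.log_intensity_grid))


def quest_propose_and_update(
    state: StaircaseState, outcome: bool | str, shown_offset: float
) -> StaircaseState:
    """Bayes-update the threshold posterior after one trial.

    Parameters
    ----------
    outcome : True / "correct" or False / "wrong".
    shown_offset : the log10 contrast offset actually tested.

    Returns a new state whose ``proposed_offset`` is the updated posterior
    mean.  If virtually all posterior mass ends up on a grid edge the state's
    ``degenerate`` flag is set (the threshold has likely escaped the grid).
    """
    if isinstance(outcome, str):
        if outcome not in ("correct", "wrong"):
            raise ValueError("outcome must be 'correct' or 'wrong'")
        correct = outcome == "correct"
    else:
        correct = bool(outcome)
    p = weibull_p_correct(
        shown_offset,
        state.log_intensity_grid,
        state.assumed_slope,
        state.guess_rate,
        state.lapse_rate,
        state.target_accuracy,
    )
    like = p if correct else 1.0 - p
    post = state.posterior * like
    total = post.sum()
    if total <= 0:
        raise FloatingPointError("posterior update annihilated all probability mass")
    post = post / total
    edge_mass = post[0] + post[-1]
    return replace(state, posterior=post, degenerate=bool(edge_mass > 0.5))


def run_staircase(
    n_trials: int,
    observer_p_correct,
    state: StaircaseState | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[StaircaseState, np.ndarray, np.ndarray]:
    """Run the staircase against a simulated observer.

    ``observer_p_correct(log_offset)`` returns the true probability of a
    correct response at the proposed offset.  Returns the final state, the
    array of shown log10 offsets, and the boolean outcome array.
    """
    require_rng(rng)
    if state is None:
        state = StaircaseState()
    offsets = np.empty(n_trials)
    outcomes = np.empty(n_trials, dtype=bool)
    for t in range(n_trials):
        x = state.proposed_offset
        correct = rng.random() < observer_p_correct(x)
        state = quest_propose_and_update(state, correct, x)
        offsets[t] = x
        outcomes[t] = correct
    return state, offsets, outcomes
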