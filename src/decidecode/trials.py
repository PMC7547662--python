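"""Trial-table generation: stimulus sampling, staircase loop, observer.

A trial presents ten contrast samples drawn i.i.d. from
N(0.5 +/- offset, sd_level) with the per-trial sd_level picked at random
from {0.05, 0.1, 0.15} and the offset controlled by a QUEST staircase that
titrates accuracy to 75%.  Draws falling outside [0, 1] are redrawn
(per-sample rejection).  The *realized* mean of the ten draws defines the
stimulus category (stronger iff mean > 0.5), the simulated observer
produces choice/confidence/RT, and correctness feeds back into the
staircase.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import require_rng, substream
from .observer import ObserverParams, simulate_observer
from .staircase import StaircaseState, quest_propose_and_update

__all__ = [
    "SD_LEVELS",
    "SAMPLE_COLUMNS",
    "sample_trial_contrasts",
    "generate_trial_table",
]

SD_LEVELS = (0.05, 0.1, 0.15)
SAMPLE_COLUMNS = [f"s{i:02d}" for i in range(1, 11)]


def _truncated_normal(mean, sd, size, rng):
    """Per-sample rejection sampling of N(mean, sd) into [0, 1]."""
    out = rng.normal(mean, sd, size=size)
    if sd == 0:
        return np.clip(out, 0.0, 1.0)
    bad = (out < 0) | (out > 1)
    while np.any(bad):
        out[bad] = rng.normal(np.broadcast_to(mean, out.shape)[bad] if np.ndim(mean) else mean,
                              sd, size=int(bad.sum()))
        bad = (out < 0) | (out > 1)
    return out


def sample_trial_contrasts(
    mean_offset: float,
    sd_level: float,
    category: str,
    rng: np.random.Generator,
    n_samples: int = 10,
) -> np.ndarray:
    """Draw the contrast samples of one trial.

    ``category`` ("stronger"/"weaker") sets the sign of the offset around
    the 0.5 reference.  Samples outside [0, 1] are redrawn individually.
    """
    require_rng(rng)
    if category not in ("stronger", "weaker"):
        raise ValueError("category must be 'stronger' or 'weaker'")
    mean = 0.5 + mean_offset if category == "stronger" else 0.5 - mean_offset
    if not 0.0 < mean < 1.0:
        raise ValueError("mean contrast 0.5 +/- offset must lie inside (0, 1)")
    return _truncated_normal(mean, sd_level, n_samples, rng)


def _hand_mapping(subject: int) -> dict:
    # choice-to-hand mapping counterbalanced across subjects
    if subject % 2 == 0:
        return {"stronger": "right", "weaker": "left"}
    return {"stronger": "left", "weaker": "right"}


def generate_trial_table(
    n_subjects: int = 15,
    n_trials: int = 500,
    observer: ObserverParams | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    sd_levels: tuple = SD_LEVELS,
    adaptive: bool = True,
    fixed_offset: float = 0.05,
    choice_policy: str = "observer",
    staircase: StaircaseState | None = None,
) -> pd.DataFrame:
    """Simulate a cohort and return one tidy trial table.

    Parameters
    ----------
    adaptive : run the QUEST staircase per subject (sequential); if False,
        every trial uses ``fixed_offset`` and generation is vectorized.
    choice_policy : "observer" (accumulator) or "coin" (choices by fair
        coin, independent of the contrasts — the null for kernel analyses).

    Returns a DataFrame with one row per trial and columns: subject, trial,
    s01..s10, sd_level, trial_mean, stimulus_category, choice, confidence,
    rt, correct, response_hand.
    """
    if rng is None:
        if seed is None:
            raise ValueError("pass either seed or rng")
        rng = substream(seed, "trials")
    require_rng(rng)
    observer = observer or ObserverParams()
    if choice_policy not in ("observer", "coin"):
        raise ValueError("choice_policy must be 'observer' or 'coin'")

    frames = []
    for subj in range(n_subjects):
        hand_map = _hand_mapping(subj)
        sd = np.asarray(sd_levels)[rng.integers(0, len(sd_levels), size=n_trials)]
        intended = np.where(rng.random(n_trials) < 0.5, "stronger", "weaker")
        if adaptive:
            state = staircase if staircase is not None else StaircaseState()
            samples = np.empty((n_trials, 10))
            choice = np.empty(n_trials, dtype=object)
            confidence = np.empty(n_trials, dtype=object)
            rt = np.empty(n_trials)
            correct = np.empty(n_trials, dtype=bool)
            category = np.empty(n_trials, dtype=object)
            for t in range(n_trials):
                offset = 10.0 ** state.proposed_offset
                c = sample_trial_contrasts(offset, sd[t], intended[t], rng)
                samples[t] = c
                ch, cf, r, _ = simulate_observer(c, observer, rng)
                category[t] = "stronger" if c.mean() > 0.5 else "weaker"
                choice[t], confidence[t], rt[t] = ch, cf, r
                correct[t] = choice[t] == category[t]
                state = quest_propose_and_update(state, bool(correct[t]), state.proposed_offset)
        else:
            means = np.where(intended == "stronger", 0.5 + fixed_offset, 0.5 - fixed_offset)
            samples = rng.normal(means[:, None], sd[:, None], size=(n_trials, 10))
            bad = (samples < 0) | (samples > 1)
            while np.any(bad):
                redraw = rng.normal(np.broadcast_to(means[:, None], samples.shape)[bad],
                                    np.broadcast_to(sd[:, None], samples.shape)[bad])
                samples[bad] = redraw
                bad = (samples < 0) | (samples > 1)
            ch, cf, rt, _ = simulate_observer(samples, observer, rng)
            choice, confidence = ch, cf
            category = np.where(samples.mean(axis=1) > 0.5, "stronger", "weaker")
            correct = choice == category
        if choice_policy == "coin":
            choice = np.where(rng.random(n_trials) < 0.5, "stronger", "weaker")
            correct = choice == category
        df = pd.DataFrame(samples, columns=SAMPLE_COLUMNS)
        df.insert(0, "subject", subj)
        df.insert(1, "trial", np.arange(n_trials))
        df["sd_level"] = sd
        df["trial_mean"] = samples.mean(axis=1)
        df["stimulus_category"] = category
        df["choice"] = choice
        df["confidence"] = confidence
        df["rt"] = rt
        df["correct"] = correct
        df["response_hand"] = [hand_map[c] for c in df["choice"]]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def sample_matrix(trials: pd.DataFrame) -> np.ndarray:
    """The (n_trials, 10) contrast-sample matrix of a trial table."""
    return trials[SAMPLE_COLUMNS].to_numpy(float)
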