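"""Group-level inference.

* A hierarchical Bayesian model of group-average decoding accuracy: each
  subject's AUC at time t is a draw from StudentT(mu_t, sigma_t, gamma)
  with weakly informative priors mu_t ~ N(0.5, 1), sigma_t ~ U(0, 5) and
  gamma ~ Exponential(mean 29) + 1 (gamma shared across time).  The
  posterior is sampled with emcee's affine-invariant ensemble sampler
  (two independent ensembles, 3000 iterations each by default) and gated
  on split-R-hat < 1.05.
* Threshold-free cluster enhancement (TFCE, H = 2, E = 0.5) with
  sign-flip permutation tests for family-wise error control on 1-D time
  courses and 2-D time-frequency maps.
* Benjamini-Hochberg FDR correction and thin t-test / one-way ANOVA
  utilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupPosterior",
    "group_auc_posterior",
    "tfce",
    "ClusterTestResult",
    "cluster_permutation_test",
    "fdr_correct",
    "one_sample_t",
    "paired_t",
    "one_way_anova",
]


# ---------------------------------------------------------------------------
# hierarchical Bayesian AUC model


@dataclass
class GroupPosterior:
    """Posterior summaries for the group-mean AUC time course."""

    mu_mean: np.ndarray          # posterior mean of mu_t
    mu_hdi: np.ndarray           # (time, 2) 95% highest-density interval
    sigma_mean: np.ndarray
    gamma_mean: float
    rhat: dict                   # split-R-hat per parameter block (max over time)
    converged: bool              # all R-hat < 1.05
    draws: np.ndarray = field(repr=False, default=None)  # (chain, draw, ndim)


def _logprob_factory(data: np.ndarray):
    n_t = data.shape[1]

    def logprob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        mu = theta[:, :n_t]
        sigma = theta[:, n_t:2 * n_t]
        gamma = theta[:, 2 * n_t]
        bad = (sigma <= 0).any(axis=1) | (sigma >= 5).any(axis=1) | (gamma <= 1)
        out = np.full(theta.shape[0], -np.inf)
        ok = ~bad
        if ok.any():
            lp = stats.t.logpdf(
                data[None, :, :],
                df=gamma[ok, None, None],
                loc=mu[ok, None, :],
                scale=sigma[ok, None, :],
            ).sum(axis=(1, 2))
            prior = (
                stats.norm.logpdf(mu[ok], 0.5, 1.0).sum(axis=1)
                - (gamma[ok] - 1.0) / 29.0
            )
            out[ok] = lp + prior
        return out

    return logprob


def group_auc_posterior(
    auc: np.ndarray,
    draws: int = 3000,
    chains: int = 2,
    seed: int = 0,
    rhat_threshold: float = 1.05,
) -> GroupPosterior:
    """Sample the hierarchical StudentT model of subject AUC time courses.

    ``auc`` is (subject, time) with at least 3 subjects.  Returns posterior
    summaries; if any split-R-hat exceeds the threshold the result is
    flagged (``converged=False``) but summaries are still returned.
    """
    import arviz as az
    import emcee

    auc = np.atleast_2d(np.asarray(auc, float))
    n_s, n_t = auc.shape
    if n_s < 3:
        raise ValueError("need at least 3 subjects")
    ndim = 2 * n_t + 1
    n_walkers = max(2 * ndim + 2, 16)
    n_walkers += n_walkers % 2
    logprob = _logprob_factory(auc)
    rng = np.random.default_rng(seed)
    chains_out = []
    for c in range(chains):
        init = np.empty((n_walkers, ndim))
        init[:, :n_t] = auc.mean(axis=0) + rng.normal(0, 0.02, (n_walkers, n_t))
        init[:, n_t:2 * n_t] = np.clip(
            auc.std(axis=0, ddof=1) * np.exp(rng.normal(0, 0.2, (n_walkers, n_t))),
            1e-3, 4.9)
        init[:, -1] = 1.0 + rng.exponential(10.0, n_walkers)
        sampler = emcee.EnsembleSampler(n_walkers, ndim, logprob, vectorize=True)
        sampler._random = np.random.RandomState(seed * 1000 + c + 1)
        sampler.run_mcmc(init, draws, progress=False)
        chains_out.append(sampler.get_chain(discard=draws // 2))  # (draw, walker, ndim)
    # each independent ensemble is one chain: pool walkers draw-major so the
    # split-R-hat halves correspond to early vs late draws
    all_chains = np.stack(
        [ch.reshape(-1, ndim) for ch in chains_out], axis=0)    # (chain, draw*walker, ndim)
    posterior = {
        "mu": all_chains[:, :, :n_t],
        "sigma": all_chains[:, :, n_t:2 * n_t],
        "gamma": all_chains[:, :, -1],
    }
    ds = az.convert_to_dataset(posterior)
    rhat_ds = az.rhat(ds)
    rhat = {k: float(np.nanmax(rhat_ds[k].values)) for k in ("mu", "sigma", "gamma")}
    converged = all(v < rhat_threshold for v in rhat.values())
    flat = all_chains.reshape(-1, ndim)
    hdi = az.hdi(ds, hdi_prob=0.95)["mu"].values.reshape(n_t, 2)
    return GroupPosterior(
        mu_mean=flat[:, :n_t].mean(axis=0),
        mu_hdi=hdi,
        sigma_mean=flat[:, n_t:2 * n_t].mean(axis=0),
        gamma_mean=float(flat[:, -1].mean()),
        rhat=rhat,
        converged=converged,
        draws=all_chains,
    )


# ---------------------------------------------------------------------------
# TFCE and permutation testing


def _adjacency_structure(ndim: int) -> np.ndarray:
    # 2-neighborhood in 1-D, 4-neighborhood in 2-D
    return ndimage.generate_binary_structure(ndim, 1)


def tfce(
    stat_map: np.ndarray, H: float = 2.0, E: float = 0.5, dh: float | None = None,
    n_steps: int = 100,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a 1-D or 2-D statistic map.

    TFCE(v) = sum_h extent(v, h)^E * h^H * dh over thresholds 0 < h <=
    |stat(v)|, applied separately to the positive and negative tails (the
    output keeps the sign of the input).  Default integration step
    dh = max|stat| / 100.
    """
    stat_map = np.asarray(stat_map, float)
    if not np.all(np.isfinite(stat_map)):
        raise ValueError("stat map contains non-finite values")
    vmax = np.abs(stat_map).max()
    if vmax == 0:
        return np.zeros_like(stat_map)
    if dh is None:
        dh = vmax / n_steps
    out = np.zeros_like(stat_map)
    for sign in (1.0, -1.0):
        s = sign * stat_map
        smax = s.max()
        if smax <= 0:
            continue
        n_thresh = int(np.floor(smax / dh + 1e-9))
        thresholds = dh * np.arange(1, n_thresh + 1)
        if stat_map.ndim == 1:
            out += sign * _tfce_tail_1d(s, thresholds, H, E, dh)
        else:
            structure = _adjacency_structure(stat_map.ndim)
            for h in thresholds:
                mask = s >= h
                labels, n = ndimage.label(mask, structure=structure)
                if n:
                    extent = np.bincount(labels.ravel())[labels[mask]]
                    out[mask] += sign * (extent.astype(float) ** E) * (h**H) * dh
    return out


def _tfce_tail_1d(s: np.ndarray, thresholds: np.ndarray, H: float, E: float,
                  dh: float) -> np.ndarray:
    """Vectorized positive-tail TFCE for 1-D maps (runs as clusters)."""
    n = s.size
    mask = s[None, :] >= thresholds[:, None]                 # (T, n)
    starts = mask & ~np.pad(mask, ((0, 0), (1, 0)))[:, :-1]
    run_id = np.cumsum(starts, axis=1) * mask                # 1-based per row
    max_id = run_id.max() if run_id.size else 0
    if max_id == 0:
        return np.zeros(n)
    rows = np.arange(thresholds.size)[:, None]
    flat = (rows * (max_id + 1) + run_id).ravel()
    extent_lut = np.bincount(flat, weights=mask.ravel(),
                             minlength=thresholds.size * (max_id + 1))
    extent = extent_lut[flat].reshape(mask.shape) * mask
    contrib = np.where(mask, extent**E, 0.0) * (thresholds**H)[:, None] * dh
    return contrib.sum(axis=0)


@dataclass
class ClusterTestResult:
    """TFCE permutation-test output."""

    enhanced: np.ndarray       # TFCE of the observed t map (signed)
    null_max: np.ndarray       # max |TFCE| per permutation
    p: np.ndarray              # corrected two-sided p per element
    mask: np.ndarray           # p < alpha
    alpha: float


def _one_sample_t_map(data: np.ndarray) -> np.ndarray:
    mean = data.mean(axis=0)
    sem = data.std(axis=0, ddof=1) / np.sqrt(data.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sem > 0, mean / np.where(sem > 0, sem, 1.0), 0.0)
    return t


def cluster_permutation_test(
    data: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    H: float = 2.0,
    E: float = 0.5,
) -> ClusterTestResult:
    """One-sample TFCE permutation test against zero (sign-flip null).

    ``data`` is (subject, *map).  The null distribution is the maximum
    |TFCE| statistic over random per-subject sign flips; corrected p-values
    are the rank of the observed enhanced values in that distribution.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    data = np.asarray(data, float)
    if n_perm < max(500, int(np.ceil(1.0 / alpha)) - 1):
        raise ValueError(f"n_perm={n_perm} too small for alpha={alpha}")
    obs = tfce(_one_sample_t_map(data), H=H, E=E)
    null_max = np.empty(n_perm)
    n_s = data.shape[0]
    for p_i in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=n_s)
        flipped = data * flips.reshape((n_s,) + (1,) * (data.ndim - 1))
        null_max[p_i] = np.abs(tfce(_one_sample_t_map(flipped), H=H, E=E)).max()
    p = (1.0 + (null_max[None, :] >= np.abs(obs.ravel())[:, None]).sum(axis=1)) / (
        n_perm + 1.0)
    p = p.reshape(obs.shape)
    return ClusterTestResult(obs, null_max, p, p < alpha, alpha)


# ---------------------------------------------------------------------------
# simple frequentist utilities


def fdr_correct(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)


def one_sample_t(x: np.ndarray, popmean: float = 0.0):
    x = np.asarray(x, float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    return stats.ttest_1samp(x, popmean)


def paired_t(a: np.ndarray, b: np.ndarray):
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape[0] < 2:
        raise ValueError("need at least 2 pairs")
    return stats.ttest_rel(a, b)


def one_way_anova(*groups):
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    return stats.f_oneway(*groups)
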