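"""End-to-end orchestration: generate -> behavior -> decode -> kernels -> stats.

``run_pipeline`` ties the synthetic generator and every analysis stage into
one deterministic run: given a seed and a :class:`RunConfig` it simulates a
cohort, computes psychophysical and neural kernels, choice and contrast
decoding time courses, the alpha x gamma interaction model, the M1 ->
visual-cortex cross-correlation with its leakage reference, and group
statistics, writing tables (TSV), results (JSON) and a manifest with the
config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._rng import substream
from .behavior import (
    exclude_fast_rts,
    fit_choice_logreg,
    kernel_slope,
    psychophysical_kernel,
)
from .decoding import (
    decode_choice_spectral,
    decode_contrast,
    encoding_regression,
    envelope,
)
from .group_stats import cluster_permutation_test, fdr_correct, group_auc_posterior
from .io import write_results, write_trials
from .kernels import (
    band_power_by_sample,
    correlate_kernels,
    crosscorr_choice_feedback,
    group_crosscorr,
    highres_kernel,
    interaction_logreg,
    leakage_reference,
    neural_kernel,
)
from .neural import MOTOR_ROIS, VISUAL_ROIS, NeuralGenParams, default_frequency_grid, generate_power_tensor
from .observer import ObserverParams
from .spectral import GAMMA_BAND, LOW_FREQUENCY_BAND, baseline_normalize, hemi_average, lateralize
from .trials import generate_trial_table

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("decidecode")


@dataclass
class RunConfig:
    """Parameters of one reproducible pipeline run.

    Defaults follow the study conditions: 15 subjects, 75% staircase
    target, sample SD levels {0.05, 0.1, 0.15}, 190 ms encoding latency,
    150 ms feedback lag, 1.225 s RT exclusion, lags -215..215 ms, SVM
    C = 1, ridge grid {0.1, 1, 10}, TFCE H = 2 / E = 0.5.
    """

    seed: int = 0
    n_subjects: int = 15
    n_trials: int = 300               # analyzed trials per subject
    n_calibration_trials: int = 100   # initial staircase block, excluded from analysis
    observer: dict = field(default_factory=dict)
    neural: dict = field(default_factory=dict)
    coarse_grid: bool = True          # reduced frequency grid for simulation runs
    decode_rois: tuple = ("M1-hand",)
    contrast_roi: str = "V1"
    n_folds: int = 10
    decode_time_stride: int = 1       # stride of the M1 choice-decoding grid
    contrast_time_stride: int = 6     # stride of the contrast-decoding grid
    n_perm: int = 1000
    posterior_draws: int = 3000
    lag_range: tuple = (-0.215, 0.215)
    out_dir: str = "results"

    def validate(self) -> "RunConfig":
        if self.n_subjects < 1 or self.n_trials < 50:
            raise ValueError("need at least 1 subject and 50 trials")
        if self.n_folds < 2 or self.n_perm < 500:
            raise ValueError("n_folds >= 2 and n_perm >= 500 required")
        unknown = set(self.observer) - {f.name for f in dataclasses.fields(ObserverParams)}
        if unknown:
            raise ValueError(f"unknown observer parameters: {sorted(unknown)}")
        unknown = set(self.neural) - {f.name for f in dataclasses.fields(NeuralGenParams)}
        if unknown:
            raise ValueError(f"unknown neural parameters: {sorted(unknown)}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        return cfg.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("decode_rois", "lag_range"):
            d[key] = list(d[key])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _observer(config: RunConfig) -> ObserverParams:
    kwargs = dict(config.observer)
    if "weights" in kwargs:
        kwargs["weights"] = np.asarray(kwargs["weights"], float)
    return ObserverParams(**kwargs)


def _neural(config: RunConfig) -> NeuralGenParams:
    kwargs = dict(config.neural)
    kwargs.setdefault("frequency_grid", default_frequency_grid(coarse=config.coarse_grid))
    return NeuralGenParams(**kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a simulated cohort; returns the results dict.

    Deterministic given ``config.seed``; writes trials.tsv, results.json
    and manifest.json into ``config.out_dir``.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    observer = _observer(config)
    neural = _neural(config)
    results: dict = {}
    t0 = _time.time()

    def _stage(name):
        logger.info("stage %-12s +%.1fs", name, _time.time() - t0)

    try:
        _stage("generate")
        raw_trials = generate_trial_table(
            n_subjects=config.n_subjects,
            n_trials=config.n_trials + config.n_calibration_trials,
            observer=observer, rng=substream(config.seed, "trials"))
        # the first block calibrates the staircase (the experiment's training
        # session) and is excluded from analysis
        trials = raw_trials[raw_trials.groupby("subject").cumcount()
                            >= config.n_calibration_trials].reset_index(drop=True)
        write_trials(trials, out_dir / "trials.tsv")

        _stage("behavior")
        trials_used = exclude_fast_rts(trials)
        results["n_trials_total"] = int(len(trials))
        results["n_excluded_fast_rt"] = trials_used.attrs["n_excluded_fast_rt"]
        kernels_pp, slopes, accs = [], [], []
        for s, sub in trials_used.groupby("subject"):
            k = psychophysical_kernel(sub)
            kernels_pp.append(k)
            slopes.append(kernel_slope(k))
            accs.append(fit_choice_logreg(sub).cv_accuracy)
        kernels_pp = np.array(kernels_pp)
        results["psychophysical_kernel_group"] = kernels_pp.mean(axis=0)
        results["psychophysical_kernel_slope_group"] = float(np.mean(slopes))
        results["choice_model_cv_accuracy"] = float(np.mean(accs))
        results["accuracy"] = float(trials_used["correct"].mean())
        # FDR-corrected one-sample t against chance across sample positions
        from scipy.stats import ttest_1samp
        p_pos = ttest_1samp(kernels_pp, 0.5, axis=0).pvalue
        results["psychophysical_kernel_fdr_mask"] = fdr_correct(p_pos)

        _stage("neural")
        rng_neural = substream(config.seed, "neural")
        tensors = {}
        for s, sub in trials_used.groupby("subject"):
            raw = generate_power_tensor(sub.reset_index(drop=True), neural,
                                        roi_set=VISUAL_ROIS + MOTOR_ROIS,
                                        rng=rng_neural, observer=observer)
            tensors[s] = baseline_normalize(raw)

        _stage("decoding")
        rng_dec = substream(config.seed, "decoding")
        times = neural.times
        # full-resolution grid on [0, 0.8] s: the cross-correlation with the
        # visual kernel needs matched time bases (no stride aliasing)
        dec_times = times[(times >= 0) & (times <= 0.8 + 1e-9)][::config.decode_time_stride]
        contrast_times = times[times >= 0][::config.contrast_time_stride]
        m1_curves = []
        for s, sub in trials_used.groupby("subject"):
            tc = decode_choice_spectral(tensors[s], sub.reset_index(drop=True),
                                        "M1-hand", rng_dec, n_folds=config.n_folds,
                                        times=dec_times)
            m1_curves.append(tc.score)
        m1_curves = np.array(m1_curves)
        results["m1_choice_auc_times"] = dec_times
        results["m1_choice_auc_group"] = m1_curves.mean(axis=0)

        # contrast decoding: one early and one late sample plus running means
        v1_sample_curves = []
        for i in (1, 5, 10):
            per_subj = []
            for s, sub in trials_used.groupby("subject"):
                sub = sub.reset_index(drop=True)
                p = hemi_average(tensors[s].sel(roi=config.contrast_roi))
                tc = decode_contrast(p, sub[f"s{i:02d}"].to_numpy(float), rng_dec,
                                     n_folds=config.n_folds, times=contrast_times)
                per_subj.append(tc.score)
            v1_sample_curves.append(np.mean(per_subj, axis=0))
        results["v1_contrast_decoding_times"] = contrast_times
        results["v1_contrast_decoding_samples"] = np.array(v1_sample_curves)
        results["v1_contrast_decoding_envelope"] = envelope(np.array(v1_sample_curves))

        enc = []
        for s, sub in trials_used.groupby("subject"):
            p = hemi_average(tensors[s].sel(roi=config.contrast_roi))
            enc.append(encoding_regression(p, sub.reset_index(drop=True)).values)
        results["encoding_beta_freqs"] = np.asarray(
            tensors[min(tensors)]["freq"].values, float)
        results["encoding_beta_group"] = np.nanmean(enc, axis=0)

        _stage("kernels")
        gamma_overall, gamma_resid, low_overall, low_resid = [], [], [], []
        pp_gamma_r, pp_low_r, inter_asym = [], [], []
        xc_rows, ref_rows = [], []
        dt = float(np.median(np.diff(times)))
        n_lag = int(round(config.lag_range[1] / dt))
        lags = np.arange(-n_lag, n_lag + 1) * dt
        for si, (s, sub) in enumerate(trials_used.groupby("subject")):
            sub = sub.reset_index(drop=True)
            v1 = hemi_average(tensors[s].sel(roi="V1"))
            gamma_overall.append(neural_kernel(v1, sub, GAMMA_BAND, "overall"))
            gamma_resid.append(neural_kernel(v1, sub, GAMMA_BAND, "residual"))
            low_overall.append(neural_kernel(v1, sub, LOW_FREQUENCY_BAND, "overall"))
            low_resid.append(neural_kernel(v1, sub, LOW_FREQUENCY_BAND, "residual"))
            ppk = psychophysical_kernel(sub)
            pp_gamma_r.append(correlate_kernels(gamma_overall[-1], ppk))
            pp_low_r.append(correlate_kernels(low_overall[-1], ppk))
            inter_asym.append(interaction_logreg(
                sub,
                band_power_by_sample(v1, LOW_FREQUENCY_BAND),
                band_power_by_sample(v1, GAMMA_BAND)).asymmetry)
            kt, kv = highres_kernel(v1, sub, LOW_FREQUENCY_BAND)
            # the motor choice signal is lateralized, so the M1 kernel series
            # (leakage reference) uses contra-ipsi power wrt the stronger hand
            hand = sub.loc[sub["choice"] == "stronger", "response_hand"].iloc[0]
            m1 = lateralize(tensors[s].sel(roi="M1-hand"), hand)
            mt, mk = highres_kernel(m1, sub, LOW_FREQUENCY_BAND)
            xc_rows.append(crosscorr_choice_feedback(
                dec_times, m1_curves[si], kt, kv, lags))
            ref_rows.append(leakage_reference(dec_times, m1_curves[si], mt, mk))
        xc = group_crosscorr(np.array(xc_rows), lags,
                             reference_r=float(np.nanmean(ref_rows)))
        results["v1_gamma_kernel_group"] = np.mean(gamma_overall, axis=0)
        results["v1_gamma_kernel_residual_group"] = np.mean(gamma_resid, axis=0)
        results["v1_low_kernel_group"] = np.mean(low_overall, axis=0)
        results["v1_low_kernel_residual_group"] = np.mean(low_resid, axis=0)
        results["v1_gamma_vs_psychophysical_r"] = float(np.mean(pp_gamma_r))
        results["v1_low_vs_psychophysical_r"] = float(np.mean(pp_low_r))
        results["interaction_asymmetry_group"] = {
            k: float(np.mean([a[k] for a in inter_asym]))
            for k in ("low_frequency", "gamma", "interaction")}
        results["crosscorr_lags"] = lags
        results["crosscorr_group_r"] = xc.group_r
        results["crosscorr_peak_lag"] = xc.peak_lag
        results["crosscorr_reference_r"] = xc.reference_r

        _stage("stats")
        rng_stats = substream(config.seed, "stats")
        if config.n_subjects >= 3:
            post = group_auc_posterior(m1_curves[:, ::8], draws=config.posterior_draws,
                                       seed=config.seed)
            results["m1_posterior_mu"] = post.mu_mean
            results["m1_posterior_hdi"] = post.mu_hdi
            results["m1_posterior_converged"] = bool(post.converged)
            perm = cluster_permutation_test(
                np.array(low_overall) - 0.5, n_perm=config.n_perm, rng=rng_stats)
            results["v1_low_kernel_tfce_mask"] = perm.mask

        manifest = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "elapsed_s": _time.time() - t0,
        }
        write_results(results, out_dir / "results.json")
        write_results(manifest, out_dir / "manifest.json")
        return results
    except Exception as exc:  # halt with stage context; keep partial outputs
        write_results(results, out_dir / "results_partial.json")
        raise RuntimeError(f"pipeline halted: {exc}") from exc
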