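"""Calibration experiments on synthetic cohorts.

These routines validate the pipeline's statistical behaviour end to end:
false-positive control of the robust mean-FDR rule under a global null,
recovery of planted FT4 effects, hormone-trajectory calibration, and
classifier sanity under permuted and strongly separated labels.  Each one
generates its data, runs the relevant pipeline stages, and measures the
result; sizes default to desk-scale settings (documented in the methods
note) and every function is reproducible given its seed.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .association import fit_feature_model
from .classification import CVConfig, complete_feature_filter, label_samples, nested_cv
from .preprocess import log10_transform
from .robustness import make_subsets, robust_associate
from .synthetic import (
    make_design,
    metabolite_defaults,
    simulate_features,
    simulate_hormones,
)

__all__ = [
    "null_calibration_rate",
    "hormone_calibration",
    "effect_recovery",
    "classifier_null_auc",
    "classifier_signal_auc",
]


def _spawn(seed, n):
    return [int(s.generate_state(1)[0] % (2**31 - 1))
            for s in np.random.SeedSequence(seed).spawn(n)]


def null_calibration_rate(
    seed: int,
    n_datasets: int = 200,
    n_features: int = 100,
    n_random_subsets: int = 19,
) -> dict:
    """Family-wise false-positive rate of the robust mean-FDR rule.

    Simulates independent global-null cohorts (16 subjects x 5 visits, no
    planted effects, no missingness), runs the mixed-model screen with
    per-subset BH adjustment over a reduced leave-three-out plan
    (``n_random_subsets`` random draws + the fixed exclusion), and returns the
    percentage of datasets in which any feature is declared significant.
    """
    hits = 0
    for s in _spawn(seed, n_datasets):
        rng = np.random.default_rng(s)
        design, subjects = make_design(seed=int(rng.integers(2**31 - 1)))
        samples = simulate_hormones(design, subjects, rng=rng)
        cfg = metabolite_defaults(
            n_features=n_features, effect_fraction=0.0, missing_rate=0.0,
            runday_scaling=False, outlier_shift_sd=0.0,
        )
        matrix, _ = simulate_features(design, subjects, samples, cfg, rng=rng)
        plan = make_subsets(
            design.subject_ids, n_random=n_random_subsets,
            fixed_exclusion=tuple(sorted(design.outlier_subjects)), rng=rng,
        )
        agg = robust_associate(log10_transform(matrix), samples, plan, "metabolite")
        hits += int(agg["significant"].any())
    return {"rate_percent": 100.0 * hits / n_datasets, "n": n_datasets}


def hormone_calibration(seed: int, n_subjects: int = 10_000) -> dict:
    """Mean FT4 at the 4-week treatment visit in a large simulated cohort."""
    design, subjects = make_design(n_subjects=n_subjects, n_outliers=0, seed=seed)
    samples = simulate_hormones(design, subjects, seed=seed + 1)
    w4 = samples.loc[samples["time_point"] == "w4", "ft4"]
    return {
        "mean_ft4_w4": float(w4.mean()),
        "mc_se": float(w4.std(ddof=1) / np.sqrt(len(w4))),
        "n": int(len(w4)),
    }


def effect_recovery(
    seed: int,
    n_reps: int = 200,
    beta_true: float = 0.02,
    residual_sd: float = 0.05,
    subject_sd: float = 0.10,
) -> dict:
    """Bias and 95% CI coverage for a planted effect at low noise."""
    estimates, covered = [], 0
    for s in _spawn(seed, n_reps):
        rng = np.random.default_rng(s)
        design, subjects = make_design(n_outliers=0, seed=int(rng.integers(2**31 - 1)))
        samples = simulate_hormones(design, subjects, rng=rng)
        cfg = metabolite_defaults(
            n_features=1, effect_fraction=1.0, positive_fraction=1.0,
            beta_range=(beta_true, beta_true), residual_sd=residual_sd,
            subject_sd=subject_sd, missing_rate=0.0, runday_scaling=False,
        )
        matrix, _ = simulate_features(design, subjects, samples, cfg, rng=rng)
        fit = fit_feature_model(log10_transform(matrix).iloc[:, 0], samples, "metabolite")
        estimates.append(fit["beta"])
        df = fit["n_used"] - design.n_subjects - 4 + 1
        tcrit = sps.t.ppf(0.975, df)
        covered += abs(fit["beta"] - beta_true) <= tcrit * fit["se"]
    estimates = np.asarray(estimates)
    return {
        "beta_true": beta_true,
        "mean_beta": float(estimates.mean()),
        "relative_bias_percent": float(
            100.0 * abs(estimates.mean() - beta_true) / beta_true
        ),
        "coverage_percent": 100.0 * covered / n_reps,
        "n": n_reps,
    }


def _classifier_run(rng, permute: bool, strong: bool, cv_kwargs: dict) -> float:
    design, subjects = make_design(seed=int(rng.integers(2**31 - 1)))
    samples = simulate_hormones(design, subjects, rng=rng)
    if strong:
        cfg = metabolite_defaults(
            n_features=40, effect_fraction=0.30, beta_range=(0.02, 0.04),
            residual_sd=0.10, missing_rate=0.0, runday_scaling=False,
        )
    else:
        cfg = metabolite_defaults(
            n_features=40, effect_fraction=0.25, beta_range=(0.01, 0.03),
            missing_rate=0.0, runday_scaling=False,
        )
    matrix, _ = simulate_features(design, subjects, samples, cfg, rng=rng)
    logm = log10_transform(matrix)
    labeled = label_samples(samples)
    if permute:
        labeled = labeled.copy()
        labeled["state"] = rng.permutation(labeled["state"].to_numpy())
    kept = complete_feature_filter(logm, labeled)
    cv = nested_cv(
        logm[kept], labeled,
        CVConfig(seed=int(rng.integers(2**31 - 1)), **cv_kwargs),
    )
    return cv.mean_auc


_REDUCED_CV = dict(n_outer=5, n_inner=6, n_trees=40, panel_size=10)


def classifier_null_auc(seed: int, n_reps: int = 20) -> dict:
    """Mean nested-CV AUC under randomly permuted labels (expected ~0.5)."""
    aucs = [
        _classifier_run(np.random.default_rng(s), permute=True, strong=False,
                        cv_kwargs=_REDUCED_CV)
        for s in _spawn(seed, n_reps)
    ]
    return {"mean_auc": float(np.mean(aucs)), "n": n_reps}


def classifier_signal_auc(seed: int) -> dict:
    """Mean nested-CV AUC under strong planted class separation."""
    auc = _classifier_run(np.random.default_rng(seed), permute=False, strong=True,
                          cv_kwargs=_REDUCED_CV)
    return {"mean_auc": float(auc), "n": 1}
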