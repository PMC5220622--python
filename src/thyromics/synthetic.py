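"""Synthetic longitudinal plasma-omics cohorts.

Emulates a controlled thyrotoxicosis challenge: healthy subjects receive
levothyroxine for eight weeks and plasma is sampled at five visits (baseline,
weeks 4 and 8 under treatment, weeks 12 and 16 after withdrawal).  Free
thyroxine (FT4) rises from ~13 to ~29 pmol/L under treatment while TSH is
suppressed to near zero, then both normalise.  Metabolite and protein
intensities follow a log10-linear model in FT4 with a per-subject random
intercept, age/BMI covariate effects, proteome batch shifts, acquisition
run-day scale factors, and configurable missingness — i.e. exactly the
structure the downstream mixed-model screen assumes, plus ground-truth effect
labels for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TIME_POINTS",
    "TREATED_POINTS",
    "HORMONE_PARAMS",
    "StudyDesign",
    "LayerConfig",
    "metabolite_defaults",
    "protein_defaults",
    "make_design",
    "simulate_hormones",
    "simulate_features",
]

TIME_POINTS = ("bas", "w4", "w8", "w12", "w16")
TREATED_POINTS = ("w4", "w8")

# Per-visit hormone (mean, SD): FT4 in pmol/L, TSH in mU/L.
HORMONE_PARAMS = {
    "bas": {"ft4": (13.2, 1.4), "tsh": (2.104, 1.017)},
    "w4": {"ft4": (28.6, 6.5), "tsh": (0.017, 0.029)},
    "w8": {"ft4": (25.9, 5.7), "tsh": (0.007, 0.007)},
    "w12": {"ft4": (11.5, 1.5), "tsh": (2.298, 1.309)},
    "w16": {"ft4": (12.8, 1.5), "tsh": (2.177, 0.897)},
}


@dataclass(frozen=True)
class StudyDesign:
    """Longitudinal sampling grid: every subject is sampled at every visit."""

    n_subjects: int = 16
    time_points: tuple = TIME_POINTS
    treated_points: tuple = TREATED_POINTS
    outlier_subjects: frozenset = frozenset()
    seed: int | None = None

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("invalid design: n_subjects must be >= 1")
        if len(set(self.time_points)) != len(self.time_points):
            raise ValueError("invalid design: time points must be unique")
        if not set(self.treated_points) <= set(self.time_points):
            raise ValueError("invalid design: treated_points must be a subset of time_points")
        if len(self.outlier_subjects) > self.n_subjects:
            raise ValueError("invalid design: more outliers than subjects")

    @property
    def n_samples(self) -> int:
        return self.n_subjects * len(self.time_points)

    @property
    def subject_ids(self) -> tuple:
        width = max(2, len(str(self.n_subjects)))
        return tuple(f"S{i + 1:0{width}d}" for i in range(self.n_subjects))


@dataclass(frozen=True)
class LayerConfig:
    """Generative settings for one omics layer.

    Effect sizes are on the log10-intensity scale per pmol/L FT4; with FT4
    spanning roughly 17 pmol/L during the challenge, the default 0.005-0.03
    magnitude range corresponds to ~1.2- to 3-fold excursions, matching the
    moderate-to-strong responders seen in targeted assays.
    """

    layer: str = "metabolite"
    n_features: int = 349
    effect_fraction: float = 0.19  # share of features truly FT4-associated
    positive_fraction: float = 45 / 65  # sign split among associated features
    beta_range: tuple = (0.005, 0.03)  # log-uniform |beta| range
    baseline_log10_range: tuple = (4.0, 7.0)  # raw area counts 1e4-1e7
    age_coef: float = 0.002
    bmi_coef: float = 0.005
    subject_sd: float = 0.20  # SD of the per-subject random intercept
    residual_sd: float = 0.15
    batch_sd: float = 0.10  # per-feature batch shifts (proteome only)
    runday_log10_range: tuple = (-0.2, 0.2)  # log10 of run-day scale factors
    runday_scaling: bool = True
    # missingness concentrates in a subset of features, as in LC-MS data:
    # missing_feature_fraction of the features draw a per-feature missingness
    # rate uniform on (0, missing_rate], straddling the 40% filter boundary
    missing_rate: float = 0.50
    missing_feature_fraction: float = 0.50
    missing_mode: str = "mcar"  # "mcar" or "censor" (left-censoring)
    outlier_shift_sd: float = 0.5
    outlier_feature_fraction: float = 0.05

    def __post_init__(self):
        if self.layer not in ("metabolite", "protein"):
            raise ValueError(f"unknown layer {self.layer!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.missing_mode not in ("mcar", "censor"):
            raise ValueError(f"unknown missing_mode {self.missing_mode!r}")
        if not 0.0 <= self.effect_fraction <= 1.0:
            raise ValueError("effect_fraction must lie in [0, 1]")


def metabolite_defaults(**overrides) -> LayerConfig:
    """Metabolome layer: 349 features, 19% associated, 45:20 sign split."""
    return replace(LayerConfig(), **overrides)


def protein_defaults(**overrides) -> LayerConfig:
    """Proteome layer: 437 features, 14% associated, 47:16 sign split.

    Run-day rescaling is a metabolome platform correction, so proteome
    intensities carry batch shifts instead of run-day scale factors.
    """
    base = LayerConfig(
        layer="protein",
        n_features=437,
        effect_fraction=0.14,
        positive_fraction=47 / 63,
        runday_scaling=False,
    )
    return replace(base, **overrides)


def make_design(
    n_subjects: int = 16,
    time_points=TIME_POINTS,
    n_outliers: int = 3,
    seed: int | None = None,
    age_range=(22.0, 34.0),
    bmi_range=(21.0, 30.0),
    treated_points=TREATED_POINTS,
):
    """Draw a study design plus per-subject profiles.

    Ages and BMIs are uniform over the configured ranges; ``n_outliers``
    subjects are flagged as idiosyncratic responders (the fixed exclusion set
    of the robustness stage).  The ``random_intercept`` column is a standard
    normal latent, scaled by each layer's ``subject_sd`` during feature
    simulation.

    Returns
    -------
    (StudyDesign, pandas.DataFrame)
        The design and the subject table (subject_id, age, bmi,
        random_intercept, is_outlier).
    """
    if n_subjects < 1:
        raise ValueError("invalid design: n_subjects must be >= 1")
    if n_outliers > n_subjects:
        raise ValueError("invalid design: n_outliers exceeds n_subjects")
    rng = np.random.default_rng(seed)
    tmp = StudyDesign(n_subjects=n_subjects, time_points=tuple(time_points),
                      treated_points=tuple(treated_points), seed=seed)
    ids = tmp.subject_ids
    outliers = frozenset(rng.choice(ids, size=n_outliers, replace=False)) if n_outliers else frozenset()
    design = replace(tmp, outlier_subjects=outliers)
    subjects = pd.DataFrame(
        {
            "subject_id": ids,
            "age": rng.uniform(*age_range, size=n_subjects),
            "bmi": rng.uniform(*bmi_range, size=n_subjects),
            "random_intercept": rng.standard_normal(n_subjects),
            "is_outlier": [sid in outliers for sid in ids],
        }
    ).set_index("subject_id", drop=False)
    subjects.index.name = None
    return design, subjects


def _truncated_normal(rng, mean, sd, size, lower=0.0):
    if sd == 0:
        return np.full(size, float(mean))
    a = (lower - mean) / sd
    return sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_hormones(
    design: StudyDesign,
    subjects: pd.DataFrame,
    params: dict | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    n_batches: int = 2,
    samples_per_run_day: int = 10,
) -> pd.DataFrame:
    """Draw FT4/TSH trajectories and technical annotations for every sample.

    Hormones are independent truncated normals (at zero) per subject and
    visit, parameterised by per-visit means/SDs.  Proteome batches are
    assigned by subject (consecutive blocks); run days follow acquisition
    order in chunks of ``samples_per_run_day``.

    Returns a sample table indexed by ``"<subject>:<time_point>"`` with
    columns subject_id, time_point, ft4, tsh, age, bmi, batch, run_day.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    params = HORMONE_PARAMS if params is None else params
    for tp in design.time_points:
        if tp not in params:
            raise KeyError(f"hormone parameters missing for time point {tp!r}")

    ids = list(subjects["subject_id"])
    rows = []
    for tp in design.time_points:
        ft4_mean, ft4_sd = params[tp]["ft4"]
        tsh_mean, tsh_sd = params[tp]["tsh"]
        if min(ft4_sd, tsh_sd) < 0:
            raise ValueError("hormone SDs must be non-negative")
        ft4 = _truncated_normal(rng, ft4_mean, ft4_sd, len(ids))
        tsh = _truncated_normal(rng, tsh_mean, tsh_sd, len(ids))
        for i, sid in enumerate(ids):
            rows.append((sid, tp, ft4[i], tsh[i]))
    samples = pd.DataFrame(rows, columns=["subject_id", "time_point", "ft4", "tsh"])
    samples["age"] = subjects.loc[samples["subject_id"], "age"].to_numpy()
    samples["bmi"] = subjects.loc[samples["subject_id"], "bmi"].to_numpy()

    batch_of = {
        sid: f"B{(i * n_batches) // len(ids) + 1}" for i, sid in enumerate(ids)
    }
    samples["batch"] = samples["subject_id"].map(batch_of)
    # acquisition order is randomised (as measurement campaigns do, so that
    # run day is not confounded with visit) and chunked into run days
    acquisition = rng.permutation(len(samples))
    run_day = np.empty(len(samples), dtype=object)
    run_day[acquisition] = [
        f"D{i // samples_per_run_day + 1}" for i in range(len(samples))
    ]
    samples["run_day"] = run_day
    samples.index = samples["subject_id"] + ":" + samples["time_point"]
    return samples


def simulate_features(
    design: StudyDesign,
    subjects: pd.DataFrame,
    samples: pd.DataFrame,
    config: LayerConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Simulate a raw-scale intensity matrix plus its ground-truth catalog.

    The generative model on the log10 scale is

        log10 I[s, j] = mu_j + beta_j * FT4_s + g_age * age_s + g_bmi * bmi_s
                        + b_subject(s) + batch[b(s), j] + outlier shift + eps,

    after which values are multiplied by the sample's run-day scale factor
    (metabolome platform drift) and exponentiated to the raw scale; missing
    entries are then inserted completely at random or by left-censoring each
    feature below its ``missing_rate`` quantile.

    Returns
    -------
    (pandas.DataFrame, pandas.DataFrame)
        The samples x features raw intensity matrix (NaN = missing) and the
        feature catalog (feature_id, layer, true_beta, class_tag).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    cfg = config
    n_feat = cfg.n_features
    n_samp = len(samples)
    prefix = cfg.layer[:3]
    feature_ids = [f"{prefix}_{i + 1:04d}" for i in range(n_feat)]

    # plant signed FT4 effects on a random feature subset
    true_beta = np.zeros(n_feat)
    n_effect = int(round(cfg.effect_fraction * n_feat))
    effect_idx = rng.choice(n_feat, size=n_effect, replace=False)
    n_pos = int(round(cfg.positive_fraction * n_effect))
    lo, hi = np.log10(cfg.beta_range[0]), np.log10(cfg.beta_range[1])
    magnitudes = 10.0 ** rng.uniform(lo, hi, size=n_effect)
    signs = np.concatenate([np.ones(n_pos), -np.ones(n_effect - n_pos)])
    true_beta[effect_idx] = signs * magnitudes

    mu = rng.uniform(*cfg.baseline_log10_range, size=n_feat)
    b_subject = cfg.subject_sd * subjects["random_intercept"]
    b_sample = b_subject.loc[samples["subject_id"]].to_numpy()

    log10_val = (
        mu[None, :]
        + np.outer(samples["ft4"].to_numpy(), true_beta)
        + cfg.age_coef * samples["age"].to_numpy()[:, None]
        + cfg.bmi_coef * samples["bmi"].to_numpy()[:, None]
        + b_sample[:, None]
    )

    if cfg.layer == "protein" and cfg.batch_sd > 0:
        batches = pd.unique(samples["batch"])
        shifts = {b: rng.normal(0.0, cfg.batch_sd, size=n_feat) for b in batches}
        log10_val += np.stack([shifts[b] for b in samples["batch"]])

    # idiosyncratic responders: extra shift on a designated feature subset
    n_out_feat = int(round(cfg.outlier_feature_fraction * n_feat))
    outlier_features = np.zeros(n_feat, dtype=bool)
    if design.outlier_subjects and n_out_feat and cfg.outlier_shift_sd > 0:
        out_idx = rng.choice(n_feat, size=n_out_feat, replace=False)
        outlier_features[out_idx] = True
        shift = rng.normal(0.0, cfg.outlier_shift_sd, size=n_out_feat)
        is_out = samples["subject_id"].isin(design.outlier_subjects).to_numpy()
        log10_val[np.ix_(is_out, out_idx)] += shift[None, :]

    log10_val += rng.normal(0.0, cfg.residual_sd, size=(n_samp, n_feat))
    raw = 10.0**log10_val

    if cfg.runday_scaling:
        days = pd.unique(samples["run_day"])
        scale = {d: 10.0 ** rng.uniform(*cfg.runday_log10_range) for d in days}
        raw *= samples["run_day"].map(scale).to_numpy()[:, None]

    if cfg.missing_rate > 0 and cfg.missing_feature_fraction > 0:
        n_miss_feat = int(round(cfg.missing_feature_fraction * n_feat))
        miss_idx = rng.choice(n_feat, size=n_miss_feat, replace=False)
        rates = rng.uniform(0.0, cfg.missing_rate, size=n_miss_feat)
        if cfg.missing_mode == "mcar":
            drop = rng.random(size=(n_samp, n_miss_feat)) < rates[None, :]
            block = raw[:, miss_idx]
            block[drop] = np.nan
            raw[:, miss_idx] = block
        else:  # left-censor each affected feature below its rate quantile
            block = raw[:, miss_idx]
            cut = np.array([np.quantile(block[:, j], r) for j, r in enumerate(rates)])
            block[block < cut[None, :]] = np.nan
            raw[:, miss_idx] = block

    matrix = pd.DataFrame(raw, index=samples.index, columns=feature_ids)
    # tag values avoid pandas' default NA strings ("null", "NA", ...) so the
    # catalog round-trips through TSV unchanged
    tags = np.where(true_beta > 0, "ft4_positive",
                    np.where(true_beta < 0, "ft4_negative", "no_effect"))
    catalog = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "layer": cfg.layer,
            "true_beta": true_beta,
            "class_tag": [
                t + "+outlier" if o else t for t, o in zip(tags, outlier_features)
            ],
        }
    ).set_index("feature_id", drop=False)
    catalog.index.name = None
    return matrix, catalog
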