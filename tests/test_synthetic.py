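import numpy as np
import pandas as pd
import pytest

from thyromics.association import fit_feature_model
from thyromics.preprocess import log10_transform
from thyromics.synthetic import (
    HORMONE_PARAMS,
    LayerConfig,
    make_design,
    metabolite_defaults,
    protein_defaults,
    simulate_features,
    simulate_hormones,
)


@pytest.mark.parametrize("n_subjects,expected_slots", [(16, 80), (1, 5), (3, 15)])
def test_design_sample_slots(n_subjects, expected_slots):
    design, subjects = make_design(n_subjects=n_subjects, n_outliers=0, seed=0)
    assert design.n_samples == expected_slots
    assert len(subjects) == n_subjects


def test_design_is_deterministic_given_seed():
    d1, s1 = make_design(seed=42)
    d2, s2 = make_design(seed=42)
    assert d1 == d2
    pd.testing.assert_frame_equal(s1, s2)


def test_design_rejects_invalid_sizes():
    with pytest.raises(ValueError):
        make_design(n_subjects=0)
    with pytest.raises(ValueError):
        make_design(n_subjects=2, n_outliers=3)


def test_design_profiles_within_ranges_and_outlier_count():
    design, subjects = make_design(seed=7)
    assert subjects["age"].between(22, 34).all()
    assert subjects["bmi"].between(21, 30).all()
    assert len(design.outlier_subjects) == 3
    assert subjects["is_outlier"].sum() == 3
    assert set(design.outlier_subjects) <= set(subjects["subject_id"])


def test_hormones_degenerate_sd_yields_exact_means():
    design, subjects = make_design(n_subjects=4, n_outliers=0, seed=1)
    params = {
        tp: {"ft4": (v["ft4"][0], 0.0), "tsh": (v["tsh"][0], 0.0)}
        for tp, v in HORMONE_PARAMS.items()
    }
    samples = simulate_hormones(design, subjects, params=params, seed=2)
    bas = samples.loc[samples["time_point"] == "bas", "ft4"]
    assert (bas == 13.2).all()


def test_hormone_tsh_nadir_at_week8():
    design, subjects = make_design(n_subjects=400, n_outliers=0, seed=3)
    samples = simulate_hormones(design, subjects, seed=4)
    means = samples.groupby("time_point")["tsh"].mean()
    assert means.idxmin() == "w8"
    assert (samples["ft4"] > 0).all()
    assert (samples["tsh"] >= 0).all()


def test_hormones_missing_time_point_raises():
    design, subjects = make_design(n_subjects=4, n_outliers=0, seed=1)
    params = {tp: HORMONE_PARAMS[tp] for tp in ("bas", "w4")}
    with pytest.raises(KeyError, match="w8"):
        simulate_hormones(design, subjects, params=params, seed=2)


def test_one_record_per_subject_time_point(cohort):
    _, _, samples = cohort
    assert not samples.duplicated(["subject_id", "time_point"]).any()


def test_layer_config_validation():
    with pytest.raises(ValueError):
        LayerConfig(missing_rate=1.0)
    with pytest.raises(ValueError):
        LayerConfig(layer="lipid")
    with pytest.raises(ValueError):
        LayerConfig(missing_mode="halo")


def test_features_positive_and_deterministic(cohort):
    design, subjects, samples = cohort
    cfg = metabolite_defaults(n_features=30)
    m1, c1 = simulate_features(design, subjects, samples, cfg, seed=11)
    m2, c2 = simulate_features(design, subjects, samples, cfg, seed=11)
    pd.testing.assert_frame_equal(m1, m2)
    pd.testing.assert_frame_equal(c1, c2)
    vals = m1.to_numpy()
    assert np.all(vals[~np.isnan(vals)] > 0)


def test_planted_fraction_matches_config(cohort):
    design, subjects, samples = cohort
    for cfg in (metabolite_defaults(n_features=349), protein_defaults(n_features=437)):
        _, cat = simulate_features(design, subjects, samples, cfg, seed=12)
        frac = (cat["true_beta"] != 0).mean()
        assert abs(frac - cfg.effect_fraction) < 1.0 / cfg.n_features
        n_eff = (cat["true_beta"] != 0).sum()
        n_pos = (cat["true_beta"] > 0).sum()
        assert abs(n_pos / n_eff - cfg.positive_fraction) < 1.0 / n_eff + 1e-12


def test_noiseless_feature_recovers_planted_beta(cohort):
    """With residual and subject variance at zero the fitted slope is exact."""
    design, subjects, samples = cohort
    cfg = metabolite_defaults(
        n_features=5,
        effect_fraction=0.2,
        positive_fraction=1.0,
        beta_range=(0.01, 0.01),
        residual_sd=0.0,
        subject_sd=0.0,
        missing_rate=0.0,
        runday_scaling=False,
        outlier_shift_sd=0.0,
    )
    matrix, catalog = simulate_features(design, subjects, samples, cfg, seed=13)
    planted = catalog.index[catalog["true_beta"] != 0][0]
    fit = fit_feature_model(log10_transform(matrix)[planted], samples, "metabolite")
    assert fit["converged"]
    assert fit["beta"] == pytest.approx(0.01, abs=1e-8)


def test_generator_fitter_consistency():
    """Planted beta is recovered without bias: the mean estimate over
    replicates stays within 3 Monte-Carlo SEs of the truth."""
    beta_true = 0.015
    estimates = []
    for i in range(25):
        rng = np.random.default_rng(900 + i)
        design, subjects = make_design(n_outliers=0, seed=int(rng.integers(2**31 - 1)))
        samples = simulate_hormones(design, subjects, rng=rng)
        cfg = metabolite_defaults(
            n_features=1,
            effect_fraction=1.0,
            positive_fraction=1.0,
            beta_range=(beta_true, beta_true),
            residual_sd=0.08,
            subject_sd=0.15,
            missing_rate=0.0,
            runday_scaling=False,
        )
        matrix, _ = simulate_features(design, subjects, samples, cfg, rng=rng)
        fit = fit_feature_model(log10_transform(matrix).iloc[:, 0], samples, "metabolite")
        estimates.append(fit["beta"])
    estimates = np.asarray(estimates)
    mc_se = estimates.std(ddof=1) / np.sqrt(len(estimates))
    assert abs(estimates.mean() - beta_true) < 3 * mc_se


def test_left_censoring_removes_low_values(cohort):
    design, subjects, samples = cohort
    cfg = metabolite_defaults(
        n_features=20, missing_mode="censor", missing_rate=0.4,
        missing_feature_fraction=1.0, runday_scaling=False,
    )
    matrix, _ = simulate_features(design, subjects, samples, cfg, seed=14)
    for col in matrix.columns:
        vals = matrix[col]
        if vals.isna().any() and vals.notna().any():
            assert vals.min() == vals.dropna().min()  # only low tail removed


def test_outlier_subject_shift_is_confined(cohort):
    design, subjects, samples = cohort
    cfg = metabolite_defaults(
        n_features=50, missing_rate=0.0, runday_scaling=False,
        residual_sd=0.0, subject_sd=0.0, effect_fraction=0.0,
        age_coef=0.0, bmi_coef=0.0,
        outlier_shift_sd=1.0, outlier_feature_fraction=0.1,
    )
    matrix, catalog = simulate_features(design, subjects, samples, cfg, seed=15)
    log = np.log10(matrix.to_numpy())
    is_out = samples["subject_id"].isin(design.outlier_subjects).to_numpy()
    shifted_features = catalog["class_tag"].str.endswith("+outlier").to_numpy()
    assert shifted_features.sum() == 5
    spread = log.max(axis=0) - log.min(axis=0)
    # without noise, only outlier-designated features vary across samples
    assert (spread[shifted_features] > 0).all()
    assert np.allclose(spread[~shifted_features], 0, atol=1e-9)
    # and within non-outlier subjects those features are constant
    assert np.allclose(
        log[~is_out][:, shifted_features].std(axis=0), 0, atol=1e-9
    )
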