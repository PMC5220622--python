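"""End-to-end driver: simulate -> preprocess -> associate -> robust -> foldchange -> classify.

Configuration is a nested mapping (YAML on disk) validated against the
defaults below; every unknown or ill-typed key is reported with its full key
path.  All randomness flows from the single top-level seed through named
`numpy` SeedSequence substreams, one per stage, so runs are reproducible and
individual stages can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from copy import deepcopy
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import associate_layer
from .classification import (
    CVConfig,
    complete_feature_filter,
    label_samples,
    nested_cv,
)
from .foldchange import mean_log2fc
from .io import ensure_dir, read_matrix, read_samples, write_matrix, write_samples, write_table
from .preprocess import log10_transform, missingness_filter, runday_normalize
from .robustness import make_subsets, robust_associate
from .synthetic import (
    LayerConfig,
    make_design,
    metabolite_defaults,
    protein_defaults,
    simulate_features,
    simulate_hormones,
)

__all__ = ["default_config", "load_config", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "associate", "robust", "foldchange", "classify")


def default_config() -> dict:
    """The full default configuration (also what ``thyromics defaults`` prints)."""
    met = metabolite_defaults()
    pro = protein_defaults()

    def layer_dict(cfg: LayerConfig) -> dict:
        d = {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}
        d.pop("layer")
        d["beta_range"] = list(d["beta_range"])
        d["baseline_log10_range"] = list(d["baseline_log10_range"])
        d["runday_log10_range"] = list(d["runday_log10_range"])
        return d

    return {
        "seed": 0,
        "design": {
            "n_subjects": 16,
            "n_outliers": 3,
            "time_points": ["bas", "w4", "w8", "w12", "w16"],
        },
        "layers": {"metabolite": layer_dict(met), "protein": layer_dict(pro)},
        "preprocess": {
            "threshold": 0.40,
            # run-day rescaling is a metabolome platform correction by default
            "runday_normalize": {"metabolite": True, "protein": False},
        },
        "association": {"reml": True, "df_method": "within"},
        "robustness": {"n_random": 100, "min_converged_frac": 0.8},
        "classification": {
            "n_outer": 30,
            "n_inner": 50,
            "panel_size": 15,
            "n_trees": 500,
            "outer_valid_frac": 1 / 3,
            "inner_test_frac": 1 / 3,
            "subject_aware": False,
        },
    }


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = deepcopy(base)
    for key, value in override.items():
        where = f"{path}.{key}" if path else str(key)
        if key not in base:
            raise ValueError(f"config: unknown key {where!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"config: {where!r} must be a mapping")
            out[key] = _merge(base[key], value, where)
        else:
            out[key] = value
    return out


def validate_config(config: dict) -> dict:
    """Merge a (partial) user config onto the defaults and sanity-check it."""
    cfg = _merge(default_config(), config or {})
    checks = [
        ("seed", cfg["seed"], lambda v: isinstance(v, int), "an integer"),
        ("design.n_subjects", cfg["design"]["n_subjects"],
         lambda v: isinstance(v, int) and v >= 1, "a positive integer"),
        ("design.n_outliers", cfg["design"]["n_outliers"],
         lambda v: isinstance(v, int) and 0 <= v <= cfg["design"]["n_subjects"],
         "an integer within [0, n_subjects]"),
        ("preprocess.threshold", cfg["preprocess"]["threshold"],
         lambda v: 0 < v <= 1, "in (0, 1]"),
        ("robustness.n_random", cfg["robustness"]["n_random"],
         lambda v: isinstance(v, int) and v >= 0, "a non-negative integer"),
        ("classification.panel_size", cfg["classification"]["panel_size"],
         lambda v: isinstance(v, int) and v >= 1, "a positive integer"),
    ]
    for where, value, ok, expect in checks:
        if not ok(value):
            raise ValueError(f"config: {where} = {value!r}, expected {expect}")
    for layer, ld in cfg["layers"].items():
        if not 0 <= ld["missing_rate"] < 1:
            raise ValueError(f"config: layers.{layer}.missing_rate must lie in [0, 1)")
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return validate_config(raw)


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _substreams(seed: int, layer_names) -> dict:
    names = ["design", "hormones", "robust", "classify"] + [
        f"features:{name}" for name in sorted(layer_names)
    ]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return dict(zip(names, children))


def _layer_config(name: str, overrides: dict) -> LayerConfig:
    d = dict(overrides)
    for key in ("beta_range", "baseline_log10_range", "runday_log10_range"):
        d[key] = tuple(d[key])
    base = metabolite_defaults if name == "metabolite" else protein_defaults
    d["n_features"] = int(d["n_features"])
    return base(**{k: v for k, v in d.items() if k != "layer"}) if name in (
        "metabolite", "protein") else LayerConfig(layer=name, **d)


def run_pipeline(config: dict, outdir, resume: bool = False) -> dict:
    """Execute all stages, writing TSV outputs and a run manifest.

    With ``resume=True`` a stage whose outputs already exist is skipped.
    Returns the manifest (also written to ``manifest.json``).
    """
    cfg = validate_config(config)
    outdir = ensure_dir(outdir)
    layers = list(cfg["layers"])
    streams = _substreams(cfg["seed"], layers)
    manifest = {
        "package": "thyromics",
        "version": __version__,
        "config_hash": config_hash(cfg),
        "seed": cfg["seed"],
        "versions": _versions(),
        "stages": {},
    }

    def outputs_exist(files):
        return all((outdir / f).exists() for f in files)

    def record(stage, files, **counts):
        manifest["stages"][stage] = {"outputs": sorted(files), **counts}

    # ------------------------------------------------------------------ simulate
    sim_files = ["samples.tsv", "truth.tsv"] + [f"{l}_intensities.tsv" for l in layers]
    if resume and outputs_exist(sim_files):
        logger.info("simulate: outputs present, skipping")
        samples = read_samples(outdir / "samples.tsv")
        matrices = {l: read_matrix(outdir / f"{l}_intensities.tsv") for l in layers}
        design, _ = make_design(
            n_subjects=cfg["design"]["n_subjects"],
            time_points=tuple(cfg["design"]["time_points"]),
            n_outliers=cfg["design"]["n_outliers"],
            seed=_seed_of(streams["design"]),
        )
    else:
        design, subjects = make_design(
            n_subjects=cfg["design"]["n_subjects"],
            time_points=tuple(cfg["design"]["time_points"]),
            n_outliers=cfg["design"]["n_outliers"],
            seed=_seed_of(streams["design"]),
        )
        samples = simulate_hormones(
            design, subjects, rng=np.random.default_rng(streams["hormones"])
        )
        matrices, catalogs = {}, []
        for layer in layers:
            lcfg = _layer_config(layer, cfg["layers"][layer])
            mat, cat = simulate_features(
                design, subjects, samples, lcfg,
                rng=np.random.default_rng(streams[f"features:{layer}"]),
            )
            matrices[layer] = mat
            catalogs.append(cat)
            write_matrix(mat, outdir / f"{layer}_intensities.tsv")
        write_samples(samples, outdir / "samples.tsv")
        write_table(pd.concat(catalogs, ignore_index=True), outdir / "truth.tsv")
    record("simulate", sim_files, n_samples=len(samples),
           n_features={l: matrices[l].shape[1] for l in layers})

    # ---------------------------------------------------------------- preprocess
    normalized, logged = {}, {}
    pre_files = [f"{l}_{kind}.tsv" for l in layers for kind in ("normalized", "log10")]
    for layer in layers:
        mat = matrices[layer]
        if cfg["preprocess"]["runday_normalize"].get(layer, False):
            mat = runday_normalize(mat, samples["run_day"])
        mat, kept = missingness_filter(mat, cfg["preprocess"]["threshold"])
        normalized[layer] = mat
        logged[layer] = log10_transform(mat)
        write_matrix(mat, outdir / f"{layer}_normalized.tsv")
        write_matrix(logged[layer], outdir / f"{layer}_log10.tsv")
    record("preprocess", pre_files,
           n_kept={l: normalized[l].shape[1] for l in layers})

    # ----------------------------------------------------------------- associate
    assoc_files = [f"associations_{l}.tsv" for l in layers]
    assoc = {}
    for layer in layers:
        assoc[layer] = associate_layer(
            logged[layer], samples, layer, **cfg["association"]
        )
        write_table(assoc[layer], outdir / f"associations_{layer}.tsv")
    record("associate", assoc_files,
           n_significant={l: int((assoc[l]["q"] < 0.05).sum()) for l in layers})

    # -------------------------------------------------------------------- robust
    robust_files = [f"robust_{l}.tsv" for l in layers]
    fixed = tuple(sorted(design.outlier_subjects)) if len(design.outlier_subjects) == 3 else None
    plan = make_subsets(
        [s for s in samples["subject_id"].unique()],
        n_random=cfg["robustness"]["n_random"],
        fixed_exclusion=fixed,
        rng=np.random.default_rng(streams["robust"]),
    )
    logger.info("robust stage: %d subsets", len(plan))
    robust = {}
    for layer in layers:
        robust[layer] = robust_associate(
            logged[layer], samples, plan, layer,
            min_converged_frac=cfg["robustness"]["min_converged_frac"],
            **cfg["association"],
        )
        write_table(robust[layer], outdir / f"robust_{layer}.tsv")
    record("robust", robust_files, n_subsets=len(plan),
           n_significant={l: int(robust[l]["significant"].sum()) for l in layers})

    # ---------------------------------------------------------------- foldchange
    fc_files = []
    for layer in layers:
        fc = mean_log2fc(normalized[layer], samples)
        fc.log2fc.insert(0, "feature_id", fc.log2fc.index)
        fc.counts.insert(0, "feature_id", fc.counts.index)
        write_table(fc.log2fc, outdir / f"foldchange_{layer}.tsv")
        write_table(fc.counts, outdir / f"counts_{layer}.tsv")
        fc_files += [f"foldchange_{layer}.tsv", f"counts_{layer}.tsv"]
    record("foldchange", fc_files)

    # ------------------------------------------------------------------ classify
    cls_files = ["panel.tsv", "auc_summary.tsv", "roc_points.tsv"]
    combined = pd.concat([logged[l] for l in layers], axis=1)
    labeled = label_samples(samples)
    kept = complete_feature_filter(combined, labeled)
    cv_cfg = CVConfig(seed=_seed_of(streams["classify"]), **cfg["classification"])
    cv = nested_cv(combined[kept], labeled, cv_cfg)
    write_table(cv.panel_table(), outdir / "panel.tsv")
    auc_rows = pd.DataFrame(
        {"loop": np.arange(1, len(cv.outer) + 1), "auc": cv.outer_aucs}
    )
    auc_rows.loc[len(auc_rows)] = ["mean", cv.mean_auc]
    write_table(auc_rows, outdir / "auc_summary.tsv")
    roc_rows = pd.concat(
        [
            pd.DataFrame({"loop": i + 1, "fpr": o.fpr, "tpr": o.tpr})
            for i, o in enumerate(cv.outer)
        ],
        ignore_index=True,
    )
    write_table(roc_rows, outdir / "roc_points.tsv")
    record("classify", cls_files, n_labeled=len(labeled),
           n_complete_features=len(kept), mean_auc=round(cv.mean_auc, 4),
           panel=cv.panel)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


def _versions() -> dict:
    import sklearn
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _seed_of(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1)[0] % (2**31 - 1))
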