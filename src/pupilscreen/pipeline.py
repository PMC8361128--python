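"""End-to-end pipeline driver and YAML configuration handling.

One config dict (YAML on disk) drives simulate -> preprocess -> features
-> rank -> evaluate -> plot. Every study constant — the 16 ms reduction
window, the 80% missingness exclusion, the 5000 ms probe, k = 9 features
per fold, 10 outer folds, 40 repetitions — is a config default, never
hard-coded in the stages. Identical config + seed gives identical
artifacts.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import yaml

from . import __version__
from .custom_features import ProbeTiming
from .errors import SchemaError
from .evaluation import ClassifierSpec, nested_cv
from .general_features import build_feature_matrix, default_feature_specs
from .preprocess import preprocess_cohort
from .stats import RankMethod, rank_features, select_top_k
from .synthetic import GeneratorConfig, generate_cohort
from .trial_io import read_trials, write_feature_matrix, write_trials
from . import viz

__all__ = ["default_config", "load_config", "validate_config",
           "run_pipeline"]

logger = logging.getLogger(__name__)


def default_config() -> dict:
    return {
        "seed": 0,
        "io": {"trials_csv": None, "dialect": None},
        "simulate": {
            "enabled": True,
            "effect": "strong",
            "n_adhd": 28,
            "n_ctrl": 22,
            "trials_per_subject": 8,
            "duration_ms": 8000,
            "sampling_hz": 1000,
            "probe_ms": 5000,
        },
        "preprocess": {"max_missing_fraction": 0.8, "window_ms": 16},
        "features": {
            "probe_ms": 5000,
            "trial_end_ms": 8000,
            "item19_interpretation": "literal",
            "general": {
                "fft_k": 2, "ql": 0.4, "qh": 0.8,
                "apen_m": 2, "apen_r_factor": 0.2, "peaks_n": 10,
            },
        },
        "stats": {"adjust": "none", "radviz_top_n": 15},
        "evaluation": {
            "classifiers": ["svm"],
            "outer_folds": 10,
            "inner_folds": 5,
            "k_select": 9,
            "repetitions": 40,
            "ci_mode": "sem",
        },
        "plot": {"enabled": True},
    }


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    cfg = copy.deepcopy(default_config())
    for section, value in user.items():
        if section not in cfg:
            raise SchemaError(f"unknown config section {section!r}")
        if isinstance(cfg[section], dict):
            if not isinstance(value, dict):
                raise SchemaError(f"config section {section!r} must be a map")
            for key, v in value.items():
                if key not in cfg[section]:
                    raise SchemaError(
                        f"unknown config key {section}.{key}"
                    )
                if isinstance(cfg[section][key], dict) and isinstance(
                    v, dict
                ):
                    for k2, v2 in v.items():
                        if k2 not in cfg[section][key]:
                            raise SchemaError(
                                f"unknown config key {section}.{key}.{k2}"
                            )
                        cfg[section][key][k2] = v2
                else:
                    cfg[section][key] = v
        else:
            cfg[section] = value
    return cfg


#: Number of features in the default registry (22 custom + 12 general).
_N_DEFAULT_FEATURES = 34


def validate_config(cfg: dict) -> None:
    """Fail fast on config mistakes, before any compute."""
    ev = cfg["evaluation"]
    if ev["k_select"] > _N_DEFAULT_FEATURES:
        raise SchemaError(
            f"evaluation.k_select={ev['k_select']} exceeds the "
            f"{_N_DEFAULT_FEATURES} features of the default registry"
        )
    if not ev["classifiers"]:
        raise SchemaError("evaluation.classifiers must be non-empty")
    if not cfg["simulate"]["enabled"] and not cfg["io"]["trials_csv"]:
        raise SchemaError(
            "either simulate.enabled or io.trials_csv is required"
        )
    sim = cfg["simulate"]
    if sim["enabled"] and not 0 < sim["probe_ms"] < sim["duration_ms"]:
        raise SchemaError("simulate.probe_ms must lie inside the trial")


def run_pipeline(cfg: dict, out_dir, seed: int | None = None) -> Path:
    """Run the full pipeline; returns the artifact directory.

    Writes feature_matrix.csv, ranked_features.csv, one
    evaluation_report_<classifier>.json and roc_<classifier>.csv per
    classifier, figures/ and a run manifest. ``seed`` overrides the
    config seed.
    """
    validate_config(cfg)
    if seed is not None:
        cfg = {**copy.deepcopy(cfg), "seed": int(seed)}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()

    # --- input ---
    if cfg["simulate"]["enabled"]:
        sim = cfg["simulate"]
        gen_cfg = GeneratorConfig(
            n_adhd=sim["n_adhd"], n_ctrl=sim["n_ctrl"],
            trials_per_subject=sim["trials_per_subject"],
            duration_ms=sim["duration_ms"],
            sampling_hz=sim["sampling_hz"],
            probe_ms=sim["probe_ms"], effect=sim["effect"],
            seed=cfg["seed"],
        )
        cohort, truth = generate_cohort(gen_cfg)
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(asdict(truth), fh, indent=2)
    else:
        cohort = read_trials(cfg["io"]["trials_csv"],
                             cfg["io"]["dialect"])
    logger.info("input: %d subjects, %d trials", len(cohort),
                cohort.n_trials)

    # --- preprocess ---
    pp = cfg["preprocess"]
    clean, dropped = preprocess_cohort(
        cohort, pp["max_missing_fraction"], pp["window_ms"]
    )
    n_dropped = sum(len(v) for v in dropped.values())
    logger.info("preprocess: excluded %d trials", n_dropped)

    # --- features ---
    fe = cfg["features"]
    timing = ProbeTiming(fe["probe_ms"], fe["trial_end_ms"])
    specs = default_feature_specs(timing, **fe["general"])
    fm = build_feature_matrix(clean, specs, timing)
    write_feature_matrix(fm, out / "feature_matrix.csv")
    logger.info("features: %d x %d matrix", fm.n_subjects,
                len(fm.feature_names))

    # --- rank ---
    ranked = rank_features(fm, RankMethod.MANN_WHITNEY,
                           adjust=cfg["stats"]["adjust"])
    with open(out / "ranked_features.csv", "w") as fh:
        fh.write("feature,statistic,p_value\n")
        for name, stat, p in ranked.entries:
            fh.write(f"{name},{stat:.17g},{p:.17g}\n")

    # --- evaluate ---
    ev = cfg["evaluation"]
    reports = []
    for clf in ev["classifiers"]:
        spec = ClassifierSpec(name=clf, inner_folds=ev["inner_folds"])
        report = nested_cv(
            fm, spec,
            outer_folds=ev["outer_folds"], k_select=ev["k_select"],
            repetitions=ev["repetitions"], seed=cfg["seed"],
            ci_mode=ev["ci_mode"],
        )
        report.to_json(out / f"evaluation_report_{clf}.json")
        pts = report.roc_points[0]
        with open(out / f"roc_{clf}.csv", "w") as fh:
            fh.write("fpr,tpr\n")
            for fpr, tpr in pts:
                fh.write(f"{fpr:.17g},{tpr:.17g}\n")
        reports.append(report)
        agg = report.aggregate
        logger.info(
            "evaluate %s: AUROC %.3f (+/- %.3f)", clf,
            agg["auroc"]["mean"], agg["auroc"]["half_width"],
        )

    # --- figures ---
    if cfg["plot"]["enabled"]:
        figdir = out / "figures"
        figdir.mkdir(exist_ok=True)
        for kind in ("size", "velocity", "acceleration"):
            viz.group_mean_lineplot(
                clean, figdir / f"group_mean_{kind}.png", kind,
                probe_ms=fe["probe_ms"],
            )
        viz.feature_distribution_plot(
            fm, "size_std", figdir / "size_std_box.png", "box")
        viz.feature_distribution_plot(
            fm, "size_std", figdir / "size_std_violin.png", "violin")
        top = select_top_k(
            ranked, min(cfg["stats"]["radviz_top_n"],
                        len(ranked.entries)))
        try:
            viz.radviz_plot(fm, figdir / "radviz_top.png", top)
        except Exception as exc:  # constant feature in a tiny run
            logger.warning("radviz skipped: %s", exc)
        viz.roc_plot(reports, figdir / "roc.png")

    logger.info("pipeline done in %.1f s", time.perf_counter() - t_start)
    # manifest excludes wall time so identical config+seed runs are
    # byte-identical
    manifest = {
        "package_version": __version__,
        "seed": cfg["seed"],
        "config": cfg,
        "n_subjects": fm.n_subjects,
        "n_features": len(fm.feature_names),
        "trials_excluded": n_dropped,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def write_simulated_trials(cfg: GeneratorConfig, trials_path,
                           truth_path=None):
    """Generate a cohort and write it (and optionally its ground truth)."""
    cohort, truth = generate_cohort(cfg)
    write_trials(cohort, trials_path)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(asdict(truth), fh, indent=2)
    return cohort, truth
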