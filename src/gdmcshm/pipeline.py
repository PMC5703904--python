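"""End-to-end experiment orchestration.

``run_experiment`` reproduces the canonical study design on synthetic
cohorts: simulate -> preprocess -> stratified 90/10 split -> k-fold
cross-validation of the five baselines and the symmetric-cost ensemble on
the training part -> a cost sweep over lambda1 -> held-out test evaluation
-> significance comparisons (DTPR with one-sample t-tests, and DeLong's
correlated-AUC test).  Everything is reproducible from the config plus one
global seed, fanned out deterministically to per-stage seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import preprocess as pp
from .cshm import CostSpec, predict_ensemble, train_cshm
from .evaluation import accuracy, auc, confidence_report, confusion_matrix, crossval_evaluate, fpr, roc_curve, tpr
from .learners import LearnerConfig, train_learner, predict
from .significance import delong_test, dtpr, one_sample_t
from .synthetic_cohort import CohortConfig, default_feature_catalog, generate_cohort

__all__ = ["ExperimentConfig", "validate_config", "run_experiment", "default_config"]

log = logging.getLogger(__name__)

BASELINE_KINDS = ("LR", "NB", "NN", "SVM", "CHAID")

_DEFAULTS: dict = {
    "seed": 0,
    "cohort": {"n_subjects": 4378, "target_prevalence": 0.14},
    "preprocess": {
        "feature_threshold": 0.5,
        "subject_threshold": 0.5,
        "n_bins": 3,
        "m": 5,
        "k_donors": 5,
        "pooling": "median_mode",
    },
    "split": {"train_fraction": 0.9, "stratified": True},
    "cv_k": 10,
    "run_cv": True,
    "learners": {kind: {} for kind in BASELINE_KINDS},
    "cshm": {
        "lambda1": [1.0, 1.5, 5.0, 10.0, 100.0, 1000.0],
        "lambda2": 1.0,
        "rule": "confidence_weighted",
        "discard_auc": 0.6,
        "base_kinds": ["LR", "SVM", "CHAID"],
    },
    "out_dir": None,
}


@dataclasses.dataclass(frozen=True)
class ExperimentConfig:
    """Validated, fully defaulted experiment settings."""

    raw: dict

    def __getitem__(self, key):
        return self.raw[key]

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.raw, sort_keys=True).encode()).hexdigest()[:16]


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        if key in user:
            uval = user[key]
            if isinstance(dval, dict) and key != "learners":
                if not isinstance(uval, dict):
                    raise ValueError(f"config key {path + key!r} must be a mapping")
                out[key] = _merge(dval, uval, path + key + ".")
            else:
                out[key] = uval
        else:
            out[key] = dval
    unknown = set(user) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(path + k for k in unknown)}")
    return out


def default_config(**overrides) -> ExperimentConfig:
    return validate_config_dict(overrides)


def validate_config_dict(user: dict) -> ExperimentConfig:
    cfg = _merge(_DEFAULTS, user)
    lam = cfg["cshm"]["lambda1"]
    if not isinstance(lam, (list, tuple)) or not lam:
        raise ValueError("cshm.lambda1 must be a non-empty list")
    if any(v <= 0 for v in lam):
        raise ValueError("cshm.lambda1 entries must be positive")
    if cfg["cshm"]["lambda2"] <= 0:
        raise ValueError("cshm.lambda2 must be positive")
    if not 0 < cfg["split"]["train_fraction"] < 1:
        raise ValueError("split.train_fraction must lie in (0, 1)")
    if cfg["cohort"]["n_subjects"] < 2:
        raise ValueError("cohort.n_subjects must be >= 2")
    if not 0 < cfg["cohort"]["target_prevalence"] < 1:
        raise ValueError("cohort.target_prevalence must lie in (0, 1)")
    return ExperimentConfig(raw=cfg)


def validate_config(path: str | Path) -> ExperimentConfig:
    """Load a YAML config file, apply defaults, reject unknown keys."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError("config file must contain a mapping")
    return validate_config_dict(user)


def _stage_seeds(global_seed: int, names: list[str]) -> dict[str, int]:
    """Deterministic per-stage seeds below 2**31 from one global seed."""
    seeds = {}
    for i, name in enumerate(names):
        h = hashlib.sha256(f"{global_seed}:{i}:{name}".encode()).digest()
        seeds[name] = int.from_bytes(h[:4], "big") % (2**31)
    return seeds


def _metrics(pred, truth) -> dict:
    cm = confusion_matrix(pred.labels, truth)
    try:
        a = auc(roc_curve(pred.scores, truth))
    except ValueError:
        a = None
    rep = confidence_report(pred.confidences, pred.labels == truth)
    return {
        "accuracy": accuracy(cm),
        "auc": a,
        "tpr": tpr(cm),
        "fpr": fpr(cm),
        "mean_correct": rep.mean_correct,
        "mean_incorrect": rep.mean_incorrect,
        "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
    }


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full study design; returns the (JSON-serialisable) report."""
    t0 = time.time()
    cfg = config.raw
    seeds = _stage_seeds(
        cfg["seed"], ["cohort", "impute", "split", "cv", "learner", "cshm"]
    )

    # --- simulate ---------------------------------------------------------
    cohort = generate_cohort(
        CohortConfig(
            n_subjects=cfg["cohort"]["n_subjects"],
            features=default_feature_catalog(),
            target_prevalence=cfg["cohort"]["target_prevalence"],
            seed=seeds["cohort"],
        )
    )
    log.info("simulated cohort: %d x %d", cohort.n_subjects, cohort.n_features)

    # --- preprocess -------------------------------------------------------
    pcfg = cfg["preprocess"]
    table, filter_report = pp.filter_by_missingness(
        cohort, pcfg["feature_threshold"], pcfg["subject_threshold"]
    )
    table, _cuts = pp.discretize_continuous(table, pcfg["n_bins"])
    table, _mm = pp.min_max_normalize(table)
    imputations = pp.impute_pmm(table, pcfg["k_donors"], pcfg["m"], seeds["impute"])
    table = pp.pool_imputations(imputations, pcfg["pooling"])
    log.info("preprocessed: %d x %d complete", table.n_subjects, table.n_features)

    # --- split ------------------------------------------------------------
    split = pp.SplitSpec(
        train_fraction=cfg["split"]["train_fraction"],
        stratified=cfg["split"]["stratified"],
        seed=seeds["split"],
    )
    train, test = pp.split_train_test(table, split)
    log.info("split: %d train / %d test", train.n_subjects, test.n_subjects)

    lam_list = [float(v) for v in cfg["cshm"]["lambda1"]]
    lam2 = float(cfg["cshm"]["lambda2"])
    ccfg = cfg["cshm"]

    def cshm_trainer(lam1):
        def fit(tbl):
            return train_cshm(
                tbl,
                CostSpec(lambda1=lam1, lambda2=lam2),
                base_kinds=tuple(ccfg["base_kinds"]),
                rule=ccfg["rule"],
                seed=seeds["cshm"],
                discard_auc=ccfg["discard_auc"],
            )
        return fit

    report: dict = {
        "provenance": {
            "config_digest": config.digest(),
            "seed": cfg["seed"],
            "stage_seeds": seeds,
        },
        "filter": {
            "dropped_features": filter_report.dropped_features,
            "n_dropped_subjects": len(filter_report.dropped_subjects),
        },
        "split": {"n_train": train.n_subjects, "n_test": test.n_subjects},
        "models": {},
        "significance": [],
    }

    # --- cross-validation of baselines + symmetric-cost ensemble ----------
    if cfg["run_cv"]:
        for kind in BASELINE_KINDS:
            lcfg = LearnerConfig(kind=kind, seed=seeds["learner"], settings=cfg["learners"].get(kind, {}))
            cv = crossval_evaluate(
                train, lambda tbl, _c=lcfg: train_learner(tbl, _c), k=cfg["cv_k"], seed=seeds["cv"]
            )
            report["models"].setdefault(kind, {})["cv"] = cv["summary"]
            log.info("CV done: %s", kind)
        cv = crossval_evaluate(train, cshm_trainer(1.0) if 1.0 in lam_list else cshm_trainer(lam_list[0]),
                               k=cfg["cv_k"], seed=seeds["cv"])
        report["models"].setdefault("CSHM(1)", {})["cv"] = cv["summary"]
        log.info("CV done: CSHM")

    # --- fit on full training set, evaluate on test ------------------------
    test_preds: dict[str, object] = {}
    for kind in BASELINE_KINDS:
        lcfg = LearnerConfig(kind=kind, seed=seeds["learner"], settings=cfg["learners"].get(kind, {}))
        model = train_learner(train, lcfg)
        pred_tr, pred_te = predict(model, train), predict(model, test)
        test_preds[kind] = pred_te
        report["models"].setdefault(kind, {})["train"] = _metrics(pred_tr, train.labels)
        report["models"][kind]["test"] = _metrics(pred_te, test.labels)
        log.info("test eval done: %s", kind)

    for lam1 in lam_list:
        name = f"CSHM({lam1:g})"
        ens = train_cshm(
            train,
            CostSpec(lambda1=lam1, lambda2=lam2),
            base_kinds=tuple(ccfg["base_kinds"]),
            rule=ccfg["rule"],
            seed=seeds["cshm"],
            discard_auc=ccfg["discard_auc"],
        )

        pred_tr, pred_te = predict_ensemble(ens, train), predict_ensemble(ens, test)
        test_preds[name] = pred_te
        entry = report["models"].setdefault(name, {})
        entry["train"] = _metrics(pred_tr, train.labels)
        entry["test"] = _metrics(pred_te, test.labels)
        entry["kept_bases"] = [k for k, kept in zip(ccfg["base_kinds"], ens.kept_mask) if kept]
        entry["validation_aucs"] = ens.validation_aucs
        log.info("test eval done: %s", name)

    # --- significance comparisons ------------------------------------------
    comparisons: list[tuple[str, str]] = []
    if "CSHM(1)" in test_preds:
        for other in ("LR", "NN", "SVM"):
            comparisons.append(("CSHM(1)", other))
    if "CSHM(100)" in test_preds:
        for other in ("CSHM(1)", "CSHM(5)", "CSHM(10)", "CSHM(1000)"):
            if other in test_preds:
                comparisons.append(("CSHM(100)", other))
    for name1, name2 in comparisons:
        p1, p2 = test_preds[name1], test_preds[name2]
        roc1 = roc_curve(p1.scores, test.labels)
        roc2 = roc_curve(p2.scores, test.labels)
        series = dtpr(roc1, roc2)
        entry = {
            "comparison": f"{name1}-{name2}",
            "n_thresholds": int(series.fpr_grid.size),
            "dtpr_mean": float(series.differences.mean()),
        }
        try:
            t_res = one_sample_t(series.differences)
            entry["t_test"] = {
                "t": t_res.t, "df": t_res.df, "p": _fmt_p(t_res.p_two_sided),
                "ci": [t_res.ci_low, t_res.ci_high], "mean": t_res.mean, "sd": t_res.sd,
            }
        except ValueError:
            entry["t_test"] = None
        d = delong_test(p1.scores, p2.scores, test.labels)
        entry["delong"] = {
            "auc1": d.auc1, "auc2": d.auc2, "statistic": d.statistic,
            "p": _fmt_p(d.p_two_sided),
        }
        report["significance"].append(entry)

    report["runtime_seconds"] = round(time.time() - t0, 2)
    if cfg["out_dir"]:
        out = Path(cfg["out_dir"])
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _fmt_p(p: float):
    """p-values below representable precision as strings, not zeros."""
    return "<1e-300" if p < 1e-300 else p
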