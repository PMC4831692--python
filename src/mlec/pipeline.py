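"""Cross-validation orchestration, EC label encoding, and experiment runs.

The evaluation protocol is k-fold cross-validation (default 5 folds) with
predictions pooled across folds into a single confusion table before the
metric suite is applied — the convention of the WEKA/MULAN evaluation
framework. Fold assignment depends only on (n, folds, seed, stratify),
never on feature values, so reports are bit-reproducible for a fixed seed.

EC label encoding maps Enzyme Commission number strings to the six
top-level classes: label j is set when some annotated EC number's first
digit is j. Multifunctional enzymes (two or more EC numbers) yield
multi-label rows.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from mlec.dataset import MultiLabelDataset
from mlec.ensemble import combine_predictions
from mlec.knn import (
    BRkNN,
    IB1Classifier,
    IBLRClassifier,
    MLkNN,
    PredictionResult,
)
from mlec.metrics import EvaluationReport, evaluate_predictions

logger = logging.getLogger(__name__)

#: The six EC top-level classes, in class-number order.
EC_CLASS_NAMES = (
    "oxidoreductases",
    "transferases",
    "hydrolases",
    "lyases",
    "isomerases",
    "ligases",
)

_CLASSIFIERS = {
    "mlknn": MLkNN,
    "brknn": BRkNN,
    "iblr": IBLRClassifier,
    "ib1": IB1Classifier,
}


def make_classifier(name: str, k: int = 10):
    """Instantiate a classifier by name: mlknn, brknn, iblr, or ib1."""
    if name not in _CLASSIFIERS:
        raise ValueError(f"unknown classifier {name!r}; choose from {sorted(_CLASSIFIERS)}")
    if name == "ib1":
        return IB1Classifier(k=1)
    return _CLASSIFIERS[name](k=k)


@dataclass
class CVConfig:
    folds: int = 5
    seed: int = 0
    stratify: bool = False
    classifier: str = "mlknn"
    k: int = 10
    ensemble_rule: str | None = None  # fuse all classifiers when set
    ensemble_K: int = 3

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def ec_labels_from_annotation(annotations) -> tuple[list[str], np.ndarray]:
    """Encode id → EC-number-string annotations as an n×6 binary matrix.

    ``annotations`` is a mapping or iterable of (id, ec_string) where the
    string holds one or more EC numbers ("1.1.1.1; 3.5.2.6", ';' or ','
    separated). Label j is set when some EC number's first digit is j;
    duplicates collapse. First digits outside 1..6 are rejected — the
    six-class scheme predates EC class 7 (translocases).
    """
    items = annotations.items() if hasattr(annotations, "items") else annotations
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for sid, ec_string in items:
        row = np.zeros(6, dtype=int)
        for token in str(ec_string).replace(",", ";").split(";"):
            token = token.strip()
            if not token:
                continue
            first = token.split(".")[0]
            if not first.isdigit() or not 1 <= int(first) <= 6:
                raise ValueError(
                    f"ID {sid!r}: EC number {token!r} has top-level class outside 1-6"
                )
            row[int(first) - 1] = 1
        ids.append(str(sid))
        rows.append(row)
    return ids, np.array(rows, dtype=int)


def _fold_indices(n: int, cfg: CVConfig, Y: np.ndarray):
    if cfg.folds > n:
        raise ValueError(f"folds={cfg.folds} exceeds n={n}")
    if cfg.stratify:
        # label-powerset stratification: one stratum per distinct label set
        powerset = np.array(["".join(map(str, row)) for row in Y])
        splitter = StratifiedKFold(
            n_splits=cfg.folds, shuffle=True, random_state=cfg.seed
        )
        return list(splitter.split(np.zeros(n), powerset))
    splitter = KFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    return list(splitter.split(np.zeros(n)))


def cross_validate(
    dataset: MultiLabelDataset, cfg: CVConfig
) -> tuple[EvaluationReport, list[EvaluationReport], PredictionResult]:
    """K-fold CV with pooled out-of-fold predictions.

    Returns the pooled report, the per-fold reports, and the pooled
    PredictionResult (row order = dataset order).
    """
    n, m = dataset.Y.shape
    folds = _fold_indices(n, cfg, dataset.Y)
    pooled_scores = np.full((n, m), np.nan)
    pooled_bip = np.zeros((n, m), dtype=int)
    fold_reports = []
    for fold_no, (train_idx, test_idx) in enumerate(folds):
        try:
            if cfg.ensemble_rule:
                members = [
                    make_classifier(name, k=cfg.k).fit(dataset.subset(train_idx))
                    for name in ("mlknn", "brknn", "iblr")
                ]
                results = [c.predict(dataset.X[test_idx]) for c in members]
                pred = combine_predictions(
                    results, rule=cfg.ensemble_rule, K=cfg.ensemble_K
                )
            else:
                clf = make_classifier(cfg.classifier, k=cfg.k)
                clf.fit(dataset.subset(train_idx))
                pred = clf.predict(dataset.X[test_idx])
        except Exception as exc:
            raise RuntimeError(f"classifier failed on fold {fold_no}: {exc}") from exc
        pooled_scores[test_idx] = pred.scores
        pooled_bip[test_idx] = pred.bipartition
        fold_reports.append(
            evaluate_predictions(dataset.Y[test_idx], pred, dataset.label_names)
        )
    assert not np.isnan(pooled_scores).any(), "folds did not cover all samples"
    pooled = PredictionResult(scores=pooled_scores, bipartition=pooled_bip)
    report = evaluate_predictions(dataset.Y, pooled, dataset.label_names)
    return report, fold_reports, pooled


# ---------------------------------------------------------------------------
# Config-driven experiment runs


def _parse_config(path) -> dict[str, str]:
    """Flat key=value config; '#' starts a comment."""
    cfg: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line without '=': {line!r}")
        key, value = line.split("=", 1)
        cfg[key.strip()] = value.strip()
    return cfg


def run_experiment(config_path, out_dir=None) -> dict:
    """Run a config-driven CV experiment and write a reproducible manifest.

    Recognized keys: features, labels (CSV paths), lag, classifiers
    (comma-separated), k, folds, seed, stratify, ensemble_rule, ensemble_K,
    out_dir. Outputs: one report JSON per classifier, an optional ensemble
    report, and manifest.json recording the full configuration and a hash.
    """
    from mlec.pssm import load_dataset

    cfg = _parse_config(config_path)
    for key in ("features", "labels"):
        if key not in cfg:
            raise ValueError(f"config missing required key {key!r}")
        if not Path(cfg[key]).exists():
            raise FileNotFoundError(f"{key} file not found: {cfg[key]}")
    out = Path(out_dir or cfg.get("out_dir", "mlec_run"))
    out.mkdir(parents=True, exist_ok=True)

    dataset = load_dataset(cfg["features"], cfg["labels"])
    classifiers = [c.strip() for c in cfg.get("classifiers", "mlknn").split(",")]
    k = int(cfg.get("k", 10))
    folds = int(cfg.get("folds", 5))
    seed = int(cfg.get("seed", 0))
    stratify = cfg.get("stratify", "false").lower() == "true"
    rule = cfg.get("ensemble_rule") or None
    K = int(cfg.get("ensemble_K", 3))

    member_files = []
    member_results = []
    for name in classifiers:
        cv = CVConfig(folds=folds, seed=seed, stratify=stratify, classifier=name, k=k)
        report, _, pooled = cross_validate(dataset, cv)
        payload = {
            "classifier": name,
            "k": k,
            "folds": folds,
            "seed": seed,
            "report": report.to_dict(),
            "scores": pooled.scores.tolist(),
            "bipartition": pooled.bipartition.tolist(),
        }
        path = out / f"report_{name}.json"
        path.write_text(json.dumps(payload, sort_keys=True) + "\n")
        member_files.append(path.name)
        member_results.append(pooled)
        logger.info("%s: average precision %.4f", name, report.average_precision)

    ensemble_file = None
    if rule:
        fused = combine_predictions(member_results, rule=rule, K=K)
        report = evaluate_predictions(dataset.Y, fused, dataset.label_names)
        payload = {
            "rule": rule,
            "K": K,
            "members": classifiers,
            "report": report.to_dict(),
        }
        epath = out / "report_ensemble.json"
        epath.write_text(json.dumps(payload, sort_keys=True) + "\n")
        ensemble_file = epath.name

    manifest = {
        "config": {
            "lag": int(cfg.get("lag", 1)),
            "classifiers": classifiers,
            "k": k,
            "folds": folds,
            "seed": seed,
            "stratify": stratify,
            "ensemble_rule": rule,
            "ensemble_K": K if rule else None,
        },
        "inputs": {"features": cfg["features"], "labels": cfg["labels"]},
        "outputs": {"members": member_files, "ensemble": ensemble_file},
        "version": "0.1.0",
    }
    blob = json.dumps(manifest, sort_keys=True)
    manifest["manifest_hash"] = hashlib.sha256(blob.encode()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True) + "\n")
    return manifest
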