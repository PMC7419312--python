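"""End-to-end orchestration: train, predict, evaluate.

The full analysis is: preprocess the training spectra, fit one shared
penalized FPCA basis, choose K by explained variance, compute PC scores,
fit one logistic model per functional group (with seeded oversampling of
rare positive classes), then predict group probabilities for new spectra
and assemble the joint nine-class labeling and its evaluation report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import fpca, glm
from .config import RunConfig
from .io import GROUPS, LabelRecord, Spectrum
from .preprocess import preprocess_dataset

logger = logging.getLogger(__name__)

_FLAG_ATTR = {
    "amide": "has_amide",
    "aniline": "has_aniline",
    "benzene": "has_benzene",
    "piperidine": "has_piperidine",
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class TrainResult:
    basis: fpca.FpcaBasis
    k: int
    models: dict[str, glm.GroupClassifier]
    scores: fpca.ScoreMatrix
    report: dict


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc

        return wrapped

    return deco


def _labels_for(records: list[LabelRecord], ids: tuple[str, ...], group: str) -> np.ndarray:
    by_id = {r.compound_id: r for r in records}
    missing = [i for i in ids if i not in by_id]
    if missing:
        raise ValueError(f"compounds without labels: {missing[:5]}")
    attr = _FLAG_ATTR[group]
    return np.array([getattr(by_id[i], attr) for i in ids], dtype=bool)


def train(
    spectra: list[Spectrum],
    records: list[LabelRecord],
    config: RunConfig | None = None,
) -> TrainResult:
    """Fit the shared FPCA basis and the four group classifiers."""
    config = config or RunConfig()
    train_records = [r for r in records if r.split == "train"]
    if not train_records:
        raise PipelineError("[train] empty training manifest")
    train_ids = {r.compound_id for r in train_records}
    train_spectra = [s for s in spectra if s.compound_id in train_ids]

    logger.info("preprocess: %d training spectra", len(train_spectra))
    pre = _stage("preprocess")(preprocess_dataset)(
        train_spectra,
        config.grid,
        config.baseline_trigger_ratio,
        config.baseline_enabled,
    )
    if pre.rejects:
        logger.warning("preprocess: dropped %d compounds", len(pre.rejects))

    n = len(pre.spectra)
    k_max = min(config.fpca_k_max, n - 1, config.grid.points)
    basis = _stage("fpca")(fpca.fit_fpca)(pre.spectra, config.fpca_penalty, k_max)
    k = _stage("select_k")(fpca.select_k)(
        basis.eigenvalues, config.fpca_variance_threshold
    )
    scores = _stage("scores")(fpca.compute_scores)(basis, pre.spectra, k)
    logger.info("fpca: K=%d of %d components", k, basis.k_max)

    models: dict[str, glm.GroupClassifier] = {}
    diagnostics: dict[str, dict] = {}
    for group in GROUPS:
        y = _labels_for(train_records, scores.compound_ids, group)
        f = scores.scores
        target = config.glm_oversample.get(group)
        n_pos = int(y.sum())
        if target is not None and n_pos and target > n_pos:
            f, y = _stage("oversample")(glm.oversample_minority)(
                f, y, target, config.seed
            )
            logger.info("oversample: %s positives %d -> %d", group, n_pos, target)
        model = _stage("glm")(glm.fit_group_model)(
            f,
            y,
            group,
            threshold=config.glm_threshold,
            max_iter=config.glm_max_iter,
            ridge_on_separation=config.glm_ridge_on_separation,
            basis_ref=basis.basis_id,
        )
        models[group] = model
        fitted = glm.predict_probabilities(model, scores.scores)
        diagnostics[group] = {
            "n_train": int(y.size),
            "n_positive": int(y.sum()),
            "separation": model.separation,
            "intercept": model.intercept,
            "train_accuracy": float(
                np.mean(
                    (fitted > model.threshold)
                    == _labels_for(train_records, scores.compound_ids, group)
                )
            ),
        }

    cum = fpca.explained_variance(basis.eigenvalues)
    report = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "basis_id": basis.basis_id,
        "n_train": n,
        "rejects": pre.rejects,
        "eigenvalues": basis.eigenvalues.tolist(),
        "cumulative_variance": cum.tolist(),
        "chosen_k": k,
        "variance_at_k": float(cum[k - 1]),
        "groups": diagnostics,
    }
    return TrainResult(basis=basis, k=k, models=models, scores=scores, report=report)


def predict(
    basis: fpca.FpcaBasis,
    models: dict[str, glm.GroupClassifier],
    spectra: list[Spectrum],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per-compound group probabilities, flags and joint label."""
    config = config or RunConfig()
    for group, model in models.items():
        if model.basis_ref and model.basis_ref != basis.basis_id:
            raise PipelineError(f"[predict] model {group} references a different basis")
    pre = _stage("preprocess")(preprocess_dataset)(
        spectra, config.grid, config.baseline_trigger_ratio, config.baseline_enabled
    )
    k = max(m.k for m in models.values())
    scores = _stage("scores")(fpca.compute_scores)(basis, pre.spectra, k)
    rows = []
    for i, cid in enumerate(scores.compound_ids):
        row: dict[str, object] = {"compound_id": cid}
        flags = []
        for group in GROUPS:
            model = models[group]
            p = glm.predict_probability(model, scores.scores[i, : model.k])
            flag = glm.classify(model, p)
            row[f"p_{group}"] = p
            row[f"pred_{group}"] = flag
            flags.append(flag)
        row["joint_label"] = ev.derive_joint_label(flags).value
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate_predictions(
    predictions: pd.DataFrame,
    records: list[LabelRecord],
) -> dict:
    """Full evaluation report for a prediction table against ground truth."""
    by_id = {r.compound_id: r for r in records}
    missing = [c for c in predictions["compound_id"] if c not in by_id]
    if missing:
        raise PipelineError(f"[evaluate] unlabeled compounds: {missing[:5]}")

    truth_flags = []
    pred_flags = []
    report: dict = {"groups": {}}
    accs = []
    for group in GROUPS:
        attr = _FLAG_ATTR[group]
        truth = np.array(
            [getattr(by_id[c], attr) for c in predictions["compound_id"]], dtype=bool
        )
        pred = predictions[f"pred_{group}"].to_numpy(dtype=bool)
        probs = predictions[f"p_{group}"].to_numpy(dtype=float)
        cm = ev.confusion(pred, truth)
        r = ev.rates(cm)
        entry = {
            "confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
            "fpr": r.fpr,
            "fnr": r.fnr,
            "accuracy": r.accuracy,
        }
        if truth.any() and not truth.all():
            entry["auc"] = ev.roc_auc(probs, truth).auc
        report["groups"][group] = entry
        accs.append(r.accuracy)

    report["average_accuracy"] = float(np.mean(accs))
    for cid in predictions["compound_id"]:
        truth_flags.append(by_id[cid].flags)
    for _, row in predictions.iterrows():
        pred_flags.append(tuple(bool(row[f"pred_{g}"]) for g in GROUPS))
    jc = ev.joint_confusion(pred_flags, truth_flags)
    report["joint"] = {
        "accuracy": jc.accuracy,
        "n": jc.n,
        "diagonal_total": jc.diagonal_total,
        "table": {t: jc.table.loc[t].to_dict() for t in jc.table.index},
    }
    report["taxonomy"] = ev.error_taxonomy(pred_flags, truth_flags)
    return report


def run_all(
    spectra: list[Spectrum],
    records: list[LabelRecord],
    config: RunConfig | None = None,
) -> tuple[TrainResult, pd.DataFrame, dict]:
    """Train on the train split, predict and evaluate on the test split."""
    config = config or RunConfig()
    result = train(spectra, records, config)
    test_ids = {r.compound_id for r in records if r.split == "test"}
    test_spectra = [s for s in spectra if s.compound_id in test_ids]
    if not test_spectra:
        raise PipelineError("[predict] empty test split")
    predictions = predict(result.basis, result.models, test_spectra, config)
    report = evaluate_predictions(predictions, records)
    report["config_hash"] = config.config_hash
    report["seed"] = config.seed
    return result, predictions, report


def save_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, default=float))
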