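"""The comparison protocol: repeated train/test splits over a cohort.

The protocol assigns 96 tumors to training and the remaining 11 to
testing, repeats this over three disjoint test sets, trains every model in
the roster on each split, and reports mean ± spread (population SD over
repeats) of sensitivity, specificity and accuracy per model.

A convention note: the study this protocol mirrors *swaps* the usual
definitions — its sensitivity is the proportion of non-responders
(class 0) correctly identified, and its specificity the proportion of
responders (class 1) correctly identified. That convention is implemented
verbatim as the default; pass ``convention="standard"`` to flip it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classical import (
    ModelSpec,
    fit_classifier,
    suvmax_median_threshold,
    suvmax_roc_threshold,
)
from .cnn import CNNConfig, make_dataset, predict_tumor
from .cnn import train as train_cnn
from .core import TumorROI
from .features import extract_all, feature_table

#: every model name the experiment roster understands
FULL_ROSTER: tuple[str, ...] = (
    "3s-cnn",
    "1s-cnn",
    "lr",
    "lr-pca",
    "gb",
    "gb-pca",
    "rf",
    "rf-pca",
    "svm",
    "svm-pca",
    "suvmax-roc",
    "suvmax-median",
)


@dataclass(frozen=True)
class ExperimentPlan:
    """Protocol settings: split sizes, repeats, model roster, seeds."""

    n_repeats: int = 3
    train_size: int = 96
    test_size: int = 11
    roster: tuple[str, ...] = FULL_ROSTER
    seed: int = 0
    stratify: bool = False
    convention: str = "paper"
    cnn_config: CNNConfig = field(default_factory=CNNConfig)
    augment: bool = True
    balance: bool = True
    classical_spec: ModelSpec = field(default_factory=ModelSpec)

    def __post_init__(self) -> None:
        unknown = set(self.roster) - set(FULL_ROSTER)
        if unknown:
            raise ValueError(f"unknown roster entries: {sorted(unknown)}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def compute_metrics(
    truth: np.ndarray, predictions: np.ndarray, convention: str = "paper"
) -> dict[str, float | None]:
    """Sensitivity, specificity and accuracy in percent.

    With the default (protocol) convention, sensitivity is the fraction of
    non-responders (label 0) identified and specificity the fraction of
    responders (label 1) identified; ``convention="standard"`` restores the
    textbook definitions. A class absent from ``truth`` leaves the
    corresponding rate as None rather than 0.
    """
    truth = np.asarray(truth, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if truth.shape != predictions.shape:
        raise ValueError("truth and predictions must have equal length")
    if convention not in ("paper", "standard"):
        raise ValueError("convention must be 'paper' or 'standard'")
    neg, pos = truth == 0, truth == 1
    rate0 = float((predictions[neg] == 0).mean() * 100.0) if neg.any() else None
    rate1 = float((predictions[pos] == 1).mean() * 100.0) if pos.any() else None
    accuracy = float((predictions == truth).mean() * 100.0)
    if convention == "paper":
        sens, spec = rate0, rate1
    else:
        sens, spec = rate1, rate0
    return {"sensitivity": sens, "specificity": spec, "accuracy": accuracy}


@dataclass
class MetricsReport:
    """Aggregated protocol results plus full per-subject predictions."""

    summary: pd.DataFrame  # model x (sensitivity/specificity/accuracy mean & sd)
    per_repeat: pd.DataFrame  # model, repeat, metric values
    predictions: pd.DataFrame  # model, repeat, subject_id, truth, predicted
    plan: ExperimentPlan

    def mean(self, model: str, metric: str) -> float:
        row = self.summary.loc[self.summary["model"] == model]
        if row.empty:
            raise KeyError(model)
        return float(row[f"{metric}_mean"].iloc[0])


def _split_indices(
    n: int, plan: ExperimentPlan, labels: np.ndarray, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Disjoint-test train/test splits; one permutation feeds all repeats."""
    if plan.n_repeats * plan.test_size > n:
        raise ValueError("cohort too small for disjoint test sets")
    if plan.train_size + plan.test_size != n:
        raise ValueError(
            f"plan sizes {plan.train_size}+{plan.test_size} do not cover the "
            f"cohort of {n}"
        )
    if plan.stratify:
        # proportional draw per class for each test chunk
        order = []
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            order.append(rng.permutation(idx))
        # interleave classes so consecutive chunks stay near-proportional
        merged = np.empty(n, dtype=int)
        parts = np.concatenate(order)
        fractions = np.concatenate(
            [np.arange(len(o)) / len(o) for o in order]
        )
        merged = parts[np.argsort(fractions, kind="stable")]
        perm = merged
    else:
        perm = rng.permutation(n)
    splits = []
    for r in range(plan.n_repeats):
        test = perm[r * plan.test_size : (r + 1) * plan.test_size]
        train = np.setdiff1d(perm, test)
        splits.append((train, test))
    return splits


def run_experiment(rois: list[TumorROI], plan: ExperimentPlan) -> MetricsReport:
    """Run the full comparison protocol on delineated, labelled ROIs.

    Splits are audited for disjointness; a model failing in one repeat is
    recorded as missing and the run continues. Hand-crafted features are
    extracted once per subject (they do not depend on the split; all
    split-dependent fitting — scaling, PCA, hyperparameter search —
    happens inside the training pipelines).
    """
    labels = np.array([r.label for r in rois], dtype=int)
    if np.any(labels < 0):
        raise ValueError("every ROI needs a binary label")
    n = len(rois)
    rng = np.random.default_rng(plan.seed)
    splits = _split_indices(n, plan, labels, rng)
    for (tr_a, te_a) in splits:
        assert len(np.intersect1d(tr_a, te_a)) == 0
        assert len(tr_a) + len(te_a) == n

    needs_features = any(m not in ("3s-cnn", "1s-cnn") for m in plan.roster)
    table = None
    if needs_features:
        table = feature_table([extract_all(r) for r in rois])
        feat_cols = [c for c in table.columns if c not in ("subject_id", "label")]

    rows_repeat, rows_pred = [], []
    for rep, (tr_idx, te_idx) in enumerate(splits):
        rep_seed = plan.seed * 1000 + rep
        truth = labels[te_idx]
        for model_name in plan.roster:
            try:
                preds = _run_model(
                    model_name, rois, table, feat_cols if table is not None else None,
                    tr_idx, te_idx, labels, plan, rep_seed,
                )
            except Exception as exc:  # pragma: no cover - defensive
                warnings.warn(
                    f"{model_name} failed in repeat {rep}: {exc}", stacklevel=2
                )
                continue
            m = compute_metrics(truth, preds, convention=plan.convention)
            rows_repeat.append({"model": model_name, "repeat": rep, **m})
            for i, te in enumerate(te_idx):
                rows_pred.append(
                    {
                        "model": model_name,
                        "repeat": rep,
                        "subject_id": rois[te].subject_id,
                        "truth": int(labels[te]),
                        "predicted": int(preds[i]),
                    }
                )
    per_repeat = pd.DataFrame(rows_repeat)
    summary_rows = []
    for model_name in plan.roster:
        sub = per_repeat[per_repeat["model"] == model_name]
        if sub.empty:
            continue
        row: dict[str, object] = {"model": model_name, "n_repeats": len(sub)}
        for metric in ("sensitivity", "specificity", "accuracy"):
            vals = sub[metric].dropna().to_numpy(dtype=float)
            row[f"{metric}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{metric}_sd"] = vals.std() if len(vals) else np.nan
        summary_rows.append(row)
    return MetricsReport(
        summary=pd.DataFrame(summary_rows),
        per_repeat=per_repeat,
        predictions=pd.DataFrame(rows_pred),
        plan=plan,
    )


def _run_model(
    model_name: str,
    rois: list[TumorROI],
    table: pd.DataFrame | None,
    feat_cols: list[str] | None,
    tr_idx: np.ndarray,
    te_idx: np.ndarray,
    labels: np.ndarray,
    plan: ExperimentPlan,
    rep_seed: int,
) -> np.ndarray:
    if model_name in ("3s-cnn", "1s-cnn"):
        variant = "3s" if model_name.startswith("3s") else "1s"
        config = replace(plan.cnn_config.for_variant(variant), seed=rep_seed)
        train_set = make_dataset(
            [rois[i] for i in tr_idx],
            variant=variant,
            augment=plan.augment,
            balance=plan.balance,
            seed=rep_seed,
        )
        model = train_cnn(train_set, config)
        return np.array(
            [predict_tumor(model, rois[i], variant=variant).predicted for i in te_idx]
        )
    assert table is not None and feat_cols is not None
    x_tr = table.iloc[tr_idx][feat_cols]
    x_te = table.iloc[te_idx][feat_cols].to_numpy(dtype=float)
    y_tr = labels[tr_idx]
    if model_name == "suvmax-roc":
        clf = suvmax_roc_threshold(x_tr["suv_max"].to_numpy(), y_tr)
        return clf.predict(table.iloc[te_idx]["suv_max"].to_numpy())
    if model_name == "suvmax-median":
        clf = suvmax_median_threshold(x_tr["suv_max"].to_numpy())
        return clf.predict(table.iloc[te_idx]["suv_max"].to_numpy())
    family = model_name.split("-")[0]
    spec = replace(
        plan.classical_spec,
        family=family,
        use_pca=model_name.endswith("-pca"),
        seed=rep_seed,
    )
    fitted = fit_classifier(x_tr, y_tr, spec)
    return fitted.predict(x_te)
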