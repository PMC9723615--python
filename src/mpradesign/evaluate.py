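"""Classifier evaluation, budget planning and the incremental-learning harness.

AUROC here is the pairwise concordance probability (ties count 1/2) and
AUPR the step-interpolated area under the precision-recall curve; both are
delegated to scikit-learn, whose definitions coincide with those brute-force
constructions.  ``bayes_precision`` converts a validation-set recall, an
assumed genome-wide prevalence of functional variants and a screening budget
into the expected precision of a screen via Bayes' rule:

    P(+ | predict+) = P(predict+ | +) * P(+) / P(predict+)

``incremental_learning`` replays the design loop in which a classifier is
retrained from scratch as each batch of newly assayed positives (plus their
matched controls) arrives, tracking validation AUROC/AUPR per iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from .calibrate import CalibrationReference, threshold_for_fraction
from .errors import ConfigError
from .features import Standardizer
from .model import ModelSpec, TrainConfig, build_model, predict, train


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ConfigError("both classes must be present")


def auroc(scores, labels) -> float:
    """Area under the ROC curve == P(score_pos > score_neg) with ties at 1/2."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def aupr(scores, labels) -> float:
    """Step-interpolated area under the precision-recall curve."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(average_precision_score(labels, np.asarray(scores, float)))


@dataclass
class EvalReport:
    auroc: float
    aupr: float
    roc_points: np.ndarray  # columns (fpr, tpr)
    pr_points: np.ndarray  # columns (recall, precision)
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "aupr": self.aupr,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "roc_points": np.asarray(self.roc_points).tolist(),
            "pr_points": np.asarray(self.pr_points).tolist(),
        }


def evaluate(scores, labels) -> EvalReport:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    fpr, tpr, _ = roc_curve(labels, scores)
    prec, rec, _ = precision_recall_curve(labels, scores)
    return EvalReport(
        auroc=auroc(scores, labels),
        aupr=aupr(scores, labels),
        roc_points=np.column_stack([fpr, tpr]),
        pr_points=np.column_stack([rec[::-1], prec[::-1]]),
        n_pos=int((labels == 1).sum()),
        n_neg=int((labels != 1).sum()),
    )


def recall_at_fraction(scores_val, labels_val, fraction: float, reference: CalibrationReference) -> float:
    """Validation recall when predicting positive above the top-``fraction``
    genome-wide threshold."""
    labels_val = np.asarray(labels_val)
    scores_val = np.asarray(scores_val, float)
    pos = scores_val[labels_val == 1]
    if pos.size == 0:
        raise ConfigError("validation set contains no positives")
    thr = threshold_for_fraction(reference, fraction)
    return float(np.mean(pos >= thr))


@dataclass
class PrecisionEstimate:
    recall: float
    prevalence: float
    fraction_predicted: float
    precision: float
    clipped: bool = False


def bayes_precision(recall: float, prevalence: float, fraction_predicted: float) -> PrecisionEstimate:
    """Expected screening precision P(+|predict+) via Bayes' rule."""
    for name, v in (("recall", recall), ("prevalence", prevalence),
                    ("fraction_predicted", fraction_predicted)):
        if not 0.0 < v <= 1.0:
            if name == "fraction_predicted" and v == 0:
                raise ConfigError("fraction_predicted must be > 0")
            raise ConfigError(f"{name} must lie in (0, 1], got {v}")
    precision = recall * prevalence / fraction_predicted
    clipped = precision > 1.0
    if clipped:
        warnings.warn(
            f"recall x prevalence ({recall * prevalence:.4g}) exceeds "
            f"fraction_predicted ({fraction_predicted:.4g}); precision clipped to 1",
            stacklevel=2,
        )
        precision = 1.0
    return PrecisionEstimate(recall, prevalence, fraction_predicted, precision, clipped)


@dataclass
class IncrementalResult:
    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def incremental_learning(
    records: pd.DataFrame,
    x_site: np.ndarray,
    x_nbhd: np.ndarray,
    spec: ModelSpec,
    train_config: TrainConfig,
    start_n_pos: int = 100,
    step_n_pos: int = 50,
    source_order: list | None = None,
    seeds=(0,),
) -> IncrementalResult:
    """Retrain-from-scratch learning curve over growing training cohorts.

    ``records`` is a matched-cohort table (GROUP, ROLE, SPLIT, SOURCE
    columns) aligned row-wise with the feature arrays.  The validation split
    is fixed before the loop.  Starting from ``start_n_pos`` positive groups,
    each iteration adds ``step_n_pos`` groups — exhausting sources in
    ``source_order`` (default: order of appearance) — retrains from scratch,
    and evaluates on the fixed validation split.  A final step that exhausts
    the remaining groups is allowed and flagged partial.
    """
    if "SPLIT" not in records.columns:
        raise ConfigError("records need a SPLIT column; run split_holdout first")
    records = records.reset_index(drop=True)
    val_mask = (records["SPLIT"] == "validation").to_numpy()
    y = (records["ROLE"] == "positive").to_numpy().astype(float)
    if val_mask.sum() == 0 or y[val_mask].sum() == 0:
        raise ConfigError("fixed validation split is empty or has no positives")

    train_pos = records[(records["SPLIT"] == "train") & (records["ROLE"] == "positive")]
    if source_order is None:
        source_order = list(dict.fromkeys(train_pos["SOURCE"]))
    group_rows = {g: np.flatnonzero((records["GROUP"] == g).to_numpy() & ~val_mask)
                  for g in train_pos["GROUP"]}

    rows = []
    for seed in seeds:
        rng = np.random.default_rng([int(seed), 23])
        ordered_groups, group_source = [], {}
        for src in source_order:
            gs = train_pos.loc[train_pos["SOURCE"] == src, "GROUP"].to_numpy().copy()
            rng.shuffle(gs)
            ordered_groups.extend(gs)
            for g in gs:
                group_source[g] = src
        total = len(ordered_groups)
        if total < start_n_pos:
            raise ConfigError(
                f"only {total} training groups available but start_n_pos={start_n_pos}"
            )
        counts = [start_n_pos]
        while counts[-1] < total:
            counts.append(min(counts[-1] + step_n_pos, total))
        for it, n_pos in enumerate(counts):
            active = ordered_groups[:n_pos]
            idx = np.concatenate([group_rows[g] for g in active])
            std = Standardizer().fit(x_site[idx], x_nbhd[idx])
            xs_tr, xn_tr = std.transform(x_site[idx], x_nbhd[idx])
            xs_va, xn_va = std.transform(x_site[val_mask], x_nbhd[val_mask])
            cfg = TrainConfig(
                epochs=train_config.epochs, batch_size=train_config.batch_size,
                learning_rate=train_config.learning_rate, l2=train_config.l2,
                seed=int(seed),
            )
            net = build_model(spec, seed=int(seed))
            train(net, xs_tr, xn_tr, y[idx], cfg)
            scores = predict(net, xs_va, xn_va)
            y_val = y[val_mask]
            rows.append({
                "seed": int(seed),
                "iteration": it,
                "n_pos": n_pos,
                "source": group_source[active[-1]],
                "auroc": auroc(scores, y_val),
                "aupr": aupr(scores, y_val),
                "partial": n_pos != start_n_pos + it * step_n_pos,
            })
    return IncrementalResult(table=pd.DataFrame(rows))
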