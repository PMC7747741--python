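"""Repeated stratified k-fold Random-Forest evaluation of a signature.

Samples (columns of the signature-restricted gene matrix) are classified
into case vs control with a Random Forest (500 trees by default).  Each
repeat draws a fresh seeded stratified k-fold split; out-of-fold
predictions are pooled within the repeat to compute accuracy, precision,
sensitivity, specificity and the class-probability AUC, and the per-repeat
values are averaged.  Stratification is required because the design can
be highly unbalanced (a handful of cases against many controls), where
unstratified folds may lack a class entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .errors import ParameterError, ValidationError
from .preprocess import GeneMatrix


@dataclass
class CVReport:
    """Averaged cross-validation metrics plus the per-repeat table."""

    k: int
    repeats: int
    seed: int
    avg_accuracy: float
    avg_auc: float
    avg_precision: float
    avg_sensitivity: float
    avg_specificity: float
    per_repeat: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "k": self.k, "repeats": self.repeats, "seed": self.seed,
            "avg_accuracy": self.avg_accuracy, "avg_auc": self.avg_auc,
            "avg_precision": self.avg_precision,
            "avg_sensitivity": self.avg_sensitivity,
            "avg_specificity": self.avg_specificity,
        }


def evaluate_signature(g: GeneMatrix, k: int, repeats: int = 10,
                       seed: int = 17, n_trees: int = 500) -> CVReport:
    """Repeated stratified k-fold Random-Forest cross-validation.

    ``g`` must be restricted to the signature genes and carry group
    labels.  Deterministic for a fixed seed: fold shuffles and forest
    seeds all derive from one master seed sequence.
    """
    if g.groups is None:
        raise ValidationError("gene matrix has no group labels")
    y = np.array([1 if g.groups[s] == "case" else 0 for s in g.sample_ids])
    if y.sum() == 0 or y.sum() == y.size:
        raise ValidationError("both classes must be present")
    n_min = min(int(y.sum()), int(y.size - y.sum()))
    if k < 2:
        raise ParameterError("k must be >= 2")
    if k > n_min:
        raise ParameterError(
            f"stratified {k}-fold needs >= {k} samples in the smaller class (have {n_min})"
        )
    if repeats < 1:
        raise ParameterError("repeats must be >= 1")
    X = g.values.T  # samples x genes

    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(2 * repeats) % (2 ** 31)
    rows = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rep_seeds[2 * rep]))
        prob = np.empty(y.size)
        pred = np.empty(y.size, dtype=int)
        for f, (tr, te) in enumerate(skf.split(X, y)):
            rf = RandomForestClassifier(
                n_estimators=n_trees,
                random_state=int((rep_seeds[2 * rep + 1] + f) % (2 ** 31)),
            )
            rf.fit(X[tr], y[tr])
            p = rf.predict_proba(X[te])
            case_col = list(rf.classes_).index(1)
            prob[te] = p[:, case_col]
            pred[te] = (prob[te] >= 0.5).astype(int)
        tp = int(((pred == 1) & (y == 1)).sum())
        tn = int(((pred == 0) & (y == 0)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        rows.append({
            "repeat": rep,
            "accuracy": (tp + tn) / y.size,
            "auc": float(roc_auc_score(y, prob)),
            "precision": tp / (tp + fp) if tp + fp else 0.0,
            "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
            "specificity": tn / (tn + fp) if tn + fp else 0.0,
        })
    table = pd.DataFrame(rows)
    return CVReport(
        k=k, repeats=repeats, seed=seed,
        avg_accuracy=float(table["accuracy"].mean()),
        avg_auc=float(table["auc"].mean()),
        avg_precision=float(table["precision"].mean()),
        avg_sensitivity=float(table["sensitivity"].mean()),
        avg_specificity=float(table["specificity"].mean()),
        per_repeat=table,
    )
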