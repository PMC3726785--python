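"""Exhaustive-subset LDA signature search with cross-cohort ROC/AUC validation.

Every non-empty subset of the validated marker panel (127 signatures for 7
miRNAs) is fitted as a two-class linear discriminant on the training cohort's
relative-Ct values and scored on the held-out cohort: accuracy, sensitivity
and specificity at the 0.5-posterior cut, plus the full ROC curve and its
trapezoidal AUC.

The discriminant is the classical two-Gaussian shared-covariance model:
pooled within-class covariance S, weights w = S^-1 (mu_AD - mu_NC), and the
AD posterior sigma(w.x + b) with b absorbing the class means and priors.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import ValidationError

POSITIVE = "AD"
NEGATIVE = "NC"


@dataclass
class SignatureModel:
    """Fitted linear discriminant for one miRNA subset."""

    features: tuple
    mean_pos: np.ndarray
    mean_neg: np.ndarray
    covariance: np.ndarray    # pooled within-class, (p, p)
    priors: dict              # class -> prior, sums to 1
    weights: np.ndarray       # S^-1 (mu_pos - mu_neg)
    offset: float             # log-odds at x = 0
    regularized: bool = False
    training_id: str = ""


@dataclass
class MetricsReport:
    """Classification metrics for one signature on one evaluation set."""

    features: tuple
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    roc: pd.DataFrame         # columns: threshold, fpr, tpr
    auc: float

    @property
    def name(self) -> str:
        return "+".join(self.features)


def enumerate_signatures(panel: list[str]) -> list[tuple]:
    """All non-empty subsets of ``panel``, ordered by size then name."""
    if len(panel) == 0:
        raise ValidationError("panel must be non-empty")
    if len(set(panel)) != len(panel):
        dupes = sorted({n for n in panel if panel.count(n) > 1})
        raise ValidationError(f"duplicate panel names: {dupes}")
    names = sorted(panel)
    out: list[tuple] = []
    for size in range(1, len(names) + 1):
        out.extend(combinations(names, size))
    return out


def _as_matrix(x, features=None) -> tuple[np.ndarray, tuple]:
    if isinstance(x, pd.DataFrame):
        if features is not None:
            missing = [f for f in features if f not in x.columns]
            if missing:
                raise ValidationError(f"features absent from data: {missing}")
            x = x[list(features)]
        return x.to_numpy(dtype=float), tuple(x.columns)
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    cols = tuple(features) if features is not None else tuple(
        f"x{i}" for i in range(arr.shape[1])
    )
    return arr, cols


def fit_lda(x, labels, priors: str = "empirical", training_id: str = "") -> SignatureModel:
    """Fit the two-class shared-covariance linear discriminant.

    The pooled covariance uses the n-2 divisor; if it is singular it is
    ridge-regularized by eps * trace(S)/p on the diagonal (eps = 1e-8) and the
    model is flagged. Priors are the training class frequencies, or equal.
    """
    mat, features = _as_matrix(x)
    labels = np.asarray(labels)
    if priors not in {"empirical", "equal"}:
        raise ValueError(f"unknown priors mode {priors!r}")
    classes = {POSITIVE, NEGATIVE}
    if set(labels) - classes:
        raise ValidationError(f"labels must be in {sorted(classes)}")
    pos = mat[labels == POSITIVE]
    neg = mat[labels == NEGATIVE]
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError("each class needs at least 2 samples")

    mu_pos = pos.mean(axis=0)
    mu_neg = neg.mean(axis=0)
    n, p = mat.shape
    scatter = (pos - mu_pos).T @ (pos - mu_pos) + (neg - mu_neg).T @ (neg - mu_neg)
    cov = scatter / (n - 2)

    regularized = False
    with np.errstate(divide="ignore", invalid="ignore"):
        cond_ok = np.linalg.cond(cov) < 1e12 if np.isfinite(cov).all() else False
    if not cond_ok:
        tr = np.trace(cov)
        ridge = 1e-8 * (tr / p if tr > 0 else 1.0)
        cov = cov + ridge * np.eye(p)
        regularized = True

    if priors == "empirical":
        pri = {POSITIVE: len(pos) / n, NEGATIVE: len(neg) / n}
    else:
        pri = {POSITIVE: 0.5, NEGATIVE: 0.5}

    cov_inv = np.linalg.inv(cov)
    w = cov_inv @ (mu_pos - mu_neg)
    offset = (
        -0.5 * (mu_pos @ cov_inv @ mu_pos - mu_neg @ cov_inv @ mu_neg)
        + np.log(pri[POSITIVE] / pri[NEGATIVE])
    )
    return SignatureModel(
        features=features,
        mean_pos=mu_pos,
        mean_neg=mu_neg,
        covariance=cov,
        priors=pri,
        weights=w,
        offset=float(offset),
        regularized=regularized,
        training_id=training_id,
    )


def predict(model: SignatureModel, x) -> pd.DataFrame:
    """AD posterior probability and hard label (AD when posterior >= 0.5)."""
    if isinstance(x, pd.DataFrame):
        mat, features = _as_matrix(x, model.features)
        index = x.index
    else:
        mat, features = _as_matrix(x, model.features)
        index = pd.RangeIndex(len(mat))
    if features != model.features:
        raise ValidationError(
            f"feature mismatch: model {model.features}, data {features}"
        )
    if mat.shape[1] != len(model.features):
        raise ValidationError("feature-count mismatch")
    logit = mat @ model.weights + model.offset
    with np.errstate(over="ignore"):
        posterior = 1.0 / (1.0 + np.exp(-logit))
    label = np.where(posterior >= 0.5, POSITIVE, NEGATIVE)
    return pd.DataFrame({"posterior_ad": posterior, "label": label}, index=index)


def roc_curve(scores, labels) -> pd.DataFrame:
    """ROC points from a threshold sweep over the unique scores (plus +inf).

    Predicts positive when score >= threshold; the curve runs from (0,0) to
    (1,1) and tied scores produce diagonal segments (half credit in the AUC).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == POSITIVE
    neg = labels == NEGATIVE
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present to build a ROC curve")
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    rows = []
    for t in thresholds:
        called = scores >= t
        rows.append(
            {
                "threshold": t,
                "fpr": (called & neg).sum() / n_neg,
                "tpr": (called & pos).sum() / n_pos,
            }
        )
    return pd.DataFrame(rows)


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC curve plus its trapezoidal AUC (equals Mann-Whitney with ties at 1/2)."""
    roc = roc_curve(scores, labels)
    auc = float(np.trapezoid(roc["tpr"], roc["fpr"]))
    return roc, auc


def _confusion_metrics(features, pred: pd.DataFrame, labels, roc, auc) -> MetricsReport:
    labels = np.asarray(labels)
    called_pos = (pred["label"] == POSITIVE).to_numpy()
    is_pos = labels == POSITIVE
    tp = int((called_pos & is_pos).sum())
    fp = int((called_pos & ~is_pos).sum())
    fn = int((~called_pos & is_pos).sum())
    tn = int((~called_pos & ~is_pos).sum())
    return MetricsReport(
        features=tuple(features),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=(tp + tn) / len(labels),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        roc=roc,
        auc=auc,
    )


def evaluate_signature(
    features,
    train_x: pd.DataFrame,
    train_labels,
    test_x: pd.DataFrame,
    test_labels,
    priors: str = "empirical",
    training_id: str = "cohort1",
) -> MetricsReport:
    """Fit one subset on the training cohort and score it on the test cohort."""
    model = fit_lda(
        train_x[list(features)], train_labels, priors=priors, training_id=training_id
    )
    pred = predict(model, test_x[list(features)])
    roc, auc = roc_auc(pred["posterior_ad"], test_labels)
    return _confusion_metrics(features, pred, test_labels, roc, auc)


def evaluate_signatures(
    train_x: pd.DataFrame,
    train_labels,
    test_x: pd.DataFrame,
    test_labels,
    panel: list[str] | None = None,
    priors: str = "empirical",
) -> list[MetricsReport]:
    """Exhaustive search: every non-empty subset of ``panel``, fitted on the
    training cohort and evaluated on the held-out cohort."""
    overlap = set(train_x.index) & set(test_x.index)
    if overlap:
        raise ValidationError(f"cohorts share sample ids: {sorted(overlap)}")
    if panel is None:
        panel = list(train_x.columns)
    missing = [f for f in panel if f not in test_x.columns]
    if missing:
        raise ValidationError(f"panel features absent from test cohort: {missing}")
    return [
        evaluate_signature(
            subset, train_x, train_labels, test_x, test_labels, priors=priors
        )
        for subset in enumerate_signatures(panel)
    ]


def rank_signatures(
    reports: list[MetricsReport],
    min_spec: float = 0.9,
    min_sens: float = 0.8,
    min_auc: float = 0.9,
) -> list[MetricsReport]:
    """Keep signatures strictly exceeding all three cutoffs, best first.

    Sort order: AUC desc, accuracy desc, subset size asc, subset name asc.
    """
    if len(reports) == 0:
        raise ValidationError("no reports to rank")
    kept = [
        r
        for r in reports
        if r.specificity > min_spec and r.sensitivity > min_sens and r.auc > min_auc
    ]
    return sorted(
        kept, key=lambda r: (-r.auc, -r.accuracy, len(r.features), r.features)
    )


def reports_table(reports: list[MetricsReport]) -> pd.DataFrame:
    """Flatten reports into the ranked-signature table written to disk."""
    return pd.DataFrame(
        [
            {
                "subset": r.name,
                "n_mirnas": len(r.features),
                "accuracy": r.accuracy,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "auc": r.auc,
            }
            for r in reports
        ]
    )
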