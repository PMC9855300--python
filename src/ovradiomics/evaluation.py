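"""Logistic-regression modeling of radscores and ROC evaluation.

The radscore is the single predictor of a univariate logistic model for
HGSC vs non-HGSC.  Performance is reported as AUC, accuracy, sensitivity
and specificity; in the full pipeline each of the 100 stratified 8:2
resamples contributes a training estimate (pooled 10-fold cross-validated
predictions within the training cohort) and a testing estimate (the
train-fitted model applied once to the held-out 20%), and metrics are
aggregated over resamples as the mean with a percentile 95% CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression as SkLogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .selection import (
    FilterConfig,
    ResamplePlan,
    VotedLassoModel,
    VotedLassoResults,
)
from .tables import FeatureTable

__all__ = [
    "LogisticScoreModel",
    "fit_lr",
    "RocResult",
    "roc_metrics",
    "PipelineResults",
    "evaluate_pipeline",
]


@dataclass
class LogisticScoreModel:
    """Univariate logistic model P(HGSC | radscore) = expit(a + b·score)."""

    intercept: float
    slope: float
    converged: bool = True
    slope_pvalue: float = float("nan")

    def predict_proba(self, scores) -> np.ndarray:
        z = self.intercept + self.slope * np.asarray(scores, dtype=float)
        return 1.0 / (1.0 + np.exp(-z))


def fit_lr(scores, labels) -> LogisticScoreModel:
    """Maximum-likelihood univariate logistic fit of labels on scores.

    Predicted probability is monotone in the radscore by construction.
    Perfect separation (infinite MLE) falls back to a ridge-penalized fit
    with a warning.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    exog = sm.add_constant(s)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            res = sm.Logit(y, exog).fit(disp=0)
        a, b = res.params
        return LogisticScoreModel(
            float(a), float(b), converged=True,
            slope_pvalue=float(res.pvalues[1]),
        )
    except Exception:
        warnings.warn(
            "perfect separation or non-convergence in logistic fit; "
            "using a penalized fallback",
            stacklevel=2,
        )
        ridge = SkLogisticRegression(C=100.0, solver="lbfgs", max_iter=1000)
        ridge.fit(s.reshape(-1, 1), y)
        return LogisticScoreModel(
            float(ridge.intercept_[0]), float(ridge.coef_[0, 0]),
            converged=False,
        )


@dataclass
class RocResult:
    """ROC evaluation at one operating point.

    When the result aggregates many resamples, ``ci95`` is the 95% CI of
    the mean (normal approximation, SD/√R — it narrows as resamples are
    added, matching the tight intervals a 100-resample ensemble yields)
    and ``spread95`` is the 2.5–97.5 percentile range of the per-resample
    values (the between-resample variability itself).  Both are None for
    a single score set.
    """

    auc: float
    ci95: tuple[float, float] | None
    accuracy: float
    sensitivity: float
    specificity: float
    operating_threshold: float
    cohort: str = ""
    spread95: tuple[float, float] | None = None
    metric_cis: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.ci95 is not None and self.ci95[0] > self.ci95[1]:
            raise ValueError("CI low > high")

    def as_dict(self) -> dict:
        return {
            "cohort": self.cohort,
            "auc": self.auc,
            "ci95": self.ci95,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "operating_threshold": self.operating_threshold,
            "spread95": self.spread95,
        }


def _point_metrics(y, scores, threshold):
    pred = np.asarray(scores) >= threshold
    y = np.asarray(y).astype(bool)
    tp = int((pred & y).sum())
    tn = int((~pred & ~y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / len(y)
    return acc, sens, spec


def youden_threshold(y, scores) -> float:
    """Operating point maximizing Youden's J = sensitivity + specificity − 1."""
    fpr, tpr, thr = roc_curve(y, scores)
    j = tpr - fpr
    return float(thr[int(np.argmax(j))])


def roc_metrics(scores, labels, threshold: float | None = None, cohort: str = "") -> RocResult:
    """AUC (midrank/trapezoidal) plus accuracy, sensitivity and
    specificity at the operating point (Youden's J unless a threshold is
    given)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(y, s))
    thr = youden_threshold(y, s) if threshold is None else float(threshold)
    acc, sens, spec = _point_metrics(y, s, thr)
    return RocResult(
        auc=auc,
        ci95=None,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        operating_threshold=thr,
        cohort=cohort,
    )


def _aggregate(rows: list[dict], cohort: str) -> RocResult:
    df = pd.DataFrame(rows)
    R = len(df)

    def mean_ci(col):
        m = df[col].mean()
        half = 1.96 * df[col].std(ddof=1) / np.sqrt(R) if R > 1 else 0.0
        return float(m - half), float(m + half)

    def spread(col):
        lo, hi = np.percentile(df[col], [2.5, 97.5])
        return float(lo), float(hi)

    return RocResult(
        auc=float(df["auc"].mean()),
        ci95=mean_ci("auc"),
        accuracy=float(df["accuracy"].mean()),
        sensitivity=float(df["sensitivity"].mean()),
        specificity=float(df["specificity"].mean()),
        operating_threshold=float(df["threshold"].mean()),
        cohort=cohort,
        spread95=spread("auc"),
        metric_cis={
            m: mean_ci(m) for m in ("accuracy", "sensitivity", "specificity")
        },
    )


@dataclass
class PipelineResults:
    """Aggregated train/test performance of the radscore logistic model."""

    train: RocResult
    test: RocResult
    selection: VotedLassoResults
    per_resample: pd.DataFrame

    def summary(self) -> str:
        lines = [
            "Radscore logistic model — resample-aggregated performance",
            "=" * 64,
            f"{'cohort':<8}{'AUC':>8}{'95% CI':>18}{'acc':>7}{'sens':>7}{'spec':>7}",
        ]
        for r in (self.train, self.test):
            lo, hi = r.ci95
            lines.append(
                f"{r.cohort:<8}{r.auc:>8.3f}{f'({lo:.3f}-{hi:.3f})':>18}"
                f"{r.accuracy:>7.3f}{r.sensitivity:>7.3f}{r.specificity:>7.3f}"
            )
        return "\n".join(lines)

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [self.train.as_dict(), self.test.as_dict()]
        ).set_index("cohort")


def _cv_pooled_probs(scores, y, folds, seed):
    """Out-of-fold logistic predictions within a cohort (stratified)."""
    probs = np.empty_like(scores, dtype=float)
    folds = max(2, min(folds, int(np.bincount(y).min())))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for fit_idx, held_idx in skf.split(scores.reshape(-1, 1), y):
        lr = fit_lr(scores[fit_idx], y[fit_idx])
        probs[held_idx] = lr.predict_proba(scores[held_idx])
    return probs


def evaluate_pipeline(
    table: FeatureTable,
    plan: ResamplePlan | None = None,
    filter_config: FilterConfig | None = None,
    folds: int = 10,
    selection: VotedLassoResults | None = None,
) -> PipelineResults:
    """Run selection (unless given) and the resample-aggregated ROC study.

    For each resample of the plan: radscores come from the averaged
    coefficients; the training estimate pools ``folds``-fold
    cross-validated out-of-fold predictions within the training cohort;
    the operating point is Youden's J on that pooled training ROC; the
    train-fitted model and threshold are then applied once to the held-out
    test cohort.  Training metrics never see test labels.
    """
    plan = plan or ResamplePlan()
    if selection is None:
        selection = VotedLassoModel(
            table, plan=plan, filter_config=filter_config
        ).fit()

    scores = selection.radscore(table)
    y = table.y
    train_rows, test_rows = [], []
    for rec, seed in zip(selection.records, plan.resample_seeds):
        tr, te = rec.train_idx, rec.test_idx
        s_tr, y_tr = scores[tr], y[tr]
        s_te, y_te = scores[te], y[te]

        p_tr = _cv_pooled_probs(s_tr, y_tr, folds, int(seed))
        thr = youden_threshold(y_tr, p_tr)
        acc, sens, spec = _point_metrics(y_tr, p_tr, thr)
        train_rows.append(
            {
                "auc": roc_auc_score(y_tr, p_tr),
                "accuracy": acc,
                "sensitivity": sens,
                "specificity": spec,
                "threshold": thr,
            }
        )

        lr = fit_lr(s_tr, y_tr)
        p_te = lr.predict_proba(s_te)
        acc, sens, spec = _point_metrics(y_te, p_te, thr)
        test_rows.append(
            {
                "auc": roc_auc_score(y_te, p_te),
                "accuracy": acc,
                "sensitivity": sens,
                "specificity": spec,
                "threshold": thr,
            }
        )

    per = pd.concat(
        [
            pd.DataFrame(train_rows).assign(cohort="train"),
            pd.DataFrame(test_rows).assign(cohort="test"),
        ],
        ignore_index=True,
    )
    return PipelineResults(
        train=_aggregate(train_rows, "train"),
        test=_aggregate(test_rows, "test"),
        selection=selection,
        per_resample=per,
    )
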