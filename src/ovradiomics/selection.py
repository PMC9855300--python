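"""Voted-LASSO feature selection and the radscore.

The selection procedure, run on a labeled feature table:

1. Draw ``n_resamples`` (default 100) stratified 8:2 train/test splits.
2. Per resample, on the training portion only: standardize features,
   keep those whose two-sided Mann-Whitney U test between HGSC and
   non-HGSC has p < α (default .05), then fit an L1-penalized logistic
   regression at the λ minimizing 10-fold cross-validated deviance.
3. Tally how often each feature receives a nonzero LASSO coefficient
   ("votes") across resamples and rank features by that frequency.
4. Retain the top 10% of the ever-selected pool, capped at 20 features,
   and average each retained feature's LASSO coefficient across resamples
   (zeros included for resamples where it was not selected).
5. The radscore of a patient is the sum of retained feature values times
   their averaged coefficients.

``VotedLassoModel`` is the model object; ``fit()`` returns a
``VotedLassoResults`` carrying frequencies, averaged coefficients, the
retained set, per-resample records, and ``radscore``/``summary``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .tables import FeatureTable

__all__ = [
    "ResamplePlan",
    "FilterConfig",
    "stratified_split",
    "mwu_test",
    "lasso_fit",
    "VotedLassoModel",
    "VotedLassoResults",
    "voted_lasso",
    "radscore",
    "retention_count",
]


@dataclass
class ResamplePlan:
    """The resampling design: how many splits, at what ratio, seeded how.

    Per-resample seeds are derived deterministically from ``base_seed``
    via a ``numpy.random.SeedSequence`` so the whole procedure is
    reproducible from one integer.
    """

    n_resamples: int = 100
    train_fraction: float = 0.8
    stratified: bool = True
    base_seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")

    @property
    def resample_seeds(self) -> np.ndarray:
        state = np.random.SeedSequence(self.base_seed).generate_state(
            self.n_resamples, dtype=np.uint64
        )
        return (state % np.uint64(2**31 - 1)).astype(np.int64)


@dataclass
class FilterConfig:
    """Univariate Mann-Whitney prefilter settings."""

    alpha: float = 0.05
    two_sided: bool = True

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def stratified_split(
    labels, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test index split.

    Per class, ``round(class_n × train_fraction)`` patients go to the
    training set; the split is disjoint and exhaustive.
    """
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            raise ValueError(
                f"class {cls!r} has {len(idx)} member(s); need at least 2"
            )
        idx = rng.permutation(idx)
        n_train = int(round(len(idx) * train_fraction))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train.append(idx[:n_train])
        test.append(idx[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def mwu_test(x, y, two_sided: bool = True) -> tuple[float, float]:
    """Mann-Whitney U test between two samples.

    Uses exact enumeration when ``min(n, m) <= 8`` and the data are
    tie-free, otherwise the normal approximation with tie correction and
    continuity correction.  Returns ``(U, p)`` with U counted for ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    alternative = "two-sided" if two_sided else "greater"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def _mwu_filter_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Mann-Whitney p-values, one per column."""
    res = stats.mannwhitneyu(
        X[y == 1], X[y == 0], alternative="two-sided", method="asymptotic", axis=0
    )
    return np.asarray(res.pvalue)


def lasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float | None = None,
    family: str = "logistic",
    cv: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """L1-penalized fit; "selected" features are those with nonzero
    coefficients.

    Columns are expected to be standardized (zero mean, unit SD on the
    data passed in).  ``lam`` is the penalty weight on the per-sample
    scale (the ``alpha`` of the coordinate-descent LASSO, or ``1/(n·C)``
    for the logistic solver); ``lam=None`` selects it by stratified
    ``cv``-fold cross-validation minimizing deviance.  Returns
    ``(coefficients, lam_used)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if family == "linear":
        if lam is None:
            raise ValueError("linear family requires an explicit lam")
        model = Lasso(alpha=lam, fit_intercept=True, max_iter=10000)
        model.fit(X, y)
        return model.coef_.copy(), float(lam)
    if family != "logistic":
        raise ValueError(f"unknown family {family!r}")
    if lam is not None:
        C = 1.0 / (n * lam)
        model = LogisticRegression(
            penalty="l1", C=C, solver="liblinear", max_iter=1000
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            model.fit(X, y)
        return model.coef_.ravel().copy(), float(lam)
    # internal CV cannot have more folds than the smallest class
    class_min = int(np.bincount(y).min())
    folds = StratifiedKFold(
        n_splits=max(2, min(cv, class_min)), shuffle=True, random_state=seed
    )
    model = LogisticRegressionCV(
        Cs=np.logspace(-2.5, 2.0, 12),
        cv=folds,
        penalty="l1",
        solver="liblinear",
        scoring="neg_log_loss",
        max_iter=1000,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # scikit-learn 1.9 emits transition FutureWarnings for the
        # penalty/l1_ratios API; the l1 behavior itself is unchanged
        warnings.simplefilter("ignore", FutureWarning)
        model.fit(X, y)
    return model.coef_.ravel().copy(), float(1.0 / (n * model.C_[0]))


def retention_count(
    pool_size: int, target_fraction: float = 0.10, target_k: int = 20
) -> int:
    """How many features the voting step retains from an ever-selected
    pool: the top ``ceil(target_fraction × pool)``, capped at
    ``target_k`` — e.g. exactly 20 for a 200-feature pool at 10%."""
    if pool_size < 1:
        raise ValueError("pool must be nonempty")
    return min(target_k, math.ceil(target_fraction * pool_size))


@dataclass
class ResampleRecord:
    """What one resample contributed: the split, the univariate-filter
    survivors, the LASSO-selected features with coefficients, and λ."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    survivors: list[str]
    selected: dict[str, float]
    lam: float


class VotedLassoModel:
    """Stability-voted LASSO feature selection on a labeled feature table.

    Parameters
    ----------
    table : FeatureTable
        Patients × features with binary labels (1 = HGSC).
    plan : ResamplePlan
        Resampling design (100 stratified 8:2 splits by default).
    filter_config : FilterConfig
        Mann-Whitney prefilter level (α = .05 two-sided by default).
    target_fraction, target_k
        Retention rule: top ``ceil(target_fraction × pool)`` of the
        ever-selected pool, capped at ``target_k`` (10% / 20 by default).
    coef_average : {"all", "selected"}
        Average coefficients over all resamples (zeros included; default)
        or only over resamples where the feature was selected.
    """

    def __init__(
        self,
        table: FeatureTable,
        plan: ResamplePlan | None = None,
        filter_config: FilterConfig | None = None,
        target_fraction: float = 0.10,
        target_k: int = 20,
        coef_average: str = "all",
    ):
        if table.n_features < 2:
            raise ValueError("need at least 2 features")
        classes = np.unique(table.y)
        if len(classes) < 2:
            raise ValueError("both classes must be present")
        if coef_average not in ("all", "selected"):
            raise ValueError("coef_average must be 'all' or 'selected'")
        self.table = table
        self.plan = plan or ResamplePlan()
        self.filter_config = filter_config or FilterConfig()
        self.target_fraction = target_fraction
        self.target_k = target_k
        self.coef_average = coef_average

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label", **kwargs):
        return cls(FeatureTable.from_dataframe(df, label_col), **kwargs)

    def fit(self) -> "VotedLassoResults":
        X = self.table.X
        y = self.table.y
        names = np.asarray(self.table.feature_names)
        p = len(names)
        alpha = self.filter_config.alpha
        seeds = self.plan.resample_seeds

        freq = np.zeros(p, dtype=int)
        coef_sum = np.zeros(p)
        abs_coef_sum = np.zeros(p)
        records: list[ResampleRecord] = []
        warned_constant = False

        for r, seed in enumerate(seeds):
            tr, te = stratified_split(y, self.plan.train_fraction, int(seed))
            Xtr, ytr = X[tr], y[tr]
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            keep = sd > 0
            if not keep.all() and not warned_constant:
                warnings.warn(
                    f"{(~keep).sum()} constant column(s) on a training "
                    "resample were dropped from selection",
                    stacklevel=2,
                )
                warned_constant = True
            Z = (Xtr[:, keep] - mu[keep]) / sd[keep]

            pvals = _mwu_filter_pvalues(Z, ytr)
            surv_local = np.flatnonzero(pvals < alpha)
            surv_global = np.flatnonzero(keep)[surv_local]
            record = ResampleRecord(
                train_idx=tr,
                test_idx=te,
                survivors=list(names[surv_global]),
                selected={},
                lam=float("nan"),
            )
            if surv_local.size > 0:
                coefs, lam = lasso_fit(
                    Z[:, surv_local], ytr, family="logistic", seed=int(seed)
                )
                record.lam = lam
                nz = np.flatnonzero(coefs != 0.0)
                sel_global = surv_global[nz]
                freq[sel_global] += 1
                coef_sum[sel_global] += coefs[nz]
                abs_coef_sum[sel_global] += np.abs(coefs[nz])
                record.selected = dict(zip(names[sel_global], coefs[nz].tolist()))
            records.append(record)

        pool = np.flatnonzero(freq > 0)
        if pool.size == 0:
            raise ValueError(
                "no feature was ever selected by LASSO across the resamples"
            )

        if self.coef_average == "all":
            wbar = coef_sum / self.plan.n_resamples
        else:
            wbar = np.where(freq > 0, coef_sum / np.maximum(freq, 1), 0.0)

        # rank: frequency desc, mean |coefficient| desc, name asc
        mean_abs = abs_coef_sum / self.plan.n_resamples
        order = sorted(
            pool.tolist(), key=lambda j: (-freq[j], -mean_abs[j], names[j])
        )
        k = retention_count(pool.size, self.target_fraction, self.target_k)
        retained = [names[j] for j in order[:k]]

        return VotedLassoResults(
            model=self,
            feature_names=list(names),
            frequencies=pd.Series(freq, index=names, name="frequency"),
            avg_coefficients=pd.Series(wbar, index=names, name="avg_coefficient"),
            retained=retained,
            records=records,
            pooled_mean=pd.Series(X.mean(axis=0), index=names),
            pooled_sd=pd.Series(X.std(axis=0), index=names),
        )


@dataclass
class VotedLassoResults:
    """Fitted voted-LASSO state: votes, averaged coefficients, retained set.

    Averaged coefficients live on the standardized feature scale; the
    pooled mean/SD stored here let radscores be computed for new patients
    without refitting.
    """

    model: VotedLassoModel
    feature_names: list[str]
    frequencies: pd.Series
    avg_coefficients: pd.Series
    retained: list[str]
    records: list[ResampleRecord]
    pooled_mean: pd.Series
    pooled_sd: pd.Series

    @property
    def n_resamples(self) -> int:
        return self.model.plan.n_resamples

    @property
    def pool(self) -> list[str]:
        """Features selected at least once."""
        return list(self.frequencies.index[self.frequencies > 0])

    def radscore(self, data, standardize: bool = True) -> np.ndarray:
        """Radscore per patient: Σ (standardized) feature × averaged
        coefficient over the retained set."""
        if isinstance(data, FeatureTable):
            df = data.data
        elif isinstance(data, pd.DataFrame):
            df = data
        else:
            df = pd.DataFrame(np.atleast_2d(data), columns=self.feature_names)
        missing = [f for f in self.retained if f not in df.columns]
        if missing:
            raise KeyError(f"radscore: missing retained feature(s) {missing}")
        vals = df[self.retained].to_numpy(dtype=float)
        if standardize:
            mu = self.pooled_mean[self.retained].to_numpy()
            sd = self.pooled_sd[self.retained].to_numpy()
            sd = np.where(sd > 0, sd, 1.0)
            vals = (vals - mu) / sd
        w = self.avg_coefficients[self.retained].to_numpy()
        return vals @ w

    def frequency_table(self) -> pd.DataFrame:
        """Ever-selected features ranked by vote count (descending)."""
        df = pd.DataFrame(
            {
                "frequency": self.frequencies,
                "avg_coefficient": self.avg_coefficients,
            }
        )
        df = df[df["frequency"] > 0].sort_values(
            ["frequency", "avg_coefficient"], ascending=[False, False]
        )
        df["retained"] = df.index.isin(self.retained)
        return df

    def summary(self) -> str:
        lines = [
            "Voted LASSO selection",
            "=" * 56,
            f"resamples: {self.n_resamples}  "
            f"train fraction: {self.model.plan.train_fraction}",
            f"ever-selected pool: {len(self.pool)} of "
            f"{len(self.feature_names)} features",
            f"retained: {len(self.retained)} "
            f"(top {self.model.target_fraction:.0%}, cap {self.model.target_k})",
            "-" * 56,
            f"{'feature':<32}{'votes':>6}{'avg coef':>12}",
        ]
        for name in self.retained:
            lines.append(
                f"{name:<32}{self.frequencies[name]:>6d}"
                f"{self.avg_coefficients[name]:>12.4f}"
            )
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "n_resamples": self.n_resamples,
            "base_seed": self.model.plan.base_seed,
            "train_fraction": self.model.plan.train_fraction,
            "frequencies": {
                k: int(v) for k, v in self.frequencies.items() if v > 0
            },
            "avg_coefficients": {
                k: float(self.avg_coefficients[k]) for k in self.pool
            },
            "retained": self.retained,
            "pooled_mean": {k: float(self.pooled_mean[k]) for k in self.retained},
            "pooled_sd": {k: float(self.pooled_sd[k]) for k in self.retained},
            "lambda_per_resample": [r.lam for r in self.records],
        }
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def voted_lasso(
    table: FeatureTable,
    plan: ResamplePlan | None = None,
    filter_config: FilterConfig | None = None,
    target_fraction: float = 0.10,
    target_k: int = 20,
    coef_average: str = "all",
) -> VotedLassoResults:
    """Functional wrapper: build a :class:`VotedLassoModel` and fit it."""
    return VotedLassoModel(
        table,
        plan=plan,
        filter_config=filter_config,
        target_fraction=target_fraction,
        target_k=target_k,
        coef_average=coef_average,
    ).fit()


def radscore(features, result: VotedLassoResults) -> float:
    """Radscore of one patient: Σ x_j · w̄_j over the retained features.

    ``features`` maps feature name → value (a dict or pandas Series).
    Values are used as given (no standardization); see
    :meth:`VotedLassoResults.radscore` for the standardized pipeline path.
    """
    if not isinstance(features, pd.Series):
        features = pd.Series(dict(features))
    missing = [f for f in result.retained if f not in features.index]
    if missing:
        raise KeyError(f"radscore: missing retained feature(s) {missing}")
    w = result.avg_coefficients[result.retained].to_numpy()
    x = features[result.retained].to_numpy(dtype=float)
    return float(x @ w)
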