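"""Feature tables: the labeled patients × features container, a simulator
with planted discriminative features, and the packaged cohort-composition
table of the multicenter study (4 centers, 665 patients, 65.6% HGSC)."""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "TableSimConfig",
    "simulate_feature_table",
    "CohortTableFixture",
    "cohort_table_fixture",
]


@dataclass
class FeatureTable:
    """Patients × named radiomic features plus a binary subtype label.

    ``data`` holds one row per patient (index = patient id) with float
    feature columns; ``labels`` is aligned with ``data`` and contains
    0 (non-HGSC) / 1 (HGSC).
    """

    data: pd.DataFrame
    labels: pd.Series
    informative: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.data.index.equals(self.labels.index):
            raise ValueError("data and labels must share the same patient index")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if self.data.isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_patients(self) -> int:
        return len(self.data)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels.to_numpy(dtype=int)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label"):
        if label_col not in df.columns:
            raise ValueError(f"missing {label_col!r} column")
        labels = df[label_col].astype(int)
        return cls(df.drop(columns=[label_col]).astype(float), labels)

    @classmethod
    def from_csv(cls, path: str | Path, label_col: str = "label"):
        df = pd.read_csv(path, index_col="patient_id")
        return cls.from_dataframe(df, label_col)

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "label", self.labels)
        out.index.name = "patient_id"
        out.to_csv(path)


@dataclass
class TableSimConfig:
    """Simulation of a labeled feature table.

    Features are unit-variance, pairwise-equicorrelated Gaussians; the
    first ``n_informative`` features receive a standardized mean shift
    (``effect_sizes``) in the HGSC class, the rest are exchangeable nulls.
    Defaults emulate the study's table: 665 patients, 65.6% HGSC.
    """

    n_patients: int = 665
    n_features: int = 100
    prevalence: float = 0.656
    n_informative: int = 5
    effect_sizes: float | tuple[float, ...] = (1.0, 0.9, 0.8, 0.7, 0.6)
    correlation: float = 0.1
    exact_prevalence: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_informative > self.n_features:
            raise ValueError("n_informative exceeds n_features")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must be in [0, 1)")
        eff = np.atleast_1d(np.asarray(self.effect_sizes, dtype=float))
        if eff.size == 1:
            eff = np.repeat(eff, self.n_informative)
        if eff.size != self.n_informative:
            raise ValueError(
                f"{eff.size} effect sizes for {self.n_informative} "
                "informative features"
            )
        if not np.all(np.isfinite(eff)):
            raise ValueError("effect sizes must be finite")
        self._effects = eff


def simulate_feature_table(cfg: TableSimConfig) -> FeatureTable:
    """Draw a labeled feature table per the configuration.

    With ``exact_prevalence`` the positive count is ``round(n × prevalence)``
    in a random order; otherwise labels are Bernoulli draws (redrawn, then
    rejected, if a tiny sample comes out single-class).
    """
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_patients, cfg.n_features

    if cfg.exact_prevalence:
        n_pos = int(round(n * cfg.prevalence))
        if n_pos <= 0 or n_pos >= n:
            raise ValueError(
                f"prevalence {cfg.prevalence} with n={n} gives a "
                "single-class cohort"
            )
        y = np.zeros(n, dtype=int)
        y[:n_pos] = 1
        y = y[rng.permutation(n)]
    else:
        for _ in range(10):
            y = (rng.random(n) < cfg.prevalence).astype(int)
            if 0 < y.sum() < n:
                break
        else:
            raise ValueError("could not draw a two-class label vector")

    rho = cfg.correlation
    shared = rng.standard_normal((n, 1))
    noise = rng.standard_normal((n, p))
    X = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise

    X[y == 1, : cfg.n_informative] += cfg._effects[None, :]

    names = [f"f{j:04d}" for j in range(1, p + 1)]
    ids = [f"P{i:04d}" for i in range(1, n + 1)]
    data = pd.DataFrame(X, index=pd.Index(ids, name="patient_id"), columns=names)
    labels = pd.Series(y, index=data.index, name="label")
    return FeatureTable(data, labels, informative=names[: cfg.n_informative])


@dataclass
class CohortTableFixture:
    """The study's cohort-composition table: per-center patient counts by
    histologic subtype (HGSC vs non-HGSC, the latter split into clear
    cell (CCC), mucinous (MC), low-grade serous (LGSC) and endometrioid
    (EC) carcinoma)."""

    table: pd.DataFrame

    CENTERS = ["center_a", "center_b", "center_c", "center_d"]
    SUBTYPES = ["ccc", "mc", "lgsc", "ec"]

    def __post_init__(self):
        t = self.table
        if (t.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        for col in ["total"] + self.CENTERS:
            if t.loc["hgsc", col] + t.loc["non_hgsc", col] != t.loc["patients", col]:
                raise ValueError(f"subtype counts do not sum to total in {col}")
            if t.loc[self.SUBTYPES, col].sum() != t.loc["non_hgsc", col]:
                raise ValueError(f"non-HGSC subtypes do not sum in {col}")
        if t.loc["patients", self.CENTERS].sum() != t.loc["patients", "total"]:
            raise ValueError("center totals do not sum to the cohort total")

    @property
    def n_patients(self) -> int:
        return int(self.table.loc["patients", "total"])

    @property
    def hgsc_fraction(self) -> float:
        return float(self.table.loc["hgsc", "total"]) / self.n_patients


def cohort_table_fixture() -> CohortTableFixture:
    """Load the packaged cohort table (counts as printed by the study)."""
    ref = importlib.resources.files("ovradiomics").joinpath(
        "data/cohort_table.csv"
    )
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, index_col="characteristic")
    return CohortTableFixture(df.astype(int))
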