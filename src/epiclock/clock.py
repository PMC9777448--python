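"""Ridge-regression epigenetic age clock on CpG-unit M-values.

The clock regresses chronological age on the standardized M-values of all CpG
units of the targeted assay, with an L2 (ridge) penalty chosen by age-balanced
k-fold cross-validation, training on reference samples in a fixed age window
(default 20–80 years, where blood methylation drifts approximately linearly
with age).  The fitted model extrapolates freely outside the training window —
deliberately, since centenarian samples fall well above it.

`MethylationAgeClock` is a scikit-learn estimator: ``fit(X, y)`` takes a
complete samples × units beta DataFrame and chronological ages, ``predict(X)``
returns epigenetic ages in years.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Ridge
from sklearn.utils.validation import check_is_fitted

from .io import MethylationMatrix, SampleSheet
from .preprocess import beta_to_m

__all__ = [
    "ClockConfig",
    "FitReport",
    "MethylationAgeClock",
    "age_balanced_folds",
    "accuracy_metrics",
    "train_clock",
    "predict_age",
    "save_clock",
    "load_clock",
]

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-4, 4, 25))


@dataclass
class ClockConfig:
    """Training settings: age window, CV layout and the ridge penalty grid."""

    age_min: float = 20.0
    age_max: float = 80.0
    k_folds: int = 5
    age_bin_width: float = 10.0
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    eps: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.age_min >= self.age_max:
            raise ValueError("age_min must be < age_max")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        grid = np.asarray(self.lambda_grid, dtype=float)
        if grid.size == 0 or np.any(grid <= 0):
            raise ValueError("lambda_grid must be non-empty and positive")


@dataclass
class FitReport:
    """Cross-validation metrics at the selected penalty, plus training-set fit."""

    fold_spearman: list[float]
    fold_mad_median: list[float]
    fold_mad_mean: list[float]
    fold_n_train: list[int]
    fold_n_test: list[int]
    cv_spearman: float
    cv_mad_median: float
    cv_mad_mean: float
    train_spearman: float
    train_mad_median: float
    train_mad_mean: float
    training_predictions: pd.Series  # final-model predictions on training samples
    selected_lambda: float
    n_samples: int

    def summary(self) -> str:
        return (
            f"n={self.n_samples} lambda={self.selected_lambda:.4g} | "
            f"CV rho={self.cv_spearman:.3f} MAD(median)={self.cv_mad_median:.2f}y "
            f"MAD(mean)={self.cv_mad_mean:.2f}y | "
            f"train rho={self.train_spearman:.3f} MAD(median)={self.train_mad_median:.2f}y"
        )


def age_balanced_folds(
    ages, k_folds: int = 5, age_bin_width: float = 10.0, seed: int = 0
) -> list[np.ndarray]:
    """Partition sample indices into k folds balanced over age bins.

    Samples are binned by ``floor(age / age_bin_width)``; within each bin the
    members are shuffled (seeded) and dealt round-robin across folds, with the
    starting fold rotating between bins so overall fold sizes stay even.  Every
    bin therefore contributes to each fold a count differing by at most one.
    """
    ages = np.asarray(ages, dtype=float)
    n = ages.size
    if n < k_folds:
        raise ValueError(f"cannot make {k_folds} folds from {n} samples")
    rng = np.random.default_rng(seed)
    bins = np.floor(ages / age_bin_width).astype(int)
    folds: list[list[int]] = [[] for _ in range(k_folds)]
    offset = 0
    for b in np.unique(bins):
        members = np.flatnonzero(bins == b)
        members = members[rng.permutation(members.size)]
        for i, idx in enumerate(members):
            folds[(offset + i) % k_folds].append(int(idx))
        offset = (offset + members.size) % k_folds
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def accuracy_metrics(pred, chrono) -> dict[str, float]:
    """Spearman correlation and absolute-deviation summaries, in years.

    Returns ``spearman_rho`` (midrank ties), ``mad_median`` (median absolute
    deviation between predicted and chronological age) and ``mad_mean`` (mean
    absolute deviation).
    """
    pred = np.asarray(pred, dtype=float)
    chrono = np.asarray(chrono, dtype=float)
    if pred.shape != chrono.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {chrono.shape}")
    if pred.size < 3:
        raise ValueError("need at least 3 samples")
    rho = stats.spearmanr(pred, chrono).statistic
    err = np.abs(pred - chrono)
    return {
        "spearman_rho": float(rho),
        "mad_median": float(np.median(err)),
        "mad_mean": float(np.mean(err)),
    }


class MethylationAgeClock(RegressorMixin, BaseEstimator):
    """Ridge-regression age predictor on standardized CpG-unit M-values.

    Parameters
    ----------
    age_min, age_max : float
        Training age window in years; samples outside it are excluded from
        fitting (predictions are unrestricted).
    k_folds : int
        Folds for the age-balanced cross-validation that selects the penalty.
    age_bin_width : float
        Width in years of the stratification bins.
    lambda_grid : sequence of float
        Candidate ridge penalties; the one minimizing mean CV squared error
        is kept and the model refit on all retained samples.
    eps : float
        Logit clipping bound for the beta → M transform.
    seed : int
        Seeds the fold shuffling.

    Attributes
    ----------
    unit_ids_ : list of predictor CpG-unit names
    coef_ : ndarray, weight per unit applied to standardized M-values
    intercept_ : float, years
    unit_means_, unit_sds_ : ndarray, standardization parameters in M space
    lambda_ : float, selected penalty
    training_age_range_ : (float, float)
    fit_report_ : FitReport
    """

    def __init__(
        self,
        age_min: float = 20.0,
        age_max: float = 80.0,
        k_folds: int = 5,
        age_bin_width: float = 10.0,
        lambda_grid=DEFAULT_LAMBDA_GRID,
        eps: float = 0.001,
        seed: int = 0,
    ):
        self.age_min = age_min
        self.age_max = age_max
        self.k_folds = k_folds
        self.age_bin_width = age_bin_width
        self.lambda_grid = lambda_grid
        self.eps = eps
        self.seed = seed

    # ------------------------------------------------------------------ fit

    def fit(self, X, y) -> "MethylationAgeClock":
        X, unit_ids, sample_ids = self._coerce_X(X)
        y = np.asarray(y, dtype=float)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have different numbers of samples")
        if np.isnan(X).any():
            raise ValueError("beta matrix must be complete (impute first)")

        keep = (y >= self.age_min) & (y <= self.age_max)
        X, y = X[keep], y[keep]
        sample_ids = [s for s, k in zip(sample_ids, keep) if k]
        n = y.size
        if n < 10:
            raise ValueError(f"only {n} samples inside the training age window")
        if np.var(y) == 0:
            raise ValueError("chronological age has zero variance")

        M = beta_to_m(X, eps=self.eps)
        sds = M.std(axis=0, ddof=0)
        zero_var = sds <= 1e-9  # tolerate float noise around a constant column
        if zero_var.any():
            dropped = [u for u, z in zip(unit_ids, zero_var) if z]
            warnings.warn(f"dropping zero-variance units: {dropped}")
            M = M[:, ~zero_var]
            unit_ids = [u for u, z in zip(unit_ids, zero_var) if not z]

        grid = np.sort(np.asarray(self.lambda_grid, dtype=float))
        folds = age_balanced_folds(y, self.k_folds, self.age_bin_width, self.seed)
        cv_mse = np.zeros(grid.size)
        fold_preds: dict[float, list[np.ndarray]] = {lam: [] for lam in grid}
        for test_idx in folds:
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            mu = M[train_idx].mean(axis=0)
            sd = M[train_idx].std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            Ztr = (M[train_idx] - mu) / sd
            Zte = (M[test_idx] - mu) / sd
            for j, lam in enumerate(grid):
                ridge = Ridge(alpha=lam, fit_intercept=True)
                ridge.fit(Ztr, y[train_idx])
                pred = ridge.predict(Zte)
                cv_mse[j] += np.sum((pred - y[test_idx]) ** 2)
                fold_preds[lam].append(pred)
        best = int(np.argmin(cv_mse))  # first minimum -> smallest lambda on ties
        lam = float(grid[best])

        # final refit on all retained samples at the chosen penalty
        self.unit_means_ = M.mean(axis=0)
        self.unit_sds_ = M.std(axis=0, ddof=0)
        self.unit_sds_[self.unit_sds_ == 0] = 1.0
        Z = (M - self.unit_means_) / self.unit_sds_
        ridge = Ridge(alpha=lam, fit_intercept=True)
        ridge.fit(Z, y)
        self.coef_ = ridge.coef_.astype(float)
        self.intercept_ = float(ridge.intercept_)
        self.unit_ids_ = list(unit_ids)
        self.lambda_ = lam
        self.training_age_range_ = (float(self.age_min), float(self.age_max))
        self.n_features_in_ = len(unit_ids)

        fold_rho, fold_mmed, fold_mmean, n_tr, n_te = [], [], [], [], []
        for test_idx, pred in zip(folds, fold_preds[lam]):
            met = accuracy_metrics(pred, y[test_idx])
            fold_rho.append(met["spearman_rho"])
            fold_mmed.append(met["mad_median"])
            fold_mmean.append(met["mad_mean"])
            n_te.append(int(test_idx.size))
            n_tr.append(int(n - test_idx.size))
        train_pred = Z @ self.coef_ + self.intercept_
        train_met = accuracy_metrics(train_pred, y)
        self.fit_report_ = FitReport(
            fold_spearman=fold_rho,
            fold_mad_median=fold_mmed,
            fold_mad_mean=fold_mmean,
            fold_n_train=n_tr,
            fold_n_test=n_te,
            cv_spearman=float(np.mean(fold_rho)),
            cv_mad_median=float(np.mean(fold_mmed)),
            cv_mad_mean=float(np.mean(fold_mmean)),
            train_spearman=train_met["spearman_rho"],
            train_mad_median=train_met["mad_median"],
            train_mad_mean=train_met["mad_mean"],
            training_predictions=pd.Series(train_pred, index=sample_ids),
            selected_lambda=lam,
            n_samples=n,
        )
        return self

    # -------------------------------------------------------------- predict

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X, unit_ids, _ = self._coerce_X(X)
        if unit_ids != self.unit_ids_:
            index = {u: j for j, u in enumerate(unit_ids)}
            missing = [u for u in self.unit_ids_ if u not in index]
            if missing:
                raise ValueError(f"input is missing model units: {missing}")
            X = X[:, [index[u] for u in self.unit_ids_]]
        M = beta_to_m(X, eps=self.eps)
        Z = (M - self.unit_means_) / self.unit_sds_
        return Z @ self.coef_ + self.intercept_

    @staticmethod
    def _coerce_X(X) -> tuple[np.ndarray, list[str], list[str]]:
        if isinstance(X, MethylationMatrix):
            X = X.beta
        if isinstance(X, pd.DataFrame):
            return (
                X.to_numpy(dtype=float),
                [str(c) for c in X.columns],
                [str(i) for i in X.index],
            )
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        return (
            arr,
            [f"x{j}" for j in range(arr.shape[1])],
            [str(i) for i in range(arr.shape[0])],
        )

    # -------------------------------------------------------- serialization

    def to_json(self) -> str:
        check_is_fitted(self, "coef_")
        doc = {
            "format": "epiclock-model",
            "version": 1,
            "unit_ids": self.unit_ids_,
            "coef": list(map(float, self.coef_)),
            "intercept": self.intercept_,
            "unit_means": list(map(float, self.unit_means_)),
            "unit_sds": list(map(float, self.unit_sds_)),
            "lambda": self.lambda_,
            "training_age_range": list(self.training_age_range_),
            "eps": self.eps,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MethylationAgeClock":
        doc = json.loads(text)
        if doc.get("format") != "epiclock-model":
            raise ValueError("not a clock model file")
        lo, hi = doc["training_age_range"]
        model = cls(age_min=lo, age_max=hi, eps=doc["eps"])
        model.unit_ids_ = list(doc["unit_ids"])
        model.coef_ = np.array(doc["coef"], dtype=float)
        model.intercept_ = float(doc["intercept"])
        model.unit_means_ = np.array(doc["unit_means"], dtype=float)
        model.unit_sds_ = np.array(doc["unit_sds"], dtype=float)
        model.lambda_ = float(doc["lambda"])
        model.training_age_range_ = (float(lo), float(hi))
        model.n_features_in_ = len(model.unit_ids_)
        return model


# ------------------------------------------------------ functional wrappers


def train_clock(
    m: MethylationMatrix, sheet: SampleSheet, cfg: ClockConfig | None = None
) -> tuple[MethylationAgeClock, FitReport]:
    """Fit the clock on a complete beta matrix and matching sample sheet."""
    cfg = cfg or ClockConfig()
    clock = MethylationAgeClock(
        age_min=cfg.age_min,
        age_max=cfg.age_max,
        k_folds=cfg.k_folds,
        age_bin_width=cfg.age_bin_width,
        lambda_grid=cfg.lambda_grid,
        eps=cfg.eps,
        seed=cfg.seed,
    )
    ages = sheet.table.loc[m.sample_ids, "age"].to_numpy(dtype=float)
    clock.fit(m.beta, ages)
    return clock, clock.fit_report_


def predict_age(model: MethylationAgeClock, m: MethylationMatrix) -> pd.Series:
    """Epigenetic age (years) per sample, indexed by sample id."""
    return pd.Series(model.predict(m.beta), index=m.sample_ids, name="epigenetic_age")


def save_clock(model: MethylationAgeClock, path: str | Path) -> None:
    Path(path).write_text(model.to_json())


def load_clock(path: str | Path) -> MethylationAgeClock:
    return MethylationAgeClock.from_json(Path(path).read_text())
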