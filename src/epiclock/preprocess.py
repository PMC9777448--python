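"""Missing-value imputation and beta ↔ M-value conversion.

Targeted bisulfite assays report beta-values (fraction methylated, in [0, 1])
with sporadic dropouts.  The pipeline fills missing entries by chained-equations
regression imputation in beta space, then converts to M-values,
``M = log2(b / (1 - b))``, the approximately homoscedastic scale on which the
age model is fit.  The logit is undefined at 0 and 1, so betas are clipped to
``[eps, 1 - eps]`` first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import LinearRegression

from .io import MethylationMatrix

__all__ = [
    "PreprocessConfig",
    "ImputationError",
    "beta_to_m",
    "m_to_beta",
    "ChainedEquationsImputer",
    "impute_missing",
    "matrix_to_m",
]


class ImputationError(ValueError):
    """Imputation cannot proceed (e.g. every unit was dropped)."""


@dataclass
class PreprocessConfig:
    """Settings for imputation and the logit transform.

    eps:
        Clipping bound applied to beta before the log2-odds transform
        (the transform diverges at 0 and 1).
    max_missing_fraction_unit:
        Units missing in more than this fraction of samples are dropped
        rather than imputed.
    imputation_iterations:
        Number of chained-equation sweeps over the incomplete units.
    """

    eps: float = 0.001
    max_missing_fraction_unit: float = 0.3
    imputation_iterations: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.eps < 0.5:
            raise ValueError("eps must be in (0, 0.5)")
        if not 0 <= self.max_missing_fraction_unit <= 1:
            raise ValueError("max_missing_fraction_unit must be in [0, 1]")
        if self.imputation_iterations < 1:
            raise ValueError("imputation_iterations must be >= 1")


def beta_to_m(beta, eps: float = 0.001):
    """Convert beta-values to M-values: ``log2(b / (1 - b))`` after clipping.

    Accepts scalars or arrays; strictly increasing on ``(eps, 1 - eps)``.
    Raises for values outside [0, 1] (NaN passes through as NaN).
    """
    b = np.asarray(beta, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (b < 0) | (b > 1)
    if np.any(bad):
        raise ValueError(f"beta value outside [0, 1]: {b[bad].flat[0]!r}")
    clipped = np.clip(b, eps, 1 - eps)
    m = np.log2(clipped / (1 - clipped))
    return m if np.ndim(beta) else float(m)


def m_to_beta(m):
    """Inverse logit: ``beta = 2**M / (1 + 2**M)``; maps R to (0, 1)."""
    arr = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(arr) | np.isnan(arr)):
        raise ValueError("M-values must be finite")
    # numerically symmetric form avoids overflow for large |M|
    with np.errstate(over="ignore"):
        beta = 1.0 / (1.0 + np.exp2(-arr))
    return beta if np.ndim(m) else float(beta)


class ChainedEquationsImputer(TransformerMixin, BaseEstimator):
    """Single-dataset chained-equations imputation of beta matrices.

    Units whose missing fraction exceeds ``max_missing_fraction_unit`` are
    dropped.  Remaining missing entries are initialized with unit means, then a
    fixed number of sweeps regresses each incomplete unit on all other units
    (ordinary least squares over the rows where the unit is observed) and
    replaces its missing entries with the predictions, clipped to [0, 1].
    Observed entries are never modified.  Deterministic given the inputs.

    Parameters
    ----------
    max_missing_fraction_unit : float, default 0.3
    n_sweeps : int, default 5
    seed : int, default 0
        Recorded for provenance; the least-squares sweep itself is
        deterministic.

    Attributes
    ----------
    kept_units_ : list of unit ids retained
    dropped_units_ : dict mapping dropped unit id -> missing fraction
    """

    def __init__(
        self,
        max_missing_fraction_unit: float = 0.3,
        n_sweeps: int = 5,
        seed: int = 0,
    ):
        self.max_missing_fraction_unit = max_missing_fraction_unit
        self.n_sweeps = n_sweeps
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None) -> "ChainedEquationsImputer":
        X = self._as_frame(X)
        if X.shape[1] < 2 or (X.notna().any(axis=1).sum()) < 3:
            raise ImputationError("need at least 2 units and 3 samples with data")
        frac = X.isna().mean(axis=0)
        self.dropped_units_ = {
            str(u): float(f)
            for u, f in frac.items()
            if f > self.max_missing_fraction_unit
        }
        self.kept_units_ = [u for u in X.columns if u not in self.dropped_units_]
        if not self.kept_units_:
            raise ImputationError("all units exceed the missing-fraction threshold")
        self._imputer_ = IterativeImputer(
            estimator=LinearRegression(),
            max_iter=self.n_sweeps,
            tol=1e-12,
            initial_strategy="mean",
            imputation_order="ascending",
            sample_posterior=False,
            min_value=0.0,
            max_value=1.0,
            random_state=self.seed,
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = self._as_frame(X)
        kept = X[self.kept_units_]
        if kept.isna().to_numpy().any():
            import warnings

            with warnings.catch_warnings():
                # fixed number of sweeps by design; the tol criterion is moot
                warnings.filterwarnings(
                    "ignore", message=r".*Early stopping criterion not reached.*"
                )
                filled = self._imputer_.fit_transform(kept.to_numpy(dtype=float))
        else:
            filled = kept.to_numpy(dtype=float)
        out = pd.DataFrame(filled, index=kept.index, columns=kept.columns)
        # observed entries must survive bit-identically
        out = out.where(kept.isna(), kept)
        return out

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, MethylationMatrix):
            return X.beta
        return pd.DataFrame(X)


def impute_missing(
    m: MethylationMatrix, cfg: PreprocessConfig | None = None
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Impute a beta matrix; returns the completed matrix and a per-unit report.

    The report has one row per unit with its missing fraction and the action
    taken (``kept`` / ``dropped``).
    """
    cfg = cfg or PreprocessConfig()
    imputer = ChainedEquationsImputer(
        max_missing_fraction_unit=cfg.max_missing_fraction_unit,
        n_sweeps=cfg.imputation_iterations,
        seed=cfg.seed,
    )
    completed = imputer.fit(m.beta).transform(m.beta)
    frac = m.beta.isna().mean(axis=0)
    report = pd.DataFrame(
        {
            "unit_id": [str(u) for u in m.beta.columns],
            "missing_fraction": [float(frac[u]) for u in m.beta.columns],
            "action": [
                "dropped" if str(u) in imputer.dropped_units_ else "kept"
                for u in m.beta.columns
            ],
        }
    )
    return MethylationMatrix(completed), report


def matrix_to_m(m: MethylationMatrix, eps: float = 0.001) -> pd.DataFrame:
    """M-value DataFrame of a (complete) beta matrix."""
    return pd.DataFrame(
        beta_to_m(m.beta.to_numpy(dtype=float), eps=eps),
        index=m.beta.index,
        columns=m.beta.columns,
    )
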