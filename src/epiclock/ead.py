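"""Epigenetic age discrepancy (EAD) and group/intervention comparisons.

EAD is a sample's residual from the ordinary-least-squares regression of
epigenetic age on chronological age fit in a reference group:

    EAD_i = epigenetic_age_i − (intercept + slope · chronological_age_i)

Positive values mean epigenetically older than expected for one's age,
negative values younger.  The reference line is fit once (e.g. on controls
aged 20–80, or on the baseline timepoint of an intervention cohort) and
applied unchanged to every group, including ages far outside the reference
range.  By the OLS residual property the mean EAD over the reference samples
themselves is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "EADReference",
    "GroupComparison",
    "fit_ead_reference",
    "compute_ead",
    "compare_groups",
    "intervention_delta",
]

EXACT_RANKSUM_MAX_N = 12


class EADReference(BaseEstimator):
    """OLS line of epigenetic age on chronological age in a reference group.

    Attributes (after ``fit``)
    --------------------------
    slope_ : float (dimensionless)
    intercept_ : float (years)
    n_ref_ : int, samples used for the fit
    """

    def __init__(self, reference_label: str = "reference"):
        self.reference_label = reference_label

    def fit(self, chrono, pred) -> "EADReference":
        chrono = np.asarray(chrono, dtype=float)
        pred = np.asarray(pred, dtype=float)
        if chrono.size != pred.size:
            raise ValueError("chronological and epigenetic ages differ in length")
        if chrono.size < 3:
            raise ValueError("need at least 3 reference samples")
        if np.var(chrono) == 0:
            raise ValueError("chronological age has zero variance in the reference")
        res = stats.linregress(chrono, pred)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.n_ref_ = int(chrono.size)
        return self

    def residuals(self, chrono, pred) -> np.ndarray:
        """Signed EAD in years for arbitrary samples (extrapolation allowed)."""
        chrono = np.asarray(chrono, dtype=float)
        pred = np.asarray(pred, dtype=float)
        return pred - (self.intercept_ + self.slope_ * chrono)


def fit_ead_reference(pred, chrono, label: str = "reference") -> EADReference:
    """Fit the reference regression (epigenetic age ~ chronological age)."""
    return EADReference(reference_label=label).fit(chrono, pred)


def compute_ead(
    ref: EADReference, pred: pd.Series, chrono: pd.Series
) -> pd.DataFrame:
    """Per-sample EAD table with epigenetic and chronological ages.

    ``pred`` and ``chrono`` must share an index of sample ids (or be
    positionally aligned arrays).
    """
    pred = pd.Series(pred)
    chrono = pd.Series(np.asarray(chrono, dtype=float), index=pred.index)
    ead = ref.residuals(chrono.to_numpy(), pred.to_numpy())
    return pd.DataFrame(
        {
            "sample_id": pred.index.astype(str),
            "epigenetic_age": pred.to_numpy(dtype=float),
            "chronological_age": chrono.to_numpy(),
            "ead": ead,
        }
    ).set_index("sample_id", drop=False)


@dataclass
class GroupComparison:
    """Result of a two-group location test on EAD values."""

    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    degenerate: bool = False


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided exact rank-sum test by full enumeration with midranks.

    Enumerates all assignments of the pooled values to a group of size
    ``len(a)``; the p-value is the fraction of assignments whose rank-sum
    deviates from its null mean at least as much as the observed one.  Handles
    ties through midranks, so identical multisets give p = 1 exactly.
    Returns (U statistic, p).
    """
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n = na + nb
    w_obs = ranks[:na].sum()
    center = na * (n + 1) / 2.0
    dev_obs = abs(w_obs - center)
    count = 0
    total = 0
    for idx in combinations(range(n), na):
        w = ranks[list(idx)].sum()
        if abs(w - center) >= dev_obs - 1e-9:
            count += 1
        total += 1
    u_obs = w_obs - na * (na + 1) / 2.0
    return float(u_obs), count / total


def compare_groups(ead_a, ead_b, test: str = "wilcoxon_ranksum") -> GroupComparison:
    """Two-sided two-group comparison of EAD values.

    Tests
    -----
    ``wilcoxon_ranksum``
        Wilcoxon–Mann–Whitney.  Exact enumeration when the combined size is
        at most 12; tie-corrected normal approximation with continuity
        correction otherwise.
    ``welch_t``
        Welch's unequal-variance t-test (Satterthwaite degrees of freedom).
    ``paired_t``
        Student's paired t-test; requires equal lengths with aligned subjects.
    """
    a = np.asarray(ead_a, dtype=float)
    b = np.asarray(ead_b, dtype=float)
    base = dict(
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
    )
    if test == "paired_t":
        if a.size != b.size:
            raise ValueError("paired test requires equal-length, aligned groups")
        if a.size < 2:
            raise ValueError("need at least 2 pairs")
        diff = a - b
        if np.var(diff) == 0:
            return GroupComparison(
                test=test, statistic=float("nan"), p_value=float("nan"),
                degenerate=True, **base,
            )
        res = stats.ttest_rel(a, b)
        return GroupComparison(
            test=test, statistic=float(res.statistic), p_value=float(res.pvalue), **base
        )
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 samples")
    if test == "welch_t":
        res = stats.ttest_ind(a, b, equal_var=False)
        return GroupComparison(
            test=test, statistic=float(res.statistic), p_value=float(res.pvalue), **base
        )
    if test == "wilcoxon_ranksum":
        if a.size + b.size <= EXACT_RANKSUM_MAX_N:
            u, p = _exact_ranksum_p(a, b)
        else:
            res = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=True
            )
            u, p = float(res.statistic), float(res.pvalue)
        return GroupComparison(
            test=test, statistic=u, p_value=min(p, 1.0), **base
        )
    raise ValueError(f"unknown test {test!r}")


def intervention_delta(ead_t0, ead_t1, subjects=None) -> dict:
    """Paired before/after analysis of EAD values.

    Parameters
    ----------
    ead_t0, ead_t1:
        EAD values per subject at baseline and follow-up, either pandas Series
        indexed by subject id (paired on the index intersection; incomplete
        subjects dropped) or positionally aligned arrays.
    subjects:
        Optional explicit subject ids for positional inputs.

    Returns a dict with ``mean_delta`` (mean of T1 − T0 over paired subjects,
    years), the ``paired_t``, ``unpaired_wilcoxon`` and ``welch``
    comparisons (each T1 vs T0), ``n_pairs`` and the ``dropped`` subject ids.
    """
    if not isinstance(ead_t0, pd.Series):
        idx = subjects if subjects is not None else range(len(ead_t0))
        ead_t0 = pd.Series(np.asarray(ead_t0, dtype=float), index=idx)
    if not isinstance(ead_t1, pd.Series):
        idx = subjects if subjects is not None else range(len(ead_t1))
        ead_t1 = pd.Series(np.asarray(ead_t1, dtype=float), index=idx)
    shared = ead_t0.index.intersection(ead_t1.index)
    dropped = sorted(
        set(map(str, ead_t0.index)).symmetric_difference(set(map(str, ead_t1.index)))
    )
    if len(shared) == 0:
        raise ValueError("no subjects present at both timepoints")
    t0 = ead_t0.loc[shared].to_numpy(dtype=float)
    t1 = ead_t1.loc[shared].to_numpy(dtype=float)
    return {
        "mean_delta": float(np.mean(t1 - t0)),
        "paired_t": compare_groups(t1, t0, test="paired_t"),
        "unpaired_wilcoxon": compare_groups(t1, t0, test="wilcoxon_ranksum"),
        "welch": compare_groups(t1, t0, test="welch_t"),
        "n_pairs": int(len(shared)),
        "dropped": dropped,
    }
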