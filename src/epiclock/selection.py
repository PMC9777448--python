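"""Candidate-probe selection from Infinium-style methylation panels.

Given per-probe beta-values with ages and group labels, a probe is a candidate
for a biological-age clock if it (1) correlates with chronological age in an
aging reference set, (2) differs between an accelerated-aging case group and
its controls (e.g. Down-syndrome persons vs their siblings), (3) differs
between a decelerated-aging group and its controls (e.g. centenarians'
offspring vs age-matched controls), and (4) the three effect directions are
mutually consistent: probes gaining methylation with age should be higher in
the accelerated group and lower in the decelerated group, and vice versa.
Surviving probes are ranked by the summed magnitude of the two group
differences.  A relaxed path drops the second contrast, mirroring how extra
clock sites are often recruited from strong age/case signals alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "GroupedPanel",
    "SelectionCriteria",
    "CandidateProbe",
    "score_probes",
    "select_candidates",
    "relaxed_select",
    "ProbeSelector",
    "candidates_to_frame",
]


@dataclass
class GroupedPanel:
    """Samples × probes beta matrix with per-sample age and group label."""

    beta: pd.DataFrame
    ages: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.groups = np.asarray(self.groups, dtype=object)
        n = self.beta.shape[0]
        if self.ages.size != n or self.groups.size != n:
            raise ValueError("ages/groups length must match the number of samples")
        vals = self.beta.to_numpy(dtype=float)
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValueError("panel beta values must lie in [0, 1]")

    def mask(self, labels) -> np.ndarray:
        labels = {labels} if isinstance(labels, str) else set(labels)
        missing = labels - set(self.groups)
        if missing:
            raise KeyError(f"groups not present in panel: {sorted(missing)}")
        return np.isin(self.groups, list(labels))


@dataclass
class SelectionCriteria:
    """Nominal significance levels for the age and contrast filters."""

    alpha_age: float = 0.05
    alpha_contrast: float = 0.05
    require_both_contrasts: bool = True

    def __post_init__(self) -> None:
        for a in (self.alpha_age, self.alpha_contrast):
            if not 0 < a < 1:
                raise ValueError("significance levels must be in (0, 1)")


@dataclass
class CandidateProbe:
    """Per-probe selection statistics.

    ``delta_dsp`` is the case−control mean beta difference of the
    accelerated-aging contrast, ``delta_off`` of the decelerated one;
    ``rank_score`` = |delta_dsp| + |delta_off|.
    """

    probe_id: str
    rho_age: float
    p_age: float
    delta_dsp: float
    p_dsp: float
    delta_off: float
    p_off: float
    sign_consistent: bool
    rank_score: float
    degenerate: bool = False


def _contrast(x_case: np.ndarray, x_ctrl: np.ndarray, method: str) -> tuple[float, float]:
    delta = float(np.mean(x_case) - np.mean(x_ctrl))
    if method == "ranksum":
        res = stats.mannwhitneyu(x_case, x_ctrl, alternative="two-sided")
    elif method == "welch":
        res = stats.ttest_ind(x_case, x_ctrl, equal_var=False)
    else:
        raise ValueError(f"unknown contrast test {method!r}")
    return delta, float(res.pvalue)


def score_probes(
    panel: GroupedPanel,
    aging_groups,
    contrast1: tuple[str, str],
    contrast2: tuple[str, str],
    contrast_test: str = "ranksum",
) -> list[CandidateProbe]:
    """Score every probe: age correlation, two group contrasts, sign pattern.

    ``aging_groups`` selects the samples for the Spearman age correlation;
    ``contrast1``/``contrast2`` are (case, control) label pairs — conventionally
    the accelerated-aging contrast (DSP vs DSS) and the longevity contrast
    (OFF vs CTR).  Probes that are constant over all involved samples are
    returned with ``degenerate=True`` and NaN statistics.
    """
    age_mask = panel.mask(aging_groups)
    c1_case, c1_ctrl = panel.mask(contrast1[0]), panel.mask(contrast1[1])
    c2_case, c2_ctrl = panel.mask(contrast2[0]), panel.mask(contrast2[1])
    for name, msk in [("aging", age_mask), ("contrast1 case", c1_case),
                      ("contrast1 control", c1_ctrl), ("contrast2 case", c2_case),
                      ("contrast2 control", c2_ctrl)]:
        if msk.sum() < 3:
            raise ValueError(f"{name} group has fewer than 3 samples")

    out: list[CandidateProbe] = []
    ages = panel.ages[age_mask]
    for probe in panel.beta.columns:
        x = panel.beta[probe].to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            out.append(
                CandidateProbe(
                    probe_id=str(probe), rho_age=float("nan"), p_age=float("nan"),
                    delta_dsp=float("nan"), p_dsp=float("nan"),
                    delta_off=float("nan"), p_off=float("nan"),
                    sign_consistent=False, rank_score=float("nan"), degenerate=True,
                )
            )
            continue
        rho, p_age = stats.spearmanr(x[age_mask], ages)
        d1, p1 = _contrast(x[c1_case], x[c1_ctrl], contrast_test)
        d2, p2 = _contrast(x[c2_case], x[c2_ctrl], contrast_test)
        consistent = (rho > 0 and d1 > 0 and d2 < 0) or (rho < 0 and d1 < 0 and d2 > 0)
        out.append(
            CandidateProbe(
                probe_id=str(probe),
                rho_age=float(rho),
                p_age=float(p_age),
                delta_dsp=d1,
                p_dsp=p1,
                delta_off=d2,
                p_off=p2,
                sign_consistent=bool(consistent),
                rank_score=abs(d1) + abs(d2),
            )
        )
    return out


def _rank(probes: list[CandidateProbe]) -> list[CandidateProbe]:
    return sorted(probes, key=lambda c: (-c.rank_score, c.p_age, c.probe_id))


def select_candidates(
    scored: list[CandidateProbe], criteria: SelectionCriteria | None = None
) -> list[CandidateProbe]:
    """Full selection: age filter, both contrasts, sign consistency; ranked.

    Ranking is by ``rank_score`` descending, ties broken by the age p-value
    then the probe id.  An empty result is allowed.
    """
    criteria = criteria or SelectionCriteria()
    kept = [
        c
        for c in scored
        if not c.degenerate
        and c.sign_consistent
        and c.p_age < criteria.alpha_age
        and c.p_dsp < criteria.alpha_contrast
        and (not criteria.require_both_contrasts or c.p_off < criteria.alpha_contrast)
    ]
    return _rank(kept)


def relaxed_select(
    scored: list[CandidateProbe], criteria: SelectionCriteria | None = None
) -> list[CandidateProbe]:
    """Secondary path: age filter and the accelerated-aging contrast only.

    The direction requirement is reduced accordingly: the probe's age trend
    and its case−control difference must agree in sign (the second contrast
    is ignored).  Always a superset of :func:`select_candidates`.
    """
    criteria = criteria or SelectionCriteria()
    kept = [
        c
        for c in scored
        if not c.degenerate
        and np.sign(c.rho_age) == np.sign(c.delta_dsp)
        and c.rho_age != 0
        and c.p_age < criteria.alpha_age
        and c.p_dsp < criteria.alpha_contrast
    ]
    return _rank(kept)


def candidates_to_frame(probes: list[CandidateProbe]) -> pd.DataFrame:
    """Tabular view of scored or selected probes."""
    return pd.DataFrame([vars(c) for c in probes])


class ProbeSelector(BaseEstimator):
    """Estimator facade over the scoring/selection pipeline.

    ``fit`` scores and filters a :class:`GroupedPanel`; the kept probe ids are
    in ``selected_ids_`` and all per-probe statistics in ``scores_``.

    Parameters mirror :func:`score_probes` / :class:`SelectionCriteria`.
    """

    def __init__(
        self,
        aging_groups=("DSS", "DSM"),
        contrast1=("DSP", "DSS"),
        contrast2=("OFF", "CTR"),
        alpha_age: float = 0.05,
        alpha_contrast: float = 0.05,
        require_both_contrasts: bool = True,
        contrast_test: str = "ranksum",
    ):
        self.aging_groups = aging_groups
        self.contrast1 = contrast1
        self.contrast2 = contrast2
        self.alpha_age = alpha_age
        self.alpha_contrast = alpha_contrast
        self.require_both_contrasts = require_both_contrasts
        self.contrast_test = contrast_test

    def fit(self, panel: GroupedPanel, y=None) -> "ProbeSelector":
        criteria = SelectionCriteria(
            alpha_age=self.alpha_age,
            alpha_contrast=self.alpha_contrast,
            require_both_contrasts=self.require_both_contrasts,
        )
        self.scores_ = score_probes(
            panel,
            self.aging_groups,
            tuple(self.contrast1),
            tuple(self.contrast2),
            contrast_test=self.contrast_test,
        )
        self.selected_ = select_candidates(self.scores_, criteria)
        self.relaxed_ = relaxed_select(self.scores_, criteria)
        self.selected_ids_ = [c.probe_id for c in self.selected_]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Restrict a beta DataFrame to the selected probes."""
        return X[self.selected_ids_]
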