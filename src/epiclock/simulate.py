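"""Synthetic methylation cohorts for end-to-end testing of the clock pipeline.

The generative model mirrors what the clock assumes: each CpG unit's M-value
is linear in a subject's *effective* age, where

    effective_age = chronological_age + delta_accel + Normal(0, sd_accel)

``delta_accel`` is a group-level biological-age offset (positive for an
accelerated-aging group, negative for longevity groups) and ``sd_accel`` the
between-subject spread of age acceleration.  Unit noise is drawn in M space
with a within-amplicon shared component (methylation of neighbouring CpG
units is correlated), M-values are mapped through the inverse logit to
beta-values, and entries are masked missing completely at random.  Paired
designs add a follow-up timepoint one year later with an intervention effect
applied to the effective age at follow-up.

The default cohort reproduces the group structure the clock is meant for:
278 controls aged 21–80, an accelerated-aging group (n=62, +11 years), a
centenarian-like group (n=106, ages 100–112, −6.5 years), a longevity
offspring group (n=143, −1.65 years), and a paired nutritional-intervention
design (n=233, ages 65–79, −0.58 years at follow-up).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import MethylationMatrix, SampleSheet
from .preprocess import m_to_beta
from .selection import GroupedPanel

__all__ = [
    "UnitModel",
    "GroupSpec",
    "CohortSpec",
    "SimulatedCohort",
    "PlantedProbe",
    "simulate_targeted_cohort",
    "simulate_infinium_panel",
    "default_units",
    "default_spec",
]

# amplicon layout of the packaged assay: gene label -> number of CpG units
DEFAULT_AMPLICONS = (
    ("ELOVL2", 15),
    ("NHLRC1", 21),
    ("SIRT7_MAFG", 6),
    ("AIM2", 7),
    ("EDARADD", 5),
    ("TFAP2E", 16),
)


@dataclass(frozen=True)
class UnitModel:
    """Linear-in-age model of one CpG unit in M-value space."""

    unit_id: str
    slope_m: float  # M-value change per year of effective age
    intercept_m: float  # M-value at effective age 0
    sd_unit: float  # residual SD in M space
    region_id: str  # owning amplicon

    def __post_init__(self) -> None:
        if self.sd_unit < 0:
            raise ValueError("sd_unit must be >= 0")
        if not (np.isfinite(self.slope_m) and np.isfinite(self.intercept_m)):
            raise ValueError("slope/intercept must be finite")


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: size, age range and its age-acceleration model."""

    label: str
    n: int
    age_low: float
    age_high: float
    delta_accel: float = 0.0  # group-level EAD offset, years
    sd_accel: float = 6.0  # between-subject acceleration SD, years
    paired: bool = False  # add a follow-up timepoint (T0/T1 design)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.label}: n must be >= 1")
        if self.age_low > self.age_high:
            raise ValueError(f"group {self.label}: age_low > age_high")


@dataclass(frozen=True)
class CohortSpec:
    """Full simulation design: groups plus noise/missingness settings."""

    groups: tuple[GroupSpec, ...]
    rho_amplicon: float = 0.3  # within-amplicon shared-noise variance fraction
    missing_rate: float = 0.05  # MCAR masking probability
    intervention_effect: float = 0.0  # years, applied at T1 of paired groups
    followup_years: float = 1.0  # chronological time between T0 and T1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rho_amplicon < 1:
            raise ValueError("rho_amplicon must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not self.groups:
            raise ValueError("at least one group is required")

    def subset(self, labels) -> "CohortSpec":
        labels = {labels} if isinstance(labels, str) else set(labels)
        kept = tuple(g for g in self.groups if g.label in labels)
        if not kept:
            raise ValueError(f"no groups match {sorted(labels)}")
        return replace(self, groups=kept)


@dataclass
class SimulatedCohort:
    """A simulated matrix + sheet, with the generating truth per sample."""

    matrix: MethylationMatrix
    sheet: SampleSheet
    truth: pd.DataFrame  # sample_id, group, age, effective_age, delta_accel


def simulate_targeted_cohort(
    units: list[UnitModel], spec: CohortSpec
) -> SimulatedCohort:
    """Draw one cohort under the linear-M generative model.

    Fully reproducible from ``spec.seed``; the truth table records each
    sample's effective age (including acceleration and, at follow-up, the
    intervention effect).
    """
    if not units:
        raise ValueError("need at least one unit model")
    rng = np.random.default_rng(spec.seed)
    regions = sorted({u.region_id for u in units})
    region_index = {r: i for i, r in enumerate(regions)}

    rows = []  # (sample_id, subject_id, group, timepoint, age, effective_age, delta)
    for g in spec.groups:
        ages = rng.uniform(g.age_low, g.age_high, size=g.n)
        accel = g.delta_accel + rng.normal(0.0, g.sd_accel, size=g.n)
        for i in range(g.n):
            subject = f"{g.label}_{i + 1:04d}"
            if g.paired:
                rows.append(
                    (f"{subject}_T0", subject, g.label, "T0",
                     ages[i], ages[i] + accel[i], g.delta_accel)
                )
                t1_age = ages[i] + spec.followup_years
                rows.append(
                    (f"{subject}_T1", subject, g.label, "T1",
                     t1_age, t1_age + accel[i] + spec.intervention_effect,
                     g.delta_accel)
                )
            else:
                rows.append(
                    (subject, subject, g.label, "", ages[i], ages[i] + accel[i],
                     g.delta_accel)
                )

    n_samples = len(rows)
    eff = np.array([r[5] for r in rows])
    slopes = np.array([u.slope_m for u in units])
    intercepts = np.array([u.intercept_m for u in units])
    sds = np.array([u.sd_unit for u in units])
    unit_region = np.array([region_index[u.region_id] for u in units])

    M = intercepts[None, :] + np.outer(eff, slopes)
    shared = rng.normal(size=(n_samples, len(regions)))
    indep = rng.normal(size=(n_samples, len(units)))
    noise = sds[None, :] * (
        np.sqrt(spec.rho_amplicon) * shared[:, unit_region]
        + np.sqrt(1.0 - spec.rho_amplicon) * indep
    )
    beta = m_to_beta(M + noise)
    if spec.missing_rate > 0:
        mask = rng.random(size=beta.shape) < spec.missing_rate
        beta = np.where(mask, np.nan, beta)

    sample_ids = [r[0] for r in rows]
    matrix = MethylationMatrix(
        pd.DataFrame(beta, index=sample_ids, columns=[u.unit_id for u in units])
    )
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "age": [r[4] for r in rows],
                "sex": [("F" if rng.random() < 0.5 else "M") for _ in rows],
                "group": [r[2] for r in rows],
                "timepoint": [r[3] for r in rows],
                "subject_id": [r[1] for r in rows],
            }
        )
    )
    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": [r[2] for r in rows],
            "timepoint": [r[3] for r in rows],
            "age": [r[4] for r in rows],
            "effective_age": [r[5] for r in rows],
            "delta_accel": [r[6] for r in rows],
        }
    ).set_index("sample_id", drop=False)
    return SimulatedCohort(matrix=matrix, sheet=sheet, truth=truth)


# ----------------------------------------------------------- Infinium panel


@dataclass(frozen=True)
class PlantedProbe:
    """A probe with a real age trend and group shifts of chosen signs.

    ``slope_beta`` is the beta change per year in the aging reference groups;
    ``shift_dsp``/``shift_off`` are additive beta shifts applied to the case
    group of each contrast.  A sign-consistent candidate has
    sign(shift_dsp) = sign(slope_beta) = −sign(shift_off).
    """

    probe_id: str
    slope_beta: float
    shift_dsp: float
    shift_off: float
    base_beta: float = 0.5


DEFAULT_PANEL_GROUP_SIZES = {"DSS": 29, "DSM": 29, "DSP": 29, "OFF": 19, "CTR": 30}
_PANEL_AGE_RANGES = {
    "DSS": (10, 65), "DSM": (35, 80), "DSP": (10, 65),
    "OFF": (55, 85), "CTR": (55, 85),
}


def simulate_infinium_panel(
    n_probes: int,
    planted: list[PlantedProbe],
    group_sizes: dict[str, int] | None = None,
    seed: int = 0,
    noise_sd: float = 0.03,
) -> GroupedPanel:
    """Panel of null probes plus planted age/group-signal probes.

    Null probes are age- and group-independent beta noise around a random
    baseline; planted probes get a linear age trend (centred at age 45) and
    the specified additive group shifts.  Values are clipped to [0.01, 0.99].
    """
    if len(planted) > n_probes:
        raise ValueError("more planted probes than total probes")
    sizes = dict(DEFAULT_PANEL_GROUP_SIZES if group_sizes is None else group_sizes)
    rng = np.random.default_rng(seed)
    labels, ages = [], []
    for label, n in sizes.items():
        lo, hi = _PANEL_AGE_RANGES.get(label, (20, 80))
        labels.extend([label] * n)
        ages.extend(rng.uniform(lo, hi, size=n))
    labels = np.array(labels, dtype=object)
    ages = np.array(ages)
    n_samples = ages.size

    beta = np.empty((n_samples, n_probes))
    probe_ids = []
    n_null = n_probes - len(planted)
    for j in range(n_null):
        base = rng.uniform(0.2, 0.8)
        beta[:, j] = base + rng.normal(0.0, noise_sd, size=n_samples)
        probe_ids.append(f"null{j + 1:05d}")
    for k, p in enumerate(planted):
        j = n_null + k
        col = p.base_beta + p.slope_beta * (ages - 45.0)
        col = col + np.where(labels == "DSP", p.shift_dsp, 0.0)
        col = col + np.where(labels == "OFF", p.shift_off, 0.0)
        beta[:, j] = col + rng.normal(0.0, noise_sd, size=n_samples)
        probe_ids.append(p.probe_id)
    beta = np.clip(beta, 0.01, 0.99)
    return GroupedPanel(
        beta=pd.DataFrame(beta, columns=probe_ids), ages=ages, groups=labels
    )


# ------------------------------------------------------------ default design

_UNIT_PANEL_SEED = 20221214  # fixes the default unit models, not the cohort draw


def default_units(sd_unit: float = 0.15) -> list[UnitModel]:
    """70 CpG-unit models across the six default amplicons.

    Slopes mix signs with magnitudes log-uniform in [0.005, 0.05] M/year, so
    both age-hypermethylating and age-hypomethylating units exist; baselines
    are spread over the beta range.  The parameter draw is fixed (it defines
    the default panel, independent of the cohort seed).
    """
    rng = np.random.default_rng(_UNIT_PANEL_SEED)
    units: list[UnitModel] = []
    for region, n_units in DEFAULT_AMPLICONS:
        for k in range(1, n_units + 1):
            mag = np.exp(rng.uniform(np.log(0.005), np.log(0.05)))
            sign = 1.0 if rng.random() < 0.6 else -1.0
            slope = sign * mag
            base_beta_at_50 = rng.uniform(0.15, 0.85)
            intercept = float(np.log2(base_beta_at_50 / (1 - base_beta_at_50)) - slope * 50.0)
            units.append(
                UnitModel(
                    unit_id=f"{region}_unit{k}",
                    slope_m=float(slope),
                    intercept_m=intercept,
                    sd_unit=sd_unit,
                    region_id=region,
                )
            )
    return units


def default_spec(seed: int = 0) -> tuple[list[UnitModel], CohortSpec]:
    """The default study design: reference, accelerated, longevity and paired
    intervention groups at their canonical sizes and offsets."""
    groups = (
        GroupSpec("CTR", n=278, age_low=21, age_high=80, delta_accel=0.0),
        GroupSpec("DSP", n=62, age_low=12, age_high=66, delta_accel=+11.0),
        GroupSpec("CENT", n=106, age_low=100, age_high=112, delta_accel=-6.5),
        GroupSpec("OFF", n=143, age_low=55, age_high=89, delta_accel=-1.65),
        GroupSpec("NUAGE", n=233, age_low=65, age_high=79, delta_accel=0.0,
                  paired=True),
    )
    spec = CohortSpec(
        groups=groups,
        rho_amplicon=0.3,
        missing_rate=0.05,
        intervention_effect=-0.58,
        seed=seed,
    )
    return default_units(), spec
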