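"""Library-level workflow: impute, train on a reference set, compute EAD.

This is the programmatic counterpart of the CLI chain
``preprocess -> train -> predict -> ead``: one call takes a (possibly
incomplete) cohort to a per-sample EAD table, fitting the clock and the EAD
reference line on a designated reference subset and applying both to every
sample, including ages far outside the training window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clock import ClockConfig, FitReport, MethylationAgeClock, predict_age, train_clock
from .ead import EADReference, compute_ead, fit_ead_reference
from .io import MethylationMatrix, SampleSheet
from .preprocess import PreprocessConfig, impute_missing
from .simulate import SimulatedCohort

__all__ = ["EADWorkflowResult", "reference_ead_workflow"]


@dataclass
class EADWorkflowResult:
    """Everything the reference workflow produced."""

    ead_table: pd.DataFrame  # per-sample: ages, ead, group, timepoint, subject
    model: MethylationAgeClock
    fit_report: FitReport
    reference: EADReference
    reference_sample_ids: list[str]  # exact samples the EAD line was fit on


def reference_ead_workflow(
    matrix: MethylationMatrix,
    sheet: SampleSheet,
    reference_group: str,
    reference_timepoint: str | None = None,
    clock_cfg: ClockConfig | None = None,
    preprocess_cfg: PreprocessConfig | None = None,
) -> EADWorkflowResult:
    """Impute, train the clock on the reference subset, and compute EAD.

    The reference subset is the given group (optionally restricted to one
    timepoint) inside the clock's training age window; the clock and the EAD
    regression are both fit on it, then applied to every sample of the cohort.
    """
    clock_cfg = clock_cfg or ClockConfig()
    completed, _ = impute_missing(matrix, preprocess_cfg)

    meta = sheet.table
    ref_mask = meta["group"] == reference_group
    if reference_timepoint is not None:
        ref_mask &= meta["timepoint"] == reference_timepoint
    ref_mask &= meta["age"].between(clock_cfg.age_min, clock_cfg.age_max)
    ref_mask = ref_mask.to_numpy()
    ref_ids = meta.loc[ref_mask, "sample_id"].tolist()
    if len(ref_ids) < 10:
        raise ValueError(
            f"reference subset {reference_group!r} has only {len(ref_ids)} samples"
        )

    model, report = train_clock(
        MethylationMatrix(completed.beta.loc[ref_ids]),
        SampleSheet(meta.loc[ref_mask].reset_index(drop=True)),
        clock_cfg,
    )
    pred = predict_age(model, completed)
    chrono = meta.loc[pred.index, "age"]
    reference = fit_ead_reference(
        pred.loc[ref_ids].to_numpy(), chrono.loc[ref_ids].to_numpy(),
        label=reference_group,
    )
    table = compute_ead(reference, pred, chrono)
    table["group"] = meta.loc[table.index, "group"].to_numpy()
    for col in ("timepoint", "subject_id"):
        if col in meta.columns:
            table[col] = meta.loc[table.index, col].to_numpy()
    return EADWorkflowResult(
        ead_table=table,
        model=model,
        fit_report=report,
        reference=reference,
        reference_sample_ids=ref_ids,
    )


def cohort_workflow(
    cohort: SimulatedCohort, reference_group: str, seed: int, **kwargs
) -> EADWorkflowResult:
    """Convenience wrapper for simulated cohorts: seeds both stages."""
    return reference_ead_workflow(
        cohort.matrix,
        cohort.sheet,
        reference_group,
        clock_cfg=kwargs.pop("clock_cfg", ClockConfig(seed=seed)),
        preprocess_cfg=kwargs.pop("preprocess_cfg", PreprocessConfig(seed=seed)),
        **kwargs,
    )
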