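"""Headline specificity metrics of a targeted-methylation experiment.

Inputs are average methylation percentages: the on-target channel is the
mean over the analysis CpGs of the targeted promoter amplicon, the
off-target channel the mean over all CpGs of an untargeted sensitive
promoter amplicon.  Three quantities summarize a construct:

* specificity factor — on / off ratio, 1-decimal rounding;
* residual activity — on-target percentage relative to a reference
  construct (the wild-type effector), integer rounding;
* off-target reduction — percentage drop of off-target methylation
  relative to the reference, integer rounding (negative = increase).

Rounding is half-away-from-zero throughout, matching how such ratios are
conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import round_half_away
from .errors import MissingDataError, ParameterError


@dataclass
class SpecificityReport:
    sample: str
    on_target_pct: float
    off_target_pct: float
    specificity_factor: float              # inf when off-target is exactly 0
    specificity_infinite: bool = False
    residual_activity_pct: float | None = None
    off_target_reduction_pct: float | None = None
    reference: str | None = None


def specificity_factor(on_pct: float, off_pct: float) -> float:
    """On/off methylation ratio, rounded half away from zero to 1 decimal.

    ``off_pct == 0`` yields ``inf`` (flagged by callers); negative inputs
    are rejected.
    """
    if on_pct < 0 or off_pct < 0:
        raise ParameterError("methylation percentages must be non-negative")
    if off_pct == 0:
        return float("inf")
    return round_half_away(on_pct / off_pct, 1)


def residual_activity(mut_on_pct: float, ref_on_pct: float) -> float:
    """Mutant on-target methylation as integer percent of the reference's."""
    if ref_on_pct <= 0:
        raise ParameterError("reference on-target percentage must be positive")
    if mut_on_pct < 0:
        raise ParameterError("methylation percentages must be non-negative")
    return round_half_away(100.0 * mut_on_pct / ref_on_pct, 0)


def off_target_reduction(mut_off_pct: float, ref_off_pct: float) -> float:
    """Drop of off-target methylation vs the reference, integer percent.

    Negative values indicate an increase and are passed through.
    """
    if ref_off_pct <= 0:
        raise ParameterError("reference off-target percentage must be positive")
    if mut_off_pct < 0:
        raise ParameterError("methylation percentages must be non-negative")
    return round_half_away(100.0 * (1.0 - mut_off_pct / ref_off_pct), 0)


def build_report(summaries: pd.DataFrame, reference: str) -> pd.DataFrame:
    """One report row per sample, all three metrics computed vs ``reference``.

    ``summaries`` needs columns sample / on_target_pct / off_target_pct.
    An empty table yields an empty report; a missing reference row is an
    error.
    """
    required = {"sample", "on_target_pct", "off_target_pct"}
    if not required <= set(summaries.columns):
        raise MissingDataError(f"summary table must contain columns {sorted(required)}")
    cols = [
        "sample",
        "on_target_pct",
        "off_target_pct",
        "specificity_factor",
        "specificity_infinite",
        "residual_activity_pct",
        "off_target_reduction_pct",
        "reference",
    ]
    if summaries.empty:
        return pd.DataFrame(columns=cols)
    ref_rows = summaries[summaries["sample"] == reference]
    if ref_rows.empty:
        raise MissingDataError(f"reference sample {reference!r} not in summary table")
    ref_on = float(ref_rows.iloc[0]["on_target_pct"])
    ref_off = float(ref_rows.iloc[0]["off_target_pct"])

    rows = []
    for rec in summaries.itertuples(index=False):
        on, off = float(rec.on_target_pct), float(rec.off_target_pct)
        factor = specificity_factor(on, off)
        rows.append(
            SpecificityReport(
                sample=rec.sample,
                on_target_pct=on,
                off_target_pct=off,
                specificity_factor=factor,
                specificity_infinite=np.isinf(factor),
                residual_activity_pct=residual_activity(on, ref_on),
                off_target_reduction_pct=off_target_reduction(off, ref_off),
                reference=reference,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows], columns=cols)
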