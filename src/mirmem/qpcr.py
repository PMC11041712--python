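"""Relative quantification of qPCR data by the 2^-ddCt method.

Cycle-threshold (Ct) triplicates for each (sample, assay) pair are reduced
to a fold change relative to a calibrator sample:

    dCt   = mean Ct(target) - mean Ct(reference assay)   within one sample
    ddCt  = dCt(sample) - dCt(calibrator sample)
    FC    = 2^-ddCt

The reference assay is a transcript assumed invariant between conditions
(U6 snRNA here); the calibrator sample's own fold change is exactly 1.
Replicate noise is propagated as sd(dCt) = sqrt(sd_t^2 + sd_ref^2) and
mapped through the exponential, which makes the error bars asymmetric:

    upper = 2^-(ddCt - sd) - FC        (always the larger arm)
    lower = FC - 2^-(ddCt + sd)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CtMeasurement",
    "FoldChangeEstimate",
    "delta_ct",
    "ddct_fold_change",
    "log2_fold_change",
    "quantify_table",
    "read_ct_csv",
    "write_ct_csv",
    "write_fold_changes_csv",
]

DEFAULT_REFERENCE_ASSAY = "U6"
DEFAULT_CALIBRATOR = "UM"

#: Replicate dCt spread (cycles) above which the validator warns.
MAX_CT_RANGE_WARN = 1.0


class QpcrInputError(ValueError):
    """Raised for malformed Ct tables."""


@dataclass(frozen=True)
class CtMeasurement:
    """Technical-replicate Ct values for one assay in one sample pool."""

    sample_id: str
    assay: str
    ct_values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.ct_values)
        if not vals:
            raise QpcrInputError(f"{self.sample_id}/{self.assay}: no Ct replicates")
        if not all(math.isfinite(v) for v in vals):
            raise QpcrInputError(f"{self.sample_id}/{self.assay}: non-finite Ct")
        object.__setattr__(self, "ct_values", vals)

    @property
    def mean(self) -> float:
        return float(np.mean(self.ct_values))

    @property
    def sd(self) -> float:
        if len(self.ct_values) < 2:
            return 0.0
        return float(np.std(self.ct_values, ddof=1))


@dataclass(frozen=True)
class FoldChangeEstimate:
    """2^-ddCt point estimate with asymmetric propagated error bars."""

    assay: str
    sample_id: str
    calibrator_id: str
    ddct: float
    fold_change: float
    upper_error: float
    lower_error: float
    sd_dct: float


def delta_ct(target: CtMeasurement, reference: CtMeasurement) -> dict[str, float]:
    """Within-sample dCt: mean(target) - mean(reference), SDs in quadrature."""
    if target.sample_id != reference.sample_id:
        raise QpcrInputError(
            f"sample mismatch: {target.sample_id} vs {reference.sample_id}"
        )
    return {
        "dct_mean": target.mean - reference.mean,
        "dct_sd": math.hypot(target.sd, reference.sd),
    }


def ddct_fold_change(
    dct_mean: float,
    dct_sd: float,
    calibrator_dct_mean: float,
    assay: str = "",
    sample_id: str = "",
    calibrator_id: str = "",
) -> FoldChangeEstimate:
    """Fold change 2^-ddCt with asymmetric error bars.

    When the sample is its own calibrator (``dct_mean ==
    calibrator_dct_mean``) the fold change is exactly 1.
    """
    ddct = dct_mean - calibrator_dct_mean
    fc = 2.0 ** (-ddct)
    upper = 2.0 ** (-(ddct - dct_sd)) - fc
    lower = fc - 2.0 ** (-(ddct + dct_sd))
    return FoldChangeEstimate(
        assay=assay,
        sample_id=sample_id,
        calibrator_id=calibrator_id,
        ddct=ddct,
        fold_change=fc,
        upper_error=upper,
        lower_error=lower,
        sd_dct=dct_sd,
    )


def log2_fold_change(estimate: FoldChangeEstimate) -> float:
    """log2 of the fold change; equals -ddCt and negates under pool swap."""
    if estimate.fold_change <= 0:
        raise QpcrInputError("non-positive fold change has no log")
    return math.log2(estimate.fold_change)


def quantify_table(
    measurements: Sequence[CtMeasurement],
    reference_assay: str = DEFAULT_REFERENCE_ASSAY,
    calibrator_sample: str = DEFAULT_CALIBRATOR,
    max_ct_range: float | None = None,
) -> list[FoldChangeEstimate]:
    """Quantify every (assay, sample) pair against the calibrator sample.

    Each sample must include the reference assay; each target assay must be
    measured in the calibrator sample.  ``max_ct_range`` optionally warns
    when a replicate set spans more than that many cycles.
    """
    import warnings

    by_sample: dict[str, dict[str, CtMeasurement]] = {}
    for m in measurements:
        if max_ct_range is not None and len(m.ct_values) > 1:
            span = max(m.ct_values) - min(m.ct_values)
            if span > max_ct_range:
                warnings.warn(
                    f"{m.sample_id}/{m.assay}: Ct replicate range {span:.2f} "
                    f"cycles exceeds {max_ct_range:.2f}",
                    stacklevel=2,
                )
        if m.assay in by_sample.setdefault(m.sample_id, {}):
            raise QpcrInputError(f"duplicate measurement {m.sample_id}/{m.assay}")
        by_sample[m.sample_id][m.assay] = m

    if calibrator_sample not in by_sample:
        raise QpcrInputError(f"calibrator sample {calibrator_sample!r} not in table")
    for sid, assays in by_sample.items():
        if reference_assay not in assays:
            raise QpcrInputError(f"sample {sid!r} lacks reference assay {reference_assay!r}")

    cal_dct = {
        assay: delta_ct(m, by_sample[calibrator_sample][reference_assay])
        for assay, m in by_sample[calibrator_sample].items()
        if assay != reference_assay
    }

    out = []
    for sid in sorted(by_sample):
        ref = by_sample[sid][reference_assay]
        for assay in sorted(by_sample[sid]):
            if assay == reference_assay:
                continue
            if assay not in cal_dct:
                raise QpcrInputError(
                    f"assay {assay!r} missing from calibrator sample {calibrator_sample!r}"
                )
            d = delta_ct(by_sample[sid][assay], ref)
            out.append(
                ddct_fold_change(
                    d["dct_mean"],
                    d["dct_sd"],
                    cal_dct[assay]["dct_mean"],
                    assay=assay,
                    sample_id=sid,
                    calibrator_id=calibrator_sample,
                )
            )
    return out


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

def read_ct_csv(path) -> list[CtMeasurement]:
    """Read a long-format Ct table: sample_id, assay, replicate, ct."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"sample_id", "assay", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise QpcrInputError(f"Ct CSV missing columns: {sorted(missing)}")
    out = []
    for (sid, assay), grp in df.groupby(["sample_id", "assay"], sort=True):
        ordered = grp.sort_values("replicate")
        out.append(
            CtMeasurement(
                sample_id=str(sid), assay=str(assay), ct_values=tuple(ordered["ct"])
            )
        )
    return out


def write_ct_csv(measurements: Iterable[CtMeasurement], path) -> None:
    rows = [
        {"sample_id": m.sample_id, "assay": m.assay, "replicate": i + 1, "ct": ct}
        for m in measurements
        for i, ct in enumerate(m.ct_values)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_fold_changes_csv(estimates: Iterable[FoldChangeEstimate], path) -> None:
    """Write fold changes in a Table-1-like layout."""
    pd.DataFrame(
        [
            {
                "assay": e.assay,
                "sample": e.sample_id,
                "fold_change": e.fold_change,
                "upper_error": e.upper_error,
                "lower_error": e.lower_error,
            }
            for e in estimates
        ]
    ).to_csv(path, index=False)
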