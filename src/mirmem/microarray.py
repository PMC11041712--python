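"""Two-channel LNA miRNA microarray processing.

Processes probe-level two-channel intensities (as produced by spot
quantification software) into per-miRNA expression calls:

1. drop spots flagged marginal/absent (``filter_flags``);
2. per-slide log2(Hy3/Hy5) ratios, median-centred on the slide's endogenous
   control probes (``normalize_slide``);
3. keep probes whose mean log2 intensity lies strictly inside (8, 14) to
   avoid the noise floor and saturation (``intensity_filter``);
4. average technical-replicate slides per miRNA (``average_replicates``);
5. call up/down/unchanged by the +/-0.7 log2-ratio rule (``call_expression``)
   and tally (``summarize_calls``).

Sign convention: Hy3 (green) carries the Impaired pool and Hy5 (red) the
Unimpaired pool, so a positive log2 ratio means higher expression in the
Impaired group.  The |mean| > 0.5 / SD 0.4 retention rule is computed as a
separate stage (``retention_filter``) and recorded per call as
``passed_retention``; categories are assigned over the whole considered
(post-intensity) universe.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace
from statistics import median
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeMeasurement",
    "NormalizedRatio",
    "ExpressionCall",
    "CallSummary",
    "read_probe_table",
    "write_probe_table",
    "filter_flags",
    "normalize_slide",
    "intensity_filter",
    "retention_filter",
    "average_replicates",
    "call_expression",
    "summarize_calls",
    "run_pipeline",
    "write_calls_csv",
    "write_summary_json",
]

FLAG_OK = "ok"
FLAG_MARGINAL = "marginal"
FLAG_ABSENT = "absent"

CATEGORY_UP = "up"
CATEGORY_DOWN = "down"
CATEGORY_UNCHANGED = "unchanged"

#: Default strict bounds of the mean-log2-intensity window.
INTENSITY_LO = 8.0
INTENSITY_HI = 14.0

#: Default |mean log2 FC| bound of the retention rule.
FC_THRESH = 0.5
#: Default replicate-SD bound of the retention rule.
SD_THRESH = 0.4
#: Default log2-ratio magnitude for an up/down call.
CALL_THRESH = 0.7

SdComparatorMode = Literal["as_printed", "reproducibility"]


class ArrayInputError(ValueError):
    """Raised for malformed probe tables or invalid configuration."""


@dataclass(frozen=True)
class ProbeMeasurement:
    """One array spot: probe identity, two channel intensities, QC flag."""

    probe_id: str
    mirna_name: str
    intensity_hy3: float  # green channel, Impaired pool
    intensity_hy5: float  # red channel, Unimpaired pool
    flag: str = FLAG_OK
    is_control: bool = False
    slide_id: str = "slide1"

    def __post_init__(self) -> None:
        if self.intensity_hy3 < 0 or self.intensity_hy5 < 0:
            raise ArrayInputError(f"{self.probe_id}: negative intensity")
        if self.flag not in (FLAG_OK, FLAG_MARGINAL, FLAG_ABSENT):
            raise ArrayInputError(f"{self.probe_id}: unknown flag {self.flag!r}")


@dataclass(frozen=True)
class NormalizedRatio:
    """Per-probe normalized log2(Hy3/Hy5) ratio on one slide."""

    mirna_name: str
    slide_id: str
    log2_ratio: float
    mean_log_intensity: float
    is_control: bool = False


@dataclass(frozen=True)
class ExpressionCall:
    """Replicate-averaged per-miRNA expression call."""

    mirna_name: str
    mean_log2_fc: float
    sd_log2_fc: float
    n_replicates: int
    category: str
    passed_retention: bool = False


@dataclass(frozen=True)
class CallSummary:
    n_total: int
    n_up: int
    n_down: int
    n_unchanged: int


# ---------------------------------------------------------------------------
# Reading probe tables
# ---------------------------------------------------------------------------

# GenePix flag codes: >= 0 good/unflagged, -50 not found (marginal),
# -75 absent, -100 bad.
def _map_gpr_flag(code: float) -> str:
    if code >= 0:
        return FLAG_OK
    if code == -50:
        return FLAG_MARGINAL
    return FLAG_ABSENT


_GPR_REQUIRED = {"Name", "F635 Median", "F532 Median", "Flags"}
_SIMPLE_REQUIRED = {"probe_id", "mirna_name", "hy3", "hy5", "flag"}


def read_probe_table(
    path,
    slide_id: str | None = None,
    control_names: set[str] | None = None,
) -> list[ProbeMeasurement]:
    """Read probe-level intensities from a GPR-like TSV or a simplified CSV.

    The GPR-like dialect is tab-delimited with columns ``Block``, ``Row``,
    ``Column``, ``Name``, ``F635 Median`` (red, Hy5), ``F532 Median``
    (green, Hy3) and ``Flags`` (GenePix codes); control probes are
    identified by membership in ``control_names`` or a name containing
    ``control`` (case-insensitive).  The simplified dialect is a CSV with
    columns ``probe_id, mirna_name, hy3, hy5, flag[, is_control, slide_id]``.
    """
    with open(path) as fh:
        header_line = fh.readline()
    if not header_line.strip():
        warnings.warn(f"{path}: empty probe table", stacklevel=2)
        return []
    if "\t" in header_line:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        dialect = "gpr"
    else:
        df = pd.read_csv(path, float_precision="round_trip")
        dialect = "simple"

    if dialect == "gpr":
        missing = _GPR_REQUIRED - set(df.columns)
        if missing:
            raise ArrayInputError(f"unknown probe-table dialect; missing {sorted(missing)}")
        if df.empty:
            warnings.warn(f"{path}: empty data section", stacklevel=2)
            return []
        coord_cols = [c for c in ("Block", "Row", "Column") if c in df.columns]
        if coord_cols and df.duplicated(subset=coord_cols).any():
            raise ArrayInputError("duplicate probe coordinates")
        sid = slide_id or str(path)
        controls = {c.lower() for c in (control_names or set())}
        out = []
        for i in range(len(df)):
            name = str(df.iloc[i]["Name"])
            hy5 = float(df.iloc[i]["F635 Median"])
            hy3 = float(df.iloc[i]["F532 Median"])
            flag = _map_gpr_flag(float(df.iloc[i]["Flags"]))
            if hy3 < 0 or hy5 < 0:
                raise ArrayInputError(f"{name}: negative intensity")
            is_ctrl = name.lower() in controls or "control" in name.lower()
            out.append(
                ProbeMeasurement(
                    probe_id=f"{sid}:{i}",
                    mirna_name=name,
                    intensity_hy3=hy3,
                    intensity_hy5=hy5,
                    flag=flag,
                    is_control=is_ctrl,
                    slide_id=sid,
                )
            )
        return out

    missing = _SIMPLE_REQUIRED - set(df.columns)
    if missing:
        raise ArrayInputError(f"unknown probe-table dialect; missing {sorted(missing)}")
    if df.empty:
        warnings.warn(f"{path}: empty data section", stacklevel=2)
        return []
    if df["probe_id"].duplicated().any() and "slide_id" not in df.columns:
        raise ArrayInputError("duplicate probe ids")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ProbeMeasurement(
                probe_id=str(row.probe_id),
                mirna_name=str(row.mirna_name),
                intensity_hy3=float(row.hy3),
                intensity_hy5=float(row.hy5),
                flag=str(row.flag),
                is_control=bool(getattr(row, "is_control", False)),
                slide_id=str(getattr(row, "slide_id", slide_id or "slide1")),
            )
        )
    return out


def write_probe_table(probes: Iterable[ProbeMeasurement], path) -> None:
    """Write probes in the simplified CSV dialect."""
    pd.DataFrame(
        [
            {
                "probe_id": p.probe_id,
                "mirna_name": p.mirna_name,
                "hy3": p.intensity_hy3,
                "hy5": p.intensity_hy5,
                "flag": p.flag,
                "is_control": p.is_control,
                "slide_id": p.slide_id,
            }
            for p in probes
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def filter_flags(probes: Sequence[ProbeMeasurement]) -> list[ProbeMeasurement]:
    """Keep only unflagged (ok) spots; warn when everything was flagged."""
    kept = [p for p in probes if p.flag == FLAG_OK]
    removed = len(probes) - len(kept)
    if probes and not kept:
        warnings.warn(f"all {removed} spots flagged; nothing retained", stacklevel=2)
    return kept


def normalize_slide(
    probes: Sequence[ProbeMeasurement],
    normalize: bool = True,
) -> list[NormalizedRatio]:
    """Per-slide log2(Hy3/Hy5) ratios, median-centred on control probes.

    Probes with a zero intensity in either channel cannot be log-transformed
    and are dropped with a warning.  When ``normalize`` is True the median
    raw log2 ratio over the slide's control probes is subtracted from every
    probe; a slide without usable controls is an error.  With ``normalize``
    False, raw ratios pass through.
    """
    slides = {p.slide_id for p in probes}
    if len(slides) > 1:
        raise ArrayInputError(f"normalize_slide got multiple slides: {sorted(slides)}")
    usable: list[ProbeMeasurement] = []
    for p in probes:
        if p.intensity_hy3 <= 0 or p.intensity_hy5 <= 0:
            warnings.warn(
                f"{p.probe_id}: non-positive intensity, probe dropped", stacklevel=2
            )
            continue
        usable.append(p)
    raw = {
        p.probe_id: math.log2(p.intensity_hy3) - math.log2(p.intensity_hy5)
        for p in usable
    }
    offset = 0.0
    if normalize:
        ctrl_ratios = [raw[p.probe_id] for p in usable if p.is_control]
        if not ctrl_ratios:
            raise ArrayInputError(
                "slide has no usable control probes; pass normalize=False to skip"
            )
        offset = median(ctrl_ratios)
    return [
        NormalizedRatio(
            mirna_name=p.mirna_name,
            slide_id=p.slide_id,
            log2_ratio=raw[p.probe_id] - offset,
            mean_log_intensity=(math.log2(p.intensity_hy3) + math.log2(p.intensity_hy5))
            / 2.0,
            is_control=p.is_control,
        )
        for p in usable
    ]


def intensity_filter(
    ratios: Sequence[NormalizedRatio],
    lo: float = INTENSITY_LO,
    hi: float = INTENSITY_HI,
) -> list[NormalizedRatio]:
    """Keep ratios with ``lo < mean_log_intensity < hi`` (strict bounds)."""
    if lo >= hi:
        raise ArrayInputError(f"invalid intensity window ({lo}, {hi})")
    return [r for r in ratios if lo < r.mean_log_intensity < hi]


def _group_by_mirna(ratios: Sequence[NormalizedRatio]) -> dict[str, list[float]]:
    grouped: dict[str, list[float]] = {}
    for r in ratios:
        grouped.setdefault(r.mirna_name, []).append(r.log2_ratio)
    return grouped


def average_replicates(ratios: Sequence[NormalizedRatio]) -> list[ExpressionCall]:
    """Average technical-replicate log2 ratios per miRNA (mean, sample SD).

    The returned calls carry a provisional ``unchanged`` category; apply
    ``call_expression``/``run_pipeline`` for categorization.
    """
    out = []
    for name in sorted(_group_by_mirna(ratios)):
        vals = np.asarray(_group_by_mirna(ratios)[name], dtype=float)
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        out.append(
            ExpressionCall(
                mirna_name=name,
                mean_log2_fc=float(vals.mean()),
                sd_log2_fc=sd,
                n_replicates=int(vals.size),
                category=CATEGORY_UNCHANGED,
            )
        )
    return out


def retention_filter(
    calls: Sequence[ExpressionCall],
    fc_thresh: float = FC_THRESH,
    sd_thresh: float = SD_THRESH,
    sd_mode: SdComparatorMode = "as_printed",
) -> list[ExpressionCall]:
    """Apply the fold-change/SD retention rule; return the retained subset.

    A miRNA is retained when ``|mean_log2_fc| > fc_thresh`` and its replicate
    SD passes the comparator: ``as_printed`` keeps SD > sd_thresh (the rule
    as published), ``reproducibility`` keeps SD < sd_thresh (the common
    replicate-agreement reading).
    """
    if sd_mode not in ("as_printed", "reproducibility"):
        raise ArrayInputError(f"unknown sd_mode {sd_mode!r}")
    out = []
    for c in calls:
        fc_ok = abs(c.mean_log2_fc) > fc_thresh
        sd_ok = c.sd_log2_fc > sd_thresh if sd_mode == "as_printed" else c.sd_log2_fc < sd_thresh
        if fc_ok and sd_ok:
            out.append(c)
    return out


def call_expression(mean_log2_fc: float, call_thresh: float = CALL_THRESH) -> str:
    """Categorize a mean log2 fold change as up, down or unchanged (+/-0.7)."""
    if not math.isfinite(mean_log2_fc):
        raise ArrayInputError("non-finite mean log2 fold change")
    if mean_log2_fc > call_thresh:
        return CATEGORY_UP
    if mean_log2_fc < -call_thresh:
        return CATEGORY_DOWN
    return CATEGORY_UNCHANGED


def summarize_calls(calls: Sequence[ExpressionCall]) -> CallSummary:
    """Count calls per category; total always equals the number of inputs."""
    n_up = sum(1 for c in calls if c.category == CATEGORY_UP)
    n_down = sum(1 for c in calls if c.category == CATEGORY_DOWN)
    return CallSummary(
        n_total=len(calls),
        n_up=n_up,
        n_down=n_down,
        n_unchanged=len(calls) - n_up - n_down,
    )


def run_pipeline(
    probes_by_slide: Mapping[str, Sequence[ProbeMeasurement]] | Sequence[ProbeMeasurement],
    lo: float = INTENSITY_LO,
    hi: float = INTENSITY_HI,
    fc_thresh: float = FC_THRESH,
    sd_thresh: float = SD_THRESH,
    sd_mode: SdComparatorMode = "as_printed",
    call_thresh: float = CALL_THRESH,
    normalize: bool = True,
) -> list[ExpressionCall]:
    """Full probe-to-call pipeline over one or more technical-replicate slides.

    A miRNA enters the considered universe when at least one of its spots
    survives flag removal, normalization and the intensity window; control
    probes are excluded from calling.  Each call's category follows the
    +/-``call_thresh`` rule and ``passed_retention`` records the
    fold-change/SD retention rule.
    """
    if not isinstance(probes_by_slide, Mapping):
        grouped: dict[str, list[ProbeMeasurement]] = {}
        for p in probes_by_slide:
            grouped.setdefault(p.slide_id, []).append(p)
        probes_by_slide = grouped
    kept_ratios: list[NormalizedRatio] = []
    for slide_id in sorted(probes_by_slide):
        probes = filter_flags(probes_by_slide[slide_id])
        if not probes:
            continue
        ratios = normalize_slide(probes, normalize=normalize)
        ratios = [r for r in ratios if not r.is_control]
        kept_ratios.extend(intensity_filter(ratios, lo=lo, hi=hi))
    precursors = average_replicates(kept_ratios)
    retained = {c.mirna_name for c in retention_filter(precursors, fc_thresh, sd_thresh, sd_mode)}
    return [
        replace(
            c,
            category=call_expression(c.mean_log2_fc, call_thresh=call_thresh),
            passed_retention=c.mirna_name in retained,
        )
        for c in precursors
    ]


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_calls_csv(calls: Iterable[ExpressionCall], path) -> None:
    pd.DataFrame(
        [
            {
                "mirna": c.mirna_name,
                "mean_log2_fc": c.mean_log2_fc,
                "sd": c.sd_log2_fc,
                "n": c.n_replicates,
                "category": c.category,
                "passed_retention": c.passed_retention,
            }
            for c in calls
        ]
    ).to_csv(path, index=False)


def write_summary_json(summary: CallSummary, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "n_total": summary.n_total,
                "n_up": summary.n_up,
                "n_down": summary.n_down,
                "n_unchanged": summary.n_unchanged,
            },
            fh,
            indent=2,
        )
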