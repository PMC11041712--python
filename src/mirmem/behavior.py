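"""Scoring and phenotype classification for the six-different-object task (6-DOT).

The 6-DOT probes short-term memory capacity under high load: a mouse studies
six distinct objects (study phase, exploration capped at 210 s = 35 s per
object), then at test one object is replaced by a novel one.  A subject that
remembers the studied set preferentially explores the novel object.  Subjects
are classified a posteriori as Unimpaired when novel-object exploration
strictly exceeds ``mean(familiar) + k * sd(familiar)`` (default k = 1.5),
otherwise Impaired.

The module also provides the omnibus statistics used to report such
experiments: the pooled-variance unpaired t-test, one-way repeated-measures
ANOVA over the six objects, and the split-plot (mixed) ANOVA with phenotype
as the between-subject factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "N_OBJECTS",
    "STUDY_CAP_S",
    "ExplorationRecord",
    "PhenotypeCall",
    "OpenFieldSummary",
    "CohortTally",
    "percent_new",
    "classify_subject",
    "classify_cohort",
    "unpaired_t",
    "anova_rm_oneway",
    "anova_rm_mixed",
    "read_behavior_csv",
    "write_behavior_csv",
    "write_calls_csv",
]

#: Number of objects presented in study and test phases.
N_OBJECTS = 6

#: Study-phase exploration cap in seconds (35 s per object).
STUDY_CAP_S = 210.0

UNIMPAIRED = "Unimpaired"
IMPAIRED = "Impaired"

SdMode = Literal["sample", "population"]


class BehaviorInputError(ValueError):
    """Raised for structurally invalid exploration data."""


@dataclass(frozen=True)
class ExplorationRecord:
    """Per-subject, per-phase object exploration times.

    Parameters
    ----------
    subject_id
        Opaque subject identifier.
    phase
        One of ``habituation``, ``study``, ``test``.
    object_times
        The six per-object exploration durations in seconds (study/test).
    novel_index
        0-based position of the novel object; required for (and only valid
        in) the test phase.
    group
        Optional group label (e.g. treatment arm).
    """

    subject_id: str
    phase: str
    object_times: tuple[float, ...]
    novel_index: int | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if self.phase not in ("habituation", "study", "test"):
            raise BehaviorInputError(f"unknown phase {self.phase!r}")
        times = tuple(float(t) for t in self.object_times)
        object.__setattr__(self, "object_times", times)
        if self.phase in ("study", "test"):
            if len(times) != N_OBJECTS:
                raise BehaviorInputError(
                    f"{self.subject_id}: expected {N_OBJECTS} object times, "
                    f"got {len(times)}"
                )
            if any(t < 0 for t in times):
                raise BehaviorInputError(f"{self.subject_id}: negative exploration time")
        if self.phase == "test":
            if self.novel_index is None:
                raise BehaviorInputError(f"{self.subject_id}: test record lacks novel_index")
            if not 0 <= self.novel_index < len(times):
                raise BehaviorInputError(
                    f"{self.subject_id}: novel_index {self.novel_index} out of range"
                )
        elif self.novel_index is not None:
            raise BehaviorInputError(
                f"{self.subject_id}: novel_index only valid in test phase"
            )

    @property
    def new_time(self) -> float:
        if self.phase != "test":
            raise BehaviorInputError("new_time is defined for test records only")
        return self.object_times[self.novel_index]  # type: ignore[index]

    @property
    def familiar_times(self) -> tuple[float, ...]:
        if self.phase != "test":
            raise BehaviorInputError("familiar_times is defined for test records only")
        return tuple(
            t for i, t in enumerate(self.object_times) if i != self.novel_index
        )

    def validate_study_cap(self, cap: float = STUDY_CAP_S) -> bool:
        """Warn (and return False) when a study record exceeds the cap."""
        if self.phase != "study":
            return True
        total = sum(self.object_times)
        if total > cap + 1e-9:
            warnings.warn(
                f"{self.subject_id}: study exploration {total:.1f}s exceeds "
                f"the {cap:.0f}s cap",
                stacklevel=2,
            )
            return False
        return True


@dataclass(frozen=True)
class PhenotypeCall:
    """Unimpaired/Impaired label with the quantities that produced it."""

    subject_id: str
    label: str
    new_time: float
    familiar_mean: float
    familiar_sd: float
    threshold: float
    k: float = 1.5


@dataclass(frozen=True)
class OpenFieldSummary:
    """Habituation-phase open-field activity counts and durations."""

    subject_id: str
    peripheral_crossings: int = 0
    central_crossings: int = 0
    leaning_s: float = 0.0
    rearing_s: float = 0.0
    grooming_s: float = 0.0

    def __post_init__(self) -> None:
        vals = (
            self.peripheral_crossings,
            self.central_crossings,
            self.leaning_s,
            self.rearing_s,
            self.grooming_s,
        )
        if any(v < 0 for v in vals):
            raise BehaviorInputError(f"{self.subject_id}: negative open-field value")


@dataclass(frozen=True)
class CohortTally:
    """Cohort-level label counts and rounded percentages."""

    n_total: int
    n_unimpaired: int
    n_impaired: int
    pct_unimpaired: float
    pct_impaired: float
    calls: tuple[PhenotypeCall, ...] = field(repr=False, default=())


def _round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (55.17 -> 55.2), unlike banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent_new(record: ExplorationRecord) -> float:
    """Percentage of test-phase exploration devoted to the novel object.

    Returns ``100 * new_time / total_exploration``; raises when the total
    exploration is zero (the percentage is undefined).
    """
    if record.phase != "test":
        raise BehaviorInputError("percent_new requires a test-phase record")
    total = sum(record.object_times)
    if total <= 0:
        raise BehaviorInputError(
            f"{record.subject_id}: zero total exploration, percentage undefined"
        )
    return 100.0 * record.new_time / total


def classify_subject(
    record: ExplorationRecord,
    k: float = 1.5,
    sd_mode: SdMode = "sample",
) -> PhenotypeCall:
    """Classify one subject by the novel-vs-familiar exceedance criterion.

    The subject is Unimpaired iff the novel-object time strictly exceeds
    ``mean(familiar) + k * sd(familiar)``; equality or shortfall yields
    Impaired.  ``sd_mode`` selects the sample (n-1, default) or population
    (n) standard deviation of the five familiar times.
    """
    if record.phase != "test":
        raise BehaviorInputError("classification requires a test-phase record")
    familiar = np.asarray(record.familiar_times, dtype=float)
    if familiar.size < 2:
        raise BehaviorInputError(
            f"{record.subject_id}: need >= 2 familiar times to compute an SD"
        )
    mean = float(familiar.mean())
    ddof = 1 if sd_mode == "sample" else 0
    sd = float(familiar.std(ddof=ddof))
    threshold = mean + k * sd
    label = UNIMPAIRED if record.new_time > threshold else IMPAIRED
    return PhenotypeCall(
        subject_id=record.subject_id,
        label=label,
        new_time=record.new_time,
        familiar_mean=mean,
        familiar_sd=sd,
        threshold=threshold,
        k=k,
    )


def classify_cohort(
    records: Iterable[ExplorationRecord],
    k: float = 1.5,
    sd_mode: SdMode = "sample",
) -> CohortTally:
    """Classify every subject and tally label counts and percentages.

    Percentages are rounded to one decimal, half away from zero.
    """
    calls = tuple(classify_subject(r, k=k, sd_mode=sd_mode) for r in records)
    if not calls:
        raise BehaviorInputError("empty cohort")
    n = len(calls)
    n_um = sum(1 for c in calls if c.label == UNIMPAIRED)
    n_im = n - n_um
    return CohortTally(
        n_total=n,
        n_unimpaired=n_um,
        n_impaired=n_im,
        pct_unimpaired=_round_half_up(100.0 * n_um / n),
        pct_impaired=_round_half_up(100.0 * n_im / n),
        calls=calls,
    )


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def unpaired_t(a: Sequence[float], b: Sequence[float]) -> dict[str, float]:
    """Pooled-variance two-sample t-test.

    Returns ``{"t", "df", "p"}`` with df = nA + nB - 2 and a two-sided p.
    When the pooled variance is zero and the means are equal, t = 0 and
    p = 1 by convention; zero variance with unequal means is an error.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise BehaviorInputError("each group needs >= 2 values")
    df = x.size + y.size - 2
    pooled = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    if pooled == 0:
        if x.mean() == y.mean():
            return {"t": 0.0, "df": float(df), "p": 1.0}
        raise BehaviorInputError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return {"t": float(t), "df": float(df), "p": float(p)}


def _as_matrix(data: Sequence[Sequence[float]]) -> np.ndarray:
    mat = np.asarray(data, dtype=float)
    if mat.ndim != 2:
        raise BehaviorInputError("expected a subjects x levels matrix")
    if np.isnan(mat).any():
        raise BehaviorInputError("missing cells are not allowed")
    return mat


def anova_rm_oneway(data: Sequence[Sequence[float]]) -> dict[str, float]:
    """One-way repeated-measures ANOVA (uncorrected, univariate).

    ``data`` is an N-subjects x K-levels matrix.  Returns F with
    df1 = K - 1, df2 = (K - 1)(N - 1); no sphericity correction.  A matrix
    with zero effect and zero error sum of squares reports F = 0.
    """
    mat = _as_matrix(data)
    n, k = mat.shape
    if n < 2 or k < 2:
        raise BehaviorInputError("need >= 2 subjects and >= 2 levels")
    grand = mat.mean()
    ss_cond = n * ((mat.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((mat.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((mat - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_err = ss_err / df2
    if ms_err <= 0:
        f = 0.0 if ss_cond == 0 else np.inf
    else:
        f = (ss_cond / df1) / ms_err
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    if f == 0.0:
        p = 1.0
    return {"F": float(f), "df1": float(df1), "df2": float(df2), "p": p}


def anova_rm_mixed(
    data: Sequence[Sequence[float]],
    group: Sequence[str],
) -> dict[str, dict[str, float]]:
    """Split-plot (mixed-design) ANOVA: one within factor, one between factor.

    ``data`` is N x K; ``group`` assigns each subject to a between-subject
    group.  Returns the three omnibus tests::

        {"between":     {F, df1, df2, p},   # df = (G-1, N-G)
         "within":      {F, df1, df2, p},   # df = (K-1, (K-1)(N-G))
         "interaction": {F, df1, df2, p}}   # df = ((K-1)(G-1), (K-1)(N-G))
    """
    mat = _as_matrix(data)
    n, k = mat.shape
    labels = np.asarray(group)
    if labels.shape != (n,):
        raise BehaviorInputError("group labels must match the number of subjects")
    groups = pd.unique(labels)
    g = len(groups)
    if g < 2:
        raise BehaviorInputError("need >= 2 groups")
    sizes = {lab: int((labels == lab).sum()) for lab in groups}
    if min(sizes.values()) < 2:
        raise BehaviorInputError("every group needs >= 2 subjects")

    grand = mat.mean()
    subj_means = mat.mean(axis=1)
    col_means = mat.mean(axis=0)

    ss_between_subjects = k * ((subj_means - grand) ** 2).sum()
    ss_group = k * sum(
        sizes[lab] * (subj_means[labels == lab].mean() - grand) ** 2 for lab in groups
    )
    ss_err_between = ss_between_subjects - ss_group

    ss_time = n * ((col_means - grand) ** 2).sum()
    ss_cells = sum(
        sizes[lab] * ((mat[labels == lab].mean(axis=0) - grand) ** 2).sum()
        for lab in groups
    )
    ss_inter = ss_cells - ss_group - ss_time
    ss_total = ((mat - grand) ** 2).sum()
    ss_err_within = ss_total - ss_between_subjects - ss_time - ss_inter

    df_group, df_err_b = g - 1, n - g
    df_time = k - 1
    df_inter = (k - 1) * (g - 1)
    df_err_w = (k - 1) * (n - g)

    def _ftest(ss_effect: float, df_effect: int, ss_err: float, df_err: int):
        ms_err = ss_err / df_err
        if ms_err <= 0:
            f = 0.0 if ss_effect <= 1e-12 else np.inf
        else:
            f = (ss_effect / df_effect) / ms_err
        f = max(f, 0.0)
        p = float(stats.f.sf(f, df_effect, df_err)) if np.isfinite(f) else 0.0
        if f == 0.0:
            p = 1.0
        return {"F": float(f), "df1": float(df_effect), "df2": float(df_err), "p": p}

    return {
        "between": _ftest(ss_group, df_group, ss_err_between, df_err_b),
        "within": _ftest(ss_time, df_time, ss_err_within, df_err_w),
        "interaction": _ftest(ss_inter, df_inter, ss_err_within, df_err_w),
    }


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

_BEHAVIOR_COLUMNS = ["subject_id", "phase", "group"] + [
    f"t_obj{i}" for i in range(1, N_OBJECTS + 1)
] + ["novel_index"]


def read_behavior_csv(path) -> list[ExplorationRecord]:
    """Read exploration records; ``novel_index`` is 1-based in files."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _BEHAVIOR_COLUMNS if c not in df.columns]
    if missing:
        raise BehaviorInputError(f"behavior CSV missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        novel = getattr(row, "novel_index")
        novel_0 = None if pd.isna(novel) else int(novel) - 1
        grp = getattr(row, "group")
        records.append(
            ExplorationRecord(
                subject_id=str(row.subject_id),
                phase=str(row.phase),
                object_times=tuple(
                    getattr(row, f"t_obj{i}") for i in range(1, N_OBJECTS + 1)
                ),
                novel_index=novel_0,
                group=None if pd.isna(grp) else str(grp),
            )
        )
    return records


def write_behavior_csv(records: Iterable[ExplorationRecord], path) -> None:
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "phase": r.phase, "group": r.group}
        for i, t in enumerate(r.object_times, start=1):
            row[f"t_obj{i}"] = t
        row["novel_index"] = None if r.novel_index is None else r.novel_index + 1
        rows.append(row)
    pd.DataFrame(rows, columns=_BEHAVIOR_COLUMNS).to_csv(path, index=False)


def write_calls_csv(tally: CohortTally, path) -> None:
    """Per-subject phenotype calls with the intermediate quantities."""
    pd.DataFrame(
        [
            {
                "subject_id": c.subject_id,
                "label": c.label,
                "new_time": c.new_time,
                "familiar_mean": c.familiar_mean,
                "familiar_sd": c.familiar_sd,
                "threshold": c.threshold,
                "k": c.k,
            }
            for c in tally.calls
        ]
    ).to_csv(path, index=False)
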