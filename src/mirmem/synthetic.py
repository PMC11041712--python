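"""Seeded generators for behavior, array and qPCR inputs with known truth.

Each generator emulates one data source of the study design so that every
pipeline stage can be exercised end-to-end without animal or slide data:

* ``simulate_cohort`` — a middle-aged cohort with a latent impaired
  fraction; unimpaired subjects explore the novel object more (a
  multiplicative novelty boost), impaired subjects treat it like any
  familiar object.  Study-phase exploration respects the 210 s cap.
* ``simulate_array`` — technical-replicate two-channel slides with
  endogenous-control probes, per-slide dye bias, and a planted set of
  upregulated miRNAs with known log2 fold changes.
* ``simulate_qpcr`` — Ct triplicates generated from latent log2 expression
  differences plus an invariant U6-like reference assay.

All generators are deterministic given (spec, seed): one integer seed is
split into independent sub-streams via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .behavior import ExplorationRecord, IMPAIRED, N_OBJECTS, STUDY_CAP_S, UNIMPAIRED
from .microarray import FLAG_OK, ProbeMeasurement
from .qpcr import CtMeasurement, DEFAULT_REFERENCE_ASSAY

__all__ = [
    "CohortSpec",
    "ArraySpec",
    "QpcrSpec",
    "simulate_cohort",
    "simulate_array",
    "simulate_qpcr",
    "DEFAULT_QPCR_EXPRESSION",
]


class SpecError(ValueError):
    """Raised for impossible generator specifications."""


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Study-cohort generator parameters.

    Defaults mirror the study design: 29 middle-aged subjects of which
    roughly 45% are latently impaired, a 210 s study cap (35 s per object),
    and log-normal per-object exploration times (right-skewed,
    non-negative) around 20 s with moderate dispersion.  ``novelty_boost``
    multiplies the novel-object time for latently unimpaired subjects;
    impaired subjects are generated with boost 1.
    """

    n_subjects: int = 29
    impaired_fraction: float = 13 / 29
    base_object_time: float = 20.0
    dispersion: float = 0.3
    novelty_boost: float = 3.0
    study_cap: float = STUDY_CAP_S
    min_object_time: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise SpecError("need at least one subject")
        if not 0.0 <= self.impaired_fraction <= 1.0:
            raise SpecError("impaired_fraction must lie in [0, 1]")
        if self.novelty_boost < 1.0:
            raise SpecError("novelty_boost must be >= 1")
        if self.dispersion <= 0 or self.base_object_time <= 0:
            raise SpecError("dispersion and base_object_time must be positive")
        if self.study_cap < N_OBJECTS * self.min_object_time:
            raise SpecError(
                f"study cap {self.study_cap}s cannot accommodate {N_OBJECTS} "
                f"objects at >= {self.min_object_time}s each"
            )


def _lognormal_times(rng: np.random.Generator, base: float, sigma: float, n: int):
    # median of the draw equals `base`
    return base * np.exp(rng.normal(0.0, sigma, size=n))


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[list[ExplorationRecord], dict[str, str]]:
    """Generate study and test records plus latent ground-truth labels.

    Returns ``(records, truth)`` where ``truth`` maps subject_id to the
    latent Unimpaired/Impaired label.  Study totals never exceed the cap:
    over-cap subjects are proportionally rescaled, mimicking the timed
    cutoff without changing n.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    n = spec.n_subjects
    n_impaired = int(round(spec.impaired_fraction * n))
    latent = np.array([IMPAIRED] * n_impaired + [UNIMPAIRED] * (n - n_impaired))
    rng.shuffle(latent)

    records: list[ExplorationRecord] = []
    truth: dict[str, str] = {}
    for i in range(n):
        sid = f"m{i + 1:03d}"
        truth[sid] = str(latent[i])

        study = _lognormal_times(rng, spec.base_object_time, spec.dispersion, N_OBJECTS)
        study = np.maximum(study, spec.min_object_time)
        total = study.sum()
        if total > spec.study_cap:
            study = study * (spec.study_cap / total)
        records.append(
            ExplorationRecord(
                subject_id=sid,
                phase="study",
                object_times=tuple(study),
                group=truth[sid],
            )
        )

        familiar = _lognormal_times(
            rng, spec.base_object_time, spec.dispersion, N_OBJECTS - 1
        )
        boost = spec.novelty_boost if latent[i] == UNIMPAIRED else 1.0
        novel = boost * _lognormal_times(rng, spec.base_object_time, spec.dispersion, 1)[0]
        novel_index = int(rng.integers(N_OBJECTS))
        times = list(familiar)
        times.insert(novel_index, novel)
        records.append(
            ExplorationRecord(
                subject_id=sid,
                phase="test",
                object_times=tuple(times),
                novel_index=novel_index,
                group=truth[sid],
            )
        )
    return records, truth


# ---------------------------------------------------------------------------
# Microarray
# ---------------------------------------------------------------------------

def _default_upregulated(n_mirnas: int, n_up: int = 38, fc: float = 1.2) -> dict[str, float]:
    n_up = min(n_up, n_mirnas)
    return {f"mir-synth-{i + 1:03d}": fc for i in range(n_up)}


@dataclass(frozen=True)
class ArraySpec:
    """Two-channel slide generator parameters.

    Defaults mirror the screen's shape: 179 considered miRNAs of which 38
    are planted upregulated (log2 FC +1.2) in the Impaired channel, two
    technical-replicate slides, ten endogenous-control probes, replicate
    noise SD 0.1 on the log2 scale, and probe abundances inside the (8, 14)
    usable-intensity window.  ``dye_bias`` is a per-slide multiplicative
    bias applied to the Hy5 channel (1.0 = unbiased).
    """

    n_mirnas: int = 179
    n_controls: int = 10
    n_replicates: int = 2
    upregulated_set: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.1
    intensity_range: tuple[float, float] = (9.0, 13.0)
    dye_bias: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas < 1 or self.n_replicates < 1 or self.n_controls < 0:
            raise SpecError("invalid array dimensions")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if not self.upregulated_set:
            object.__setattr__(self, "upregulated_set", _default_upregulated(self.n_mirnas))
        names = set(self.mirna_names())
        unknown = set(self.upregulated_set) - names
        if unknown:
            raise SpecError(f"planted miRNAs not on the array: {sorted(unknown)[:3]}")
        if self.dye_bias is not None and len(self.dye_bias) != self.n_replicates:
            raise SpecError("dye_bias needs one value per replicate slide")

    def mirna_names(self) -> list[str]:
        return [f"mir-synth-{i + 1:03d}" for i in range(self.n_mirnas)]


def simulate_array(
    spec: ArraySpec,
) -> tuple[dict[str, list[ProbeMeasurement]], dict[str, float]]:
    """Generate probe tables per technical-replicate slide plus planted truth.

    Channel intensities follow ``2^(baseline +/- fc/2 + noise)`` with the
    planted log2 fold change split symmetrically between channels (Hy3 up,
    Hy5 down for upregulated miRNAs); control probes carry zero fold
    change.  Returns ``(slides, truth)`` where ``truth`` maps each
    non-control miRNA to its planted log2 fold change (0.0 for nulls).
    """
    ss = np.random.SeedSequence(spec.seed).spawn(2)
    rng_base = np.random.default_rng(ss[0])
    rng_noise = np.random.default_rng(ss[1])

    lo, hi = spec.intensity_range
    names = spec.mirna_names()
    baselines = dict(zip(names, rng_base.uniform(lo, hi, size=spec.n_mirnas)))
    truth = {name: float(spec.upregulated_set.get(name, 0.0)) for name in names}

    ctrl_names = [f"control-{i + 1:02d}" for i in range(spec.n_controls)]
    ctrl_baselines = dict(
        zip(ctrl_names, rng_base.uniform(lo, hi, size=spec.n_controls))
    )

    slides: dict[str, list[ProbeMeasurement]] = {}
    for r in range(spec.n_replicates):
        sid = f"slide{r + 1}"
        bias = 1.0 if spec.dye_bias is None else float(spec.dye_bias[r])
        probes = []
        for j, name in enumerate(names + ctrl_names):
            is_ctrl = name in ctrl_baselines
            base = ctrl_baselines[name] if is_ctrl else baselines[name]
            fc = 0.0 if is_ctrl else truth[name]
            e3, e5 = rng_noise.normal(0.0, spec.noise_sd, size=2)
            probes.append(
                ProbeMeasurement(
                    probe_id=f"{sid}:p{j + 1:04d}",
                    mirna_name=name,
                    intensity_hy3=float(2.0 ** (base + fc / 2.0 + e3)),
                    intensity_hy5=float(2.0 ** (base - fc / 2.0 + e5) * bias),
                    flag=FLAG_OK,
                    is_control=is_ctrl,
                    slide_id=sid,
                )
            )
        slides[sid] = probes
    return slides, truth


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

#: Default latent log2 expression differences (Impaired minus Unimpaired)
#: for the five validated assays, on the scale recovered as 2^delta.
DEFAULT_QPCR_EXPRESSION: dict[str, float] = {
    "mir-135a-5p": 3.7179,
    "mir-451": 0.2829,
    "hs-miR-126": 2.5937,
    "hs-miR-21-5p": 3.0025,
    "mir-153-3p": 1.3163,
}


@dataclass(frozen=True)
class QpcrSpec:
    """Ct-table generator parameters.

    ``assays`` maps each target assay to its latent log2 expression
    difference between the two pools (Impaired minus Unimpaired); the
    reference assay has zero difference by construction.  Ct values are
    ``base_ct - expression + noise`` per technical replicate (default
    triplicates, 0.2-cycle noise).
    """

    assays: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_QPCR_EXPRESSION))
    reference_assay: str = DEFAULT_REFERENCE_ASSAY
    ct_noise_sd: float = 0.2
    n_replicates: int = 3
    base_ct: float = 28.0
    reference_base_ct: float = 20.0
    samples: tuple[str, str] = ("UM", "IM")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ct_noise_sd < 0:
            raise SpecError("ct_noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise SpecError("need >= 1 replicate")
        if self.reference_assay in self.assays:
            raise SpecError("reference assay cannot carry a latent difference")


def simulate_qpcr(
    spec: QpcrSpec,
) -> tuple[list[CtMeasurement], dict[str, float]]:
    """Generate a Ct table plus the true fold changes ``2^delta``.

    The first sample in ``spec.samples`` is the calibrator-like baseline
    (latent expression 0); the second carries each assay's latent log2
    difference.  Returns ``(measurements, truth)`` with ``truth`` mapping
    assay name to the second sample's true fold change.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    baseline_sample, contrast_sample = spec.samples
    measurements = []
    for sample in spec.samples:
        for assay in [spec.reference_assay, *sorted(spec.assays)]:
            if assay == spec.reference_assay:
                base, expr = spec.reference_base_ct, 0.0
            else:
                base = spec.base_ct
                expr = spec.assays[assay] if sample == contrast_sample else 0.0
            cts = base - expr + rng.normal(0.0, spec.ct_noise_sd, size=spec.n_replicates)
            measurements.append(
                CtMeasurement(sample_id=sample, assay=assay, ct_values=tuple(cts))
            )
    truth = {assay: float(2.0 ** delta) for assay, delta in spec.assays.items()}
    return measurements, truth
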