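"""Virtual patient cohort generation.

The simulated trial population is a heart-failure cohort with left bundle
branch block (LBBB) and preserved atrioventricular conduction.  Each virtual
patient carries the two electrophysiological quantities the study protocol
conditions on: the surface PR interval (P-wave onset to earliest ventricular
activation) and the native ventricular activation time (VAT, used
interchangeably with native QRS duration).  PR is drawn from a normal
distribution truncated above at the trial's inclusion bound (PR <= 250 ms)
and below at the lower limit of normal AV conduction (120 ms); native VAT
from a normal truncated below at an LBBB floor.

PR and native VAT are sampled independently: only marginal mean +/- SD are
available for the reference population, so the simplest joint structure
consistent with those marginals is used.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "PatientParams",
    "sample_patient",
    "make_cohort",
    "cohort_to_frame",
    "cohort_from_frame",
]

#: hard cap on rejection-sampling iterations per draw
_REJECTION_CAP = 10_000


@dataclass(frozen=True)
class CohortSpec:
    """Distributional description of a virtual cohort.

    Defaults reproduce the reference population: n = 14, PR 189.0 +/- 36.1 ms
    truncated at 250 ms, native VAT 181.6 +/- 23.9 ms with a 130 ms LBBB
    floor.  ``rng_seed`` makes the cohort a pure function of the spec.
    """

    n_patients: int = 14
    pr_mean_ms: float = 189.0
    pr_sd_ms: float = 36.1
    native_vat_mean_ms: float = 181.6
    native_vat_sd_ms: float = 23.9
    pr_max_ms: float = 250.0
    pr_min_ms: float = 120.0
    vat_min_ms: float = 130.0
    rng_seed: int = 20200226
    atrial_sense_latency_ms: float = 30.0
    anatomy_scale: float = 1.0
    # cohort annotation only -- not electrically modeled
    age_mean_years: float = 70.0
    age_sd_years: float = 7.0
    fraction_male: float = 0.786
    fraction_ischemic: float = 0.5

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("pr_sd_ms", "native_vat_sd_ms", "age_sd_years"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pr_max_ms <= self.pr_mean_ms - 3.0 * self.pr_sd_ms:
            raise ValueError(
                "pr_max_ms must exceed pr_mean_ms - 3*pr_sd_ms "
                "(truncation would reject essentially every draw)"
            )
        if self.pr_min_ms >= self.pr_max_ms:
            raise ValueError("pr_min_ms must be < pr_max_ms")
        if not (0.0 <= self.fraction_male <= 1.0 and 0.0 <= self.fraction_ischemic <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.anatomy_scale <= 0:
            raise ValueError("anatomy_scale must be > 0")


@dataclass(frozen=True)
class PatientParams:
    """One virtual patient's electrophysiological parameters.

    ``velocity_multiplier`` is unset (None) until conduction calibration has
    matched the intrinsic activation map to ``target_native_vat_ms``.
    """

    patient_id: str
    pr_interval_ms: float
    target_native_vat_ms: float
    atrial_sense_latency_ms: float = 30.0
    anatomy_scale: float = 1.0
    velocity_multiplier: Optional[float] = None
    # annotation
    age_years: float = float("nan")
    male: bool = True
    ischemic: bool = False

    def calibrated(self, multiplier: float) -> "PatientParams":
        return dataclasses.replace(self, velocity_multiplier=float(multiplier))


def _truncated_draw(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    *,
    upper: float = np.inf,
    lower: float = -np.inf,
) -> float:
    """Rejection-sample normal(mean, sd) restricted to [lower, upper]."""
    if sd == 0.0:
        if not (lower <= mean <= upper):
            raise ValueError(
                f"degenerate draw: mean {mean} outside bounds [{lower}, {upper}]"
            )
        return mean
    for _ in range(_REJECTION_CAP):
        x = rng.normal(mean, sd)
        if lower <= x <= upper:
            return float(x)
    raise ValueError(
        f"rejection sampling exceeded {_REJECTION_CAP} iterations; "
        f"spec (mean={mean}, sd={sd}, bounds=[{lower}, {upper}]) is infeasible"
    )


def sample_patient(
    spec: CohortSpec, stream: np.random.Generator, index: int = 0
) -> PatientParams:
    """Draw one patient from *spec*, consuming only *stream*.

    PR is truncated above at ``pr_max_ms`` (inclusion criterion); native VAT
    is truncated below at ``vat_min_ms`` (LBBB floor).
    """
    spec.validate()
    pr = _truncated_draw(
        stream,
        spec.pr_mean_ms,
        spec.pr_sd_ms,
        upper=spec.pr_max_ms,
        lower=spec.pr_min_ms,
    )
    vat = _truncated_draw(
        stream, spec.native_vat_mean_ms, spec.native_vat_sd_ms, lower=spec.vat_min_ms
    )
    age = stream.normal(spec.age_mean_years, spec.age_sd_years)
    male = bool(stream.random() < spec.fraction_male)
    ischemic = bool(stream.random() < spec.fraction_ischemic)
    width = max(2, len(str(spec.n_patients)))
    return PatientParams(
        patient_id=f"P{index + 1:0{width}d}",
        pr_interval_ms=pr,
        target_native_vat_ms=vat,
        atrial_sense_latency_ms=spec.atrial_sense_latency_ms,
        anatomy_scale=spec.anatomy_scale,
        age_years=float(age),
        male=male,
        ischemic=ischemic,
    )


def make_cohort(spec: CohortSpec) -> list[PatientParams]:
    """Generate the full cohort deterministically.

    Patient *i* uses the substream ``default_rng([rng_seed, i])``, so patient
    contents do not depend on ``n_patients`` (a cohort of 5 is a prefix of a
    cohort of 14 generated from the same seed).
    """
    spec.validate()
    cohort = []
    for i in range(spec.n_patients):
        stream = np.random.default_rng([spec.rng_seed, i])
        cohort.append(sample_patient(spec, stream, index=i))
    return cohort


_COHORT_COLUMNS = [
    "patient_id",
    "pr_interval_ms",
    "target_native_vat_ms",
    "atrial_sense_latency_ms",
    "anatomy_scale",
    "velocity_multiplier",
    "age_years",
    "male",
    "ischemic",
]


def cohort_to_frame(cohort: list[PatientParams]) -> pd.DataFrame:
    """One row per patient, fixed column order (the cohort CSV schema)."""
    rows = [
        {c: getattr(p, c) for c in _COHORT_COLUMNS}
        for p in cohort
    ]
    return pd.DataFrame(rows, columns=_COHORT_COLUMNS)


def cohort_from_frame(frame: pd.DataFrame) -> list[PatientParams]:
    out = []
    for _, row in frame.iterrows():
        mult = row.get("velocity_multiplier")
        out.append(
            PatientParams(
                patient_id=str(row["patient_id"]),
                pr_interval_ms=float(row["pr_interval_ms"]),
                target_native_vat_ms=float(row["target_native_vat_ms"]),
                atrial_sense_latency_ms=float(row["atrial_sense_latency_ms"]),
                anatomy_scale=float(row["anatomy_scale"]),
                velocity_multiplier=None if pd.isna(mult) else float(mult),
                age_years=float(row["age_years"]),
                male=bool(row["male"]),
                ischemic=bool(row["ischemic"]),
            )
        )
    return out
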