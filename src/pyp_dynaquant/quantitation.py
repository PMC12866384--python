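"""Absolute and relative uptake metrics: decay correction, net injected dose,
SUV, %ID/mL, and myocardium-to-reference uptake ratios.

Conventions
-----------
* All decay corrections reference the pre-injection dose assay time; the
  injection defines t = 0 for frame timing only.
* SUV assumes a tissue density of 1 g/mL, so SUV = C [Bq/mL] x body mass [g]
  / injected activity [Bq] is reported in g/mL.
* %ID/mL is a percentage: SUVmean / (weight_kg x 1000) x 100, i.e. the
  percent of the net injected dose residing in one milliliter of tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .images import DynamicImage, UNITS_CONCENTRATION, UnitError

#: Physical half-life of 99mTc in minutes (6.0067 h).
T_HALF_TC99M_MIN = 360.4

#: Exact activity unit definitions relative to Bq (1 mCi = 37 MBq).
_UNIT_BQ = {"Bq": 1.0, "kBq": 1e3, "MBq": 1e6, "mCi": 3.7e7}


class DoseError(ValueError):
    """Raised for non-physical dose bookkeeping inputs."""


class DegenerateInputError(ValueError):
    """Raised when a metric is requested on degenerate input (zero dose,
    zero weight, empty VOI, zero denominator)."""


@dataclass(frozen=True)
class SubjectRecord:
    """Dose/weight bookkeeping for one subject.

    Times are minutes relative to injection (t = 0); the syringe assay
    precedes injection and the residual assay follows it.
    """

    subject_id: str
    group: str  # "ATTR" or "non-ATTR"
    weight_kg: float
    assay_activity_MBq: float
    assay_time_min: float
    residual_activity_MBq: float
    residual_time_min: float
    injection_time_min: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in ("ATTR", "non-ATTR"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.weight_kg <= 0:
            raise DoseError("weight must be positive")
        if not (self.assay_activity_MBq > self.residual_activity_MBq >= 0):
            raise DoseError("require assay activity > residual activity >= 0")
        if not (self.assay_time_min <= self.injection_time_min <= self.residual_time_min):
            raise DoseError("require assay time <= injection time <= residual time")


@dataclass(frozen=True)
class DoseRecord:
    """Net injected activity decay-referenced to the assay time."""

    injected_activity_Bq: float
    reference_time_min: float
    half_life_min: float = T_HALF_TC99M_MIN

    def __post_init__(self) -> None:
        if self.injected_activity_Bq <= 0:
            raise DoseError("injected activity must be positive")
        if self.half_life_min <= 0:
            raise DoseError("half-life must be positive")


@dataclass
class QuantResult:
    """Per-window, per-subject quantitative metrics over the three VOIs."""

    subject_id: str
    window: tuple[float, float]
    suv_mean: dict[str, float] = field(default_factory=dict)
    suv_max: dict[str, float] = field(default_factory=dict)
    pid_per_ml: float = float("nan")  # %ID/mL of LV_myo
    ratio_myo_bone: float = float("nan")
    ratio_myo_bp: float = float("nan")


def decay_correct(concentration, t_min: float, reference_time_min: float,
                  half_life_min: float = T_HALF_TC99M_MIN):
    """Rescale activity measured at ``t_min`` to the reference time.

    C_corr = C x 2**((t - t_ref) / T_half): measurements after the reference
    are scaled up to undo physical decay.  Works elementwise on arrays.
    """
    if half_life_min <= 0:
        raise DoseError("half-life must be positive")
    return concentration * 2.0 ** ((t_min - reference_time_min) / half_life_min)


def decay_correct_image(image: DynamicImage, reference_time_min: float,
                        half_life_min: float = T_HALF_TC99M_MIN) -> DynamicImage:
    """Decay-correct every frame (at its midpoint) to the reference time."""
    if image.units != UNITS_CONCENTRATION:
        raise UnitError("decay correction applies to concentration images; "
                        f"got units {image.units!r}")
    factors = 2.0 ** ((image.schedule.midpoints - reference_time_min) / half_life_min)
    return image.with_data(image.data * factors,
                           extra_meta={"decay_reference_min": reference_time_min})


def net_injected_activity(subject: SubjectRecord,
                          half_life_min: float = T_HALF_TC99M_MIN) -> DoseRecord:
    """Net injected dose: syringe assay minus the residual, with the residual
    decay-referenced back to the assay time.  ID is in Bq."""
    residual_at_assay = decay_correct(
        subject.residual_activity_MBq, subject.residual_time_min,
        subject.assay_time_min, half_life_min)
    net_mbq = subject.assay_activity_MBq - residual_at_assay
    if net_mbq <= 0:
        raise DoseError(
            f"non-positive net injected activity ({net_mbq:.2f} MBq) for "
            f"{subject.subject_id}")
    return DoseRecord(injected_activity_Bq=net_mbq * 1e6,
                      reference_time_min=subject.assay_time_min,
                      half_life_min=half_life_min)


def suv(concentration_Bq_per_mL, dose: DoseRecord, weight_kg: float):
    """Standardized uptake value (g/mL) from decay-corrected concentration."""
    if weight_kg <= 0:
        raise DegenerateInputError("weight must be positive")
    return concentration_Bq_per_mL * (weight_kg * 1000.0) / dose.injected_activity_Bq


def percent_id_per_ml(suv_mean, weight_kg: float):
    """%ID/mL from SUVmean and body weight (percent units)."""
    if weight_kg <= 0:
        raise DegenerateInputError("weight must be positive")
    return 100.0 * suv_mean / (weight_kg * 1000.0)


def uptake_ratios(suv_myo, suv_bone, suv_bp) -> tuple:
    """(myocardium/bone, myocardium/blood-pool) SUVmean ratios."""
    if np.any(np.asarray(suv_bone) <= 0) or np.any(np.asarray(suv_bp) <= 0):
        raise DegenerateInputError("ratio denominators must be positive")
    return suv_myo / suv_bone, suv_myo / suv_bp


def activity_unit_convert(value, from_unit: str, to_unit: str):
    """Exact conversion between Bq / kBq / MBq / mCi (1 mCi = 37 MBq)."""
    try:
        return value * (_UNIT_BQ[from_unit] / _UNIT_BQ[to_unit])
    except KeyError as exc:
        raise UnitError(f"unknown activity unit {exc.args[0]!r}; "
                        f"expected one of {sorted(_UNIT_BQ)}") from None
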