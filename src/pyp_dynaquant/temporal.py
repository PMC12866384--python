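"""Time-activity curves, synthetic static images, and blood-pool subtraction.

Synthetic statics are duration-weighted voxelwise means of dynamic frames
over a closed-open window [start, end); partial frame overlaps are weighted
by the overlap duration so results do not depend on how the window cuts the
framing in the noiseless limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import DynamicImage, FrameSchedule, GeometryError, UNITS_CONCENTRATION
from .quantitation import DegenerateInputError, DoseRecord, suv
from .segmentation import voi_statistics


class WindowError(ValueError):
    """Raised when a requested window overlaps no frames."""


@dataclass
class TimeActivityCurve:
    """Per-frame SUVmean/SUVmax series for one VOI."""

    voi_label: str
    times_min: np.ndarray
    suv_mean: np.ndarray
    suv_max: np.ndarray
    window_provenance: FrameSchedule

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.suv_mean = np.asarray(self.suv_mean, dtype=float)
        self.suv_max = np.asarray(self.suv_max, dtype=float)
        n = len(self.window_provenance)
        if not (len(self.times_min) == len(self.suv_mean)
                == len(self.suv_max) == n):
            raise ValueError("TAC series lengths must equal the frame count")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("TAC times must be strictly increasing")


def extract_tac(dynamic_image: DynamicImage, masks: dict[str, np.ndarray],
                dose: DoseRecord, weight_kg: float) -> dict[str, TimeActivityCurve]:
    """Per-frame VOI statistics converted to SUV, one TAC per mask.

    The image must already be calibrated to Bq/mL and decay-corrected to the
    dose reference time.
    """
    if dynamic_image.units != UNITS_CONCENTRATION:
        raise DegenerateInputError(
            "extract_tac needs a calibrated concentration image; got units "
            f"{dynamic_image.units!r}")
    mids = dynamic_image.schedule.midpoints
    out = {}
    for label, mask in masks.items():
        means = np.empty(len(mids))
        maxes = np.empty(len(mids))
        for j in range(len(mids)):
            stats = voi_statistics(dynamic_image, mask, frame=j)
            means[j] = stats.mean
            maxes[j] = stats.max
        out[label] = TimeActivityCurve(
            voi_label=label, times_min=mids,
            suv_mean=suv(means, dose, weight_kg),
            suv_max=suv(maxes, dose, weight_kg),
            window_provenance=dynamic_image.schedule)
    return out


def synthesize_static(dynamic_image: DynamicImage, window_start: float,
                      window_end: float) -> DynamicImage:
    """Duration-weighted voxelwise mean over [window_start, window_end).

    Frames partially inside the window contribute with weight equal to their
    overlap duration.  The output is a single-frame image whose schedule
    entry is the window itself.
    """
    if window_end <= window_start:
        raise WindowError("window end must exceed window start")
    starts = dynamic_image.schedule.starts
    ends = dynamic_image.schedule.ends
    overlap = np.minimum(ends, window_end) - np.maximum(starts, window_start)
    weights = np.clip(overlap, 0.0, None)
    if weights.sum() <= 0:
        raise WindowError(
            f"window [{window_start}, {window_end}) min overlaps no frames of "
            f"schedule {dynamic_image.schedule.label()}")
    weights = weights / weights.sum()
    data = np.tensordot(dynamic_image.data, weights, axes=([3], [0]))
    window_schedule = FrameSchedule(((window_start, window_end - window_start),))
    return dynamic_image.with_data(
        data[..., np.newaxis], schedule=window_schedule,
        extra_meta={"synthetic_static_window": [window_start, window_end]})


def blood_pool_subtract(target_image: DynamicImage,
                        early_dynamic: DynamicImage,
                        la_bp_mask: np.ndarray,
                        scale: float | None = None,
                        frame: int = 0) -> DynamicImage:
    """Subtract a scaled early blood-pool template from a target image.

    The template B is the duration-weighted average of the first 5 min of
    dynamic data; the scale s matches the blood-pool means of target and
    template (s = mean(target | LA_bp) / mean(B | LA_bp)) unless overridden;
    the output is max(target - s B, 0) voxelwise.
    """
    if early_dynamic.grid_shape != target_image.grid_shape:
        raise GeometryError("early dynamic and target grids differ")
    template = synthesize_static(early_dynamic, 0.0, 5.0)
    if scale is None:
        template_bp = voi_statistics(template, la_bp_mask).mean
        if template_bp <= 0:
            raise DegenerateInputError(
                "zero blood-pool mean in the early template")
        target_bp = voi_statistics(target_image, la_bp_mask, frame=frame).mean
        scale = target_bp / template_bp
    data = np.clip(target_image.frame(frame) - scale * template.frame(0),
                   0.0, None)
    return target_image.with_data(
        data[..., np.newaxis],
        schedule=FrameSchedule((target_image.schedule.frames[frame],)),
        extra_meta={"blood_pool_subtracted": True, "subtraction_scale": scale})
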