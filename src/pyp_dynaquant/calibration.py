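"""Absolute-quantitation calibration from a uniform cylinder phantom.

A cylinder of known activity and volume is imaged with the same acquisition
emulation as the subjects; the calibration factor maps reconstructed count
rate (counts/voxel/s) to activity concentration (Bq/mL).  The mean count rate
is taken over an eroded core of the cylinder so edge voxels (spill-out under
a nonzero PSF) do not bias the factor.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .images import DynamicImage, FrameSchedule, GeometryError, UnitError, \
    UNITS_CONCENTRATION, UNITS_COUNT_RATE
from .phantom import AcquisitionModel, PhantomSizingError
from .quantitation import DegenerateInputError


@dataclass(frozen=True)
class CalibrationFactor:
    """Conversion from counts/voxel/s to Bq/mL, with provenance."""

    cf: float
    phantom_activity_MBq: float
    phantom_volume_mL: float
    acquisition_mode: str = "static"  # or "dynamic"
    assay_time_min: float = 0.0

    def __post_init__(self) -> None:
        if self.cf <= 0:
            raise DegenerateInputError("calibration factor must be positive")
        if self.phantom_volume_mL <= 0:
            raise DegenerateInputError("phantom volume must be positive")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationFactor":
        return cls(**json.loads(Path(path).read_text()))


def simulate_uniform_cylinder(activity_MBq: float, volume_mL: float,
                              grid_shape=(64, 64, 64),
                              voxel_size_mm: float = 4.92,
                              acquisition: AcquisitionModel = AcquisitionModel(),
                              duration_min: float = 15.0,
                              seed=0) -> tuple[DynamicImage, np.ndarray]:
    """Single-frame image of a uniform cylinder plus its voxel mask.

    The cylinder axis runs along z with height 0.8 x the grid z-extent and
    radius chosen to match the requested volume; voxels inside hold the
    nominal concentration activity/volume (scaled by the sensitivity and
    Poisson-resampled when the acquisition says so), background is zero.
    """
    if activity_MBq <= 0 or volume_mL <= 0:
        raise DegenerateInputError("activity and volume must be positive")
    grid_shape = tuple(int(n) for n in grid_shape)
    height_mm = 0.8 * grid_shape[2] * voxel_size_mm
    radius_mm = float(np.sqrt(volume_mL * 1000.0 / (np.pi * height_mm)))
    half_xy = tuple(n * voxel_size_mm / 2.0 for n in grid_shape[:2])
    if radius_mm + 2 * voxel_size_mm > min(half_xy):
        raise PhantomSizingError(
            f"cylinder radius {radius_mm:.0f} mm (+2 voxel margin) exceeds the "
            f"grid half-extent {min(half_xy):.0f} mm; enlarge the grid or "
            f"reduce the volume")

    coords = [(np.arange(n) - (n - 1) / 2.0) * voxel_size_mm for n in grid_shape]
    x = coords[0][:, None, None]
    y = coords[1][None, :, None]
    z = coords[2][None, None, :]
    mask = ((x**2 + y**2) <= radius_mm**2) & (np.abs(z) <= height_mm / 2.0)
    mask = np.broadcast_to(mask, grid_shape).copy()

    concentration_bq_ml = activity_MBq * 1e6 / volume_mL
    data = np.where(mask, concentration_bq_ml, 0.0)
    if acquisition.psf_fwhm_mm > 0:
        sigma = acquisition.psf_fwhm_mm / 2.354820045 / voxel_size_mm
        data = ndimage.gaussian_filter(data, sigma)

    sens = acquisition.sensitivity_cps_per_Bq_per_mL_per_voxel
    if sens is None:
        units = UNITS_CONCENTRATION
    else:
        units = UNITS_COUNT_RATE
        data = data * sens
        if acquisition.noise:
            rng = np.random.default_rng(seed)
            dur_s = duration_min * 60.0
            data = rng.poisson(data * dur_s) / dur_s

    schedule = FrameSchedule(((0.0, duration_min),))
    image = DynamicImage(data=data, voxel_size_mm=voxel_size_mm,
                         schedule=schedule, units=units,
                         meta={"phantom": "uniform_cylinder",
                               "activity_MBq": activity_MBq,
                               "volume_mL": volume_mL})
    return image, mask


def compute_calibration_factor(count_image: DynamicImage, mask: np.ndarray,
                               activity_MBq: float, volume_mL: float,
                               erosion_voxels: int = 2,
                               acquisition_mode: str = "static",
                               assay_time_min: float = 0.0) -> CalibrationFactor:
    """cf = nominal concentration / mean count rate over the eroded core.

    The core excludes voxels within ``erosion_voxels`` voxel-widths of the
    cylinder boundary to limit edge partial-volume (spill-out) bias.
    """
    if mask.shape != count_image.grid_shape:
        raise GeometryError("mask grid does not match the image grid")
    if not mask.any():
        raise DegenerateInputError("empty cylinder mask")
    if count_image.units != UNITS_COUNT_RATE:
        raise UnitError(f"expected a count-rate image, got {count_image.units!r}")
    core = mask
    if erosion_voxels > 0:
        core = ndimage.binary_erosion(mask, iterations=erosion_voxels)
    if not core.any():
        raise DegenerateInputError(
            f"mask erosion by {erosion_voxels} voxels removed every voxel")
    mean_rate = float(count_image.frame(0)[core].mean())
    if mean_rate <= 0:
        raise DegenerateInputError("zero mean count rate inside the core VOI")
    nominal = activity_MBq * 1e6 / volume_mL
    return CalibrationFactor(cf=nominal / mean_rate,
                             phantom_activity_MBq=activity_MBq,
                             phantom_volume_mL=volume_mL,
                             acquisition_mode=acquisition_mode,
                             assay_time_min=assay_time_min)


def apply_calibration(count_image: DynamicImage,
                      cf: CalibrationFactor) -> DynamicImage:
    """Voxelwise count rate -> Bq/mL; schedule and metadata preserved."""
    if count_image.units != UNITS_COUNT_RATE:
        raise UnitError(
            f"apply_calibration expects {UNITS_COUNT_RATE!r} input, got "
            f"{count_image.units!r}")
    return count_image.with_data(count_image.data * cf.cf,
                                 units=UNITS_CONCENTRATION,
                                 extra_meta={"calibration_cf": cf.cf})
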