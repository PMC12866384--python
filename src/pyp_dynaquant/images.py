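"""Voxel image containers with frame timing metadata, and NIfTI round-trip I/O.

A :class:`DynamicImage` is a 4-D voxel grid (x, y, z, frame) of either absolute
activity concentration (Bq/mL) or reconstructed count rate (counts/voxel/s),
tagged with an isotropic voxel size and a :class:`FrameSchedule` giving each
frame's start and duration in minutes post-injection.  Static images are
represented as single-frame dynamic images so every downstream operation has
one code path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: Recognised voxel-value unit tags.
UNITS_CONCENTRATION = "Bq/mL"
UNITS_COUNT_RATE = "counts/voxel/s"
VALID_UNITS = (UNITS_CONCENTRATION, UNITS_COUNT_RATE)


class ScheduleError(ValueError):
    """Raised for ill-formed frame schedules."""


class GeometryError(ValueError):
    """Raised when image/mask grids are incompatible."""


class UnitError(ValueError):
    """Raised when an operation receives an image in the wrong units."""


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered list of (start_min, duration_min) frames relative to injection.

    Frames must be non-overlapping with positive durations and non-decreasing
    starts.  Gaps are allowed (the protocol has none between 0-5 min frames,
    a 5-10 min repositioning gap, then contiguous coverage of 10-65 min and
    isolated 15-min statics at 90 and 150 min).
    """

    frames: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ScheduleError("schedule must contain at least one frame")
        frames = tuple((float(s), float(d)) for s, d in self.frames)
        object.__setattr__(self, "frames", frames)
        prev_end = -np.inf
        prev_start = -np.inf
        for start, dur in frames:
            if dur <= 0:
                raise ScheduleError(f"frame at {start} min has duration {dur} <= 0")
            if start < prev_start:
                raise ScheduleError("frame starts must be non-decreasing")
            if start < prev_end - 1e-9:
                raise ScheduleError(
                    f"frame at {start} min overlaps previous frame ending {prev_end}"
                )
            prev_start, prev_end = start, start + dur

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def starts(self) -> np.ndarray:
        return np.array([s for s, _ in self.frames])

    @property
    def durations(self) -> np.ndarray:
        return np.array([d for _, d in self.frames])

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.durations

    @property
    def midpoints(self) -> np.ndarray:
        return self.starts + self.durations / 2.0

    def segments(self) -> list["FrameSchedule"]:
        """Split into contiguous acquisition segments at temporal gaps."""
        groups: list[list[tuple[float, float]]] = [[self.frames[0]]]
        for frame in self.frames[1:]:
            prev_start, prev_dur = groups[-1][-1]
            if abs(frame[0] - (prev_start + prev_dur)) < 1e-9:
                groups[-1].append(frame)
            else:
                groups.append([frame])
        return [FrameSchedule(tuple(g)) for g in groups]

    def label(self) -> str:
        """Human-readable span label, e.g. ``"10-65min"``."""
        return f"{self.starts[0]:g}-{self.ends[-1]:g}min"


def default_frame_schedule() -> FrameSchedule:
    """The study's acquisition structure: 20 x 15 s frames over 0-5 min,
    a repositioning gap, 11 x 5 min frames over 10-65 min, and one 15-min
    static at 90 and at 150 min."""
    frames: list[tuple[float, float]] = []
    frames += [(i * 0.25, 0.25) for i in range(20)]
    frames += [(10.0 + 5.0 * i, 5.0) for i in range(11)]
    frames += [(90.0, 15.0), (150.0, 15.0)]
    return FrameSchedule(tuple(frames))


@dataclass
class DynamicImage:
    """4-D voxel array (x, y, z, t) with grid spacing, timing, and units."""

    data: np.ndarray
    voxel_size_mm: float
    schedule: FrameSchedule
    units: str = UNITS_CONCENTRATION
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 3:
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise GeometryError(f"expected 3-D or 4-D array, got ndim={self.data.ndim}")
        if self.data.shape[-1] != len(self.schedule):
            raise ScheduleError(
                f"{self.data.shape[-1]} frames in array vs "
                f"{len(self.schedule)} in schedule"
            )
        if self.units not in VALID_UNITS:
            raise UnitError(f"unknown units {self.units!r}; expected one of {VALID_UNITS}")
        if self.voxel_size_mm <= 0:
            raise GeometryError("voxel size must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def voxel_volume_ml(self) -> float:
        return float(self.voxel_size_mm**3 / 1000.0)

    def frame(self, index: int) -> np.ndarray:
        """3-D array of one frame."""
        return self.data[..., index]

    def with_data(self, data: np.ndarray, units: str | None = None,
                  schedule: FrameSchedule | None = None,
                  extra_meta: dict | None = None) -> "DynamicImage":
        meta = dict(self.meta)
        if extra_meta:
            meta.update(extra_meta)
        return DynamicImage(
            data=data,
            voxel_size_mm=self.voxel_size_mm,
            schedule=schedule if schedule is not None else self.schedule,
            units=units if units is not None else self.units,
            meta=meta,
        )


# ----------------------------------------------------------------------------
# NIfTI I/O.  Timing/units metadata ride in a JSON sidecar next to the image.
# ----------------------------------------------------------------------------

def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def save_dynamic_image(image: DynamicImage, path: str | Path) -> Path:
    """Write image as NIfTI plus a ``.json`` sidecar (schedule, units, meta)."""
    path = Path(path)
    nib.save(nib.Nifti1Image(image.data.astype(np.float32), _affine(image.voxel_size_mm)), path)
    sidecar = {
        "units": image.units,
        "voxel_size_mm": image.voxel_size_mm,
        "frames": [list(f) for f in image.schedule.frames],
        "meta": image.meta,
    }
    sidecar_path = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" \
        else path.with_suffix(".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def load_dynamic_image(path: str | Path) -> DynamicImage:
    path = Path(path)
    img = nib.load(path)
    sidecar_path = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" \
        else path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text())
    return DynamicImage(
        data=np.asarray(img.dataobj, dtype=np.float64),
        voxel_size_mm=float(sidecar["voxel_size_mm"]),
        schedule=FrameSchedule(tuple(tuple(f) for f in sidecar["frames"])),
        units=sidecar["units"],
        meta=sidecar.get("meta", {}),
    )


def save_label_image(labels: dict[str, np.ndarray], voxel_size_mm: float,
                     path: str | Path) -> Path:
    """Write a dict of boolean masks as one integer-labeled NIfTI plus a
    JSON sidecar mapping label names to integer codes."""
    path = Path(path)
    codes = {name: i + 1 for i, name in enumerate(sorted(labels))}
    vol = np.zeros(next(iter(labels.values())).shape, dtype=np.int16)
    # later labels overwrite earlier ones only if masks overlap (they should not)
    for name, mask in labels.items():
        vol[mask] = codes[name]
    nib.save(nib.Nifti1Image(vol, _affine(voxel_size_mm)), path)
    sidecar_path = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" \
        else path.with_suffix(".json")
    sidecar_path.write_text(json.dumps({"codes": codes, "voxel_size_mm": voxel_size_mm},
                                       indent=1, sort_keys=True))
    return path


def load_label_image(path: str | Path) -> tuple[dict[str, np.ndarray], float]:
    path = Path(path)
    img = nib.load(path)
    sidecar_path = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" \
        else path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text())
    vol = np.asarray(img.dataobj)
    labels = {name: vol == code for name, code in sidecar["codes"].items()}
    return labels, float(sidecar["voxel_size_mm"])
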