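"""VOI definition, transfer, and summary statistics.

Includes the semiautomated myocardial contour: on the late (150-min) image,
voxels of an anatomical search region exceeding k x the blood-pool SUVmean,
restricted to the largest 26-connected component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import DynamicImage, GeometryError
from .quantitation import DegenerateInputError


class EmptySegmentationError(ValueError):
    """Raised when thresholding leaves no voxels; carries the threshold."""

    def __init__(self, threshold: float):
        self.threshold = threshold
        super().__init__(
            f"blood-pool threshold {threshold:.4g} excluded every voxel of "
            f"the search region")


@dataclass
class VoiMask:
    """A labeled 3-D boolean mask bound to a source image."""

    label: str
    mask: np.ndarray
    source_image_id: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise DegenerateInputError(f"VOI {self.label!r} is empty")


@dataclass(frozen=True)
class VoiStats:
    """Mean/max over a VOI plus its physical volume."""

    mean: float
    max: float
    volume_mL: float
    n_voxels: int


def voi_statistics(image: DynamicImage, mask: np.ndarray,
                   frame: int = 0) -> VoiStats:
    """Arithmetic mean and maximum of one frame over the masked voxels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.grid_shape:
        raise GeometryError(
            f"mask grid {mask.shape} does not match image grid "
            f"{image.grid_shape}")
    if not mask.any():
        raise DegenerateInputError("empty mask")
    values = image.frame(frame)[mask]
    return VoiStats(mean=float(values.mean()), max=float(values.max()),
                    volume_mL=int(mask.sum()) * image.voxel_volume_ml,
                    n_voxels=int(mask.sum()))


#: 26-neighborhood connectivity for 3-D component selection.
_CONN26 = np.ones((3, 3, 3), dtype=bool)


def segment_myocardium(late_image: DynamicImage, la_bp_mask: np.ndarray,
                       search_region: np.ndarray, k: float = 1.0,
                       frame: int = 0,
                       min_component_voxels: int = 1) -> VoiMask:
    """Blood-pool-threshold myocardial contour on the late image.

    Keeps search-region voxels with value > k x (blood-pool mean on the same
    image), then the largest 26-connected component.  Larger k never yields a
    larger mask (monotone in k).

    ``min_component_voxels`` rejects segmentations whose largest component is
    smaller than a physical floor: on noisy images of subjects without
    myocardial uptake, isolated voxels can exceed the threshold by counting
    noise alone, and a handful of scattered voxels is not a myocardium.
    """
    bp_mean = voi_statistics(late_image, la_bp_mask, frame=frame).mean
    threshold = k * bp_mean
    search_region = np.asarray(search_region, dtype=bool)
    if search_region.shape != late_image.grid_shape:
        raise GeometryError("search region grid does not match the image grid")
    candidate = search_region & (late_image.frame(frame) > threshold)
    if not candidate.any():
        raise EmptySegmentationError(threshold)
    components, n = ndimage.label(candidate, structure=_CONN26)
    sizes = ndimage.sum_labels(np.ones_like(components), components,
                               index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    if sizes[largest - 1] < min_component_voxels:
        raise EmptySegmentationError(threshold)
    return VoiMask(label="LV_myo", mask=components == largest,
                   source_image_id=f"{late_image.schedule.label()}|k={k:g}")


def transfer_vois(masks: dict[str, VoiMask] | list[VoiMask],
                  target_image: DynamicImage) -> dict[str, VoiMask]:
    """Bind late-image VOIs to another image of the same subject.

    Identity transfer on a shared grid — the paper's 'minimal adjustment' of
    late contours on earlier images is implemented as no re-contouring at
    all.  A grid mismatch is an error: no resampling rule is defined.
    """
    if not isinstance(masks, dict):
        masks = {m.label: m for m in masks}
    out = {}
    for label, voi in masks.items():
        if voi.mask.shape != target_image.grid_shape:
            raise GeometryError(
                f"VOI {label!r} grid {voi.mask.shape} does not match target "
                f"grid {target_image.grid_shape}; no resampling rule declared")
        out[label] = VoiMask(label=voi.label, mask=voi.mask,
                             source_image_id=voi.source_image_id
                             + f"->{target_image.schedule.label()}")
    return out
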