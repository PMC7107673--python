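"""Non-contrast CT pre-processing: brain extraction, axial rigid alignment,
median-filter denoising with a [20, 80] attenuation window, and extraction of
the twelve 128x128 candidate patches that bracket the proximal Sylvian fissure
in both hemispheres.

The hyperdense middle-cerebral-artery (MCA) sign — a bright intravascular clot
of roughly 40–80 HU — survives the window while skull (>100 HU) and CSF/air
(<20 HU) are suppressed, so the cropped patches isolate the candidate region
for downstream segmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

__all__ = [
    "CTVolume",
    "PreprocessConfig",
    "ROIStack",
    "RigidTransform",
    "extract_brain",
    "estimate_alignment",
    "register_axial",
    "denoise_window",
    "crop_roi",
    "preprocess_volume",
    "mirror_symmetry_score",
]


@dataclass
class CTVolume:
    """An axial head-CT volume, slices x rows x cols (S x 512 x 512)."""

    voxels: np.ndarray
    pixel_mm: float = 0.426
    slice_mm: float = 5.0
    id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array (slices, rows, cols)")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class PreprocessConfig:
    """Pipeline constants.

    The attenuation window [20, 80] keeps brain parenchyma and clot while
    zeroing skull and CSF; the two bounding boxes are mirror images across the
    mid-axial row axis and each measures 128x128 on the 512x512 grid.
    ``slice_range`` is 1-based inclusive and spans six slices, giving
    6 slices x 2 hemispheres = 12 patches per patient.
    """

    window_low: float = 20.0
    window_high: float = 80.0
    median_kernel: int = 3
    slice_range: tuple[int, int] = (4, 9)
    box_a: tuple[tuple[int, int], tuple[int, int]] = ((128, 256), (212, 340))
    box_b: tuple[tuple[int, int], tuple[int, int]] = ((256, 384), (212, 340))
    skull_threshold: float = 100.0
    air_threshold: float = 10.0
    closing_radius: int = 2
    angle_limit_deg: float = 15.0
    angle_step_deg: float = 0.5

    def __post_init__(self) -> None:
        if self.window_low >= self.window_high:
            raise ValueError("window_low must be < window_high")
        if self.median_kernel % 2 != 1:
            raise ValueError("median_kernel must be odd")
        for box in (self.box_a, self.box_b):
            (r0, r1), (c0, c1) = box
            if (r1 - r0, c1 - c0) != (128, 128):
                raise ValueError("ROI boxes must be 128x128")

    @property
    def slice_indices(self) -> list[int]:
        """0-based slice indices covered by the 1-based inclusive range."""
        lo, hi = self.slice_range
        return list(range(lo - 1, hi))


@dataclass
class RigidTransform:
    """A single in-plane rotation (degrees, about the image centre) plus a
    (row, col) translation shared by every slice."""

    angle_deg: float = 0.0
    shift: tuple[float, float] = (0.0, 0.0)
    symmetry_before: float = float("nan")
    symmetry_after: float = float("nan")

    @property
    def is_identity(self) -> bool:
        return self.angle_deg == 0.0 and self.shift == (0.0, 0.0)


@dataclass
class ROIStack:
    """The 12 cropped candidate patches of one patient, slice-major with
    hemisphere A before hemisphere B within each slice."""

    patient_id: str
    patches: list[np.ndarray]
    provenance: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.patches) != 12:
            raise ValueError(f"expected 12 patches, got {len(self.patches)}")
        for p in self.patches:
            if p.shape != (128, 128):
                raise ValueError("patches must be 128x128")

    def as_array(self) -> np.ndarray:
        return np.stack(self.patches)


def extract_brain(volume: CTVolume, config: PreprocessConfig | None = None) -> np.ndarray:
    """Skull-strip: per slice, keep the largest connected component of
    sub-skull, above-air voxels, then close small gaps.

    Raises ``ValueError`` ("no brain found") when no slice contains tissue.
    """
    config = config or PreprocessConfig()
    vox = volume.voxels
    candidate = (vox > config.air_threshold) & (vox < config.skull_threshold)
    mask = np.zeros_like(candidate)
    selem = morphology.disk(config.closing_radius)
    any_brain = False
    for s in range(vox.shape[0]):
        if not candidate[s].any():
            continue
        labels = measure.label(candidate[s], connectivity=1)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        largest = counts.argmax()
        comp = labels == largest
        comp = ndimage.binary_closing(comp, structure=selem)
        # closing may re-annex skull voxels at the rim; strip them again
        comp &= vox[s] < config.skull_threshold
        mask[s] = comp
        any_brain = True
    if not any_brain:
        raise ValueError("no brain found")
    return mask


def mirror_symmetry_score(image: np.ndarray) -> float:
    """Pearson correlation between a slice and its mirror across the
    mid-row axis (the hemispheric axis of the ROI boxes)."""
    a = image.ravel().astype(np.float64)
    b = image[::-1, :].ravel().astype(np.float64)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _rotate2d(image: np.ndarray, angle_deg: float) -> np.ndarray:
    if angle_deg == 0.0:
        return image
    return ndimage.rotate(image, angle_deg, reshape=False, order=1, mode="constant", cval=0.0)


def _shift2d(image: np.ndarray, shift: tuple[float, float]) -> np.ndarray:
    if shift == (0.0, 0.0):
        return image
    return ndimage.shift(image, shift, order=1, mode="constant", cval=0.0)


def estimate_alignment(volume: CTVolume, config: PreprocessConfig | None = None) -> RigidTransform:
    """Estimate one in-plane rigid transform maximising bilateral symmetry.

    The brain-mask centroid fixes the translation; the rotation comes from a
    grid search over ``±angle_limit_deg`` in ``angle_step_deg`` steps followed
    by a finer local pass, scoring the mirror correlation of the mean
    brain-masked slab. Falls back to the identity (with a warning) when no
    brain is found or the search cannot improve symmetry.
    """
    config = config or PreprocessConfig()
    try:
        mask = extract_brain(volume, config)
    except ValueError:
        warnings.warn("alignment fell back to identity: no brain found", stacklevel=2)
        return RigidTransform()

    slab = (volume.voxels * mask).mean(axis=0)
    centroid = ndimage.center_of_mass(mask.any(axis=0).astype(np.float64))
    target = ((slab.shape[0] - 1) / 2.0, (slab.shape[1] - 1) / 2.0)
    shift = (target[0] - centroid[0], target[1] - centroid[1])

    before = mirror_symmetry_score(slab)
    centred = _shift2d(slab, shift)

    def score(angle: float) -> float:
        return mirror_symmetry_score(_rotate2d(centred, angle))

    step = config.angle_step_deg
    coarse = np.arange(-config.angle_limit_deg, config.angle_limit_deg + step / 2, step)
    scores = [score(a) for a in coarse]
    best = coarse[int(np.argmax(scores))]
    fine = best + np.arange(-step, step + 0.05, 0.1)
    fine_scores = [score(a) for a in fine]
    best = float(fine[int(np.argmax(fine_scores))])
    after = max(fine_scores)

    if after < before:
        warnings.warn("alignment fell back to identity: symmetry did not improve", stacklevel=2)
        return RigidTransform(symmetry_before=before, symmetry_after=before)
    return RigidTransform(angle_deg=best, shift=shift, symmetry_before=before, symmetry_after=float(after))


def register_axial(
    volume: CTVolume,
    config: PreprocessConfig | None = None,
    transform: RigidTransform | None = None,
) -> CTVolume:
    """Apply one shared rigid in-plane transform (estimated if not given) to
    every slice so the hemispheres sit symmetric about the mid-row axis."""
    config = config or PreprocessConfig()
    if transform is None:
        transform = estimate_alignment(volume, config)
    if transform.is_identity:
        return replace(volume, voxels=volume.voxels.copy())
    out = np.empty_like(volume.voxels)
    for s in range(volume.n_slices):
        out[s] = _rotate2d(_shift2d(volume.voxels[s], transform.shift), transform.angle_deg)
    return replace(volume, voxels=out)


def denoise_window(volume: CTVolume, config: PreprocessConfig | None = None) -> CTVolume:
    """Per-slice median filter, then zero every voxel outside
    [window_low, window_high]; in-window voxels pass through unchanged."""
    config = config or PreprocessConfig()
    k = config.median_kernel
    out = np.empty_like(volume.voxels)
    for s in range(volume.n_slices):
        out[s] = ndimage.median_filter(volume.voxels[s], size=k)
    inside = (out >= config.window_low) & (out <= config.window_high)
    out[~inside] = 0.0
    return replace(volume, voxels=out)


def crop_roi(volume: CTVolume, config: PreprocessConfig | None = None) -> ROIStack:
    """Crop the two hemispheric 128x128 boxes from each slice of the
    candidate range: 6 slices x 2 boxes = 12 patches, slice-major."""
    config = config or PreprocessConfig()
    idx = config.slice_indices
    if max(idx) >= volume.n_slices:
        raise ValueError(
            f"insufficient slices: need slice {max(idx) + 1}, volume has {volume.n_slices}"
        )
    patches: list[np.ndarray] = []
    provenance: list[tuple[int, str]] = []
    for s in idx:
        for name, box in (("A", config.box_a), ("B", config.box_b)):
            (r0, r1), (c0, c1) = box
            patches.append(volume.voxels[s, r0:r1, c0:c1].copy())
            provenance.append((s, name))
    return ROIStack(patient_id=volume.id, patches=patches, provenance=provenance)


def preprocess_volume(volume: CTVolume, config: PreprocessConfig | None = None) -> ROIStack:
    """The full four-step pipeline: brain extraction (inside alignment),
    rigid registration, median filter + window, ROI cropping."""
    config = config or PreprocessConfig()
    registered = register_axial(volume, config)
    windowed = denoise_window(registered, config)
    return crop_roi(windowed, config)
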