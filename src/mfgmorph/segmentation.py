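"""Threshold-based particle detection in bright-field micrographs.

Particles appear dark on a light background. The instrument SOP exposes a
"calibration intensity" (fraction of full grayscale taken as the calibrated
background, default 80%) and an "intensity tolerance" (default 0.20); a
pixel is foreground when it is darker than
``calibration_intensity · 255 · (1 − intensity_tolerance)`` — with the
defaults, any intensity below 163.2. Connected components under the chosen
connectivity are labeled, components below the detection floor
(``min_pixels``, default 25) are dropped, border-touching components are
excluded by default (truncated silhouettes bias shape descriptors), and a
hard cap on the component count (default 200,000) guards against
degenerate thresholding. The CE-diameter size gate (default 1.5–130 µm)
is *not* applied here: it belongs to QC filtering, after morphometry, so
that it is auditable per particle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as sk_label

__all__ = ["SegmentationConfig", "LabeledMask", "binarize", "label_particles", "segment"]


@dataclass
class SegmentationConfig:
    calibration_intensity: float = 0.80
    intensity_tolerance: float = 0.20
    min_pixels: int = 25
    max_particles: int = 200_000
    connectivity: int = 8  # 4 or 8
    border_policy: str = "exclude"  # "exclude" | "keep"
    size_gate_um: tuple[float, float] = (1.5, 130.0)

    def __post_init__(self) -> None:
        if not 0 < self.calibration_intensity <= 1:
            raise ValueError("calibration_intensity must be in (0, 1]")
        if not 0 < self.intensity_tolerance < 1:
            raise ValueError("intensity_tolerance must be in (0, 1)")
        if self.min_pixels < 1:
            raise ValueError("min_pixels must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.border_policy not in ("exclude", "keep"):
            raise ValueError("border_policy must be 'exclude' or 'keep'")
        low, high = self.size_gate_um
        if not low < high:
            raise ValueError("size_gate_um must satisfy low < high")

    @property
    def threshold(self) -> float:
        """Foreground threshold on the 0–255 scale (163.2 with defaults)."""
        return self.calibration_intensity * 255.0 * (1.0 - self.intensity_tolerance)


@dataclass
class LabeledMask:
    """Labeled particle raster: labels are contiguous integers 1..n."""

    labels: np.ndarray
    n_particles: int
    _slices: list = field(repr=False, default_factory=list)

    def particle_mask(self, lab: int) -> np.ndarray:
        """Full-frame boolean mask of one particle."""
        if not 1 <= lab <= self.n_particles:
            raise KeyError(f"label {lab} out of range 1..{self.n_particles}")
        return self.labels == lab

    def particle_slices(self, lab: int):
        """Bounding-box slices of one particle (for cropped processing)."""
        if not 1 <= lab <= self.n_particles:
            raise KeyError(f"label {lab} out of range 1..{self.n_particles}")
        return self._slices[lab - 1]

    def pixel_coords(self, lab: int) -> np.ndarray:
        """(n, 2) array of (row, col) pixel coordinates of one particle."""
        return np.argwhere(self.particle_mask(lab))


def binarize(image: np.ndarray, config: SegmentationConfig | None = None) -> np.ndarray:
    """Dark-particle foreground mask: True where intensity < threshold."""
    config = config or SegmentationConfig()
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a single-channel 2-D image, got shape {image.shape}")
    if image.size == 0:
        raise ValueError("empty image")
    return image < config.threshold


def label_particles(mask: np.ndarray, config: SegmentationConfig | None = None) -> LabeledMask:
    """Connected-component labeling with size floor and border policy."""
    config = config or SegmentationConfig()
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    raw = sk_label(mask, connectivity=1 if config.connectivity == 4 else 2)
    n_raw = int(raw.max())
    if n_raw == 0:
        return LabeledMask(labels=np.zeros_like(raw), n_particles=0)

    counts = np.bincount(raw.ravel(), minlength=n_raw + 1)
    keep = counts >= config.min_pixels
    keep[0] = False
    if config.border_policy == "exclude" and n_raw:
        border = np.unique(
            np.concatenate([raw[0, :], raw[-1, :], raw[:, 0], raw[:, -1]])
        )
        keep[border] = False

    n_kept = int(keep.sum())
    if n_kept > config.max_particles:
        raise RuntimeError(
            f"{n_kept} particles detected, exceeding max_particles={config.max_particles}"
        )
    # relabel survivors contiguously, preserving raster order of first pixel
    remap = np.zeros(n_raw + 1, dtype=raw.dtype)
    remap[keep] = np.arange(1, n_kept + 1)
    labels = remap[raw]
    slices = ndimage.find_objects(labels, max_label=n_kept)
    return LabeledMask(labels=labels, n_particles=n_kept, _slices=list(slices))


def segment(image: np.ndarray, config: SegmentationConfig | None = None) -> LabeledMask:
    """Binarize then label: the full detection step for one image."""
    config = config or SegmentationConfig()
    return label_particles(binarize(image, config), config)
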