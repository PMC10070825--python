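"""Core data containers for slices and label masks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GrayscaleSlice", "LabelMask", "CLASS_NAMES", "CLASS_INDICES"]

# Canonical class alphabet.  Indices are the contract everywhere; any color
# scheme used for display is presentation only.
CLASS_NAMES = {0: "background", 1: "RV", 2: "myo", 3: "LV"}
CLASS_INDICES = {v: k for k, v in CLASS_NAMES.items()}


@dataclass
class GrayscaleSlice:
    """One 2D short-axis intensity image with its pixel spacing.

    spacing is (row_mm, col_mm); phase_index runs 0 (end-diastole) to
    n_phases-1 (end-systole).
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    phase_index: int = 0
    subject_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValueError(f"slice pixels must be 2D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("slice contains non-finite pixels")
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if min(self.spacing) <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabelMask:
    """Per-pixel class labels over {0: background, 1: RV, 2: myo, 3: LV}."""

    labels: np.ndarray
    class_names: dict = field(default_factory=lambda: dict(CLASS_NAMES))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("mask labels must be integers")
        bad = np.setdiff1d(np.unique(self.labels), list(CLASS_NAMES))
        if bad.size:
            raise ValueError(f"mask contains out-of-alphabet labels: {bad.tolist()}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def region(self, class_index: int) -> np.ndarray:
        """Boolean pixel set of one class."""
        return self.labels == class_index
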