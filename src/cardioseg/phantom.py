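"""Synthetic short-axis cardiac phantom generator.

Real cine MRI of the heart at mid-ventricular level shows the left
ventricular blood pool as a bright disc, the myocardium as a darker annulus
around it, and the right ventricular blood pool as a bright crescent hugging
the annulus.  The generator draws exactly that stylized geometry — disc,
closed annulus, crescent — with the LV radius shrinking linearly from
end-diastole (phase 0) to end-systole (last phase), per-class mean gray
levels plus additive Gaussian noise, and anisotropic pixel spacing sampled
from the 0.70-1.92 mm range typical of short-axis acquisitions.  Because the
mask is the exact noise-free geometry, every image comes with a perfect gold
standard, which is what makes the full train/evaluate pipeline testable.

Region precedence is LV > myocardium > RV > background: the crescent is
carved from a shell outside the annulus and can never overwrite LV or
myocardial pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .types import GrayscaleSlice, LabelMask

__all__ = ["PhantomSpec", "SpecRanges", "generate_phantom", "generate_dataset",
           "split_dataset", "SPACING_RANGE_MM"]

# printed in-plane resolution range of short-axis cardiac MRI this emulates
SPACING_RANGE_MM = (0.70, 1.92)


@dataclass
class PhantomSpec:
    """Anatomical and noise parameters of one synthetic subject.

    All lengths are in pixels at end-diastole.  contraction_fraction is the
    fractional LV radius reduction reached at end-systole; intensity_means
    maps class index -> mean gray level.  small_structure_scale < 1 shrinks
    all radii, emulating near-apical slices with very few ventricular
    pixels.
    """

    image_size: int = 64
    lv_radius: float = 12.0
    myo_thickness: float = 4.0
    rv_angular_extent: float = 2.0   # radians of crescent arc
    rv_thickness: float = 5.0
    contraction_fraction: float = 0.35
    n_phases: int = 5
    intensity_means: tuple[float, float, float, float] = (30.0, 180.0, 90.0, 200.0)
    noise_sigma: float = 15.0
    pixel_spacing: tuple[float, float] = (1.25, 1.25)
    center_offset: tuple[float, float] = (0.0, 0.0)
    small_structure_scale: float = 1.0
    seed: int = 0
    subject_id: str = "phantom-000"

    def __post_init__(self):
        lo, hi = SPACING_RANGE_MM
        for s in self.pixel_spacing:
            if not lo <= s <= hi:
                raise ValueError(
                    f"pixel spacing {s} mm outside the emulated range [{lo}, {hi}] mm")
        if not 0 <= self.contraction_fraction < 1:
            raise ValueError("contraction_fraction must lie in [0, 1)")
        if self.n_phases < 2:
            raise ValueError("need at least 2 phases (ED and ES)")
        if not 0 < self.small_structure_scale <= 1:
            raise ValueError("small_structure_scale must lie in (0, 1]")
        outer = (self.lv_radius + self.myo_thickness
                 + self.rv_thickness) * self.small_structure_scale
        if outer + max(map(abs, self.center_offset)) >= self.image_size / 2:
            raise ValueError(
                f"structures (outer radius {outer:.1f}px) do not fit in a "
                f"{self.image_size}px frame")
        if len(self.intensity_means) != 4:
            raise ValueError("intensity_means needs one value per class")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")

    def lv_radius_at(self, phase_index: int) -> float:
        """LV radius interpolated linearly between ED and ES."""
        frac = phase_index / (self.n_phases - 1)
        return (self.lv_radius * self.small_structure_scale
                * (1.0 - self.contraction_fraction * frac))


def generate_phantom(spec: PhantomSpec, phase_index: int) -> tuple[GrayscaleSlice, LabelMask]:
    """One phase of one synthetic subject: noisy image + exact mask.

    Deterministic for fixed (spec.seed, phase_index).
    """
    if not 0 <= phase_index < spec.n_phases:
        raise ValueError(
            f"phase_index {phase_index} out of range [0, {spec.n_phases})")
    n = spec.image_size
    cy = (n - 1) / 2.0 + spec.center_offset[0]
    cx = (n - 1) / 2.0 + spec.center_offset[1]
    yy, xx = np.mgrid[0:n, 0:n]
    dy, dx = yy - cy, xx - cx
    dist = np.hypot(dy, dx)

    r_lv = spec.lv_radius_at(phase_index)
    r_myo = r_lv + spec.myo_thickness * spec.small_structure_scale
    r_rv = r_myo + spec.rv_thickness * spec.small_structure_scale

    labels = np.zeros((n, n), dtype=np.uint8)
    # crescent: shell outside the annulus, limited arc centered on the
    # leftward direction (angle pi), i.e. the anatomical RV side
    ang = np.arctan2(dy, dx)
    arc = np.abs(np.mod(ang - np.pi + np.pi, 2 * np.pi) - np.pi) <= spec.rv_angular_extent / 2
    labels[(dist > r_myo) & (dist <= r_rv) & arc] = 1
    labels[(dist > r_lv) & (dist <= r_myo)] = 2
    labels[dist <= r_lv] = 3

    means = np.asarray(spec.intensity_means, dtype=np.float32)
    image = means[labels]
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(phase_index,)))
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape).astype(np.float32)
    sl = GrayscaleSlice(pixels=image, spacing=spec.pixel_spacing,
                        phase_index=phase_index, subject_id=spec.subject_id)
    return sl, LabelMask(labels)


@dataclass
class SpecRanges:
    """Per-field uniform sampling intervals for subject-to-subject variation.

    Each entry is an inclusive (low, high) interval; a collapsed interval
    (low == high) pins the field.  Fields not listed here are taken from
    ``base`` unchanged.
    """

    lv_radius: tuple[float, float] = (9.0, 13.0)
    myo_thickness: tuple[float, float] = (3.0, 5.0)
    rv_thickness: tuple[float, float] = (4.0, 6.0)
    rv_angular_extent: tuple[float, float] = (1.6, 2.4)
    contraction_fraction: tuple[float, float] = (0.25, 0.45)
    pixel_spacing: tuple[float, float] = SPACING_RANGE_MM
    center_jitter: tuple[float, float] = (-2.0, 2.0)
    base: PhantomSpec = field(default_factory=PhantomSpec)

    def __post_init__(self):
        for name in ("lv_radius", "myo_thickness", "rv_thickness",
                     "rv_angular_extent", "contraction_fraction",
                     "pixel_spacing", "center_jitter"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"inverted sampling interval for {name}: ({lo}, {hi})")

    def sample(self, rng: np.random.Generator, subject_id: str, seed: int) -> PhantomSpec:
        def u(iv):
            return float(rng.uniform(iv[0], iv[1])) if iv[0] < iv[1] else float(iv[0])

        return replace(
            self.base,
            lv_radius=u(self.lv_radius),
            myo_thickness=u(self.myo_thickness),
            rv_thickness=u(self.rv_thickness),
            rv_angular_extent=u(self.rv_angular_extent),
            contraction_fraction=u(self.contraction_fraction),
            pixel_spacing=(u(self.pixel_spacing), u(self.pixel_spacing)),
            center_offset=(u(self.center_jitter), u(self.center_jitter)),
            seed=seed,
            subject_id=subject_id,
        )


def generate_dataset(n_subjects: int, spec_ranges: SpecRanges | None = None,
                     seed: int = 0) -> list[tuple[GrayscaleSlice, LabelMask]]:
    """Reproducible multi-subject, multi-phase dataset.

    Returns a flat list of (slice, mask) pairs ordered by subject then
    phase; the slice carries subject_id and phase_index.  A fixed seed
    yields a bit-identical dataset.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ranges = spec_ranges or SpecRanges()
    root = np.random.SeedSequence(entropy=seed)
    pairs = []
    for k, child in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        spec = ranges.sample(rng, subject_id=f"phantom-{k:03d}", seed=sub_seed)
        for phase in range(spec.n_phases):
            pairs.append(generate_phantom(spec, phase))
    return pairs


def split_dataset(dataset, train_fraction: float = 0.8, seed: int = 0):
    """Subject-level train/test partition (no subject straddles the split).

    Train subject count is round(train_fraction * n_subjects); with the
    customary 8:2 ratio, 10 subjects give 8 train and 2 test.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    subjects = []
    for sl, _ in dataset:
        if sl.subject_id not in subjects:
            subjects.append(sl.subject_id)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects to split")
    n_train = round(train_fraction * len(subjects))
    if n_train in (0, len(subjects)):
        raise ValueError(
            f"train_fraction {train_fraction} leaves one side of the split empty")
    order = np.random.default_rng(seed).permutation(len(subjects))
    train_ids = {subjects[i] for i in order[:n_train]}
    train = [pair for pair in dataset if pair[0].subject_id in train_ids]
    test = [pair for pair in dataset if pair[0].subject_id not in train_ids]
    return train, test
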