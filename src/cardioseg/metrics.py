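"""Segmentation accuracy metrics: Dice overlap and surface distances.

Dice(A, B) = 2|A n B| / (|A| + |B|) scores region overlap between a gold
standard A and a segmentation B.  The Hausdorff distance is the largest
nearest-neighbor distance between the two boundary point sets (worst-case
contour disagreement); the average symmetric surface distance (ASSD)
averages the nearest-surface distances over both boundaries:

    ASSD = [ sum_{a in S(A)} d(a, S(B)) + sum_{b in S(B)} d(b, S(A)) ]
           / (|S(A)| + |S(B)|)

Both distance metrics operate on surface pixels — region pixels with at
least one 4-neighbor outside the region (the image border counts as
outside) — under the Euclidean metric, scaled per-axis by the pixel
spacing when one is supplied.  Nearest distances come from an exact
Euclidean distance transform, so they equal brute-force all-pairs search.

Undefined cases: when both regions are empty Dice is 1 by convention; when
exactly one is empty Dice is 0.  Surface distances are undefined whenever
either surface is empty and are reported as NaN sentinels, which the
report excludes from averages (with a count of exclusions) rather than
fabricating a distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import CLASS_INDICES, LabelMask

__all__ = ["BinaryRegion", "dice_coefficient", "surface_pixels",
           "hausdorff_distance", "assd", "evaluate", "MetricReport"]

STRUCTURES = ("LV", "RV", "myo")


@dataclass
class BinaryRegion:
    """One class's pixel set on a grid, with optional mm spacing."""

    mask: np.ndarray
    spacing: tuple[float, float] | None = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("region mask must be 2D")
        if self.spacing is not None:
            self.spacing = (float(self.spacing[0]), float(self.spacing[1]))
            if min(self.spacing) <= 0:
                raise ValueError("spacing must be positive")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def _as_region(x, spacing=None) -> BinaryRegion:
    if isinstance(x, BinaryRegion):
        return x
    return BinaryRegion(np.asarray(x), spacing)


def _check_grids(a: BinaryRegion, b: BinaryRegion):
    if a.mask.shape != b.mask.shape:
        raise ValueError(f"grid mismatch: {a.mask.shape} vs {b.mask.shape}")
    if a.spacing != b.spacing:
        raise ValueError(f"spacing mismatch: {a.spacing} vs {b.spacing}")


def dice_coefficient(a, b) -> float:
    """2|A n B| / (|A| + |B|); 1.0 when both regions are empty."""
    a, b = _as_region(a), _as_region(b)
    _check_grids(a, b)
    denom = a.n_pixels + b.n_pixels
    if denom == 0:
        return 1.0
    return 2.0 * float((a.mask & b.mask).sum()) / denom


def surface_pixels(region, connectivity: int = 4) -> np.ndarray:
    """Boolean map of region pixels with a neighbor outside the region.

    ``connectivity`` chooses the neighborhood that defines "adjacent to
    outside" (4 edge neighbors by default; 8 adds diagonals).  The image
    border counts as outside, so a region touching the edge has its edge
    pixels on the surface.  An empty region yields an empty surface.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    region = _as_region(region)
    m = region.mask
    inside = np.pad(m, 1)
    core = (inside[:-2, 1:-1] & inside[2:, 1:-1]
            & inside[1:-1, :-2] & inside[1:-1, 2:])
    if connectivity == 8:
        core &= (inside[:-2, :-2] & inside[:-2, 2:]
                 & inside[2:, :-2] & inside[2:, 2:])
    return m & ~core


def _directed_min_dists(src_surf: np.ndarray, dst_surf: np.ndarray,
                        spacing) -> np.ndarray:
    """Distance from every src surface pixel to the nearest dst surface pixel."""
    sampling = spacing if spacing is not None else (1.0, 1.0)
    dt = ndimage.distance_transform_edt(~dst_surf, sampling=sampling)
    return dt[src_surf]


def _surface_distance_sets(a, b, spacing=None):
    a, b = _as_region(a, spacing), _as_region(b, spacing)
    _check_grids(a, b)
    sa, sb = surface_pixels(a), surface_pixels(b)
    if not sa.any() or not sb.any():
        return None
    spac = a.spacing
    return (_directed_min_dists(sa, sb, spac), _directed_min_dists(sb, sa, spac))


def hausdorff_distance(a, b, spacing=None) -> float:
    """Symmetric Hausdorff distance between the two surfaces.

    max over both directed worst-case nearest-surface distances; NaN when
    either surface is empty.  Units are mm when spacing is given, pixels
    otherwise.
    """
    sets = _surface_distance_sets(a, b, spacing)
    if sets is None:
        return float("nan")
    d_ab, d_ba = sets
    return float(max(d_ab.max(), d_ba.max()))


def assd(a, b, spacing=None) -> float:
    """Average symmetric surface distance; NaN when either surface is empty."""
    sets = _surface_distance_sets(a, b, spacing)
    if sets is None:
        return float("nan")
    d_ab, d_ba = sets
    return float((d_ab.sum() + d_ba.sum()) / (d_ab.size + d_ba.size))


@dataclass
class MetricReport:
    """Per-structure, per-phase accuracy table.

    Rows are a (structure, phase) MultiIndex with structures LV/RV/myo and
    phases ED/ES/mean; columns dice, hd, assd, n_slices, n_excluded.  The
    mean row is the arithmetic mean of the ED and ES rows.  ``units``
    records whether hd/assd are in mm or pixels.
    """

    table: pd.DataFrame
    units: str = "px"

    def get(self, structure: str, phase: str, metric: str) -> float:
        return float(self.table.loc[(structure, phase), metric])

    def to_csv(self, path) -> None:
        out = self.table.reset_index()
        out.insert(0, "units", self.units)
        out.to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {"units": self.units, "rows": []}
        for (structure, phase), row in self.table.iterrows():
            payload["rows"].append({"structure": structure, "phase": phase,
                                    **{k: (None if pd.isna(v) else float(v))
                                       for k, v in row.items()}})
        import json
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return None


def evaluate(pred_masks, gt_masks, phase_labels, spacings=None) -> MetricReport:
    """Score predicted against gold-standard masks, per structure and phase.

    pred_masks / gt_masks: aligned sequences of LabelMask (or integer
    arrays); phase_labels: per-slice "ED" or "ES" (other labels are
    ignored); spacings: optional per-slice (row_mm, col_mm), switching
    hd/assd to mm.  Per-slice undefined distances are excluded from the
    averages and counted in n_excluded.
    """
    if len(pred_masks) != len(gt_masks) or len(pred_masks) != len(phase_labels):
        raise ValueError("pred, gt and phase label sequences must align one-to-one")
    if spacings is not None and len(spacings) != len(pred_masks):
        raise ValueError("spacings must align with the slices")

    def arr(m):
        return m.labels if isinstance(m, LabelMask) else np.asarray(m)

    per = {(s, ph): {"dice": [], "hd": [], "assd": []}
           for s in STRUCTURES for ph in ("ED", "ES")}
    for i, (pm, gm, ph) in enumerate(zip(pred_masks, gt_masks, phase_labels)):
        p, g = arr(pm), arr(gm)
        if p.shape != g.shape:
            raise ValueError(f"slice {i}: pred/gt grid mismatch {p.shape} vs {g.shape}")
        if ph not in ("ED", "ES"):
            continue
        spac = None if spacings is None else spacings[i]
        for s in STRUCTURES:
            c = CLASS_INDICES[s]
            a, b = g == c, p == c
            cell = per[(s, ph)]
            cell["dice"].append(dice_coefficient(
                BinaryRegion(a, spac), BinaryRegion(b, spac)))
            cell["hd"].append(hausdorff_distance(a, b, spacing=spac))
            cell["assd"].append(assd(a, b, spacing=spac))

    rows = {}
    for s in STRUCTURES:
        for ph in ("ED", "ES"):
            cell = per[(s, ph)]
            hd_arr = np.asarray(cell["hd"], dtype=float)
            as_arr = np.asarray(cell["assd"], dtype=float)
            n = len(cell["dice"])
            n_excl = int(np.isnan(hd_arr).sum()) if n else 0
            rows[(s, ph)] = {
                "dice": float(np.mean(cell["dice"])) if n else float("nan"),
                "hd": float(np.nanmean(hd_arr)) if n and n_excl < n else float("nan"),
                "assd": float(np.nanmean(as_arr)) if n and n_excl < n else float("nan"),
                "n_slices": n,
                "n_excluded": n_excl,
            }
        ed, es = rows[(s, "ED")], rows[(s, "ES")]
        rows[(s, "mean")] = {
            k: (ed[k] + es[k]) / 2 if k in ("dice", "hd", "assd")
            else ed[k] + es[k]
            for k in ed
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index = pd.MultiIndex.from_tuples(table.index, names=["structure", "phase"])
    units = "px" if spacings is None else "mm"
    return MetricReport(table=table, units=units)
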