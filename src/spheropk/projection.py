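"""2D projection-based spheroid size readout.

The 3D stack is reduced by maximum intensity projection along z and the
spheroid outline is segmented by a fixed morphological chain:

    Gaussian blur (σ = 1 px)
    → morphological external gradient (dilation − image, disk r = 1 px)
    → global threshold at the mean intensity of the gradient image
    → opening (disk r = 1 px) → closing (disk r = 3 px) → fill holes
    → keep the largest 8-connected component

The external gradient highlights the spheroid boundary; closing and
hole-filling turn the closed boundary ring into a solid object.  The
area of the largest remaining object, in µm², is the size measure.
Series utilities interpolate the areas onto a regular time grid
(default 84 min) and normalise to a reference frame so spheroids from
different experiments can be averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian
from skimage.measure import label
from skimage.morphology import closing, dilation, disk, opening

__all__ = [
    "Mask2D",
    "max_intensity_projection",
    "segment_spheroid",
    "measure_area",
    "interpolate_series",
    "normalize_series",
    "analyze_stack",
    "area_series",
]


@dataclass
class Mask2D:
    """Binary segmentation result aligned with the projection."""

    mask: np.ndarray  # bool, same shape as the projection
    pixel_size: float = 1.0  # µm per pixel (isotropic in-plane)
    found: bool = True  # False: "no object" (flat/empty image)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def touches_border(self) -> bool:
        m = self.mask
        return bool(m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any())


def max_intensity_projection(stack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum over z of a (nz, ny, nx) stack."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("need a non-empty 3D stack (z, y, x)")
    return stack.max(axis=0)


def segment_spheroid(image: np.ndarray, pixel_size: float = 1.0) -> Mask2D:
    """Segment the spheroid outline in a 2D projection.

    Applies the fixed chain documented in the module docstring.  A flat
    image (no gradient anywhere above the mean, i.e. nothing to
    threshold) yields an empty mask with ``found=False`` rather than an
    error.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    blurred = gaussian(img, sigma=1.0, preserve_range=True)
    grad = dilation(blurred, disk(1)) - blurred
    thr = grad.mean()
    binary = grad > thr
    if not binary.any():
        return Mask2D(np.zeros_like(binary), pixel_size, found=False)
    binary = opening(binary, disk(1))
    binary = closing(binary, disk(3))
    binary = ndi.binary_fill_holes(binary)
    lbl = label(binary, connectivity=2)
    if lbl.max() == 0:
        return Mask2D(np.zeros_like(binary), pixel_size, found=False)
    counts = np.bincount(lbl.ravel())
    counts[0] = 0
    keep = counts.argmax()
    return Mask2D(lbl == keep, pixel_size, found=True)


def measure_area(mask: Mask2D) -> float:
    """Foreground area in µm² (pixel count × pixel area)."""
    return mask.area_px * mask.pixel_size**2


def analyze_stack(stack: np.ndarray, pixel_size: float = 1.0) -> tuple[float, Mask2D]:
    """Project, segment and measure one stack; returns (area µm², mask)."""
    mask = segment_spheroid(max_intensity_projection(stack), pixel_size)
    return measure_area(mask), mask


def interpolate_series(
    times_h: np.ndarray, values: np.ndarray, spacing_min: float = 84.0
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate onto the regular grid t = 0, spacing, … min.

    Only grid nodes inside the observed time range are returned (no
    extrapolation); non-finite observations are dropped first.
    """
    times_h = np.asarray(times_h, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(times_h) & np.isfinite(values)
    times_h, values = times_h[ok], values[ok]
    if times_h.size < 2:
        raise ValueError("need at least two finite observations")
    if np.any(np.diff(times_h) <= 0):
        order = np.argsort(times_h)
        times_h, values = times_h[order], values[order]
    # build the grid in minutes (exact integer multiples of the spacing)
    # and convert once, so observations on grid nodes are hit exactly
    t_min = times_h * 60.0
    k0 = int(np.ceil(t_min[0] / spacing_min - 1e-12))
    k1 = int(np.floor(t_min[-1] / spacing_min + 1e-12))
    grid = (np.arange(k0, k1 + 1) * spacing_min) / 60.0
    return grid, np.interp(grid, times_h, values)


def normalize_series(
    areas: np.ndarray, reference_index: int = 0
) -> np.ndarray:
    """Relative area: area / area[reference_index]."""
    areas = np.asarray(areas, dtype=float)
    ref = areas[reference_index]
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError("reference area must be finite and positive")
    return areas / ref


def common_reference_index(
    area_table: pd.DataFrame, max_index: int = 4
) -> int:
    """Earliest frame index at which every series in the group has a
    finite positive area (the normalisation fallback when frame 0 is
    missing for some spheroid).  Raises if none exists up to
    ``max_index``."""
    for idx in sorted(area_table["frame"].unique()):
        sub = area_table[area_table["frame"] == idx]
        ids = area_table["spheroid_id"].unique()
        if len(sub) == len(ids) and np.all(
            np.isfinite(sub["area_um2"]) & (sub["area_um2"] > 0)
        ):
            if idx > max_index:
                raise ValueError(
                    f"first frame usable by all series is {idx} > {max_index}"
                )
            return int(idx)
    raise ValueError("no frame is usable by every series in the group")


def area_series(
    stacks: list[np.ndarray],
    times_h: np.ndarray,
    pixel_size: float = 1.0,
    spheroid_id: str = "s01",
) -> pd.DataFrame:
    """Measure every frame of one spheroid.

    Returns a tidy table (spheroid_id, frame, time_h, area_um2,
    qc_empty, qc_border); frames without a segmentable object get NaN
    area and qc_empty=True.
    """
    rows = []
    for frame, (stack, t) in enumerate(zip(stacks, times_h)):
        area, mask = analyze_stack(stack, pixel_size)
        rows.append(
            {
                "spheroid_id": spheroid_id,
                "frame": frame,
                "time_h": float(t),
                "area_um2": area if mask.found else np.nan,
                "qc_empty": not mask.found,
                "qc_border": mask.found and mask.touches_border(),
            }
        )
    return pd.DataFrame(rows)
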