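"""Spindle intensity ratios and inter-kinetochore distances.

Implements the follow-up microscopy measurements: background-subtracted,
area-normalized mean intensity of a circular spindle ROI over a z-stack
(used for the acetyl-tubulin/α-tubulin ratio and for total EB1 levels), and
Euclidean inter-kinetochore distances from manually picked sister-kinetochore
pairs in a single focal plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class ZStack:
    """Ordered z-planes per channel role, with physical scale."""

    planes: dict[str, np.ndarray]           # role -> (Z, H, W)
    z_step_um: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.z_step_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("physical scales must be positive")
        shapes = set()
        for role, arr in self.planes.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 3 or arr.shape[0] < 1:
                raise ValueError(f"channel {role!r} must be a (Z, H, W) stack")
            self.planes[role] = arr
            shapes.add(arr.shape)
        if len(shapes) != 1:
            raise ValueError("channel stacks differ in shape")


@dataclass
class CircleROI:
    center_px: tuple[float, float]
    radius_px: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        if self.radius_px <= 0:
            raise ValueError("radius must be positive")
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        m = (rr - self.center_px[0]) ** 2 + (cc - self.center_px[1]) ** 2 \
            <= self.radius_px ** 2
        if not m.any():
            raise ValueError("ROI does not intersect the image")
        return m


def estimate_background(stack: ZStack, roi: CircleROI, role: str,
                        annulus_factor: float = 1.5) -> float:
    """Background per pixel from an annulus outside the ROI (whole stack)."""
    arr = stack.planes[role]
    shape = arr.shape[1:]
    inner = roi.mask(shape)
    outer = CircleROI(roi.center_px, roi.radius_px * annulus_factor).mask(shape)
    ring = outer & ~inner
    if not ring.any():
        ring = ~inner
    return float(arr[:, ring].mean())


def total_intensity(stack: ZStack, roi: CircleROI, role: str,
                    background: float | None = None) -> float:
    """Background-subtracted, area-normalized signal averaged over planes.

    Per plane, the integrated ROI intensity is divided by the ROI area and the
    background level subtracted; the result is the mean over all z-planes.
    """
    if role not in stack.planes:
        raise ValueError(f"channel {role!r} absent from stack")
    if background is None:
        background = estimate_background(stack, roi, role)
    arr = stack.planes[role]
    m = roi.mask(arr.shape[1:])
    area = m.sum()
    per_plane = arr[:, m].sum(axis=1) / area - background
    return float(per_plane.mean())


def intensity_ratio(stack: ZStack, roi: CircleROI, num_role: str, den_role: str,
                    background: dict[str, float] | None = None) -> float:
    """Ratio of two channels' area-normalized, background-subtracted means
    over the stack (e.g. acetylated α-tubulin over total α-tubulin)."""
    bg = background or {}
    num = total_intensity(stack, roi, num_role, bg.get(num_role))
    den = total_intensity(stack, roi, den_role, bg.get(den_role))
    if den <= 0:
        raise ValueError("non-positive denominator signal after background subtraction")
    return num / den


def interkt_distances(pairs, pixel_size_um: float | None = None) -> dict:
    """Euclidean distances (µm) between sister-kinetochore pairs.

    ``pairs`` is a sequence of ``(point_a, point_b)`` with points as (row,
    col) in pixels, or of ``(point_a, point_b, pixel_size_um)``.  Returns the
    per-pair distances and per-cell summary (mean, median, n).
    """
    if len(pairs) == 0:
        raise ValueError("need at least one kinetochore pair")
    dists = []
    for pair in pairs:
        if len(pair) == 3:
            a, b, px = pair
        else:
            a, b = pair
            px = pixel_size_um
        if px is None or px <= 0:
            raise ValueError("pixel size required and positive")
        if tuple(a) == tuple(b):
            raise ValueError("coincident kinetochore points")
        dists.append(math.hypot(a[0] - b[0], a[1] - b[1]) * px)
    arr = np.asarray(dists)
    return {"distances_um": dists,
            "mean_um": float(arr.mean()),
            "median_um": float(np.median(arr)),
            "n_pairs": len(dists)}
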