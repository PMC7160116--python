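"""Synthetic well and plate generator with per-cell ground truth.

The generator emulates the statistical structure of a fixed-cell 384-well
mitotic-phenotype screen: interphase nuclei, PHH3-positive mitotic figures,
anaphase/telophase nucleus pairs (optionally with chromatin bridges or lagging
chromatids between the separating masses), bi-/multinucleated cells, dead-cell
debris, and α-tubulin cytokinetic bridges with a γ-tubulin midbody spot.  It
does not attempt photorealism: cells are soft-edged elliptical blobs convolved
with a Gaussian PSF, plus Poisson and Gaussian noise, rendered at a ×20-air
objective scale (0.65 µm/px by default).  Geometry and amplitude defaults are
free parameters of the generator, chosen so that the phenotype classes are
separable by the default rule cascade in :mod:`mitoscan.phenotyping`.

Each well is rendered from its own deterministic substream: the per-well seed
is derived from the plate seed via ``SeedSequence(plate_seed, spawn_key=(row,
col))``, so any well is reproducible in isolation.

Intensity units are arbitrary; the documented scale is ``background_level`` 8
with nuclear DNA amplitudes of 45-120 units above background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .image import CHANNEL_SETS, MultiChannelImage

PHENOTYPES = ("interphase", "mitotic", "anaphase", "telophase", "multinucleated", "dead")

#: default class mix of an unperturbed well (fractions of cells)
DEFAULT_CLASS_FRACTIONS = {
    "interphase": 0.80,
    "mitotic": 0.05,
    "anaphase": 0.012,
    "telophase": 0.012,
    "multinucleated": 0.016,
    "dead": 0.11,
}

# geometry in micrometres, amplitudes in arbitrary intensity units above
# background.  These constants define the simulator's "study conditions".
GEOM = {
    "interphase_semi_major_um": (7.0, 0.5),     # (mean, sd)
    "interphase_axis_ratio": (0.78, 0.95),      # uniform range minor/major
    "interphase_dna_amp": (60.0, 5.0),
    "cytoplasm_margin_um": 4.5,
    "cytoplasm_tubulin_amp": (25.0, 2.0),
    "mitotic_radius_um": (3.5, 0.25),
    "mitotic_dna_amp": (120.0, 8.0),
    "mitotic_phh3_amp": (60.0, 6.0),
    "spindle_radius_um": 4.5,
    "spindle_tubulin_amp": 60.0,
    "anatelo_semi_along_um": 1.8,               # anaphase mass half-thickness
    "anatelo_semi_perp_um": 3.8,                # half-width of the mass plate
    "anatelo_gap_um": (1.8, 2.45),              # uniform boundary gap
    "anatelo_dna_amp": (110.0, 8.0),
    "anatelo_phh3_amp": (55.0, 6.0),
    "midbody_tubulin_amp": 60.0,
    "midbody_len_um": 1.6,
    "midbody_gamma_amp": 50.0,
    "cse_dna_amp": 22.0,
    "cse_half_width_px": 1.0,
    "binucleate_radius_um": (5.0, 0.25),
    "binucleate_sep_um": 9.0,
    "trinucleate_radius_um": (4.5, 0.2),
    "trinucleate_tri_radius_um": 5.0,
    "multinuc_low_tubulin_amp": 14.0,
    "dead_radius_um": (3.0, 3.5),               # uniform range
    "dead_dna_amp": (45.0, 5.0),
    "bridge_partner_dist_um": 24.0,
    "bridge_tubulin_amp": 50.0,
    "bridge_half_width_px": 0.8,
    "bridge_gamma_amp": 60.0,
    "min_unit_clearance_um": 2.0,
}


@dataclass
class SimCellSpec:
    """Ground-truth description of one simulated cell (or cell group)."""

    cell_id: int
    phenotype: str
    centroid_px: tuple[float, float]
    orientation_rad: float
    nucleus_axes_px: tuple[float, float]        # semi-axes of one nucleus/mass
    dna_amplitude: float
    marker_amplitudes: dict[str, float] = field(default_factory=dict)
    has_cse: bool = False
    pair_separation_um: float = 0.0             # boundary gap, ana/telo only
    n_nuclei: int = 1
    has_bridge: bool = False
    bridge_partner: int | None = None
    nucleus_centroids_px: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.dna_amplitude < 0 or not math.isfinite(self.dna_amplitude):
            raise ValueError("dna_amplitude must be finite and non-negative")
        for v in self.marker_amplitudes.values():
            if v < 0 or not math.isfinite(v):
                raise ValueError("marker amplitudes must be finite and non-negative")
        if self.phenotype in ("anaphase", "telophase") and self.pair_separation_um <= 0:
            raise ValueError("pair_separation_um must be > 0 for anaphase/telophase")
        if self.phenotype == "multinucleated" and self.n_nuclei < 2:
            raise ValueError("multinucleated cells need n_nuclei >= 2")


@dataclass
class WellSimConfig:
    image_shape_px: tuple[int, int] = (640, 640)
    pixel_size_um: float = 0.65
    n_cells: int = 100
    class_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS))
    cse_rate: float = 0.05
    bridge_rate: float = 0.03
    psf_sigma_px: float = 0.4
    background_level: float = 8.0
    gaussian_noise_sd: float = 1.5
    poisson_scaling: float = 0.25
    channel_set: str = "screenB"
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_shape_px
        if h <= 0 or w <= 0:
            raise ValueError("image shape must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        total = sum(self.class_fractions.get(p, 0.0) for p in PHENOTYPES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {total}, expected 1")
        for name in ("cse_rate", "bridge_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.channel_set not in CHANNEL_SETS:
            raise ValueError(f"unknown channel_set {self.channel_set!r}")


@dataclass
class GroundTruth:
    cells: list[SimCellSpec]
    true_counts: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            rows.append({
                "cell_id": c.cell_id, "phenotype": c.phenotype,
                "row_px": c.centroid_px[0], "col_px": c.centroid_px[1],
                "orientation_rad": c.orientation_rad,
                "n_nuclei": c.n_nuclei, "has_cse": c.has_cse,
                "pair_separation_um": c.pair_separation_um,
                "has_bridge": c.has_bridge, "bridge_partner": c.bridge_partner,
            })
        return pd.DataFrame(rows)


def count_truth(cells: list[SimCellSpec]) -> dict[str, int]:
    """Enumerate per-well ground-truth counts from the cell list."""
    by = {p: sum(1 for c in cells if c.phenotype == p) for p in PHENOTYPES}
    counts = {
        "n_cells": len(cells),
        "dead": by["dead"],
        "viable": len(cells) - by["dead"],
        "interphase": by["interphase"],
        "mitotic": by["mitotic"] + by["anaphase"] + by["telophase"],
        "anaphase": by["anaphase"],
        "telophase": by["telophase"],
        "anaphase_with_cse": sum(
            1 for c in cells if c.phenotype == "anaphase" and c.has_cse),
        "multinucleated": by["multinucleated"],
        "bridges": sum(1 for c in cells if c.has_bridge) // 2,
    }
    return counts


def true_ratios(counts: dict[str, int]) -> dict[str, float]:
    """Density-normalized true ratios matching the screen's four features."""
    v = counts["viable"]
    return {
        "mitotic_index": counts["mitotic"] / v if v else 0.0,
        "multinucleation_index": counts["multinucleated"] / v if v else 0.0,
        "cse_rate": (counts["anaphase_with_cse"] / counts["anaphase"]
                     if counts["anaphase"] else 0.0),
        "bridge_rate": counts["bridges"] / v if v else 0.0,
        "viability": float(v),
    }


# --------------------------------------------------------------------------
# cell sampling
# --------------------------------------------------------------------------

_UNIT_RADIUS_UM = {
    "interphase": 9.0, "mitotic": 6.0, "anaphase": 8.0, "telophase": 8.0,
    "multinucleated": 11.0, "dead": 4.0,
}


def _place_units(rng: np.random.Generator, units: list[str],
                 shape: tuple[int, int], px: float) -> list[tuple[float, float]]:
    """Dart-throwing placement with per-class exclusion radii (in px)."""
    h, w = shape
    margin = 12.0 / px
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    clearance = GEOM["min_unit_clearance_um"] / px
    for kind in units:
        r_unit = _UNIT_RADIUS_UM[kind] / px
        placed = None
        for _ in range(300):
            cand = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
            ok = True
            for (cr, cc), rr in zip(centers, radii):
                if math.hypot(cand[0] - cr, cand[1] - cc) < rr + r_unit + clearance:
                    ok = False
                    break
            if ok:
                placed = cand
                break
        if placed is None:  # crowded well: accept overlap rather than drop the cell
            placed = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
        centers.append(placed)
        radii.append(r_unit)
    return centers


def sample_well_cells(config: WellSimConfig,
                      rng: np.random.Generator | None = None) -> list[SimCellSpec]:
    """Sample the ground-truth cell list for one well (no rendering)."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    fracs = np.array([config.class_fractions.get(p, 0.0) for p in PHENOTYPES])
    counts = rng.multinomial(config.n_cells, fracs)
    by_class = dict(zip(PHENOTYPES, counts))

    # decide cytokinetic-bridge pairs among interphase cells; bridge_rate is
    # calibrated so that E[#bridges] ~= bridge_rate * n_cells
    n_inter = by_class["interphase"]
    slots = n_inter // 2
    p_unit = 0.0
    if slots:
        p_unit = min(1.0, config.bridge_rate * config.n_cells / slots)
    n_bridge_units = int(rng.binomial(slots, p_unit)) if slots else 0

    units: list[tuple[str, int]] = []          # (phenotype, cells_in_unit)
    units += [("interphase", 2)] * n_bridge_units
    units += [("interphase", 1)] * (n_inter - 2 * n_bridge_units)
    for p in ("mitotic", "anaphase", "telophase", "multinucleated", "dead"):
        units += [(p, 1)] * by_class[p]
    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    centers = _place_units(rng, [u[0] for u in units], config.image_shape_px,
                           config.pixel_size_um)
    px = config.pixel_size_um
    cells: list[SimCellSpec] = []
    cid = 0
    for (kind, n_in_unit), center in zip(units, centers):
        if kind == "interphase" and n_in_unit == 2:
            theta = rng.uniform(0, 2 * math.pi)
            d = GEOM["bridge_partner_dist_um"] / px
            c1 = center
            c2 = (center[0] + d * math.sin(theta), center[1] + d * math.cos(theta))
            h, w = config.image_shape_px
            c2 = (min(max(c2[0], 8.0), h - 8.0), min(max(c2[1], 8.0), w - 8.0))
            a = cells_interphase(rng, c1, px, cid, bridge_partner=cid + 1)
            b = cells_interphase(rng, c2, px, cid + 1, bridge_partner=cid)
            cells += [a, b]
            cid += 2
        else:
            cells.append(_sample_cell(rng, kind, center, px, cid, config))
            cid += 1
    return cells


def cells_interphase(rng, center, px, cid, bridge_partner=None) -> SimCellSpec:
    a = max(4.0, rng.normal(*GEOM["interphase_semi_major_um"]))
    b = a * rng.uniform(*GEOM["interphase_axis_ratio"])
    return SimCellSpec(
        cell_id=cid, phenotype="interphase", centroid_px=center,
        orientation_rad=rng.uniform(0, math.pi),
        nucleus_axes_px=(a / px, b / px),
        dna_amplitude=max(5.0, rng.normal(*GEOM["interphase_dna_amp"])),
        marker_amplitudes={"tubulin": max(5.0, rng.normal(*GEOM["cytoplasm_tubulin_amp"]))},
        has_bridge=bridge_partner is not None, bridge_partner=bridge_partner,
        nucleus_centroids_px=[center],
    )


def _sample_cell(rng, kind, center, px, cid, config: WellSimConfig) -> SimCellSpec:
    if kind == "interphase":
        return cells_interphase(rng, center, px, cid)
    if kind == "mitotic":
        r = max(2.0, rng.normal(*GEOM["mitotic_radius_um"]))
        return SimCellSpec(
            cell_id=cid, phenotype="mitotic", centroid_px=center,
            orientation_rad=rng.uniform(0, math.pi),
            nucleus_axes_px=(r / px, r / px),
            dna_amplitude=rng.normal(*GEOM["mitotic_dna_amp"]),
            marker_amplitudes={
                "phh3": max(10.0, rng.normal(*GEOM["mitotic_phh3_amp"])),
                "tubulin": max(5.0, rng.normal(*GEOM["cytoplasm_tubulin_amp"])),
            },
            nucleus_centroids_px=[center],
        )
    if kind in ("anaphase", "telophase"):
        theta = rng.uniform(0, 2 * math.pi)
        gap = rng.uniform(*GEOM["anatelo_gap_um"])
        a = GEOM["anatelo_semi_along_um"] * rng.uniform(0.95, 1.1)
        b = GEOM["anatelo_semi_perp_um"] * rng.uniform(0.9, 1.1)
        half = (gap / 2 + a) / px
        dr, dc = math.sin(theta), math.cos(theta)
        n1 = (center[0] - half * dr, center[1] - half * dc)
        n2 = (center[0] + half * dr, center[1] + half * dc)
        has_cse = bool(rng.random() < config.cse_rate)
        return SimCellSpec(
            cell_id=cid, phenotype=kind, centroid_px=center,
            orientation_rad=theta,
            nucleus_axes_px=(b / px, a / px),   # major = perpendicular plate width
            dna_amplitude=rng.normal(*GEOM["anatelo_dna_amp"]),
            marker_amplitudes={
                "phh3": max(10.0, rng.normal(*GEOM["anatelo_phh3_amp"])),
                "tubulin": max(5.0, rng.normal(*GEOM["cytoplasm_tubulin_amp"])),
            },
            has_cse=has_cse, pair_separation_um=gap, n_nuclei=2,
            nucleus_centroids_px=[n1, n2],
        )
    if kind == "multinucleated":
        k = 2 if rng.random() < 0.6 else 3
        theta = rng.uniform(0, 2 * math.pi)
        if k == 2:
            r = max(3.0, rng.normal(*GEOM["binucleate_radius_um"]))
            half = GEOM["binucleate_sep_um"] / 2 / px
            dr, dc = math.sin(theta), math.cos(theta)
            nuclei = [(center[0] - half * dr, center[1] - half * dc),
                      (center[0] + half * dr, center[1] + half * dc)]
            tub = max(5.0, rng.normal(*GEOM["cytoplasm_tubulin_amp"]))
        else:
            r = max(3.0, rng.normal(*GEOM["trinucleate_radius_um"]))
            tri = GEOM["trinucleate_tri_radius_um"] / px
            nuclei = [(center[0] + tri * math.sin(theta + i * 2 * math.pi / 3),
                       center[1] + tri * math.cos(theta + i * 2 * math.pi / 3))
                      for i in range(3)]
            tub = GEOM["multinuc_low_tubulin_amp"]
        return SimCellSpec(
            cell_id=cid, phenotype="multinucleated", centroid_px=center,
            orientation_rad=theta, nucleus_axes_px=(r / px, r / px),
            dna_amplitude=max(5.0, rng.normal(*GEOM["interphase_dna_amp"])),
            marker_amplitudes={"tubulin": tub},
            n_nuclei=k, nucleus_centroids_px=nuclei,
        )
    # dead debris: small bright fragment without any tubulin staining
    r = rng.uniform(*GEOM["dead_radius_um"])
    return SimCellSpec(
        cell_id=cid, phenotype="dead", centroid_px=center,
        orientation_rad=rng.uniform(0, math.pi),
        nucleus_axes_px=(r / px, r / px * rng.uniform(0.8, 1.0)),
        dna_amplitude=max(10.0, rng.normal(*GEOM["dead_dna_amp"])),
        marker_amplitudes={}, nucleus_centroids_px=[center],
    )


# --------------------------------------------------------------------------
# rendering primitives
# --------------------------------------------------------------------------

def _patch(plane: np.ndarray, center, extent) -> tuple[slice, slice, np.ndarray, np.ndarray]:
    h, w = plane.shape
    r0 = max(0, int(center[0] - extent))
    r1 = min(h, int(center[0] + extent) + 2)
    c0 = max(0, int(center[1] - extent))
    c1 = min(w, int(center[1] + extent) + 2)
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    return slice(r0, r1), slice(c0, c1), rr, cc


def _add_ellipse(plane, center, semi_axes_px, orientation, amp, edge=0.12):
    a, b = semi_axes_px
    if a <= 0 or b <= 0:
        return
    extent = max(a, b) * (1 + edge) + 2
    sr, sc, rr, cc = _patch(plane, center, extent)
    if rr.size == 0:
        return
    dr = rr - center[0]
    dc = cc - center[1]
    # orientation measured as angle of the major axis from the column axis
    u = dc * math.cos(orientation) + dr * math.sin(orientation)
    v = -dc * math.sin(orientation) + dr * math.cos(orientation)
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    cov = np.clip((1.0 - rho) / edge + 0.5, 0.0, 1.0)
    plane[sr, sc] += (amp * cov).astype(plane.dtype)


def _add_line(plane, p0, p1, amp, half_width_px):
    r0, c0 = p0
    r1, c1 = p1
    extent_center = ((r0 + r1) / 2, (c0 + c1) / 2)
    extent = math.hypot(r1 - r0, c1 - c0) / 2 + half_width_px + 2
    sr, sc, rr, cc = _patch(plane, extent_center, extent)
    if rr.size == 0:
        return
    dr, dc = r1 - r0, c1 - c0
    length2 = dr * dr + dc * dc
    if length2 == 0:
        return
    t = ((rr - r0) * dr + (cc - c0) * dc) / length2
    t = np.clip(t, 0.0, 1.0)
    dist = np.hypot(rr - (r0 + t * dr), cc - (c0 + t * dc))
    cov = np.clip(half_width_px + 0.5 - dist, 0.0, 1.0)
    plane[sr, sc] += (amp * cov).astype(plane.dtype)


def _add_spot(plane, center, amp, sigma_px):
    extent = 4 * sigma_px + 2
    sr, sc, rr, cc = _patch(plane, center, extent)
    if rr.size == 0:
        return
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    plane[sr, sc] += (amp * np.exp(-d2 / (2 * sigma_px ** 2))).astype(plane.dtype)


# --------------------------------------------------------------------------
# well rendering
# --------------------------------------------------------------------------

def _render_cell(planes: dict[str, np.ndarray], cell: SimCellSpec, px: float,
                 channel_set: str) -> None:
    dna = planes["dna"]
    tub = planes["tubulin"]
    marker = "phh3" if channel_set == "screenB" else "cep215"
    cyto_margin = GEOM["cytoplasm_margin_um"] / px
    tub_amp = cell.marker_amplitudes.get("tubulin", 0.0)

    if cell.phenotype in ("interphase", "multinucleated"):
        a, b = cell.nucleus_axes_px
        if cell.phenotype == "multinucleated":
            span = max(math.hypot(n[0] - cell.centroid_px[0], n[1] - cell.centroid_px[1])
                       for n in cell.nucleus_centroids_px)
            _add_ellipse(tub, cell.centroid_px,
                         (span + a + cyto_margin, span + a + cyto_margin),
                         cell.orientation_rad, tub_amp)
        else:
            _add_ellipse(tub, cell.centroid_px, (a + cyto_margin, b + cyto_margin),
                         cell.orientation_rad, tub_amp)
        for n in cell.nucleus_centroids_px:
            _add_ellipse(dna, n, (a, b), cell.orientation_rad, cell.dna_amplitude)
        if channel_set == "screenA" and cell.phenotype == "interphase":
            # interphase centrosome focus in the CEP215 channel
            _add_spot(planes["cep215"], cell.nucleus_centroids_px[0],
                      30.0, 1.2)
    elif cell.phenotype == "mitotic":
        r = cell.nucleus_axes_px[0]
        _add_ellipse(tub, cell.centroid_px,
                     (r + cyto_margin, r + cyto_margin), 0.0, tub_amp)
        spindle = GEOM["spindle_radius_um"] / px
        _add_ellipse(tub, cell.centroid_px, (spindle, spindle), 0.0,
                     GEOM["spindle_tubulin_amp"])
        _add_ellipse(dna, cell.centroid_px, (r, r), 0.0, cell.dna_amplitude)
        if channel_set == "screenB":
            _add_ellipse(planes["phh3"], cell.centroid_px, (r, r), 0.0,
                         cell.marker_amplitudes.get("phh3", 0.0))
    elif cell.phenotype in ("anaphase", "telophase"):
        theta = cell.orientation_rad
        b, a = cell.nucleus_axes_px          # (perp half-width, along half-thickness)
        gap_px = cell.pair_separation_um / px
        half_span = gap_px / 2 + 2 * a + cyto_margin
        _add_ellipse(tub, cell.centroid_px, (half_span, b + cyto_margin),
                     theta, tub_amp)
        # chromosome plates, long axis perpendicular to the division axis
        for n in cell.nucleus_centroids_px:
            _add_ellipse(dna, n, (b, a), theta + math.pi / 2, cell.dna_amplitude)
            if channel_set == "screenB":
                _add_ellipse(planes["phh3"], n, (b, a), theta + math.pi / 2,
                             cell.marker_amplitudes.get("phh3", 0.0))
        dr, dc = math.sin(theta), math.cos(theta)
        if cell.phenotype == "telophase":
            half_mb = GEOM["midbody_len_um"] / 2 / px
            p0 = (cell.centroid_px[0] - half_mb * dr, cell.centroid_px[1] - half_mb * dc)
            p1 = (cell.centroid_px[0] + half_mb * dr, cell.centroid_px[1] + half_mb * dc)
            _add_line(tub, p0, p1, GEOM["midbody_tubulin_amp"], 0.9)
            if "gamma_tubulin" in planes:
                _add_spot(planes["gamma_tubulin"], cell.centroid_px,
                          GEOM["midbody_gamma_amp"], 1.1)
        if cell.has_cse:
            inner = max(0.3, gap_px / 2 - 0.3)
            p0 = (cell.centroid_px[0] - inner * dr, cell.centroid_px[1] - inner * dc)
            p1 = (cell.centroid_px[0] + inner * dr, cell.centroid_px[1] + inner * dc)
            _add_line(dna, p0, p1, GEOM["cse_dna_amp"], GEOM["cse_half_width_px"])
    elif cell.phenotype == "dead":
        a, b = cell.nucleus_axes_px
        _add_ellipse(dna, cell.centroid_px, (a, b), cell.orientation_rad,
                     cell.dna_amplitude)


def _render_bridges(planes, cells: list[SimCellSpec], px: float) -> None:
    tub = planes["tubulin"]
    done = set()
    for cell in cells:
        if not cell.has_bridge or cell.cell_id in done or cell.bridge_partner is None:
            continue
        partner = next((c for c in cells if c.cell_id == cell.bridge_partner), None)
        if partner is None:
            continue
        done.update({cell.cell_id, partner.cell_id})
        p0 = np.array(cell.centroid_px)
        p1 = np.array(partner.centroid_px)
        mid = (p0 + p1) / 2
        # two bright half-bridges flanking a dim midbody gap
        for (t0, t1) in ((0.30, 0.44), (0.56, 0.70)):
            _add_line(tub, tuple(p0 + t0 * (p1 - p0)), tuple(p0 + t1 * (p1 - p0)),
                      GEOM["bridge_tubulin_amp"], GEOM["bridge_half_width_px"])
        if "gamma_tubulin" in planes:
            _add_spot(planes["gamma_tubulin"], tuple(mid),
                      GEOM["bridge_gamma_amp"], 1.2)


def render_well(config: WellSimConfig) -> tuple[MultiChannelImage, GroundTruth]:
    """Render one synthetic well and return the image plus ground truth."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    cells = sample_well_cells(config, rng)
    roles = CHANNEL_SETS[config.channel_set]
    h, w = config.image_shape_px
    planes = {r: np.zeros((h, w), dtype=np.float32) for r in roles}
    for cell in cells:
        _render_cell(planes, cell, config.pixel_size_um, config.channel_set)
    _render_bridges(planes, cells, config.pixel_size_um)
    for role in roles:  # fixed order => bit-reproducible noise
        img = planes[role]
        if config.psf_sigma_px > 0:
            img = ndi.gaussian_filter(img, config.psf_sigma_px)
        img = img + config.background_level
        if config.poisson_scaling > 0:
            g = config.poisson_scaling
            img = rng.poisson(np.maximum(img, 0.0) / g).astype(np.float32) * g
        if config.gaussian_noise_sd > 0:
            img = img + rng.normal(0.0, config.gaussian_noise_sd,
                                   img.shape).astype(np.float32)
        planes[role] = np.maximum(img, 0.0).astype(np.float32)
    image = MultiChannelImage(planes, config.pixel_size_um, roles)
    return image, GroundTruth(cells=cells, true_counts=count_truth(cells))


# --------------------------------------------------------------------------
# plates
# --------------------------------------------------------------------------

_ROWS = "ABCDEFGHIJKLMNOP"


def well_name(row: int, col: int) -> str:
    return f"{_ROWS[row]}{col + 1:02d}"


@dataclass
class PlateSimConfig:
    base_well: WellSimConfig = field(default_factory=WellSimConfig)
    n_rows: int = 16
    n_cols: int = 24
    plate_id: str = "P1"
    hit_wells: dict[str, dict[str, float]] = field(default_factory=dict)
    control_wells: dict[str, str] = field(default_factory=dict)
    well_overrides: dict[str, dict[str, float]] = field(default_factory=dict)
    layout: dict[str, str] = field(default_factory=dict)   # well -> target id
    plate_factor: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_rows < 1 or self.n_rows > len(_ROWS) or self.n_cols < 1:
            raise ValueError("invalid plate geometry")
        if self.plate_factor <= 0:
            raise ValueError("plate_factor must be positive")
        valid = {well_name(r, c) for r in range(self.n_rows) for c in range(self.n_cols)}
        for name, wells in (("hit_wells", self.hit_wells),
                            ("control_wells", self.control_wells),
                            ("well_overrides", self.well_overrides)):
            bad = set(wells) - valid
            if bad:
                raise ValueError(f"{name} outside plate geometry: {sorted(bad)}")
        overlap = set(self.hit_wells) & set(self.control_wells)
        if overlap:
            raise ValueError(f"wells assigned as both hit and control: {sorted(overlap)}")
        role_ok = {"negative", "positive_mitotic", "positive_cytokinesis"}
        bad_roles = set(self.control_wells.values()) - role_ok
        if bad_roles:
            raise ValueError(f"unknown control roles: {sorted(bad_roles)}")


_CONTROL_OVERRIDES = {
    "negative": {},
    "positive_mitotic": {"mitotic": 0.15},
    "positive_cytokinesis": {"multinucleated": 0.10, "bridge_rate": 0.08},
}


def _apply_overrides(base: WellSimConfig, overrides: dict[str, float],
                     seed: int) -> WellSimConfig:
    fracs = dict(base.class_fractions)
    cse = base.cse_rate
    bridge = base.bridge_rate
    for key, val in overrides.items():
        if key == "cse_rate":
            cse = val
        elif key == "bridge_rate":
            bridge = val
        elif key in PHENOTYPES:
            fracs[key] = val
        else:
            raise ValueError(f"unknown override {key!r}")
    other = sum(v for k, v in fracs.items() if k != "interphase")
    if other > 1.0 + 1e-9:
        raise ValueError("overridden fractions exceed 1")
    fracs["interphase"] = max(0.0, 1.0 - other)
    return replace(base, class_fractions=fracs, cse_rate=cse,
                   bridge_rate=bridge, seed=seed)


def well_seed(plate_seed: int, row: int, col: int) -> int:
    ss = np.random.SeedSequence(entropy=plate_seed, spawn_key=(row, col))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def iter_plate_wells(config: PlateSimConfig) -> Iterator[tuple[str, WellSimConfig]]:
    """Yield (well_id, fully-resolved well config) in row-major order."""
    config.validate()
    for r in range(config.n_rows):
        for c in range(config.n_cols):
            wid = well_name(r, c)
            overrides: dict[str, float] = {}
            if wid in config.control_wells:
                overrides.update(_CONTROL_OVERRIDES[config.control_wells[wid]])
            if wid in config.well_overrides:
                overrides.update(config.well_overrides[wid])
            if wid in config.hit_wells:
                overrides.update(config.hit_wells[wid])
            cfg = _apply_overrides(config.base_well, overrides,
                                   well_seed(config.seed, r, c))
            yield wid, cfg


def plate_truth_row(config: PlateSimConfig, wid: str, gt: GroundTruth) -> list[dict]:
    """True per-well ratio rows (one per feature), with the plate batch factor
    applied multiplicatively as the spec of the batch effect."""
    ratios = true_ratios(gt.true_counts)
    is_ctl = wid in config.control_wells
    target = config.layout.get(wid, wid)
    return [{
        "plate_id": config.plate_id, "well_id": wid, "target_id": target,
        "feature": feat, "ratio": val * config.plate_factor,
        "is_control": is_ctl,
        "control_role": config.control_wells.get(wid, ""),
    } for feat, val in ratios.items()]


def simulate_plate(config: PlateSimConfig
                   ) -> tuple[dict[str, tuple[MultiChannelImage, GroundTruth]],
                              pd.DataFrame]:
    """Render every well of a plate; returns images+truth and the true ratio table."""
    wells: dict[str, tuple[MultiChannelImage, GroundTruth]] = {}
    rows: list[dict] = []
    for wid, cfg in iter_plate_wells(config):
        img, gt = render_well(cfg)
        wells[wid] = (img, gt)
        rows += plate_truth_row(config, wid, gt)
    return wells, pd.DataFrame(rows)


def simulate_plate_truth(config: PlateSimConfig) -> pd.DataFrame:
    """True ratio table only (no rendering) — cheap path for statistical tests."""
    rows: list[dict] = []
    for wid, cfg in iter_plate_wells(config):
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
        cells = sample_well_cells(cfg, rng)
        gt = GroundTruth(cells=cells, true_counts=count_truth(cells))
        rows += plate_truth_row(config, wid, gt)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# disk output
# --------------------------------------------------------------------------

def write_well(out_dir: str | Path, well_id: str, image: MultiChannelImage,
               gt: GroundTruth) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    image.save(out / f"{well_id}.tif")
    gt.to_frame().to_csv(out / f"{well_id}_cells.csv", index=False)
    pd.DataFrame([gt.true_counts]).to_csv(out / f"{well_id}_counts.csv", index=False)
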