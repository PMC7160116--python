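"""Rule cascade for mitotic-phenotype classification and per-well counting.

The cascade mirrors a fixed-cell screen workflow:

1. discard dead cells/debris by nucleus area and tubulin staining;
2. classify mitotic cells by condensed DNA plus a mitotic marker (PHH3 in the
   four-channel "screenB" set) or high spindle tubulin with low centrosome
   staining ("screenA");
3. among mitotic objects, find anaphase/telophase nucleus pairs (small,
   elongated, low integrated DNA), gate them by the distance between the two
   nuclei, and assign the stage from the α-tubulin intensity between the
   nuclei — anaphase has the lower inter-nucleus tubulin, telophase carries a
   bright midbody;
4. score chromosome-segregation errors (chromatin bridges / lagging
   chromatids) as residual DNA signal in the inter-nucleus corridor of
   anaphase pairs;
5. detect bi-/multinucleated cells in two steps: close round nucleus pairs by
   size/aspect/roundness, then nucleus groups sharing a cell body whose
   perinuclear tubulin is low;
6. detect cytokinetic bridges as doublets of elongated bright tubulin objects
   joining two distinct cytoplasm regions, with a γ-tubulin midbody spot;
7. count each pair/group once and report density-normalized per-well ratios.

All "high"/"low" intensity thresholds are configuration fields.  Defaults are
fixed numbers matched to the simulator's documented intensity scale; every
threshold also accepts ``"auto"``, which resolves to Otsu's threshold over the
per-object distribution of the relevant feature in the well.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import regionprops

from .image import MultiChannelImage
from .segmentation import LabelMask, detect_spots

PHENOTYPE_CLASSES = ("interphase", "mitotic", "anaphase", "telophase",
                     "multinucleated", "dead")


@dataclass
class ClassifierConfig:
    # dead-cell filter
    dead_area_um2_range: tuple[float, float] = (14.0, 500.0)
    dead_tubulin_max: float | str = 15.0
    # mitotic gate
    mitotic_marker_min: float | str = 30.0
    mitotic_dna_area_max_um2: float = 70.0
    mitotic_dna_mean_min: float | str = 80.0
    mitotic_tubulin_min: float | str = 60.0          # screenA spindle gate
    mitotic_centrosome_max: float | str = 20.0       # screenA low-CEP215 gate
    # multinucleation
    binucleate_max_centroid_dist_um: float = 12.0
    binucleate_max_aspect: float = 1.6
    binucleate_min_roundness: float = 0.75
    binucleate_area_um2_range: tuple[float, float] = (50.0, 110.0)
    perinuclear_tubulin_low_max: float | str = 24.0
    # anaphase/telophase pairing
    anatelo_dna_intensity_max_quantile: float = 0.95
    anatelo_elongation_min: float = 1.5
    anatelo_area_max_um2: float = 40.0
    pair_dist_max_anaphase_um: float = 0.65
    pair_dist_max_telophase_um: float = 2.6
    pair_gap_measure: str = "boundary"               # or "centroid"
    stage_by: str = "tubulin"                        # "tubulin", "distance", "both"
    anaphase_internuclear_tubulin_max: float | str = 55.0
    anaphase_tubulin_lower: bool = True              # as printed; False inverts
    stage_corridor_width_factor: float = 0.4         # x mean minor axis
    # chromosome segregation errors
    cse_dna_threshold_sd: float = 3.0
    cse_corridor_width_factor: float = 0.5           # x mean minor axis
    cse_mask_dilation_px: int = 1
    # cytokinetic bridges
    bridge_tubulin_min: float | str = 65.0
    bridge_eccentricity_min: float = 0.88
    bridge_length_um_range: tuple[float, float] = (2.0, 6.0)
    bridge_doublet_dist_um_range: tuple[float, float] = (0.5, 5.0)
    require_gamma_tubulin_midbody: bool = True
    gamma_spot_min_peak: float = 25.0

    def __post_init__(self) -> None:
        for name in ("dead_area_um2_range", "binucleate_area_um2_range",
                     "bridge_length_um_range", "bridge_doublet_dist_um_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is not ordered")
        if not 0.0 < self.anatelo_dna_intensity_max_quantile < 1.0:
            raise ValueError("anatelo_dna_intensity_max_quantile must be in (0,1)")
        if self.pair_gap_measure not in ("boundary", "centroid"):
            raise ValueError("pair_gap_measure must be 'boundary' or 'centroid'")
        if self.stage_by not in ("tubulin", "distance", "both"):
            raise ValueError("stage_by must be 'tubulin', 'distance' or 'both'")


@dataclass
class CellRecord:
    cell_id: int
    member_labels: list[int]
    phenotype: str
    pair_id: int | None = None
    cse_positive: bool | None = None
    bridge_id: int | None = None

    def __post_init__(self) -> None:
        if self.phenotype in ("anaphase", "telophase") and len(self.member_labels) != 2:
            raise ValueError("anaphase/telophase records carry exactly 2 labels")
        if self.phenotype == "multinucleated" and len(self.member_labels) < 2:
            raise ValueError("multinucleated records carry >= 2 labels")


@dataclass
class Bridge:
    bridge_id: int
    half_a_px: tuple[float, float]
    half_b_px: tuple[float, float]
    midpoint_px: tuple[float, float]
    cytoplasm_labels: tuple[int, int]
    gap_um: float


@dataclass
class WellPhenotypes:
    n_total_objects: int = 0
    n_dead: int = 0
    n_viable: int = 0
    n_mitotic: int = 0
    n_multinucleated: int = 0
    n_anaphase: int = 0
    n_anaphase_cse: int = 0
    n_bridges: int = 0
    mitotic_index: float = 0.0
    multinucleation_index: float = 0.0
    cse_rate: float = 0.0
    bridge_rate: float = 0.0
    quality_flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["quality_flags"] = ";".join(self.quality_flags)
        return d


def _auto(value: float | str, samples: np.ndarray, fallback: float) -> float:
    """Resolve an "auto" threshold as Otsu over a per-object distribution."""
    if value != "auto":
        return float(value)
    samples = np.asarray(samples, dtype=float)
    samples = samples[np.isfinite(samples)]
    if samples.size < 2 or samples.min() == samples.max():
        return fallback
    return float(threshold_otsu(samples))


# --------------------------------------------------------------------------
# dead-cell filter
# --------------------------------------------------------------------------

def filter_dead(features: pd.DataFrame, cfg: ClassifierConfig | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition objects into (viable, dead).

    Dead cells/debris: nucleus area outside the viable range, or mean tubulin
    (no surrounding cytoskeleton) below ``dead_tubulin_max``.
    """
    cfg = cfg or ClassifierConfig()
    if features.empty:
        return features.copy(), features.copy()
    lo, hi = cfg.dead_area_um2_range
    tub_max = _auto(cfg.dead_tubulin_max, features["mean_tubulin"].to_numpy(), 15.0)
    dead = ((features["area_um2"] < lo) | (features["area_um2"] > hi)
            | (features["mean_tubulin"] < tub_max))
    return features[~dead].copy(), features[dead].copy()


# --------------------------------------------------------------------------
# mitotic gate
# --------------------------------------------------------------------------

def classify_mitotic(viable: pd.DataFrame, cfg: ClassifierConfig | None = None,
                     mode: str = "screenB") -> pd.DataFrame:
    """Select mitotic objects: condensed DNA plus the mode's marker rule."""
    cfg = cfg or ClassifierConfig()
    if mode not in ("screenA", "screenB"):
        raise ValueError(f"unknown mode {mode!r}")
    if viable.empty:
        return viable.copy()
    condensed = ((viable["area_um2"] <= cfg.mitotic_dna_area_max_um2)
                 & (viable["mean_dna"]
                    >= _auto(cfg.mitotic_dna_mean_min, viable["mean_dna"].to_numpy(), 90.0)))
    if mode == "screenB":
        if "mean_phh3" not in viable:
            raise ValueError("screenB classification needs a PHH3 channel")
        marker_min = _auto(cfg.mitotic_marker_min, viable["mean_phh3"].to_numpy(), 30.0)
        sel = condensed & (viable["mean_phh3"] >= marker_min)
    else:
        if "mean_cep215" not in viable:
            raise ValueError("screenA classification needs a CEP215 channel")
        tub_min = _auto(cfg.mitotic_tubulin_min, viable["mean_tubulin"].to_numpy(), 60.0)
        cen_max = _auto(cfg.mitotic_centrosome_max, viable["mean_cep215"].to_numpy(), 20.0)
        sel = condensed & (viable["mean_tubulin"] >= tub_min) \
            & (viable["mean_cep215"] <= cen_max)
    return viable[sel].copy()


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def _label_coords(mask: LabelMask, label: int) -> np.ndarray:
    return np.argwhere(mask.labels == label)


def _boundary_gap_px(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimum boundary separation: closest pixel-centre distance minus 1 px."""
    # subsample very large masks; candidate nuclei are small so this is exact
    from scipy.spatial.distance import cdist
    d = cdist(coords_a, coords_b).min()
    return max(0.0, d - 1.0)


def corridor_mask(shape: tuple[int, int], c1, c2, width_px: float,
                  exclude: np.ndarray | None = None) -> np.ndarray:
    """Rectangle spanned by two points with the given width, minus ``exclude``."""
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    dr, dc = c2[0] - c1[0], c2[1] - c1[1]
    length2 = dr * dr + dc * dc
    if length2 == 0:
        return np.zeros(shape, dtype=bool)
    t = ((rr - c1[0]) * dr + (cc - c1[1]) * dc) / length2
    perp = np.abs((rr - c1[0]) * dc - (cc - c1[1]) * dr) / math.sqrt(length2)
    mask = (t >= 0) & (t <= 1) & (perp <= width_px / 2)
    if exclude is not None:
        mask &= ~exclude
    return mask


def _corridor_stats(image: MultiChannelImage, role: str, nuclei: LabelMask,
                    row_a: pd.Series, row_b: pd.Series, cfg: ClassifierConfig,
                    dilation_px: int, width_factor: float | None = None
                    ) -> tuple[float, int]:
    """Mean intensity in the inter-nucleus corridor; returns (mean, n_pixels).

    The corridor is the rectangle spanned by the two nucleus centroids.  Each
    nucleus is excluded as a disc of radius half its minor axis (the mass
    thickness along the division axis) plus ``dilation_px``; a thin chromatin
    bridge can be segmented as part of the nucleus masks, so the geometric
    exclusion keeps the inter-nucleus space measurable.
    """
    px = image.pixel_size_um
    c1 = (row_a["centroid_row"], row_a["centroid_col"])
    c2 = (row_b["centroid_row"], row_b["centroid_col"])
    if width_factor is None:
        width_factor = cfg.cse_corridor_width_factor
    width_px = (width_factor
                * (row_a["minor_axis_um"] + row_b["minor_axis_um"]) / 2 / px)
    dist = math.hypot(c2[0] - c1[0], c2[1] - c1[1])
    if 2 * dilation_px >= dist:      # exclusion zones swallow the corridor
        return float("nan"), 0
    # cap the exclusion radii so a central strip stays measurable even when a
    # chromatin bridge inflated the fitted minor axes of the nucleus masks
    rad_cap = 0.42 * dist
    rad_a = min(row_a["minor_axis_um"] / 2 / px + dilation_px, rad_cap)
    rad_b = min(row_b["minor_axis_um"] / 2 / px + dilation_px, rad_cap)
    pad = int(math.ceil(width_px + max(rad_a, rad_b) + 4))
    r0 = max(0, int(min(c1[0], c2[0])) - pad)
    r1 = min(image.shape[0], int(max(c1[0], c2[0])) + pad + 1)
    c0 = max(0, int(min(c1[1], c2[1])) - pad)
    c1_ = min(image.shape[1], int(max(c1[1], c2[1])) + pad + 1)
    shape = (r1 - r0, c1_ - c0)
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    exclude = ((rr - (c1[0] - r0)) ** 2 + (cc - (c1[1] - c0)) ** 2 <= rad_a ** 2) \
        | ((rr - (c2[0] - r0)) ** 2 + (cc - (c2[1] - c0)) ** 2 <= rad_b ** 2)
    local = corridor_mask(
        shape, (c1[0] - r0, c1[1] - c0), (c2[0] - r0, c2[1] - c0),
        width_px, exclude=exclude)
    n = int(local.sum())
    if n == 0:
        return float("nan"), 0
    return float(image[role][r0:r1, c0:c1_][local].mean()), n


# --------------------------------------------------------------------------
# anaphase/telophase pairing and CSE scoring
# --------------------------------------------------------------------------

def pair_ana_telo(mitotic: pd.DataFrame, image: MultiChannelImage,
                  nuclei: LabelMask, cfg: ClassifierConfig | None = None
                  ) -> list[tuple[int, int, str]]:
    """Pair anaphase/telophase nuclei among mitotic objects.

    Candidates are small, elongated nuclei with low integrated DNA relative to
    the mitotic population.  Greedy mutual-nearest-neighbour pairing in
    increasing distance order; a pair within the telophase distance limit is
    kept and its stage assigned per ``cfg.stage_by``.  Returns
    ``(label_a, label_b, stage)`` tuples with ``label_a < label_b``.
    """
    cfg = cfg or ClassifierConfig()
    if mitotic.empty:
        return []
    int_cut = mitotic["integrated_dna"].quantile(cfg.anatelo_dna_intensity_max_quantile)
    cand = mitotic[(mitotic["aspect_ratio"] >= cfg.anatelo_elongation_min)
                   & (mitotic["area_um2"] <= cfg.anatelo_area_max_um2)
                   & (mitotic["integrated_dna"] <= int_cut)].sort_values("label")
    if len(cand) < 2:
        return []
    px = image.pixel_size_um
    rows = {int(r["label"]): r for _, r in cand.iterrows()}
    coords = {lab: _label_coords(nuclei, lab) for lab in rows}
    labels = sorted(rows)
    gaps: dict[tuple[int, int], float] = {}
    max_gap_px = cfg.pair_dist_max_telophase_um / px
    for la, lb in combinations(labels, 2):
        ra, rb = rows[la], rows[lb]
        cd = math.hypot(ra["centroid_row"] - rb["centroid_row"],
                        ra["centroid_col"] - rb["centroid_col"])
        if cd > max_gap_px + 30:          # cheap cull before exact gap
            continue
        if cfg.pair_gap_measure == "centroid":
            gap = cd
        else:
            gap = _boundary_gap_px(coords[la], coords[lb])
        if gap <= max_gap_px:
            gaps[(la, lb)] = gap
    paired: set[int] = set()
    pairs: list[tuple[int, int, str]] = []
    for (la, lb), gap in sorted(gaps.items(), key=lambda kv: (kv[1], kv[0])):
        if la in paired or lb in paired:
            continue
        paired.update({la, lb})
        pairs.append((la, lb, _assign_stage(rows[la], rows[lb], gap * px,
                                            image, nuclei, cfg)))
    return pairs


def _assign_stage(row_a, row_b, gap_um: float, image, nuclei,
                  cfg: ClassifierConfig) -> str:
    if cfg.stage_by == "distance":
        return "anaphase" if gap_um <= cfg.pair_dist_max_anaphase_um else "telophase"
    tub_mean, n = _corridor_stats(image, "tubulin", nuclei, row_a, row_b, cfg,
                                  dilation_px=0,
                                  width_factor=cfg.stage_corridor_width_factor)
    thr = _auto(cfg.anaphase_internuclear_tubulin_max, np.array([]), 55.0)
    low = (n > 0) and (tub_mean <= thr)
    is_ana = low if cfg.anaphase_tubulin_lower else not low
    if cfg.stage_by == "both":
        is_ana = is_ana and gap_um <= cfg.pair_dist_max_anaphase_um
    return "anaphase" if is_ana else "telophase"


def background_stats(image: MultiChannelImage, role: str,
                     nuclei: LabelMask) -> tuple[float, float]:
    """Mean and SD of a channel outside (dilated) segmented objects."""
    bg = ndi.binary_dilation(nuclei.labels > 0, iterations=3)
    vals = image[role][~bg]
    if vals.size == 0:
        return 0.0, 0.0
    return float(vals.mean()), float(vals.std())


def score_cse(pair: tuple[int, int], image: MultiChannelImage, nuclei: LabelMask,
              features: pd.DataFrame, cfg: ClassifierConfig | None = None,
              bg: tuple[float, float] | None = None) -> bool:
    """Chromosome-segregation-error call for one anaphase pair.

    True iff the mean DNA intensity in the inter-nucleus corridor (excluding
    the dilated nucleus masks) exceeds background mean plus
    ``cse_dna_threshold_sd`` background SDs.  A degenerate corridor (touching
    nuclei) scores False with a warning.
    """
    cfg = cfg or ClassifierConfig()
    if bg is None:
        bg = background_stats(image, "dna", nuclei)
    idx = features.set_index("label")
    row_a, row_b = idx.loc[pair[0]], idx.loc[pair[1]]
    mean, n = _corridor_stats(image, "dna", nuclei, row_a, row_b, cfg,
                              dilation_px=cfg.cse_mask_dilation_px)
    if n == 0:
        warnings.warn("degenerate inter-nucleus corridor; CSE scored negative",
                      stacklevel=2)
        return False
    return bool(mean > bg[0] + cfg.cse_dna_threshold_sd * bg[1])


# --------------------------------------------------------------------------
# multinucleation
# --------------------------------------------------------------------------

def detect_multinucleated(viable: pd.DataFrame, cytoplasm: LabelMask,
                          cfg: ClassifierConfig | None = None
                          ) -> list[list[int]]:
    """Two-step multinucleate detection; returns groups of nucleus labels.

    Step 1 pairs close round nucleus pairs by size/aspect/roundness.  Step 2
    groups remaining nuclei that share a cell body (a connected region of the
    cytoplasm foreground) and have low perinuclear tubulin.
    """
    cfg = cfg or ClassifierConfig()
    if viable.empty:
        return []
    px_um = float(viable.attrs.get("pixel_size_um", 1.0))
    lo, hi = cfg.binucleate_area_um2_range
    low_max = _auto(cfg.perinuclear_tubulin_low_max,
                    viable["perinuclear_tubulin"].to_numpy(), 24.0)
    # nuclei with low perinuclear tubulin belong to the step-2 population, so
    # step 1 only pairs nuclei with an intact surrounding cytoskeleton
    step1 = viable[(viable["area_um2"].between(lo, hi))
                   & (viable["aspect_ratio"] <= cfg.binucleate_max_aspect)
                   & (viable["roundness"] >= cfg.binucleate_min_roundness)
                   & (viable["perinuclear_tubulin"] >= low_max)]
    groups: list[list[int]] = []
    used: set[int] = set()
    rows = {int(r["label"]): r for _, r in step1.sort_values("label").iterrows()}
    dists: dict[tuple[int, int], float] = {}
    for la, lb in combinations(sorted(rows), 2):
        ra, rb = rows[la], rows[lb]
        d_um = math.hypot(ra["centroid_row"] - rb["centroid_row"],
                          ra["centroid_col"] - rb["centroid_col"]) * px_um
        if d_um <= cfg.binucleate_max_centroid_dist_um:
            dists[(la, lb)] = d_um
    for (la, lb), _d in sorted(dists.items(), key=lambda kv: (kv[1], kv[0])):
        if la in used or lb in used:
            continue
        used.update({la, lb})
        groups.append([la, lb])

    # step 2: low perinuclear tubulin, shared cell body
    remaining = viable[~viable["label"].isin(used)]
    low_max = _auto(cfg.perinuclear_tubulin_low_max,
                    viable["perinuclear_tubulin"].to_numpy(), 24.0)
    lows = remaining[remaining["perinuclear_tubulin"] < low_max]
    if len(lows) >= 2 and cytoplasm.n_objects > 0:
        body, _ = ndi.label(cytoplasm.labels > 0)
        by_body: dict[int, list[int]] = {}
        for _, r in lows.sort_values("label").iterrows():
            b = int(body[int(round(r["centroid_row"])), int(round(r["centroid_col"]))])
            if b > 0:
                by_body.setdefault(b, []).append(int(r["label"]))
        idx = lows.set_index("label")
        for members in by_body.values():
            if len(members) < 2:
                continue
            close = all(
                math.hypot(idx.loc[a, "centroid_row"] - idx.loc[b, "centroid_row"],
                           idx.loc[a, "centroid_col"] - idx.loc[b, "centroid_col"])
                * px_um <= cfg.binucleate_max_centroid_dist_um
                for a, b in combinations(members, 2))
            if close:
                groups.append(sorted(members))
    return groups


# --------------------------------------------------------------------------
# cytokinetic bridges
# --------------------------------------------------------------------------

def detect_bridges(image: MultiChannelImage, cytoplasm: LabelMask,
                   cfg: ClassifierConfig | None = None) -> list[Bridge]:
    """Detect cytokinetic bridges as doublets of elongated bright tubulin
    objects connecting two distinct cytoplasm labels, optionally requiring a
    γ-tubulin spot near the midpoint (the midbody)."""
    cfg = cfg or ClassifierConfig()
    px = image.pixel_size_um
    tub = np.asarray(image["tubulin"], dtype=np.float64)
    thr = _auto(cfg.bridge_tubulin_min, tub[tub > np.percentile(tub, 99)], 55.0)
    bright = tub > thr
    if not bright.any():
        return []
    lab, _ = ndi.label(bright)
    lo_len, hi_len = cfg.bridge_length_um_range
    halves = []
    for rp in regionprops(lab):
        if rp.area < 3:
            continue
        length_um = rp.axis_major_length * px
        if rp.eccentricity >= cfg.bridge_eccentricity_min and lo_len <= length_um <= hi_len:
            halves.append(rp)
    if len(halves) < 2:
        return []
    lo_d, hi_d = cfg.bridge_doublet_dist_um_range
    coords = {rp.label: rp.coords for rp in halves}
    cand_pairs = []
    from scipy.spatial.distance import cdist
    for a, b in combinations(range(len(halves)), 2):
        rp_a, rp_b = halves[a], halves[b]
        gap_px = cdist(coords[rp_a.label], coords[rp_b.label]).min()
        gap_um = max(0.0, gap_px - 1.0) * px
        if lo_d <= gap_um <= hi_d:
            cand_pairs.append((gap_um, a, b))
    used: set[int] = set()
    bridges: list[Bridge] = []
    for gap_um, a, b in sorted(cand_pairs):
        if a in used or b in used:
            continue
        rp_a, rp_b = halves[a], halves[b]
        lab_a = _majority_label(cytoplasm.labels, rp_a.coords)
        lab_b = _majority_label(cytoplasm.labels, rp_b.coords)
        if lab_a == 0 or lab_b == 0 or lab_a == lab_b:
            continue
        mid = ((rp_a.centroid[0] + rp_b.centroid[0]) / 2,
               (rp_a.centroid[1] + rp_b.centroid[1]) / 2)
        if cfg.require_gamma_tubulin_midbody:
            if "gamma_tubulin" not in image or not _gamma_spot_near(
                    image, mid, 2.5 / px, cfg.gamma_spot_min_peak):
                continue
        used.update({a, b})
        bridges.append(Bridge(
            bridge_id=len(bridges) + 1,
            half_a_px=tuple(rp_a.centroid), half_b_px=tuple(rp_b.centroid),
            midpoint_px=mid, cytoplasm_labels=(int(lab_a), int(lab_b)),
            gap_um=gap_um))
    return bridges


def _majority_label(labels: np.ndarray, coords: np.ndarray) -> int:
    vals = labels[coords[:, 0], coords[:, 1]]
    vals = vals[vals > 0]
    if vals.size == 0:
        return 0
    return int(np.bincount(vals).argmax())


def _gamma_spot_near(image, mid, radius_px: float, min_peak: float) -> bool:
    r0 = max(0, int(mid[0] - radius_px - 3))
    r1 = min(image.shape[0], int(mid[0] + radius_px + 4))
    c0 = max(0, int(mid[1] - radius_px - 3))
    c1 = min(image.shape[1], int(mid[1] + radius_px + 4))
    crop = image["gamma_tubulin"][r0:r1, c0:c1]
    spots = detect_spots(crop, scale_px=1.5, min_peak=min_peak)
    for s in spots:
        if math.hypot(s.centroid_px[0] + r0 - mid[0],
                      s.centroid_px[1] + c0 - mid[1]) <= radius_px:
            return True
    return False


# --------------------------------------------------------------------------
# counting
# --------------------------------------------------------------------------

def count_well(records: list[CellRecord], bridges: list[Bridge],
               n_total_objects: int | None = None) -> WellPhenotypes:
    """Aggregate cell records into per-well counts and ratios.

    Anaphase/telophase pairs and multinucleate groups each count as one viable
    cell; dead objects are excluded from the denominator.  Ratios are reported
    as 0 with a quality flag when their denominator is empty.
    """
    seen: set[int] = set()
    for rec in records:
        for lab in rec.member_labels:
            if lab in seen:
                raise ValueError(f"object label {lab} claimed by two records")
            seen.add(lab)
    out = WellPhenotypes()
    out.n_total_objects = n_total_objects if n_total_objects is not None else len(seen)
    out.n_dead = sum(1 for r in records if r.phenotype == "dead")
    viable = [r for r in records if r.phenotype != "dead"]
    out.n_viable = len(viable)
    out.n_mitotic = sum(1 for r in viable
                        if r.phenotype in ("mitotic", "anaphase", "telophase"))
    out.n_multinucleated = sum(1 for r in viable if r.phenotype == "multinucleated")
    out.n_anaphase = sum(1 for r in viable if r.phenotype == "anaphase")
    out.n_anaphase_cse = sum(1 for r in viable
                             if r.phenotype == "anaphase" and r.cse_positive)
    out.n_bridges = len(bridges)
    if out.n_viable > 0:
        out.mitotic_index = out.n_mitotic / out.n_viable
        out.multinucleation_index = out.n_multinucleated / out.n_viable
        out.bridge_rate = out.n_bridges / out.n_viable
    else:
        out.quality_flags.append("no_viable_cells")
    if out.n_anaphase > 0:
        out.cse_rate = out.n_anaphase_cse / out.n_anaphase
    else:
        out.quality_flags.append("no_anaphases")
    return out


# --------------------------------------------------------------------------
# orchestrator
# --------------------------------------------------------------------------

def analyze_well(image: MultiChannelImage,
                 seg_cfg=None, cls_cfg: ClassifierConfig | None = None,
                 mode: str | None = None):
    """Run the full per-well cascade.

    Returns ``(WellPhenotypes, records, bridges, masks, features)`` where
    ``masks`` is ``(nuclei, cytoplasm)``.
    """
    from .segmentation import SegmentationConfig, measure_objects, segment_cytoplasm, segment_nuclei

    seg_cfg = seg_cfg or SegmentationConfig()
    cls_cfg = cls_cfg or ClassifierConfig()
    if mode is None:
        mode = "screenA" if "cep215" in image else "screenB"
    nuclei = segment_nuclei(image, seg_cfg)
    cytoplasm = segment_cytoplasm(image, nuclei, seg_cfg)
    features = measure_objects(nuclei, image, seg_cfg.ring_width_um)
    features.attrs["pixel_size_um"] = image.pixel_size_um
    if features.empty:
        wp = count_well([], [], n_total_objects=0)
        wp.quality_flags.append("empty_field")
        return wp, [], [], (nuclei, cytoplasm), features

    viable, dead = filter_dead(features, cls_cfg)
    viable.attrs["pixel_size_um"] = image.pixel_size_um
    mitotic = classify_mitotic(viable, cls_cfg, mode=mode)
    pairs = pair_ana_telo(mitotic, image, nuclei, cls_cfg)
    paired_labels = {lab for la, lb, _ in pairs for lab in (la, lb)}
    bg = background_stats(image, "dna", nuclei)

    records: list[CellRecord] = []
    next_id = 0
    for _, row in dead.iterrows():
        records.append(CellRecord(next_id, [int(row["label"])], "dead"))
        next_id += 1
    pair_id = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate corridors score negative
        for la, lb, stage in pairs:
            cse = None
            if stage == "anaphase":
                cse = score_cse((la, lb), image, nuclei, features, cls_cfg, bg)
            records.append(CellRecord(next_id, [la, lb], stage,
                                      pair_id=pair_id, cse_positive=cse))
            next_id += 1
            pair_id += 1
    mitotic_single = mitotic[~mitotic["label"].isin(paired_labels)]
    for _, row in mitotic_single.iterrows():
        records.append(CellRecord(next_id, [int(row["label"])], "mitotic"))
        next_id += 1

    taken = {lab for r in records for lab in r.member_labels}
    rest = viable[~viable["label"].isin(taken)]
    rest.attrs["pixel_size_um"] = image.pixel_size_um
    groups = detect_multinucleated(rest, cytoplasm, cls_cfg)
    for g in groups:
        records.append(CellRecord(next_id, list(g), "multinucleated"))
        next_id += 1
    grouped = {lab for g in groups for lab in g}
    for _, row in rest[~rest["label"].isin(grouped)].iterrows():
        records.append(CellRecord(next_id, [int(row["label"])], "interphase"))
        next_id += 1

    bridges = detect_bridges(image, cytoplasm, cls_cfg)
    wp = count_well(records, bridges, n_total_objects=len(features))
    return wp, records, bridges, (nuclei, cytoplasm), features
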