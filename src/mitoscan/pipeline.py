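"""End-to-end screen simulation and measurement drivers.

Couples the synthetic generator to the image-analysis cascade and the screen
statistics: build a multi-plate siRNA-screen layout, render every well, run
segmentation + phenotype counting, assemble the measured ratio table (with
each plate's multiplicative batch factor applied to its measured ratios, the
simulator's model of a plate-level staining/detection batch effect), and
normalize/Z-score/call hits.

The default mini-screen mirrors a validation-type screen: each library target
occupies two wells per plate on four plates per replicate (eight technical
wells per target and replicate), two replicates, with per-plate batch factors
{0.7, 1, 1.3, 2}.  Per-target baseline mitotic fractions are drawn once from
a log-normal distribution (median 0.045, log-SD 0.45, clipped to
[0.012, 0.25]), modelling the spread of phenotype strengths across an siRNA
library; designated hit targets override the mitotic fraction to 0.15
(three times the 0.05 baseline class fraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .phenotyping import ClassifierConfig, analyze_well
from .segmentation import SegmentationConfig
from .simulate import (PlateSimConfig, WellSimConfig, iter_plate_wells,
                       render_well, true_ratios, well_name)

FEATURES = ("mitotic_index", "multinucleation_index", "cse_rate",
            "bridge_rate", "viability")

SCREEN_DEFAULTS = {
    "n_targets": 46,
    "wells_per_target": 2,
    "n_control_wells": 4,
    "n_rows": 8,
    "n_cols": 12,
    "plate_factors": (0.7, 1.0, 1.3, 2.0),
    "n_replicates": 2,
    "base_median": 0.045,
    "base_log_sd": 0.45,
    "base_clip": (0.012, 0.25),
    "n_hits": 2,
    "hit_mitotic_fraction": 0.15,
}


@dataclass
class MiniScreenDesign:
    plates: list[PlateSimConfig]
    target_rates: dict[str, float]
    hit_targets: list[str]
    replicate_of_plate: dict[str, int]


def design_mini_screen(seed: int, base_well: WellSimConfig | None = None,
                       **overrides) -> MiniScreenDesign:
    """Draw target effects and lay out the replicate plates of a mini-screen."""
    p = dict(SCREEN_DEFAULTS)
    p.update(overrides)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(901,)))
    base_well = base_well or WellSimConfig()
    n_targets = p["n_targets"]
    targets = [f"T{i + 1:03d}" for i in range(n_targets)]
    lo, hi = p["base_clip"]
    rates = np.clip(np.exp(rng.normal(np.log(p["base_median"]),
                                      p["base_log_sd"], n_targets)), lo, hi)
    hit_idx = rng.choice(n_targets, p["n_hits"], replace=False)
    target_rates = dict(zip(targets, rates.tolist()))
    hit_targets = [targets[i] for i in sorted(hit_idx)]
    for t in hit_targets:
        target_rates[t] = p["hit_mitotic_fraction"]

    # layout: n_targets * wells_per_target library wells + controls
    n_rows, n_cols = p["n_rows"], p["n_cols"]
    well_ids = [well_name(r, c) for r in range(n_rows) for c in range(n_cols)]
    library_wells = well_ids[: n_targets * p["wells_per_target"]]
    control_ids = well_ids[n_targets * p["wells_per_target"]:
                           n_targets * p["wells_per_target"] + p["n_control_wells"]]
    layout = {w: targets[i % n_targets] for i, w in enumerate(library_wells)}
    layout.update({w: "neg_ctl" for w in control_ids})
    overrides_map = {w: {"mitotic": target_rates[t]}
                     for w, t in layout.items() if t != "neg_ctl"}
    control_map = {w: "negative" for w in control_ids}

    plates: list[PlateSimConfig] = []
    replicate_of_plate: dict[str, int] = {}
    plate_seeds = np.random.SeedSequence(entropy=seed, spawn_key=(902,))
    seeds = plate_seeds.generate_state(p["n_replicates"] * len(p["plate_factors"]))
    k = 0
    for rep in range(1, p["n_replicates"] + 1):
        for factor in p["plate_factors"]:
            pid = f"R{rep}P{k % len(p['plate_factors']) + 1}"
            plates.append(PlateSimConfig(
                base_well=base_well, n_rows=n_rows, n_cols=n_cols,
                plate_id=pid, layout=dict(layout),
                well_overrides={w: dict(o) for w, o in overrides_map.items()},
                control_wells=dict(control_map),
                plate_factor=float(factor),
                seed=int(seeds[k] % (2 ** 31))))
            replicate_of_plate[pid] = rep
            k += 1
    return MiniScreenDesign(plates=plates, target_rates=target_rates,
                            hit_targets=hit_targets,
                            replicate_of_plate=replicate_of_plate)


def measure_plate(config: PlateSimConfig,
                  seg_cfg: SegmentationConfig | None = None,
                  cls_cfg: ClassifierConfig | None = None,
                  keep_truth: bool = True) -> pd.DataFrame:
    """Render and analyze every well of a plate; one row per (well, feature).

    The measured per-well ratios are multiplied by the plate's batch factor,
    mirroring a plate-wide multiplicative staining/detection effect; the true
    ratio columns carry the same factor for comparability.
    """
    seg_cfg = seg_cfg or SegmentationConfig()
    cls_cfg = cls_cfg or ClassifierConfig()
    rows = []
    for wid, wcfg in iter_plate_wells(config):
        image, gt = render_well(wcfg)
        wp, *_ = analyze_well(image, seg_cfg, cls_cfg)
        measured = {
            "mitotic_index": wp.mitotic_index,
            "multinucleation_index": wp.multinucleation_index,
            "cse_rate": wp.cse_rate,
            "bridge_rate": wp.bridge_rate,
            "viability": float(wp.n_viable),
        }
        truth = true_ratios(gt.true_counts) if keep_truth else {}
        for feat in FEATURES:
            row = {
                "plate_id": config.plate_id, "well_id": wid,
                "target_id": config.layout.get(wid, wid), "feature": feat,
                "ratio": measured[feat] * config.plate_factor,
                "is_control": wid in config.control_wells,
                "control_role": config.control_wells.get(wid, ""),
            }
            if keep_truth:
                row["true_ratio"] = truth[feat] * config.plate_factor
            rows.append(row)
    return pd.DataFrame(rows)


def run_mini_screen(seed: int, base_well: WellSimConfig | None = None,
                    seg_cfg: SegmentationConfig | None = None,
                    cls_cfg: ClassifierConfig | None = None,
                    **overrides) -> dict:
    """Simulate, measure and score a full mini-screen.

    Returns a dict with the measured table, the normalized/Z-scored table,
    per-target calls, the design, and summary metrics (hit recall, false
    positive rate among library targets, inter-replicate Spearman of the
    mitotic index).
    """
    from . import screen_stats

    design = design_mini_screen(seed, base_well=base_well, **overrides)
    tables = [measure_plate(p, seg_cfg, cls_cfg) for p in design.plates]
    table = pd.concat(tables, ignore_index=True)

    normed, summary = screen_stats.normalize_plates(table, "mitotic_index")
    normed = screen_stats.zscore(normed, summary)
    # a target's score is the z of its MEAN normalized ratio against the
    # library's distribution of per-target means (each point of a screen
    # scatter is one target's mean ratio)
    per_target = normed[~normed["is_control"]].groupby("target_id").agg(
        mean_ratio=("normalized_ratio", "mean"), n_wells=("z", "size")).reset_index()
    mu_t = per_target["mean_ratio"].mean()
    sd_t = per_target["mean_ratio"].std(ddof=1)
    per_target["z"] = (per_target["mean_ratio"] - mu_t) / sd_t
    called = set(per_target[per_target["z"] >= 2.0]["target_id"])
    hits = set(design.hit_targets)
    library = set(design.target_rates) - hits
    recall = len(called & hits) / len(hits)
    fpr = len(called & library) / len(library)

    # replicate concordance: per-target means of normalized mitotic index
    normed["replicate"] = normed["plate_id"].map(design.replicate_of_plate)
    lib_rows = normed[~normed["is_control"]]
    rep_means = lib_rows.pivot_table(index="target_id", columns="replicate",
                                     values="normalized_ratio", aggfunc="mean")
    rep_tables = []
    for rep in sorted(set(design.replicate_of_plate.values())):
        sub = rep_means[rep].reset_index()
        sub.columns = ["target_id", "ratio"]
        sub["feature"] = "mitotic_index"
        rep_tables.append(sub)
    rho = screen_stats.replicate_correlation(
        rep_tables[0], rep_tables[1], "mitotic_index", on="target_id")

    return {"table": table, "normalized": normed, "summary": summary,
            "per_target": per_target, "design": design,
            "hit_recall": recall, "false_positive_rate": fpr,
            "replicate_spearman_mitotic_index": rho}


def cse_benchmark(seed: int, n_wells: int = 16, n_cells: int = 60,
                  cse_rate: float = 0.5,
                  base_well: WellSimConfig | None = None,
                  seg_cfg: SegmentationConfig | None = None,
                  cls_cfg: ClassifierConfig | None = None) -> dict:
    """Chromosome-segregation-error calls scored against ground truth.

    Simulates anaphase-rich wells, matches detected anaphase pairs to true
    anaphase cells by midpoint distance, and reports the sensitivity and
    specificity of the CSE call over the matched events, plus the pairing
    recall.
    """
    import math

    base = base_well or WellSimConfig()
    fracs = {"interphase": 0.55, "mitotic": 0.05, "anaphase": 0.30,
             "telophase": 0.05, "multinucleated": 0.0, "dead": 0.05}
    seeds = np.random.SeedSequence(entropy=seed, spawn_key=(905,)).generate_state(n_wells)
    tp = fp = tn = fn = missed = 0
    for i in range(n_wells):
        cfg = replace(base, n_cells=n_cells, class_fractions=fracs,
                      cse_rate=cse_rate, seed=int(seeds[i] % (2 ** 31)))
        image, gt = render_well(cfg)
        _, records, _, _, feats = analyze_well(image, seg_cfg, cls_cfg)
        det = []
        for rec in records:
            if rec.phenotype != "anaphase":
                continue
            sub = feats[feats["label"].isin(rec.member_labels)]
            det.append((sub["centroid_row"].mean(), sub["centroid_col"].mean(),
                        rec.cse_positive))
        for cell in gt.cells:
            if cell.phenotype != "anaphase":
                continue
            match = None
            for (r, c, cse) in det:
                if math.hypot(r - cell.centroid_px[0],
                              c - cell.centroid_px[1]) < 6:
                    match = cse
                    break
            if match is None:
                missed += 1
            elif cell.has_cse and match:
                tp += 1
            elif cell.has_cse:
                fn += 1
            elif match:
                fp += 1
            else:
                tn += 1
    n_events = tp + fn + fp + tn
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "n_matched_anaphases": n_events,
        "pairing_recall": n_events / (n_events + missed) if n_events + missed else 0.0,
    }


# --------------------------------------------------------------------------
# parameter-recovery sweeps
# --------------------------------------------------------------------------

def recovery_sweep(seed: int, n_wells: int = 96,
                   mitotic_range: tuple[float, float] = (0.02, 0.30),
                   cse_range: tuple[float, float] = (0.0, 0.5),
                   bridge_range: tuple[float, float] = (0.0, 0.08),
                   base_well: WellSimConfig | None = None,
                   seg_cfg: SegmentationConfig | None = None,
                   cls_cfg: ClassifierConfig | None = None) -> pd.DataFrame:
    """Wells spanning known mitotic/CSE/bridge rates, measured vs truth.

    Each well draws its own true mitotic fraction (uniform over
    ``mitotic_range``), CSE rate and bridge rate; anaphase/telophase fractions
    are raised so CSE rates are estimable.  Returns one row per well with true
    and estimated ratios.
    """
    base = base_well or WellSimConfig()
    sub_seeds = np.random.SeedSequence(entropy=seed, spawn_key=(903,))
    seeds = sub_seeds.generate_state(n_wells)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(904,)))
    rows = []
    for i in range(n_wells):
        f_mit = rng.uniform(*mitotic_range)
        f_cse = rng.uniform(*cse_range)
        f_bridge = rng.uniform(*bridge_range)
        fracs = dict(base.class_fractions)
        fracs["mitotic"] = f_mit
        fracs["anaphase"] = 0.05
        fracs["telophase"] = 0.02
        other = sum(v for k, v in fracs.items() if k != "interphase")
        fracs["interphase"] = max(0.0, 1.0 - other)
        cfg = replace(base, class_fractions=fracs, cse_rate=f_cse,
                      bridge_rate=f_bridge, seed=int(seeds[i] % (2 ** 31)))
        image, gt = render_well(cfg)
        wp, *_ = analyze_well(image, seg_cfg, cls_cfg)
        truth = true_ratios(gt.true_counts)
        rows.append({
            "well": i, "true_mitotic_fraction": f_mit, "true_cse_rate": f_cse,
            "true_bridge_cfg_rate": f_bridge,
            "true_mitotic_index": truth["mitotic_index"],
            "true_cse_index": truth["cse_rate"],
            "true_bridge_rate": truth["bridge_rate"],
            "est_mitotic_index": wp.mitotic_index,
            "est_cse_rate": wp.cse_rate,
            "est_bridge_rate": wp.bridge_rate,
            "n_anaphase_true": gt.true_counts["anaphase"],
            "n_anaphase_est": wp.n_anaphase,
        })
    return pd.DataFrame(rows)
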