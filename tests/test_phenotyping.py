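"""Rule cascade: dead filter, mitotic gate, pairing, CSE, bridges, counting."""

import math

import numpy as np
import pandas as pd
import pytest

from mitoscan.phenotyping import (Bridge, CellRecord, ClassifierConfig,
                                  analyze_well, classify_mitotic, count_well,
                                  detect_bridges, detect_multinucleated,
                                  filter_dead, pair_ana_telo, score_cse)
from mitoscan.segmentation import measure_objects, segment_cytoplasm, segment_nuclei
from mitoscan.simulate import WellSimConfig, render_well


def well(seed=0, n_cells=30, shape=(420, 420), **kw):
    fracs = {"interphase": 1.0, "mitotic": 0.0, "anaphase": 0.0,
             "telophase": 0.0, "multinucleated": 0.0, "dead": 0.0}
    fracs.update(kw.pop("fractions", {}))
    cfg = WellSimConfig(image_shape_px=shape, n_cells=n_cells, seed=seed,
                        class_fractions=fracs, **kw)
    return render_well(cfg)


def features_of(image):
    nuclei = segment_nuclei(image)
    feats = measure_objects(nuclei, image)
    feats.attrs["pixel_size_um"] = image.pixel_size_um
    return nuclei, feats


# ------------------------------------------------------------- dead filter

def test_filter_dead_empty_input():
    empty = pd.DataFrame(columns=["area_um2", "mean_tubulin"])
    viable, dead = filter_dead(empty)
    assert viable.empty and dead.empty


def test_filter_dead_recovers_debris():
    image, gt = well(seed=2, n_cells=20, bridge_rate=0.0,
                     fractions={"interphase": 0.85, "dead": 0.15})
    n_dead_true = gt.true_counts["dead"]
    _, feats = features_of(image)
    viable, dead = filter_dead(feats)
    assert len(dead) == n_dead_true
    assert len(viable) + len(dead) == len(feats)


def test_filter_dead_all_viable():
    image, _ = well(seed=3, n_cells=15, bridge_rate=0.0)
    _, feats = features_of(image)
    viable, dead = filter_dead(feats)
    assert dead.empty


# ------------------------------------------------------------- mitotic gate

def test_no_marker_no_mitotic():
    image, _ = well(seed=4, n_cells=15, bridge_rate=0.0)
    _, feats = features_of(image)
    viable, _ = filter_dead(feats)
    assert classify_mitotic(viable, mode="screenB").empty


def test_mitotic_sensitivity_specificity():
    image, gt = well(seed=3, n_cells=100, shape=(640, 640),
                     fractions={"interphase": 0.9, "mitotic": 0.1})
    nuclei, feats = features_of(image)
    viable, _ = filter_dead(feats)
    mitotic = classify_mitotic(viable, mode="screenB")
    true_pts = [c.centroid_px for c in gt.cells if c.phenotype == "mitotic"]
    called = mitotic[["centroid_row", "centroid_col"]].to_numpy()
    tp = sum(1 for t in true_pts
             if len(called) and np.hypot(called[:, 0] - t[0],
                                         called[:, 1] - t[1]).min() < 4)
    sens = tp / len(true_pts)
    spec_fp = len(called) - tp
    n_neg = len(viable) - len(true_pts)
    assert sens >= 0.9
    assert 1 - spec_fp / n_neg >= 0.9


def test_marker_threshold_monotonicity():
    image, _ = well(seed=3, n_cells=60, shape=(640, 640),
                    fractions={"interphase": 0.85, "mitotic": 0.15})
    _, feats = features_of(image)
    viable, _ = filter_dead(feats)
    counts = [len(classify_mitotic(viable, ClassifierConfig(mitotic_marker_min=m)))
              for m in (10.0, 30.0, 60.0, 1e9)]
    assert counts == sorted(counts, reverse=True)
    assert counts[-1] == 0


def test_screen_mode_channel_requirements():
    image, _ = well(seed=5, n_cells=10)
    _, feats = features_of(image)
    viable, _ = filter_dead(feats)
    with pytest.raises(ValueError):
        classify_mitotic(viable, mode="screenA")  # no CEP215 columns
    with pytest.raises(ValueError):
        classify_mitotic(viable, mode="nope")


# ------------------------------------------------------------- pairing

def ana_well(seed, ana=0.25, telo=0.0, cse=0.0, n_cells=40):
    return well(seed=seed, n_cells=n_cells, shape=(512, 512), cse_rate=cse,
                fractions={"interphase": 1.0 - ana - telo, "mitotic": 0.0,
                           "anaphase": ana, "telophase": telo})


def _pairs(image):
    nuclei, feats = features_of(image)
    viable, _ = filter_dead(feats)
    mitotic = classify_mitotic(viable)
    return nuclei, feats, pair_ana_telo(mitotic, image, nuclei)


def test_no_candidates_no_pairs():
    image, _ = well(seed=6, n_cells=15)
    nuclei, feats = features_of(image)
    viable, _ = filter_dead(feats)
    assert pair_ana_telo(classify_mitotic(viable), image, nuclei) == []


def test_anaphase_pairs_recovered_with_stage():
    image, gt = ana_well(seed=8)
    _, feats, pairs = _pairs(image)
    n_true = gt.true_counts["anaphase"]
    assert len(pairs) >= 0.8 * n_true
    assert all(stage == "anaphase" for _, _, stage in pairs)


def test_telophase_distinguished_by_midbody_tubulin():
    image, gt = ana_well(seed=9, ana=0.0, telo=0.25)
    _, feats, pairs = _pairs(image)
    n_true = sum(1 for c in gt.cells if c.phenotype == "telophase")
    stages = [s for _, _, s in pairs]
    assert stages.count("telophase") >= 0.8 * n_true
    # direction switch flips the call
    image2, _ = ana_well(seed=9, ana=0.0, telo=0.25)
    nuclei, feats2 = features_of(image2)
    viable, _ = filter_dead(feats2)
    flipped = pair_ana_telo(classify_mitotic(viable), image2, nuclei,
                            ClassifierConfig(anaphase_tubulin_lower=False))
    assert [s for _, _, s in flipped].count("anaphase") >= 0.8 * n_true


def test_distant_nuclei_not_paired():
    cfg = ClassifierConfig(pair_dist_max_telophase_um=0.1)
    image, _ = ana_well(seed=8)
    nuclei, feats = features_of(image)
    viable, _ = filter_dead(feats)
    assert pair_ana_telo(classify_mitotic(viable), image, nuclei, cfg) == []


# ------------------------------------------------------------- CSE

def test_cse_calls_on_clean_and_bridged_anaphases():
    clean_img, _ = ana_well(seed=10, cse=0.0)
    nuclei, feats, pairs = _pairs(clean_img)
    assert pairs
    for pair in pairs:
        assert score_cse((pair[0], pair[1]), clean_img, nuclei, feats) is False
    cse_img, gt = ana_well(seed=10, cse=1.0)
    nuclei, feats, pairs = _pairs(cse_img)
    assert pairs
    calls = [score_cse((a, b), cse_img, nuclei, feats) for a, b, _ in pairs]
    assert np.mean(calls) >= 0.9


def test_cse_degenerate_corridor_scores_negative():
    image, _ = ana_well(seed=11)
    nuclei, feats, pairs = _pairs(image)
    a, b, _ = pairs[0]
    cfg = ClassifierConfig(cse_mask_dilation_px=50)   # exclusion swallows corridor
    with pytest.warns(UserWarning):
        assert score_cse((a, b), image, nuclei, feats, cfg) is False


# ------------------------------------------------------------- multinucleation

def multi_well(seed, frac=0.3, n_cells=20):
    return well(seed=seed, n_cells=n_cells, shape=(512, 512),
                fractions={"interphase": 1 - frac, "multinucleated": frac})


def test_no_groups_in_plain_interphase_well():
    image, _ = well(seed=12, n_cells=15)
    nuclei, feats = features_of(image)
    cyto = segment_cytoplasm(image, nuclei)
    viable, _ = filter_dead(feats)
    assert detect_multinucleated(viable, cyto) == []


def test_bi_and_trinucleate_group_sizes():
    hits = {2: 0, 3: 0}
    total = {2: 0, 3: 0}
    for seed in range(6):
        image, gt = multi_well(seed=40 + seed)
        nuclei, feats = features_of(image)
        cyto = segment_cytoplasm(image, nuclei)
        viable, _ = filter_dead(feats)
        mitotic_labels = classify_mitotic(viable)["label"]
        rest = viable[~viable["label"].isin(mitotic_labels)]
        rest.attrs["pixel_size_um"] = image.pixel_size_um
        groups = detect_multinucleated(rest, cyto)
        centers = [(feats[feats.label.isin(g)]["centroid_row"].mean(),
                    feats[feats.label.isin(g)]["centroid_col"].mean(), len(g))
                   for g in groups]
        for cell in gt.cells:
            if cell.phenotype != "multinucleated":
                continue
            total[cell.n_nuclei] += 1
            for r, c, k in centers:
                if math.hypot(r - cell.centroid_px[0],
                              c - cell.centroid_px[1]) < 10 and k == cell.n_nuclei:
                    hits[cell.n_nuclei] += 1
                    break
    assert total[2] and total[3]
    assert hits[2] / total[2] >= 0.8
    assert hits[3] / total[3] >= 0.7


# ------------------------------------------------------------- bridges

def test_no_bright_tubulin_no_bridges():
    image, _ = well(seed=13, n_cells=10, bridge_rate=0.0)
    nuclei, _ = features_of(image)
    cyto = segment_cytoplasm(image, nuclei)
    assert detect_bridges(image, cyto) == []


def test_bridges_with_midbody_detected():
    found = 0
    total = 0
    for seed in range(5):
        image, gt = well(seed=20 + seed, n_cells=30, shape=(512, 512),
                         bridge_rate=0.08)
        nuclei, _ = features_of(image)
        cyto = segment_cytoplasm(image, nuclei)
        bridges = detect_bridges(image, cyto)
        mids = []
        done = set()
        for c in gt.cells:
            if c.has_bridge and c.cell_id not in done and c.bridge_partner is not None:
                p = next(x for x in gt.cells if x.cell_id == c.bridge_partner)
                done.update({c.cell_id, p.cell_id})
                mids.append(((c.centroid_px[0] + p.centroid_px[0]) / 2,
                             (c.centroid_px[1] + p.centroid_px[1]) / 2))
        total += len(mids)
        for m in mids:
            if any(math.hypot(b.midpoint_px[0] - m[0],
                              b.midpoint_px[1] - m[1]) < 8 for b in bridges):
                found += 1
    assert total >= 5
    assert found / total >= 0.7


def test_stress_fiber_in_single_cell_rejected():
    """An elongated bright tubulin doublet inside one cytoplasm is no bridge."""
    image, _ = well(seed=25, n_cells=6, shape=(420, 420), bridge_rate=0.0)
    tub = image["tubulin"]
    nuclei, feats = features_of(image)
    cyto = segment_cytoplasm(image, nuclei)
    row = feats.iloc[0]
    r0, c0 = int(row["centroid_row"]), int(row["centroid_col"])
    # two collinear bright 3-um segments with a gap, inside one cell
    for off in (-5, 2):
        tub[r0 + 10, c0 + off: c0 + off + 4] += 120.0
    bridges = detect_bridges(image, cyto, ClassifierConfig(
        require_gamma_tubulin_midbody=False))
    for b in bridges:
        assert b.cytoplasm_labels[0] != b.cytoplasm_labels[1]


# ------------------------------------------------------------- counting

def test_count_well_hand_enumeration():
    records = (
        [CellRecord(0, [1], "dead"), CellRecord(1, [2], "dead")]
        + [CellRecord(2, [3, 4], "anaphase", pair_id=0, cse_positive=True)]
        + [CellRecord(3, [5, 6], "multinucleated")]
        + [CellRecord(4 + i, [7 + i], "interphase") for i in range(4)])
    wp = count_well(records, bridges=[])
    assert wp.n_total_objects == 10
    assert wp.n_viable == 6
    assert wp.n_mitotic == 1
    assert wp.mitotic_index == pytest.approx(1 / 6)
    assert wp.n_anaphase_cse == 1
    assert wp.cse_rate == 1.0


def test_count_well_bridge_rate():
    records = [CellRecord(i, [i + 1], "interphase") for i in range(6)]
    bridge = Bridge(1, (0, 0), (0, 5), (0, 2.5), (1, 2), 1.5)
    wp = count_well(records, [bridge])
    assert wp.bridge_rate == pytest.approx(1 / 6)


def test_count_well_empty_flags():
    wp = count_well([], [])
    assert wp.n_total_objects == 0
    assert wp.mitotic_index == 0.0
    assert "no_viable_cells" in wp.quality_flags


def test_count_well_rejects_double_claimed_object():
    records = [CellRecord(0, [1], "interphase"), CellRecord(1, [1], "dead")]
    with pytest.raises(ValueError):
        count_well(records, [])


def test_conservation_over_simulated_wells():
    """dead + sum of viable member labels = total segmented objects."""
    for seed in (31, 32, 33):
        image, _ = well(seed=seed, n_cells=40, shape=(512, 512),
                        fractions={"interphase": 0.62, "mitotic": 0.1,
                                   "anaphase": 0.08, "telophase": 0.02,
                                   "multinucleated": 0.08, "dead": 0.1},
                        cse_rate=0.3, bridge_rate=0.04)
        wp, records, bridges, (nuclei, _), feats = analyze_well(image)
        member_total = sum(len(r.member_labels) for r in records)
        assert member_total == wp.n_total_objects == nuclei.n_objects
        labels = [lab for r in records for lab in r.member_labels]
        assert len(labels) == len(set(labels))
        assert wp.n_viable == len(records) - wp.n_dead
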