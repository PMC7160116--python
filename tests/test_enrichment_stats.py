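"""Combination statistics against brute-force oracles and worked examples."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoscan.enrichment_stats import (bh_adjust, cluster_windows,
                                       efdr_threshold, empirical_fdr,
                                       filter_windows, iut_combine,
                                       max_p_across_methods, simes_combine)

pvec = st.lists(st.floats(min_value=1e-6, max_value=1.0,
                          allow_nan=False, allow_infinity=False),
                min_size=1, max_size=8)


# ---------------------------------------------------------------- oracles

def simes_bruteforce(p):
    p = sorted(p)
    m = len(p)
    return min(m * p[i] / (i + 1) for i in range(m))


def bh_bruteforce(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def clusters_bruteforce(intervals):
    """Transitive closure of pairwise half-open overlap, per chromosome."""
    spans = []
    for chrom, start, end in intervals:
        merged = None
        for s in spans:
            if s[0] == chrom and start < s[2] and s[1] < end:
                merged = s
                break
        if merged is None:
            spans.append([chrom, start, end])
        else:
            merged[1] = min(merged[1], start)
            merged[2] = max(merged[2], end)
    # merging can cascade; iterate to fixpoint
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(list(spans), 2):
            if a[0] == b[0] and a[1] < b[2] and b[1] < a[2]:
                a[1], a[2] = min(a[1], b[1]), max(a[2], b[2])
                spans.remove(b)
                changed = True
                break
    return sorted((c, s, e) for c, s, e in spans)


# ---------------------------------------------------------------- Simes

def test_simes_worked_examples():
    assert simes_combine([0.2]) == pytest.approx(0.2)
    assert simes_combine([0.01, 0.04, 0.9]) == pytest.approx(0.03)
    assert simes_combine([0.5, 0.5, 0.5]) == pytest.approx(0.5)


def test_simes_matches_bruteforce_on_random_subsets(rng):
    p = rng.uniform(0.001, 1.0, size=8)
    for m in range(1, 9):
        for subset in itertools.combinations(range(8), m):
            vals = p[list(subset)]
            assert simes_combine(vals) == pytest.approx(
                simes_bruteforce(vals.tolist()), abs=1e-12)


@settings(derandomize=True, max_examples=200)
@given(pvec)
def test_simes_bounds_property(p):
    """Simes' p lies in (0, 1], never exceeds m*min(p), and equals the
    brute-force definition."""
    s = simes_combine(p)
    assert 0 < s <= 1
    assert s <= len(p) * min(p) + 1e-12
    assert s == pytest.approx(simes_bruteforce(p), abs=1e-12)


@settings(derandomize=True, max_examples=200)
@given(pvec)
def test_bh_is_monotone_and_bounded(p):
    """BH preserves the order of p-values and never reduces any of them."""
    adj = bh_adjust(p)
    assert np.all(adj >= np.asarray(p) - 1e-12)
    assert np.all(adj <= 1.0)
    order = np.argsort(p, kind="mergesort")
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_simes_rejects_bad_input():
    with pytest.raises(ValueError):
        simes_combine([])
    with pytest.raises(ValueError):
        simes_combine([0.0, 0.5])


# ---------------------------------------------------------------- BH

def test_bh_worked_examples():
    assert bh_adjust([0.5]) == pytest.approx([0.5])
    assert bh_adjust([0.01, 0.02, 0.9]) == pytest.approx([0.03, 0.03, 0.9])
    assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])


def test_bh_matches_bruteforce(rng):
    for _ in range(200):
        m = rng.integers(1, 9)
        p = rng.uniform(0.001, 1.0, size=m)
        assert bh_adjust(p) == pytest.approx(bh_bruteforce(p), abs=1e-12)


# ---------------------------------------------------------------- IUT

def _pv(rows):
    return pd.DataFrame(rows, columns=["gene_id", "method", "p_up", "p_down"])


def test_iut_takes_max_per_direction():
    out = iut_combine(_pv([("g1", "rnai", 0.01, 0.99), ("g1", "lna", 0.2, 0.8)]))
    assert out.loc[0, "p_up_comb"] == pytest.approx(0.2)
    assert out.loc[0, "direction"] == "up"


def test_iut_two_sided_assembly():
    out = iut_combine(_pv([("g1", "rnai", 0.01, 0.99), ("g1", "lna", 0.03, 0.97)]))
    assert out.loc[0, "p_consistent"] == pytest.approx(0.06)
    assert out.loc[0, "direction"] == "up"


def test_iut_disagreement_is_conservative():
    out = iut_combine(_pv([("g1", "rnai", 0.01, 0.99), ("g1", "lna", 0.99, 0.01)]))
    assert out.loc[0, "p_up_comb"] == pytest.approx(0.99)
    assert out.loc[0, "p_down_comb"] == pytest.approx(0.99)
    assert out.loc[0, "p_consistent"] >= 0.99


def test_iut_requires_two_methods():
    with pytest.raises(ValueError):
        iut_combine(_pv([("g1", "rnai", 0.5, 0.5)]))


def test_iut_null_controls_fdp(rng):
    """Uniform one-sided p across 2 independent methods: IUT + BH at 5%
    should yield (essentially) no discoveries."""
    n = 10_000
    rows = []
    for method in ("rnai", "lna"):
        pu = rng.uniform(size=n)
        for i in range(n):
            rows.append((f"g{i}", method, max(pu[i], 1e-12),
                         max(1 - pu[i], 1e-12)))
        # independent draw for second method
    df = _pv(rows)
    out = iut_combine(df)
    adj = bh_adjust(out["p_consistent"])
    fdp = float(np.mean(adj <= 0.05))
    assert fdp <= 0.05


def test_max_p_across_methods():
    assert max_p_across_methods(0.01, 0.2) == 0.2
    assert max_p_across_methods(0.3, 0.3) == 0.3
    with pytest.raises(ValueError):
        max_p_across_methods(0.0, 0.5)


# ---------------------------------------------------------------- windows

def _wins(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "p",
                                       "direction", "abundance"])


def test_filter_windows_fivefold_boundary():
    w = _wins([("chr1", 0, 150, 0.1, "up", 4.9),
               ("chr1", 150, 300, 0.1, "up", 5.0),
               ("chr1", 300, 450, 0.1, "up", 7.0)])
    kept = filter_windows(w, background_abundance=1.0, fold=5)
    assert kept["abundance"].tolist() == [5.0, 7.0]
    assert filter_windows(w.iloc[:0], 1.0).empty
    assert len(filter_windows(w, 1.0, fold=0)) == 3


def test_cluster_windows_overlap_chain():
    w = _wins([("chr1", 100, 250, 0.01, "up", 10),
               ("chr1", 200, 350, 0.04, "up", 10),
               ("chr1", 1000, 1150, 0.9, "down", 10)])
    _, clusters = cluster_windows(w)
    spans = sorted(zip(clusters["start"], clusters["end"]))
    assert spans == [(100, 350), (1000, 1150)]
    first = clusters.sort_values("start").iloc[0]
    assert first["combined_p"] == pytest.approx(simes_bruteforce([0.01, 0.04]))


def test_cluster_windows_transitivity():
    # A overlaps B, B overlaps C, A does not overlap C -> one cluster
    w = _wins([("chr2", 0, 100, 0.5, "up", 1),
               ("chr2", 90, 200, 0.5, "up", 1),
               ("chr2", 190, 300, 0.5, "up", 1)])
    _, clusters = cluster_windows(w)
    assert len(clusters) == 1
    assert clusters.iloc[0]["n_members"] == 3


def test_cluster_windows_touching_intervals_do_not_merge():
    # half-open: [0,100) and [100,200) share no base
    w = _wins([("chr1", 0, 100, 0.5, "up", 1),
               ("chr1", 100, 200, 0.5, "up", 1)])
    _, clusters = cluster_windows(w)
    assert len(clusters) == 2


def test_cluster_windows_permutation_invariant(rng):
    rows = []
    for _ in range(40):
        start = int(rng.integers(0, 2000))
        width = int(rng.choice([150, 300, 600, 1000]))
        rows.append((f"chr{rng.integers(1, 3)}", start, start + width,
                     float(rng.uniform(1e-4, 1)), "up", 1.0))
    w = _wins(rows)
    _, ref = cluster_windows(w)
    ref_spans = sorted(zip(ref["chrom"], ref["start"], ref["end"]))
    assert ref_spans == clusters_bruteforce(
        [(r[0], r[1], r[2]) for r in rows])
    for _ in range(5):
        perm = w.sample(frac=1.0, random_state=int(rng.integers(1 << 30)))
        _, got = cluster_windows(perm)
        assert sorted(zip(got["chrom"], got["start"], got["end"])) == ref_spans


def test_cluster_windows_rejects_malformed():
    with pytest.raises(ValueError):
        cluster_windows(_wins([("chr1", 100, 100, 0.5, "up", 1)]))


# ---------------------------------------------------------------- eFDR

def _clusters(n_up, n_down, p=0.01):
    rows = [{"combined_p": p, "direction": "up"}] * n_up \
        + [{"combined_p": p, "direction": "down"}] * n_down
    return pd.DataFrame(rows)


def test_empirical_fdr_ratio():
    res = empirical_fdr(_clusters(10, 3), p_cut=0.05)
    assert res["efdr"] == pytest.approx(0.3)
    assert res["n_discovery"] == 10
    assert res["n_false_direction"] == 3


def test_empirical_fdr_zero_and_undefined():
    assert empirical_fdr(_clusters(5, 0), 0.05)["efdr"] == 0.0
    res = empirical_fdr(_clusters(0, 2), 0.05)
    assert res["undefined"] and res["efdr"] == 1.0


def test_empirical_fdr_monotone_in_cutoff(rng):
    rows = [{"combined_p": float(rng.uniform(0, 1)),
             "direction": rng.choice(["up", "down"], p=[0.8, 0.2])}
            for _ in range(200)]
    clusters = pd.DataFrame(rows)
    cuts = np.sort(clusters["combined_p"].unique())
    counts = [(empirical_fdr(clusters, c)["n_discovery"],
               empirical_fdr(clusters, c)["n_false_direction"]) for c in cuts]
    assert all(a2 >= a1 and b2 >= b1
               for (a1, b1), (a2, b2) in zip(counts, counts[1:]))


def test_efdr_threshold_sweep():
    rows = ([{"combined_p": 0.01 * i, "direction": "up"} for i in range(1, 11)]
            + [{"combined_p": 0.05, "direction": "down"},
               {"combined_p": 0.09, "direction": "down"},
               {"combined_p": 0.30, "direction": "down"}])
    clusters = pd.DataFrame(rows)
    res = efdr_threshold(clusters, target_efdr=0.30)
    assert res["efdr"] <= 0.30
    # at the selected cutoff the whole up-set is retained
    assert res["n_discovery"] == 10
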