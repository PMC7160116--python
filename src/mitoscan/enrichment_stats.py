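"""Combination statistics for differential expression and binding analyses.

Operates on supplied per-gene one-sided p-values and genomic-window tables
(the upstream count models are out of scope):

- intersection-union test (IUT) across loss-of-function methods: a gene is
  consistently changed only if every method supports the same direction, so
  the combined one-sided p per direction is the maximum across methods;
- per-window max-p combination across two methods;
- abundance filtering of windows against expected background coverage;
- single-linkage clustering of overlapping windows from a multi-resolution
  window sweep (BED-style 0-based half-open intervals);
- Simes' combined p-value per window cluster;
- Benjamini-Hochberg adjustment;
- empirical FDR for an antisense-pulldown versus sense-control comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

WINDOW_COLUMNS = ["chrom", "start", "end", "p", "direction", "abundance"]


# --------------------------------------------------------------------------
# intersection-union test
# --------------------------------------------------------------------------

def iut_combine(pvals: pd.DataFrame, assembly: str = "two-sided") -> pd.DataFrame:
    """Combine per-method one-sided p-values into per-gene consistency calls.

    ``pvals`` has columns ``gene_id, method, p_up, p_down``; every gene needs
    at least two methods.  Per direction the combined p is the max across
    methods (a gene is consistent only if all methods agree).  ``direction``
    is the smaller combined direction.  With ``assembly="two-sided"``,
    ``p_consistent = min(1, 2 * min(p_up_comb, p_down_comb))``; with
    ``assembly="per-direction"``, ``p_consistent`` is the winning direction's
    combined p (to be FDR-corrected per direction by the caller).
    """
    if assembly not in ("two-sided", "per-direction"):
        raise ValueError(f"unknown assembly {assembly!r}")
    required = {"gene_id", "method", "p_up", "p_down"}
    if not required.issubset(pvals.columns):
        raise ValueError(f"missing columns {sorted(required - set(pvals.columns))}")
    for col in ("p_up", "p_down"):
        v = pvals[col].to_numpy(dtype=float)
        if np.any((v <= 0) | (v > 1) | ~np.isfinite(v)):
            raise ValueError(f"{col} values must lie in (0, 1]")
    n_methods = pvals.groupby("gene_id")["method"].nunique()
    short = n_methods[n_methods < 2]
    if len(short):
        raise ValueError(f"genes with fewer than 2 methods: {list(short.index[:5])}")
    agg = pvals.groupby("gene_id").agg(
        p_up_comb=("p_up", "max"), p_down_comb=("p_down", "max")).reset_index()
    up_wins = agg["p_up_comb"] <= agg["p_down_comb"]
    agg["direction"] = np.where(up_wins, "up", "down")
    p_min = np.minimum(agg["p_up_comb"], agg["p_down_comb"])
    if assembly == "two-sided":
        agg["p_consistent"] = np.minimum(1.0, 2.0 * p_min)
    else:
        agg["p_consistent"] = p_min
    return agg


def max_p_across_methods(p_a: float, p_b: float) -> float:
    """Per-window IUT across two loss-of-function methods."""
    for p in (p_a, p_b):
        if not 0 < p <= 1:
            raise ValueError("p-values must lie in (0, 1]")
    return max(p_a, p_b)


# --------------------------------------------------------------------------
# multiple testing
# --------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def simes_combine(p) -> float:
    """Simes' combined p-value: min over sorted p of (m * p_(i) / i)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    srt = np.sort(p)
    m = srt.size
    return float(np.min(m * srt / np.arange(1, m + 1)))


# --------------------------------------------------------------------------
# genomic windows
# --------------------------------------------------------------------------

def _check_windows(windows: pd.DataFrame) -> pd.DataFrame:
    missing = set(("chrom", "start", "end")) - set(windows.columns)
    if missing:
        raise ValueError(f"missing window columns {sorted(missing)}")
    w = windows.copy()
    if len(w) and (w["start"] >= w["end"]).any():
        raise ValueError("malformed intervals (start >= end)")
    return w


def filter_windows(windows: pd.DataFrame, background_abundance: float,
                   fold: float = 5.0) -> pd.DataFrame:
    """Keep windows whose average abundance is at least ``fold`` times the
    expected background coverage (default fivefold)."""
    w = _check_windows(windows)
    if w.empty:
        return w
    if not np.isfinite(w["abundance"]).all():
        raise ValueError("non-finite abundances")
    return w[w["abundance"] >= fold * background_abundance].copy()


def cluster_windows(windows: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-linkage clustering of overlapping windows (all sizes pooled).

    Overlap is on 0-based half-open intervals per chromosome; the transitive
    closure of pairwise overlap defines each cluster.  Returns the windows
    with a ``cluster_id`` column and a cluster table with the spanned
    interval, member count, Simes-combined p and direction.  A mixed-direction
    cluster takes the direction of its smallest-p member.
    """
    w = _check_windows(windows)
    if w.empty:
        empty = pd.DataFrame(columns=["cluster_id", "chrom", "start", "end",
                                      "n_members", "combined_p", "direction"])
        w["cluster_id"] = pd.Series(dtype=int)
        return w, empty
    w = w.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    cluster_ids = np.empty(len(w), dtype=int)
    cid = -1
    cur_chrom, cur_end = None, -np.inf
    for i, row in enumerate(w.itertuples(index=False)):
        if row.chrom != cur_chrom or row.start >= cur_end:
            cid += 1
            cur_chrom, cur_end = row.chrom, row.end
        else:
            cur_end = max(cur_end, row.end)
        cluster_ids[i] = cid
    w["cluster_id"] = cluster_ids
    rows = []
    for cluster_id, grp in w.groupby("cluster_id"):
        rec = {"cluster_id": int(cluster_id), "chrom": grp["chrom"].iloc[0],
               "start": int(grp["start"].min()), "end": int(grp["end"].max()),
               "n_members": len(grp)}
        if "p" in grp:
            rec["combined_p"] = simes_combine(grp["p"].to_numpy())
            if "direction" in grp:
                dirs = grp["direction"].unique()
                rec["direction"] = (dirs[0] if len(dirs) == 1
                                    else grp.loc[grp["p"].idxmin(), "direction"])
        rows.append(rec)
    return w, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# empirical FDR
# --------------------------------------------------------------------------

def empirical_fdr(clusters: pd.DataFrame, p_cut: float) -> dict:
    """Empirical FDR at a combined-p cutoff.

    Among clusters with ``combined_p <= p_cut``, the eFDR is the number of
    clusters with increased coverage in the sense control (direction "down",
    i.e. false positives) over the number with increased coverage in the
    antisense pulldown (direction "up", potential true discoveries).  An
    empty denominator reports eFDR 1 with an ``undefined`` flag.
    """
    sub = clusters[clusters["combined_p"] <= p_cut]
    n_true = int((sub["direction"] == "up").sum())
    n_false = int((sub["direction"] == "down").sum())
    if n_true == 0:
        return {"efdr": 1.0, "n_discovery": 0, "n_false_direction": n_false,
                "undefined": True}
    return {"efdr": n_false / n_true, "n_discovery": n_true,
            "n_false_direction": n_false, "undefined": False}


def efdr_threshold(clusters: pd.DataFrame, target_efdr: float = 0.30) -> dict:
    """Largest combined-p cutoff whose empirical FDR stays at or below the
    target (default 30%); sweeps the observed combined p-values."""
    cuts = np.unique(clusters["combined_p"].to_numpy())
    best = None
    for cut in cuts:
        res = empirical_fdr(clusters, cut)
        if not res["undefined"] and res["efdr"] <= target_efdr:
            best = {"p_cut": float(cut), **res}
    if best is None:
        return {"p_cut": 0.0, "efdr": 1.0, "n_discovery": 0,
                "n_false_direction": 0, "undefined": True}
    return best
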