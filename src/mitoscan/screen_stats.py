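"""Plate normalization, Z-scoring, hit calling and replicate concordance.

Per-well ratios (mitotic index, multinucleation index, CSE rate, bridge rate,
viability) are normalized between plates by mean scaling: the grand average of
all per-plate means gives a reference ratio, and per-well ratios on each plate
are scaled so the plate average equals the reference.  Z-scores are then

    z = (x - mu) / sigma

with x the normalized ratio, mu the reference ratio and sigma the standard
deviation of normalized ratios across wells.  By default mu and sigma are
estimated over library (non-control) wells only; hit calls compare each
target's depletion phenotype to the mean across the whole library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

TABLE_COLUMNS = ["plate_id", "well_id", "target_id", "feature", "ratio",
                 "normalized_ratio", "z", "is_control", "control_role"]


@dataclass
class NormalizationSummary:
    per_plate_mean: dict[str, float]
    reference_mean: float
    sd_across_wells: float
    scale_factors: dict[str, float]
    warnings: list[str] = field(default_factory=list)


def _check_table(table: pd.DataFrame, feature: str) -> pd.DataFrame:
    if table.empty:
        raise ValueError("empty screen table")
    sub = table[table["feature"] == feature].copy()
    if sub.empty:
        raise ValueError(f"no rows for feature {feature!r}")
    dup = sub.duplicated(subset=["plate_id", "well_id", "feature"])
    if dup.any():
        raise ValueError("duplicate (plate_id, well_id, feature) rows")
    if not np.isfinite(sub["ratio"]).all():
        raise ValueError("non-finite ratios")
    return sub


def normalize_plates(table: pd.DataFrame, feature: str,
                     include_controls: bool = False
                     ) -> tuple[pd.DataFrame, NormalizationSummary]:
    """Scale per-well ratios so every plate's mean equals the grand reference.

    ``scale_factor(plate) = reference_mean / plate_mean``;
    ``normalized_ratio = ratio * scale_factor``.  A plate with mean 0 keeps a
    factor of 1 and is flagged.  Plate means are computed over library wells
    unless ``include_controls``.
    """
    sub = _check_table(table, feature)
    est = sub if include_controls else sub[~sub["is_control"].astype(bool)]
    if est.empty:
        est = sub
    per_plate = est.groupby("plate_id")["ratio"].mean()
    if (sub.groupby("plate_id")["well_id"].count() < 2).any():
        raise ValueError("each plate needs at least 2 wells for the feature")
    reference = float(per_plate.mean())
    warnings_: list[str] = []
    factors: dict[str, float] = {}
    for plate, mean in per_plate.items():
        if mean == 0:
            factors[plate] = 1.0
            warnings_.append(f"plate {plate} has zero mean ratio; factor set to 1")
        else:
            factors[plate] = reference / mean
    sub["normalized_ratio"] = sub["ratio"] * sub["plate_id"].map(factors)
    est_norm = sub if include_controls else sub[~sub["is_control"].astype(bool)]
    sd = float(est_norm["normalized_ratio"].std(ddof=1))
    summary = NormalizationSummary(
        per_plate_mean={k: float(v) for k, v in per_plate.items()},
        reference_mean=reference, sd_across_wells=sd,
        scale_factors=factors, warnings=warnings_)
    return sub, summary


def zscore(table: pd.DataFrame, summary: NormalizationSummary | None = None,
           include_controls: bool = False) -> pd.DataFrame:
    """Attach z = (x - mu)/sigma with x the normalized ratio.

    mu is the reference mean and sigma the sample SD of normalized ratios
    across (library) wells; sigma = 0 raises.
    """
    if "normalized_ratio" not in table or table["normalized_ratio"].isna().all():
        raise ValueError("normalize_plates must run before zscore")
    out = table.copy()
    if summary is not None:
        mu, sd = summary.reference_mean, summary.sd_across_wells
    else:
        est = out if include_controls else out[~out["is_control"].astype(bool)]
        mu = float(est["normalized_ratio"].mean())
        sd = float(est["normalized_ratio"].std(ddof=1))
    if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, abs(mu)):
        raise ValueError("zero standard deviation across wells")
    out["z"] = (out["normalized_ratio"] - mu) / sd
    return out


def call_hits(table: pd.DataFrame, z_min: float, direction: str = "increase",
              exclude_controls: bool = True) -> pd.DataFrame:
    """Rank targets whose phenotype z exceeds the threshold.

    Wells of the same target are aggregated by their mean z.  Direction
    "increase" keeps mean z >= z_min (sorted descending), "decrease" keeps
    mean z <= -z_min (sorted ascending), "both" keeps |mean z| >= z_min.
    Ties break lexicographically by target id.
    """
    if direction not in ("increase", "decrease", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    if "z" not in table or table["z"].isna().all():
        raise ValueError("zscore must run before call_hits")
    sub = table[~table["is_control"].astype(bool)] if exclude_controls else table
    agg = sub.groupby("target_id", as_index=False).agg(
        z=("z", "mean"), n_wells=("z", "size"))
    if direction == "increase":
        agg = agg[agg["z"] >= z_min]
        agg = agg.sort_values(["z", "target_id"], ascending=[False, True])
    elif direction == "decrease":
        agg = agg[agg["z"] <= -z_min]
        agg = agg.sort_values(["z", "target_id"], ascending=[True, True])
    else:
        agg = agg[agg["z"].abs() >= z_min]
        agg = agg.reindex(agg["z"].abs().sort_values(ascending=False).index)
    return agg.reset_index(drop=True)


def replicate_correlation(table_a: pd.DataFrame, table_b: pd.DataFrame,
                          feature: str, on: str = "well_id",
                          value: str = "ratio") -> float:
    """Spearman rank correlation of a feature between two replicate tables,
    matched on well (or target) id, with average-rank tie handling."""
    a = table_a[table_a["feature"] == feature][[on, value]]
    b = table_b[table_b["feature"] == feature][[on, value]]
    merged = a.merge(b, on=on, suffixes=("_a", "_b")).dropna()
    if len(merged) < 3:
        raise ValueError("need at least 3 matched wells")
    rho, _ = stats.spearmanr(merged[f"{value}_a"], merged[f"{value}_b"])
    return float(rho)
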