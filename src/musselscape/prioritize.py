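"""Richness stacking and multi-criteria conservation priority scoring.

Single-species binary maps (prediction >= max-sens+spec threshold) are
summed into overall richness and the richness of Regional Species of
Greatest Conservation Need (RSGCN: ranked very high, high, or moderate).
Three priority surfaces follow, each a min-max-scaled combination of scaled
inputs:

* survey priority     = scale( scale(richness) - surveyed-since-cutoff binary )
* restoration priority = scale( scale(protected) + scale(forest) - scale(land-use change) ),
  one shared surface, masked per species to catchments whose HUC8 holds a
  record (restoration happens within the recorded range; species restricted
  to RSGCN rank high/very high)
* protection priority = scale( scale(richness) + scale(forest) + scale(wetland) + scale(resilience) )
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .data import CatchmentFrame
from .errors import DataError, DegenerateInputError

RSGCN_SET = ("very_high", "high", "moderate")
RESTORATION_RANKS = ("very_high", "high")


def binary_map(predictions: pd.Series, threshold: float) -> pd.Series:
    """1 where prediction >= threshold, else 0."""
    return (predictions >= threshold).astype(int)


def stack_richness(
    binary_maps: dict[str, pd.Series], rsgcn_ranks: dict[str, str]
) -> pd.DataFrame:
    """Sum the per-species binary maps into overall and RSGCN richness."""
    if not binary_maps:
        raise DataError("no binary maps to stack")
    maps = pd.DataFrame(binary_maps)
    if maps.isna().any().any():
        raise DataError("binary maps cover different catchment sets")
    rsgcn_species = [s for s in maps.columns if rsgcn_ranks.get(s) in RSGCN_SET]
    out = pd.DataFrame(
        {
            "overall_richness": maps.sum(axis=1),
            "rsgcn_richness": maps[rsgcn_species].sum(axis=1)
            if rsgcn_species
            else 0,
        },
        index=maps.index,
    )
    return out


def minmax_scale(values) -> pd.Series | np.ndarray:
    """(v - min) / (max - min); a constant vector maps to all zeros.

    NaNs propagate and are ignored when finding the extremes.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DegenerateInputError("cannot scale an empty vector")
    lo = np.nanmin(arr)
    hi = np.nanmax(arr)
    scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    if hi == lo:
        scaled = np.where(np.isnan(arr), np.nan, scaled)
    if isinstance(values, pd.Series):
        return pd.Series(scaled, index=values.index, name=values.name)
    return scaled


def survey_priority(richness: pd.DataFrame, surveyed_since: set) -> pd.Series:
    """Survey-effort priority: high richness and no recent survey score high."""
    scaled = minmax_scale(richness["overall_richness"])
    binary = richness.index.isin(surveyed_since).astype(float)
    out = minmax_scale(scaled - binary)
    out.name = "survey_priority"
    return out


def restoration_base(
    protected_pct: pd.Series,
    forest_pct: pd.Series,
    landuse_change_pct: pd.Series,
) -> pd.Series:
    """The single region-wide restoration surface before eligibility masking."""
    base = (
        minmax_scale(protected_pct)
        + minmax_scale(forest_pct)
        - minmax_scale(landuse_change_pct)
    )
    out = minmax_scale(base)
    out.name = "restoration_priority"
    return out


def restoration_priority(
    protected_pct: pd.Series,
    forest_pct: pd.Series,
    landuse_change_pct: pd.Series,
    presences: dict[str, set],
    frame: CatchmentFrame,
    rsgcn_ranks: dict[str, str],
) -> dict[str, pd.Series]:
    """Per-species restoration surfaces for high/very-high RSGCN species.

    All species share one underlying surface; a catchment is eligible for a
    species only if its HUC8 contains at least one record of that species.
    Ineligible catchments carry NaN, not zero.
    """
    base = restoration_base(protected_pct, forest_pct, landuse_change_pct)
    id_to_huc8 = frame.data.set_index("catchment_id")["huc8"]
    out: dict[str, pd.Series] = {}
    for sp, rank in rsgcn_ranks.items():
        if rank not in RESTORATION_RANKS:
            continue
        present = presences.get(sp, set())
        occupied_huc8 = set(id_to_huc8.loc[list(present)]) if present else set()
        eligible = id_to_huc8.reindex(base.index).isin(occupied_huc8)
        surface = base.where(eligible)
        surface.name = f"restoration_priority_{sp}"
        out[sp] = surface
    return out


def protection_priority(
    richness: pd.DataFrame,
    forest_pct: pd.Series,
    wetland_pct: pd.Series,
    resilience: pd.Series,
) -> pd.Series:
    """Land-protection priority from richness, forest, wetland and
    climate-resilience inputs."""
    total = (
        minmax_scale(richness["overall_richness"])
        + minmax_scale(forest_pct)
        + minmax_scale(wetland_pct)
        + minmax_scale(resilience)
    )
    out = minmax_scale(total)
    out.name = "protection_priority"
    return out


def interspecies_correlation(predictions: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation matrix between species' prediction surfaces."""
    if predictions.shape[1] < 2:
        raise DataError("need at least two species")
    ranks = predictions.rank(axis=0).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=predictions.columns, columns=predictions.columns)


def protection_vs_protected_correlation(
    protection: pd.Series,
    protected_pct: pd.Series,
    states: pd.Series | None = None,
) -> dict[str, float]:
    """Spearman correlation between protection priority and current percent
    protected land, region-wide and (if state labels are given) per state."""
    aligned = pd.DataFrame({"priority": protection, "protected": protected_pct}).dropna()
    if aligned["priority"].nunique() == 1 or aligned["protected"].nunique() == 1:
        raise DegenerateInputError("constant input; correlation undefined")
    out = {"region": float(spearmanr(aligned["priority"], aligned["protected"]).statistic)}
    if states is not None:
        for state, grp in aligned.groupby(states.reindex(aligned.index)):
            if len(grp) > 2 and grp["priority"].nunique() > 1 and grp["protected"].nunique() > 1:
                out[str(state)] = float(
                    spearmanr(grp["priority"], grp["protected"]).statistic
                )
            else:
                out[str(state)] = float("nan")
    return out


def _mean_se(values: pd.Series) -> tuple[float, float]:
    v = values.dropna()
    if len(v) == 0:
        return float("nan"), float("nan")
    se = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
    return float(v.mean()), se


def state_summaries(
    frame: CatchmentFrame,
    richness: pd.DataFrame,
    surveys: pd.DataFrame,
    survey_surface: pd.Series,
    protection_surface: pd.Series,
    restoration_surfaces: dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """Per-state summary: survey events, mean richness, and mean (SE) of each
    priority surface.  A species with no eligible catchment in a state gets
    NaN, the machine-readable stand-in for an N/A entry."""
    id_to_state = frame.data.set_index("catchment_id")["state"]
    survey_states = id_to_state.reindex(surveys["catchment_id"]).value_counts()
    rows = []
    for state, grp in frame.data.groupby("state"):
        ids = grp["catchment_id"]
        row: dict = {"state": state, "n_surveys": int(survey_states.get(state, 0))}
        row["mean_richness"] = float(
            richness["overall_richness"].reindex(ids).mean()
        )
        for label, surface in (
            ("survey_priority", survey_surface),
            ("protection_priority", protection_surface),
        ):
            m, se = _mean_se(surface.reindex(ids))
            row[f"{label}_mean"] = m
            row[f"{label}_se"] = se
        for sp, surface in (restoration_surfaces or {}).items():
            m, se = _mean_se(surface.reindex(ids))
            row[f"restoration_{sp}_mean"] = m
            row[f"restoration_{sp}_se"] = se
        rows.append(row)
    return pd.DataFrame(rows).sort_values("state").reset_index(drop=True)


def ranked_priority(surface: pd.Series) -> pd.DataFrame:
    """Catchments ranked by descending priority; ties break on catchment id."""
    df = surface.dropna().rename("score").rename_axis("catchment_id").reset_index()
    df = df.sort_values(["score", "catchment_id"], ascending=[False, True])
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)
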