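"""Model-ready responses from raw records.

Four jobs: (i) rescale effort-sensitive abundance measures to a common
within-study effort; (ii) expand records into a presence/absence table
using the rule that a species recorded anywhere in a study is an inferable
absence at that study's other sites; (iii) classify taxa into narrow- vs
wide-ranged by half-degree-cell area of occupancy around the group median;
(iv) flag forest/habitat specialists from habitat tables.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "EFFORT_SENSITIVE_MEASURES",
    "LAND_USES",
    "GROUPS",
    "correct_effort",
    "derive_occurrence",
    "cell_area_km2",
    "area_of_occupancy",
    "classify_range",
    "flag_specialists",
]

#: Measures assumed to scale in direct proportion to sampling effort.
EFFORT_SENSITIVE_MEASURES = frozenset({"abundance", "group_abundance"})

#: The six-class land-use vocabulary (RCP classes), primary forest first.
LAND_USES = (
    "primary_forest",
    "secondary_vegetation",
    "wood_plantation",
    "cropland",
    "pasture",
    "urban",
)

#: Major taxonomic groups.
GROUPS = ("invertebrates", "herptiles", "mammals", "birds")

EARTH_RADIUS_KM = 6371.0
CELL_DEG = 0.5


def correct_effort(records: pd.DataFrame) -> pd.DataFrame:
    """Rescale effort-sensitive measures to the within-study maximal effort.

    For measure types in :data:`EFFORT_SENSITIVE_MEASURES` the recorded
    value is assumed proportional to sampling effort, so the corrected value
    is what would have been recorded at the study's largest effort:
    ``corrected = value / (effort / max effort within study)``.  Other
    measure types pass through unchanged.  Idempotent: a boolean
    ``effort_corrected`` column guards against double correction.

    Raises
    ------
    ValidationError
        If any effort is non-positive (offending rows listed).
    """
    records = records.copy()
    if "effort_corrected" in records.columns and records["effort_corrected"].any():
        raise ValidationError("records already effort-corrected")
    bad = records.index[records["effort"] <= 0]
    if len(bad):
        raise ValidationError(f"non-positive effort in rows {list(bad[:20])}")
    sensitive = records["measure_type"].isin(EFFORT_SENSITIVE_MEASURES)
    max_effort = records.groupby("study_id")["effort"].transform("max")
    scale = np.where(sensitive, records["effort"] / max_effort, 1.0)
    records["value"] = records["value"] / scale
    records["effort_corrected"] = sensitive
    return records


def derive_occurrence(records: pd.DataFrame) -> pd.DataFrame:
    """Presence/absence table from the long record table.

    Within each study, a taxon with a positive value at any site gets one
    row per site of that study; ``present`` is 1 where its value is
    positive.  Taxa never recorded with a positive value in a study are
    excluded from that study's table (no inferable absences), and sites
    where they were not sampled become inferred absences.

    Raises
    ------
    ValidationError
        On duplicate (study, site, taxon) records.
    """
    dup = records.duplicated(["study_id", "site_id", "taxon_id"])
    if dup.any():
        offenders = records.loc[dup, ["study_id", "site_id", "taxon_id"]].head()
        raise ValidationError(f"duplicate (study, site, taxon) records:\n{offenders}")
    out = []
    for study_id, sub in records.groupby("study_id", sort=True):
        sites = np.sort(sub["site_id"].unique())
        recorded = np.sort(sub.loc[sub["value"] > 0, "taxon_id"].unique())
        dropped = len(sub["taxon_id"].unique()) - len(recorded)
        if dropped:
            logger.info(
                "study %s: %d taxa with no positive record excluded from "
                "occurrence table", study_id, dropped,
            )
        if len(recorded) == 0:
            continue
        grid = pd.MultiIndex.from_product(
            [sites, recorded], names=["site_id", "taxon_id"]
        ).to_frame(index=False)
        grid["study_id"] = study_id
        positives = sub.loc[sub["value"] > 0, ["site_id", "taxon_id"]]
        key = pd.MultiIndex.from_frame(grid[["site_id", "taxon_id"]])
        pos_key = pd.MultiIndex.from_frame(positives)
        grid["present"] = key.isin(pos_key).astype(int)
        out.append(grid[["study_id", "site_id", "taxon_id", "present"]])
    if not out:
        return pd.DataFrame(columns=["study_id", "site_id", "taxon_id", "present"])
    return pd.concat(out, ignore_index=True)


def cell_area_km2(lat_south: float, d: float = CELL_DEG) -> float:
    """Area of a d-degree grid cell whose southern edge is at `lat_south`.

    Spherical formula ``R^2 * dlon * (sin(lat_n) - sin(lat_s))`` with
    R = 6371 km.
    """
    dlon = math.radians(d)
    return EARTH_RADIUS_KM**2 * dlon * (
        math.sin(math.radians(lat_south + d)) - math.sin(math.radians(lat_south))
    )


def area_of_occupancy(lons: np.ndarray, lats: np.ndarray) -> float:
    """Summed area (km^2) of distinct half-degree cells holding >= 1 point.

    Cells are half-open, aligned to integer + 0.0/0.5 boundaries; a point
    on a boundary belongs to the cell to its north-east.
    """
    lon_cells = np.floor(np.asarray(lons, float) / CELL_DEG) * CELL_DEG
    lat_cells = np.floor(np.asarray(lats, float) / CELL_DEG) * CELL_DEG
    cells = set(zip(lon_cells, lat_cells))
    return float(sum(cell_area_km2(lat) for _, lat in cells))


def classify_range(points: pd.DataFrame, taxa: pd.DataFrame) -> pd.DataFrame:
    """Split each group's taxa into narrow-/wide-ranged at the median AOO.

    Parameters
    ----------
    points : DataFrame with columns taxon_id, lon, lat (occurrence records).
    taxa : DataFrame with columns taxon_id, group.

    Returns the taxa table with ``aoo_km2`` and ``range_class`` columns;
    range class is ``wide`` where AOO strictly exceeds the group median,
    ``narrow`` at or below it, and ``unset`` (with a warning) for taxa
    without occurrence points.
    """
    taxa = taxa.copy()
    aoo = (
        points.groupby("taxon_id")
        .apply(
            lambda g: area_of_occupancy(g["lon"].to_numpy(), g["lat"].to_numpy()),
            include_groups=False,
        )
        .rename("aoo_km2")
    )
    taxa = taxa.merge(aoo, on="taxon_id", how="left")
    missing = taxa["aoo_km2"].isna()
    if missing.any():
        logger.warning(
            "%d taxa have no occurrence points; range class left unset",
            int(missing.sum()),
        )
    taxa["range_class"] = "unset"
    for group, sub in taxa.groupby("group"):
        have = sub["aoo_km2"].notna()
        if not have.any():
            continue
        med = sub.loc[have, "aoo_km2"].median()
        idx = sub.index[have]
        taxa.loc[idx, "range_class"] = np.where(
            sub.loc[have, "aoo_km2"] > med, "wide", "narrow"
        )
    return taxa


def flag_specialists(taxa: pd.DataFrame, habitat_table: pd.DataFrame) -> pd.DataFrame:
    """Forest/habitat specialist flags for birds and mammals.

    Birds are forest specialists iff forest habitat is of 'major'
    importance; mammals are specialists iff their habitat breadth (number
    of habitat layers used) equals one.  Other groups, and taxa with
    missing habitat information, are 'unknown'.

    ``habitat_table`` columns: taxon_id, plus forest_importance (birds)
    and/or habitat_breadth (mammals).
    """
    taxa = taxa.copy()
    merged = taxa.merge(habitat_table, on="taxon_id", how="left")
    spec = np.full(len(taxa), "unknown", dtype=object)
    is_bird = merged["group"] == "birds"
    is_mammal = merged["group"] == "mammals"
    if "forest_importance" in merged:
        known = is_bird & merged["forest_importance"].notna()
        spec[known] = np.where(
            merged.loc[known, "forest_importance"] == "major",
            "specialist", "generalist",
        )
    if "habitat_breadth" in merged:
        known = is_mammal & merged["habitat_breadth"].notna()
        spec[known] = np.where(
            merged.loc[known, "habitat_breadth"] == 1, "specialist", "generalist"
        )
    n_missing = int(((is_bird | is_mammal) & (spec == "unknown")).sum())
    if n_missing:
        logger.warning("%d birds/mammals lack habitat data; flag unknown", n_missing)
    taxa["specialist"] = spec
    return taxa
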