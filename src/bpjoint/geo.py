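"""Regional prevalence aggregation and choropleth rendering.

Aggregates the four hypertension measures (SBP-based, DBP-based, combined,
and self-reported ever-told) to region level and shades region polygons from
a GeoJSON FeatureCollection accordingly. Region names are joined by
normalized exact match (case-insensitive, whitespace-trimmed); an unmatched
name is an error, never a silent drop.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd
from shapely.geometry import shape

from .cohort import add_hypertension_flags, round_half_away

__all__ = [
    "regional_prevalence",
    "render_choropleth",
    "load_geojson",
    "PREVALENCE_MEASURES",
]

log = logging.getLogger(__name__)

#: Column names of the four mapped measures in the prevalence table.
PREVALENCE_MEASURES = (
    "prevalence_sbp", "prevalence_dbp", "prevalence_combined", "prevalence_ever_told",
)

_FLAG_FOR_MEASURE = {
    "prevalence_sbp": "htn_sbp",
    "prevalence_dbp": "htn_dbp",
    "prevalence_combined": "htn_combined",
    "prevalence_ever_told": "ever_told",
}


def regional_prevalence(records: pd.DataFrame) -> pd.DataFrame:
    """Per-region counts and prevalences (percent, 1 decimal) of the four measures.

    Prevalence is ``100 * flagged / n`` within the region, rounded
    half-away-from-zero. Also carries the flagged counts so that summing rows
    reproduces the national counts exactly. Regions with no women simply do
    not appear (a log line records any empty region label category).
    """
    if "region" not in records.columns:
        raise ValueError("records must carry a 'region' column")
    flagged = add_hypertension_flags(records)
    rows = []
    for region, grp in flagged.groupby("region", sort=True):
        n = len(grp)
        row = {"region": region, "n_women": n}
        for measure, col in _FLAG_FOR_MEASURE.items():
            count = int(grp[col].sum())
            row[measure.replace("prevalence_", "count_")] = count
            row[measure] = round_half_away(100.0 * count / n)
        rows.append(row)
    if isinstance(records["region"].dtype, pd.CategoricalDtype):
        empty = set(records["region"].cat.categories) - {r["region"] for r in rows}
        for name in sorted(empty):
            log.info("region %r has no women; omitted from the prevalence table", name)
    return pd.DataFrame(rows)


def _normalize(name: str) -> str:
    return " ".join(str(name).split()).casefold()


def load_geojson(source) -> dict:
    """Load a GeoJSON FeatureCollection from a dict, JSON string or file path."""
    if isinstance(source, dict):
        gj = source
    elif isinstance(source, str) and source.lstrip().startswith("{"):
        gj = json.loads(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    return gj


def render_choropleth(prevalence_table: pd.DataFrame, geometry, measure: str,
                      output_path, *, cmap: str = "YlOrRd", bins: int | None = None,
                      title: str | None = None) -> str:
    """Write a choropleth of one prevalence measure to ``output_path``.

    ``geometry`` is a GeoJSON FeatureCollection (dict, JSON text, or path)
    whose features carry a ``name`` property. Every region in the table must
    match a feature by normalized name; unmatched regions raise an error
    listing them. The color scale is continuous by default; pass ``bins`` for
    an equal-interval binned scale. Returns the output path.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PatchCollection
    from matplotlib.patches import Polygon as MplPolygon

    if measure not in prevalence_table.columns:
        raise ValueError(f"measure {measure!r} not in prevalence table")
    gj = load_geojson(geometry)
    by_name = {}
    for feat in gj["features"]:
        name = feat.get("properties", {}).get("name")
        if name is None:
            raise ValueError("every feature needs a 'name' property")
        by_name[_normalize(name)] = feat

    missing = [str(r) for r in prevalence_table["region"]
               if _normalize(r) not in by_name]
    if missing:
        raise ValueError(f"no geometry for region(s): {missing}")

    values = prevalence_table[measure].to_numpy(float)
    vmin, vmax = float(values.min()), float(values.max())
    if vmax <= vmin:
        vmax = vmin + 1.0
    norm = (plt.Normalize(vmin, vmax) if bins is None
            else matplotlib.colors.BoundaryNorm(
                np.linspace(vmin, vmax, bins + 1), ncolors=256))

    fig, ax = plt.subplots(figsize=(7, 7))
    patches, vals = [], []
    for region, value in zip(prevalence_table["region"], values):
        geom = shape(by_name[_normalize(region)]["geometry"])
        polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
        for poly in polys:
            patches.append(MplPolygon(np.asarray(poly.exterior.coords), closed=True))
            vals.append(value)
        cx, cy = geom.centroid.x, geom.centroid.y
        ax.annotate(str(region), (cx, cy), ha="center", va="center", fontsize=7)
    coll = PatchCollection(patches, cmap=cmap, norm=norm, edgecolor="black",
                           linewidth=0.6)
    coll.set_array(np.asarray(vals))
    ax.add_collection(coll)
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_axis_off()
    fig.colorbar(coll, ax=ax, shrink=0.7, label=f"{measure} (%)")
    ax.set_title(title or measure)
    fig.savefig(output_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return str(output_path)
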