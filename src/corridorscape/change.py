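"""Land-cover change accounting, classification accuracy, and corridor
validation summaries.

Change tables follow the usual remote-sensing bookkeeping: percent cover per
class and time step over non-nodata cells, percent-point change per interval,
and average annual rates over the full span in both %/yr and km^2/yr (span
change divided by last year minus first year). Classification accuracy is a
confusion matrix with overall accuracy and Cohen's kappa. Corridor-level
summaries report cropland encroachment of each corridor swath over time and
an active/inactive status from interview sighting reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from corridorscape.connectivity import CorridorLink
from corridorscape.raster import RasterGrid

__all__ = [
    "ChangeTable",
    "AccuracyReport",
    "compose_change_table",
    "confusion_and_kappa",
    "corridor_encroachment",
    "corridor_activity",
]


@dataclass
class ChangeTable:
    """Per-class cover, interval changes, and annual rates."""

    table: pd.DataFrame  # indexed by class, columns documented in compose_change_table
    labels: tuple[int, ...]
    total_area_km2: float


@dataclass
class AccuracyReport:
    confusion: pd.DataFrame  # rows = reference classes, cols = predicted
    overall_accuracy: float  # percent
    kappa: float
    n_excluded: int = 0


def compose_change_table(
    landcover: Sequence[RasterGrid],
    labels: Sequence[int],
    total_area_km2: float | None = None,
    class_names: dict[int, str] | None = None,
) -> ChangeTable:
    """Build the change table from aligned land-cover grids.

    Columns: ``pct_<label>`` and ``area_km2_<label>`` per step,
    ``change_<a>_<b>`` per consecutive interval and for the full span
    (percent points), ``annual_rate_pct`` and ``annual_rate_km2`` over the
    span. Class percentages are taken over non-nodata cells; a class absent
    from a step scores 0 there.
    """
    if len(landcover) != len(labels):
        raise ValueError("one label per land-cover grid required")
    if len(landcover) < 2:
        raise ValueError("need at least two time steps")
    template = landcover[0]
    for g in landcover[1:]:
        if not g.aligned_with(template):
            raise ValueError("land-cover grids are not aligned")
    if total_area_km2 is None:
        total_area_km2 = template.valid_mask().sum() * template.cellsize**2

    codes = sorted(
        {int(v) for g in landcover for v in np.unique(g.valid_values())}
    )
    pct = {}
    for lab, g in zip(labels, landcover):
        vals = g.valid_values()
        n = vals.size
        pct[lab] = {code: 100.0 * (vals == code).sum() / n for code in codes}
    rows = []
    years = list(labels)
    span = years[-1] - years[0]
    for code in codes:
        row: dict[str, float | str] = {"class": class_names.get(code, code) if class_names else code}
        for lab in years:
            row[f"pct_{lab}"] = pct[lab][code]
            row[f"area_km2_{lab}"] = pct[lab][code] / 100.0 * total_area_km2
        for a, b in zip(years, years[1:]):
            row[f"change_{a}_{b}"] = pct[b][code] - pct[a][code]
        span_change = pct[years[-1]][code] - pct[years[0]][code]
        row[f"change_{years[0]}_{years[-1]}"] = span_change
        row["annual_rate_pct"] = span_change / span
        row["annual_rate_km2"] = span_change / 100.0 * total_area_km2 / span
        rows.append(row)
    table = pd.DataFrame(rows).set_index("class")
    return ChangeTable(table=table, labels=tuple(years), total_area_km2=float(total_area_km2))


def confusion_and_kappa(reference: pd.DataFrame, predicted: RasterGrid) -> AccuracyReport:
    """Confusion matrix, overall accuracy (%) and Cohen's kappa from
    reference points (columns x, y, class) looked up on the predicted grid.

    Points on nodata cells are excluded and counted in ``n_excluded``.
    """
    rows = np.floor((predicted.origin[1] - reference["y"].to_numpy()) / predicted.cellsize).astype(int)
    cols = np.floor((reference["x"].to_numpy() - predicted.origin[0]) / predicted.cellsize).astype(int)
    inside = (rows >= 0) & (rows < predicted.nrows) & (cols >= 0) & (cols < predicted.ncols)
    if not inside.all():
        raise ValueError(f"{(~inside).sum()} reference points fall outside the grid")
    pred_vals = predicted.values[rows, cols]
    valid = predicted.valid_mask()[rows, cols]
    n_excluded = int((~valid).sum())
    ref = reference["class"].to_numpy()[valid].astype(int)
    pred = pred_vals[valid].astype(int)
    if np.unique(ref).size < 2:
        raise ValueError("need at least 2 reference classes for an accuracy report")
    confusion = pd.crosstab(
        pd.Series(ref, name="reference"), pd.Series(pred, name="predicted"), dropna=False
    )
    # square the matrix so marginals align
    all_codes = sorted(set(confusion.index) | set(confusion.columns))
    confusion = confusion.reindex(index=all_codes, columns=all_codes, fill_value=0)
    m = confusion.to_numpy(dtype=float)
    total = m.sum()
    p_o = np.trace(m) / total
    p_e = float((m.sum(axis=1) * m.sum(axis=0)).sum()) / total**2
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0
    return AccuracyReport(
        confusion=confusion,
        overall_accuracy=float(100.0 * p_o),
        kappa=float(kappa),
        n_excluded=n_excluded,
    )


def corridor_encroachment(
    links: Sequence[CorridorLink],
    landcover: Sequence[RasterGrid],
    labels: Sequence[int],
    cropland_code: int = 4,
    threshold_pct: float = 0.0,
) -> pd.DataFrame:
    """Percent of each corridor swath classed cropland, per time step.

    A link is flagged ``encroached`` at a step when its cropland percentage
    exceeds ``threshold_pct``. Links without a corridor mask are excluded.
    """
    records = []
    for lk in links:
        if lk.corridor_mask is None:
            continue
        in_corr = lk.corridor_mask.values > 0
        if not in_corr.any():
            continue
        for lab, g in zip(labels, landcover):
            pct = 100.0 * (g.values[in_corr] == cropland_code).mean()
            records.append(
                {
                    "pa_from": lk.pa_from,
                    "pa_to": lk.pa_to,
                    "step": lab,
                    "cropland_pct": pct,
                    "encroached": pct > threshold_pct,
                }
            )
    return pd.DataFrame(records)


def corridor_activity(
    links: Sequence[CorridorLink], reports: pd.DataFrame
) -> pd.DataFrame:
    """Per-link sighting summary and active/inactive status.

    ``reports`` carries one row per respondent with columns pa_from, pa_to,
    sightings, and optionally season. A link is "active" when any respondent
    reported at least one sighting in the last year; the sightings SD is the
    sample (n-1) standard deviation. Report rows that match no link are
    excluded with a warning.
    """
    link_keys = {(lk.pa_from, lk.pa_to) for lk in links}
    keyed = reports.set_index(["pa_from", "pa_to"], drop=False)
    unmatched = set(map(tuple, reports[["pa_from", "pa_to"]].drop_duplicates().to_numpy())) - link_keys
    if unmatched:
        warnings.warn(f"report sites with no matching link excluded: {sorted(unmatched)}",
                      stacklevel=2)
    rows = []
    for lk in links:
        key = (lk.pa_from, lk.pa_to)
        try:
            sub = keyed.loc[[key]]
        except KeyError:
            continue
        counts = sub["sightings"].to_numpy(dtype=float)
        active = bool((counts >= 1).any())
        seasons = (
            sorted(set(sub["season"]) - {"-", ""}) if "season" in sub.columns and active else []
        )
        rows.append(
            {
                "pa_from": lk.pa_from,
                "pa_to": lk.pa_to,
                "n_respondents": counts.size,
                "sightings_mean": float(counts.mean()),
                "sightings_sd": float(counts.std(ddof=1)) if counts.size > 1 else 0.0,
                "seasons": "; ".join(seasons) if seasons else "-",
                "status": "active" if active else "inactive",
            }
        )
    return pd.DataFrame(rows)
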