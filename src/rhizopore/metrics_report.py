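"""Aggregation and comparative summaries across samples, days and textures.

Emits the tidy long-format tables an external statistics package (mixed
models, REML, ...) would consume; no model fitting happens here.  The two
headline comparisons of the protocol are computed directly:

* surface-vs-bulk porosity contrast per sample and day (signed difference in
  percentage points, plus the ratio), tracing how the rhizosphere converges
  to or diverges from the bulk soil over time;
* percent change of a metric between an early and a late day, with the
  convention ``(late - early) / early * 100``.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "percent_change",
    "porosity_contrast",
    "surface_bulk_contrast",
    "temporal_summary",
    "build_study_table",
]


def percent_change(early: float, late: float) -> float:
    """(late - early) / early * 100; NaN when the early value is not positive."""
    if early is None or not np.isfinite(early) or early <= 0:
        return float("nan")
    return (late - early) / early * 100.0


def porosity_contrast(surface, bulk):
    """Signed surface-minus-bulk difference and ratio, in the units given.

    Feed porosities in percent to get the difference in percentage points.
    """
    return surface - bulk, surface / bulk if bulk else float("nan")


def surface_bulk_contrast(named_table: pd.DataFrame) -> pd.DataFrame:
    """Per (sample, day): root-surface minus bulk-soil porosity.

    Expects the named-region porosity table (rows ``root_surface`` and
    ``bulk_soil``, porosity as a fraction).  Returns the contrast in
    percentage points and the porosity ratio; a missing region yields a null
    row with a warning.
    """
    rows = []
    for (sample, day), grp in named_table.groupby(["sample", "day"], sort=True):
        vals = grp.set_index("region")["porosity"]
        if "root_surface" not in vals.index or "bulk_soil" not in vals.index:
            import warnings
            warnings.warn(f"sample {sample} day {day}: named region missing",
                          stacklevel=2)
            rows.append({"sample": sample, "day": day,
                         "contrast_points": np.nan, "ratio": np.nan})
            continue
        diff, ratio = porosity_contrast(100.0 * vals["root_surface"],
                                        100.0 * vals["bulk_soil"])
        rows.append({"sample": sample, "day": day,
                     "contrast_points": diff, "ratio": ratio})
    return pd.DataFrame(rows, columns=["sample", "day", "contrast_points", "ratio"])


def temporal_summary(study_table: pd.DataFrame,
                     group_cols=("texture", "region", "metric", "day"),
                     value_col: str = "value") -> pd.DataFrame:
    """Replicate mean, standard error and n per texture x region x metric x day.

    The standard error is sd / sqrt(n) with the usual n-1 denominator in the
    sd; a single replicate yields a mean and a null s.e.
    """
    group_cols = [c for c in group_cols if c in study_table.columns]
    out = (
        study_table.groupby(group_cols, sort=True)[value_col]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    out["se"] = np.where(out["n"] >= 2, out["sd"] / np.sqrt(out["n"]), np.nan)
    return out.drop(columns="sd")


def build_study_table(region_tables: list[pd.DataFrame],
                      metadata: list[dict] | None = None) -> pd.DataFrame:
    """Stack per-run region tables into one long study table.

    ``metadata`` entries (one dict per table, e.g. ``{"texture": "sand"}``)
    are broadcast onto the corresponding rows.  The uniqueness of
    (sample, day, region, mode) rows is enforced.
    """
    frames = []
    for i, tab in enumerate(region_tables):
        tab = tab.copy()
        if metadata is not None:
            for k, v in metadata[i].items():
                tab[k] = v
        frames.append(tab)
    out = pd.concat(frames, ignore_index=True)
    key = [c for c in ("sample", "day", "region", "mode") if c in out.columns]
    if out.duplicated(subset=key).any():
        raise ValueError("duplicate (sample, day, region, mode) rows in study table")
    return out
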