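"""ROI-based quantification: box-plot-grade summary statistics of a contrast
within an organ mask, age-group comparisons, and the organ × contrast × group
summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .volumes import ContrastVolume, ROIMask

__all__ = ["RegionStats", "GroupComparison", "roi_stats", "compare_groups",
           "summary_table"]

#: fixed CSV header for RegionStats tables
STATS_COLUMNS = ["organ_label", "contrast_kind", "group_id", "n_voxels",
                 "mean", "sd", "median", "q25", "q75",
                 "whisker_low", "whisker_high", "n_outliers"]


@dataclass(frozen=True)
class RegionStats:
    """Summary of one contrast within one organ mask.

    Quartiles use linear interpolation between order statistics; whiskers are
    the most extreme data points within 1.5·IQR of the quartiles (the common
    box-plot convention) and ``n_outliers`` counts points beyond them.
    """

    n_voxels: int
    mean: float
    sd: float
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    n_outliers: int
    contrast_kind: str
    organ_label: str
    group_id: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class GroupComparison:
    """Relative change of a contrast between two groups of animals."""

    organ_label: str
    contrast_kind: str
    value_young: float
    value_old: float
    percent_change: float

    def to_dict(self) -> dict:
        return asdict(self)


def roi_stats(volume: ContrastVolume, mask: ROIMask,
              group_id: str = "") -> RegionStats:
    """Box-plot statistics of the contrast over the valid voxels of a mask."""
    if mask.mask.shape != volume.shape:
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match volume shape "
            f"{volume.shape} ({mask.organ_label}/{volume.kind})")
    sel = mask.mask & volume.valid_mask
    values = volume.data[sel]
    if values.size == 0:
        raise ValueError(
            f"no valid voxels for organ {mask.organ_label!r} in the "
            f"{volume.kind} volume")
    q25, med, q75 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    iqr = q75 - q25
    lo_fence = q25 - 1.5 * iqr
    hi_fence = q75 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return RegionStats(
        n_voxels=int(values.size),
        mean=float(values.mean()),
        sd=float(values.std(ddof=0)),
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        n_outliers=int(values.size - inside.size),
        contrast_kind=volume.kind,
        organ_label=mask.organ_label,
        group_id=group_id,
    )


def compare_groups(young: RegionStats, old: RegionStats,
                   statistic: str = "mean") -> GroupComparison:
    """Signed percent change of a contrast from the younger to the older
    group, relative to the younger group."""
    if young.organ_label != old.organ_label:
        raise ValueError(
            f"organ mismatch: {young.organ_label!r} vs {old.organ_label!r}")
    if young.contrast_kind != old.contrast_kind:
        raise ValueError(
            f"contrast mismatch: {young.contrast_kind!r} vs {old.contrast_kind!r}")
    vy = float(getattr(young, statistic))
    vo = float(getattr(old, statistic))
    if vy == 0:
        raise ValueError("younger-group value is zero; percent change undefined")
    change = round(100.0 * (vo - vy) / vy, 1)
    return GroupComparison(organ_label=young.organ_label,
                           contrast_kind=young.contrast_kind,
                           value_young=vy, value_old=vo,
                           percent_change=change)


def stats_frame(stats: list[RegionStats]) -> pd.DataFrame:
    """Long-format table of RegionStats rows with the fixed column order."""
    rows = [s.to_dict() for s in stats]
    return pd.DataFrame(rows, columns=STATS_COLUMNS)


def summary_table(stats: list[RegionStats]) -> pd.DataFrame:
    """Wide mean ± sd summary: one row per organ, attenuation then
    birefringence columns for each group (younger group first)."""
    seen = set()
    for s in stats:
        key = (s.organ_label, s.contrast_kind, s.group_id)
        if key in seen:
            raise ValueError(f"duplicate (organ, contrast, group) entry {key}")
        seen.add(key)

    groups = sorted({s.group_id for s in stats})
    columns = ["organ"]
    for g in groups:
        for kind in ("attenuation", "birefringence"):
            columns += [f"{g}_{kind}_mean", f"{g}_{kind}_sd"]
    if not stats:
        return pd.DataFrame(columns=columns)

    organs = list(dict.fromkeys(s.organ_label for s in stats))
    by_key = {(s.organ_label, s.contrast_kind, s.group_id): s for s in stats}
    rows = []
    for organ in organs:
        row: dict = {"organ": organ}
        for g in groups:
            for kind in ("attenuation", "birefringence"):
                s = by_key.get((organ, kind, g))
                row[f"{g}_{kind}_mean"] = s.mean if s else np.nan
                row[f"{g}_{kind}_sd"] = s.sd if s else np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)
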