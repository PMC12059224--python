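"""Screen-level aggregation and derived analyses.

Takes per-tile quantification tables, places them on the gradient grids,
and produces the screen's derived results:

* heatmaps of replicate-mean readouts over the datapoint or tile grid;
* ranked scatter data with top/bottom decile splits and their KS test;
* cell doubling times from the 24 h and 72 h densities;
* MCF10a-vs-MCF7 region-of-interest (ROI) selection: windows furthest from
  the identity diagonal with an individually significant difference;
* flat-vs-topography grouping (the flat S-W sample against the three
  topography-bearing samples);
* screen-vs-translation comparison for selected ROIs, including the
  low-vs-high seeding-density grouping;
* the MCF7 cluster-vs-single-cell density table.

All tabular interfaces are tidy pandas DataFrames; missing windows stay
missing (NaN) and are excluded pairwise from comparisons, never imputed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gradients import DOGLayout, GridWindow, make_datapoint_grid, make_tile_grid, material_at
from .stats import KSResult, ks_two_sample
from scipy import stats as _scipy_stats

__all__ = [
    "MATERIAL_COLUMNS",
    "Heatmap",
    "DecileSplit",
    "DoublingTime",
    "ROIRecord",
    "GroupComparison",
    "aggregate",
    "decile_split",
    "doubling_time",
    "identify_rois",
    "group_flat_vs_topo",
    "compare_screen_vs_translation",
    "cluster_vs_single_table",
]

MATERIAL_COLUMNS = ["wavelength_um", "amplitude_nm", "stiffness_mpa", "wca_deg"]

#: per-tile metrics carried through aggregation
METRIC_COLUMNS = [
    "cell_density_per_mm2",
    "area_per_cell_um2",
    "ki67_pct",
    "cluster_density_per_mm2",
    "single_density_per_mm2",
    "mean_cluster_area_um2",
]

TOPO_LAYOUTS = ("T-S", "T-W", "T-S|W")


@dataclass
class Heatmap:
    """Replicate-mean values of one metric on one grid (NaN = missing)."""

    layout: str
    metric: str
    values: np.ndarray  # (Ku, Kv)
    n: np.ndarray  # replicates contributing per cell

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values)


def aggregate(
    quant: pd.DataFrame,
    layout: DOGLayout,
    grid_kind: str = "datapoint",
) -> tuple[pd.DataFrame, dict[str, Heatmap]]:
    """Aggregate a per-tile quantification table onto a sampling grid.

    ``quant`` is a long table with a ``replicate`` column plus the per-tile
    columns produced by quantification (``tile_i``/``tile_j`` index the tile
    grid).  For the datapoint grid, tiles whose centers fall inside a 2 x 2
    mm window are averaged into it (tiles in the gaps between windows are
    unused); for the tile grid the mapping is the identity.  Window metrics
    are then averaged across replicates.

    Returns the per-window records (one row per window x replicate, with
    material properties evaluated at the window center) and one
    :class:`Heatmap` per metric.
    """
    if "replicate" not in quant.columns:
        quant = quant.assign(replicate=1)
    reps = sorted(quant["replicate"].unique())
    tile_grid = make_tile_grid(layout)
    tile_by_index = {g.index: g for g in tile_grid}

    if grid_kind == "datapoint":
        windows = make_datapoint_grid(layout)
        ku = layout.axis_u.divisions
        kv = layout.axis_v.divisions

        def window_of(tile: GridWindow) -> tuple[int, int] | None:
            for w in windows:
                if w.contains(*tile.center_mm):
                    return w.index
            return None

    elif grid_kind == "tile":
        windows = tile_grid
        ku, kv = (max(g.index[0] for g in windows) + 1,
                  max(g.index[1] for g in windows) + 1)

        def window_of(tile: GridWindow) -> tuple[int, int]:
            return tile.index

    else:
        raise ValueError(f"unknown grid kind {grid_kind!r}")

    window_by_index = {w.index: w for w in windows}
    records = []
    for rep, group in quant.groupby("replicate"):
        binned: dict[tuple[int, int], list[pd.Series]] = {}
        for _, row in group.iterrows():
            tile = tile_by_index.get((int(row["tile_i"]), int(row["tile_j"])))
            if tile is None:
                raise ValueError(
                    f"tile {(row['tile_i'], row['tile_j'])} outside the grid"
                )
            widx = window_of(tile)
            if widx is not None:
                binned.setdefault(widx, []).append(row)
        for widx, rows in binned.items():
            w = window_by_index[widx]
            cu = min(max(w.center_mm[0], 0.0), layout.side_mm)
            cv = min(max(w.center_mm[1], 0.0), layout.side_mm)
            mat = material_at(layout, cu, cv)
            rec = {
                "layout": layout.name,
                "replicate": rep,
                "grid": grid_kind,
                "i": widx[0],
                "j": widx[1],
                "wavelength_um": mat.wavelength_um,
                "amplitude_nm": mat.amplitude_nm,
                "stiffness_mpa": mat.stiffness_mpa,
                "wca_deg": mat.wca_deg,
            }
            sub = pd.DataFrame(rows)
            for metric in METRIC_COLUMNS:
                if metric in sub.columns:
                    rec[metric] = sub[metric].astype(float).mean()
            records.append(rec)
    records = pd.DataFrame(records)

    heatmaps = {}
    for metric in METRIC_COLUMNS:
        if metric not in records.columns:
            continue
        values = np.full((ku, kv), np.nan)
        counts = np.zeros((ku, kv), dtype=int)
        cell = records.groupby(["i", "j"])[metric]
        for (i, j), mean in cell.mean().items():
            values[i, j] = mean
            counts[i, j] = cell.count()[(i, j)]
        heatmaps[metric] = Heatmap(layout.name, metric, values, counts)
    return records, heatmaps


# ---------------------------------------------------------------------------
# ranked scatter / deciles


@dataclass
class DecileSplit:
    metric: str
    values: np.ndarray  # sorted ascending
    low: np.ndarray  # bottom fraction
    high: np.ndarray  # top fraction
    ks: KSResult


def decile_split(values, fraction: float = 0.1, metric: str = "") -> DecileSplit:
    """Bottom and top ``fraction`` of the ranked values, with their KS test."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 10:
        raise ValueError("need at least 10 values for a decile split")
    values = np.sort(values)
    k = int(math.floor(fraction * values.size))
    low, high = values[:k], values[-k:]
    return DecileSplit(metric, values, low, high, ks_two_sample(low, high))


# ---------------------------------------------------------------------------
# doubling time


@dataclass(frozen=True)
class DoublingTime:
    hours: float | None
    flag: str  # ok | decline | no-change | undefined

    @property
    def missing(self) -> bool:
        return self.hours is None


def doubling_time(
    x_begin: float, x_end: float, t_begin_h: float = 24.0, t_end_h: float = 72.0
) -> DoublingTime:
    """Cell doubling time (T_e - T_b) ln 2 / ln(X_e / X_b) in hours.

    A density decline gives a negative value (flag ``decline``); equal
    densities give a missing value (``no-change``, division by ln 1);
    nonpositive densities are undefined.
    """
    if x_begin is None or x_end is None or x_begin <= 0 or x_end <= 0:
        return DoublingTime(None, "undefined")
    if x_end == x_begin:
        return DoublingTime(None, "no-change")
    hours = (t_end_h - t_begin_h) * math.log(2.0) / math.log(x_end / x_begin)
    return DoublingTime(hours, "decline" if hours < 0 else "ok")


# ---------------------------------------------------------------------------
# ROI selection


@dataclass
class ROIRecord:
    id: str  # Pos1..PosK / Neg1..NegK
    label: str  # positive | negative
    window: tuple[int, int]
    mean_mcf10a_pct: float
    mean_mcf7_pct: float
    diag_distance: float
    p_value: float
    material: dict = field(default_factory=dict)


def identify_rois(
    paired: pd.DataFrame,
    k: int = 3,
    alpha: float = 0.05,
    test: str = "ks",
) -> list[ROIRecord]:
    """Regions of interest where the two cell types diverge most.

    ``paired`` is a long table with columns ``window`` (hashable id or
    (i, j)), ``cell_type`` (MCF10a / MCF7), ``value`` (the readout, e.g.
    Ki-67 %), and optionally material columns.  Per window, the distance
    from the identity diagonal is ``(mean_MCF10a - mean_MCF7)/sqrt(2)`` and
    a two-sample test across the per-window observations (replicates, or
    tiles x replicates) gives the significance.  Windows with p < alpha are
    ranked by |distance|; the top ``k`` on each side become PosN/NegN ROIs
    (ties broken by smaller p, then window index).  A side with fewer than
    ``k`` significant windows returns fewer ROIs, with a warning.
    """
    required = {"window", "cell_type", "value"}
    if not required <= set(paired.columns):
        raise ValueError(f"paired table needs columns {sorted(required)}")
    if test not in ("ks", "t"):
        raise ValueError("test must be 'ks' or 't'")

    mat_cols = [c for c in MATERIAL_COLUMNS if c in paired.columns]
    candidates = []
    for window, grp in paired.groupby("window", sort=True):
        a = grp.loc[grp["cell_type"] == "MCF10a", "value"].dropna().to_numpy()
        b = grp.loc[grp["cell_type"] == "MCF7", "value"].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            continue
        diag = (a.mean() - b.mean()) / math.sqrt(2.0)
        if test == "ks":
            p = ks_two_sample(a, b).p_value
        else:
            p = float(_scipy_stats.ttest_ind(a, b, equal_var=False).pvalue)
        material = (
            {c: float(grp[c].iloc[0]) for c in mat_cols} if mat_cols else {}
        )
        candidates.append((window, a.mean(), b.mean(), diag, p, material))

    rois: list[ROIRecord] = []
    for label, sign in (("positive", 1.0), ("negative", -1.0)):
        side = [c for c in candidates if c[4] < alpha and sign * c[3] > 0]
        side.sort(key=lambda c: (-abs(c[3]), c[4], str(c[0])))
        if len(side) < k:
            warnings.warn(
                f"only {len(side)} significant {label} windows (requested {k})"
            )
        prefix = "Pos" if label == "positive" else "Neg"
        for rank, (window, m10, m7, diag, p, material) in enumerate(side[:k], 1):
            rois.append(
                ROIRecord(
                    id=f"{prefix}{rank}",
                    label=label,
                    window=window if isinstance(window, tuple) else (window,),
                    mean_mcf10a_pct=float(m10),
                    mean_mcf7_pct=float(m7),
                    diag_distance=float(diag),
                    p_value=float(p),
                    material=material,
                )
            )
    return rois


def rois_to_frame(rois: list[ROIRecord]) -> pd.DataFrame:
    rows = []
    for r in rois:
        row = {
            "id": r.id,
            "label": r.label,
            "window": str(r.window),
            "mcf10a_pct": r.mean_mcf10a_pct,
            "mcf7_pct": r.mean_mcf7_pct,
            "diag_distance": r.diag_distance,
            "p_value": r.p_value,
        }
        row.update(r.material)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# flat vs topography grouping


@dataclass
class GroupComparison:
    metric: str
    flat_mean: float
    flat_sd: float
    n_flat: int
    topo_mean: float
    topo_sd: float
    n_topo: int
    ks: KSResult


def group_flat_vs_topo(records: pd.DataFrame, metric: str) -> GroupComparison:
    """Group all datapoints from the flat S-W sample against all datapoints
    from the topography-bearing samples (T-S, T-W, T-S|W), with a KS test."""
    if metric not in records.columns:
        raise ValueError(f"metric {metric!r} not in records")
    flat = records.loc[records["layout"] == "S-W", metric].dropna().to_numpy()
    topo = records.loc[
        records["layout"].isin(TOPO_LAYOUTS), metric
    ].dropna().to_numpy()
    if flat.size == 0 or topo.size == 0:
        raise ValueError("both the flat and the topography group must be non-empty")
    return GroupComparison(
        metric=metric,
        flat_mean=float(flat.mean()),
        flat_sd=float(flat.std(ddof=1)) if flat.size > 1 else 0.0,
        n_flat=int(flat.size),
        topo_mean=float(topo.mean()),
        topo_sd=float(topo.std(ddof=1)) if topo.size > 1 else 0.0,
        n_topo=int(topo.size),
        ks=ks_two_sample(flat, topo),
    )


# ---------------------------------------------------------------------------
# screen vs translation


def compare_screen_vs_translation(
    screen: pd.DataFrame,
    translation: pd.DataFrame,
    value_columns: tuple[str, ...] = ("mcf10a_pct", "mcf7_pct"),
) -> tuple[pd.DataFrame, dict[str, KSResult] | None]:
    """Per-ROI shifts between the screen and translated homogeneous samples.

    Both tables are indexed by ``id`` (ROI ids must match) and carry paired
    readout columns (Ki-67 % and optionally densities) for both cell types.
    The shift table lists per-ROI deltas plus a ``retained`` flag: whether
    the ROI stays on the same side of the MCF10a = MCF7 diagonal.  When the
    translation table has a ``seeding`` column (low / high), the grouped
    low-vs-high comparison per readout column is returned as well.
    """
    screen = screen.set_index("id") if "id" in screen.columns else screen
    translation = (
        translation.set_index("id") if "id" in translation.columns else translation
    )
    unmatched = sorted(set(screen.index) ^ set(translation.index.unique()))
    if unmatched:
        raise ValueError(f"unmatched ROI ids: {unmatched}")

    # collapse a seeding-resolved translation table to per-ROI means for deltas
    trans_mean = (
        translation.groupby(level=0)[list(value_columns)].mean()
        if "seeding" in translation.columns
        else translation[list(value_columns)]
    )
    rows = []
    for roi in screen.index:
        row = {"id": roi}
        for col in value_columns:
            row[f"delta_{col}"] = float(trans_mean.loc[roi, col] - screen.loc[roi, col])
        if {"mcf10a_pct", "mcf7_pct"} <= set(value_columns):
            side_screen = np.sign(
                screen.loc[roi, "mcf10a_pct"] - screen.loc[roi, "mcf7_pct"]
            )
            side_trans = np.sign(
                trans_mean.loc[roi, "mcf10a_pct"] - trans_mean.loc[roi, "mcf7_pct"]
            )
            row["retained"] = bool(side_screen == side_trans)
        rows.append(row)
    shifts = pd.DataFrame(rows).set_index("id")

    seeding_tests = None
    if "seeding" in translation.columns:
        seeding_tests = {}
        low = translation[translation["seeding"] == "low"]
        high = translation[translation["seeding"] == "high"]
        for col in value_columns:
            a = low[col].dropna().to_numpy()
            b = high[col].dropna().to_numpy()
            if a.size and b.size:
                seeding_tests[col] = ks_two_sample(a, b)
    return shifts, seeding_tests


# ---------------------------------------------------------------------------
# MCF7 clusters


def cluster_vs_single_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-window cluster vs single-cell density table for scatter export.

    Expects MCF7 records carrying cluster metrics; MCF10a input (no
    clusters by design) yields an empty table with a warning.
    """
    if "cell_type" in records.columns:
        mcf7 = records[records["cell_type"] == "MCF7"]
        if mcf7.empty:
            warnings.warn("no MCF7 records: cluster table is empty")
            return pd.DataFrame(
                columns=["single_density_per_mm2", "cluster_density_per_mm2",
                         "mean_cluster_area_um2", *MATERIAL_COLUMNS]
            )
        records = mcf7
    cols = ["single_density_per_mm2", "cluster_density_per_mm2",
            "mean_cluster_area_um2"]
    keep = [c for c in cols + MATERIAL_COLUMNS + ["layout", "i", "j"]
            if c in records.columns]
    table = records[keep].dropna(subset=["cluster_density_per_mm2"])
    return table.reset_index(drop=True)
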