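"""Synthetic DOG screens with planted, material-dependent ground truth.

The original screen's raw images are not public, so every downstream stage
is exercised on simulated data instead.  The generator plants biology whose
magnitudes match the published screen:

* per-cell Ki-67 positivity probability: 0.73 (MCF10a) / 0.78 (MCF7) on
  flat surfaces at 72 h, 0.47 / 0.44 on wrinkled topography;
* single-cell placement: homogeneous Poisson within each tile, with an
  expected density modulated by a quadratic wettability response peaking at
  a water contact angle of 35 deg;
* MCF7 aggregates: a Thomas cluster process (Poisson parents, Gaussian-
  scattered offspring) whose parent rate is 9.1 /mm^2 on flat surfaces and
  3.6 /mm^2 on topography; MCF10a cells never cluster;
* single-cell spread area: lognormal with median 800 um^2, safely below the
  2000 um^2 two-or-more-cells threshold.

Realized per-cell tables (:class:`TileTruth`) are rendered into noisy
3-channel 16-bit rasters (nuclei / cytoskeleton / proliferation) with a
Gaussian PSF, a smooth background, Poisson shot noise and Gaussian read
noise.  Everything is driven by a single seed through named
``numpy.random.SeedSequence`` substreams, so identical seeds give
byte-identical tables and rasters.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .gradients import (
    Axis,
    AxisCalibration,
    DOGLayout,
    GridWindow,
    LAYOUT_NAMES,
    MaterialPoint,
    fit_axis_calibration,
    make_tile_grid,
    material_at,
    TILE_WIDTH_UM,
    TILE_HEIGHT_UM,
    TILE_COLS,
    TILE_ROWS,
)

__all__ = [
    "TABLE1",
    "ResponseConfig",
    "default_response",
    "NoiseConfig",
    "TileTruth",
    "TileRaster",
    "ScreenConfig",
    "generate_calibrations",
    "build_layout",
    "plant_truth",
    "render_tile",
    "generate_screen",
    "TRUTH_COLUMNS",
]

# ---------------------------------------------------------------------------
# published endpoint values of each gradient (mean, sd at the weak- and
# strong-oxidation ends of the axis), used as fixture defaults

_END = tuple[tuple[float, float], tuple[float, float]]


def _endpoints(lo_mean, lo_sd, hi_mean, hi_sd) -> _END:
    return ((lo_mean, lo_sd), (hi_mean, hi_sd))


#: per-layout, per-parameter endpoint (mean, sd) pairs along the relevant axis,
#: oriented so position 0 is the weak-oxidation corner
TABLE1: dict[str, dict[str, _END]] = {
    "S-W": {
        "stiffness": _endpoints(12.6, 5.7, 478.9, 31.5),
        "wca": _endpoints(76.9, 6.9, 19.3, 5.6),
    },
    "T-S": {
        "wavelength": _endpoints(1.3, 0.03, 9.9, 0.2),
        "amplitude": _endpoints(74.5, 36.0, 1024.0, 134.0),
        "stiffness": _endpoints(12.6, 5.7, 478.9, 31.5),
    },
    "T-W": {
        "wavelength": _endpoints(1.3, 0.03, 9.9, 0.2),
        "amplitude": _endpoints(74.5, 36.0, 1024.0, 134.0),
        "stiffness": _endpoints(13.0, 3.1, 23.9, 2.3),
        "wca": _endpoints(92.7, 1.8, 10.5, 1.7),
    },
    "T-S|W": {
        "wavelength": _endpoints(1.3, 0.03, 9.9, 0.2),
        "amplitude": _endpoints(74.5, 36.0, 1024.0, 134.0),
        "stiffness": _endpoints(12.6, 5.7, 478.9, 31.5),
        "wca": _endpoints(85.3, 0.8, 10.9, 2.1),
    },
}

#: WCA of the fully hydrophilic T-S sample ("<10 deg"); modeled as fixed
TS_FIXED_WCA = 10.0

#: measurement positions along an axis (equally spaced over the 20 mm side)
N_POSITIONS = {"wavelength": 11, "amplitude": 11, "stiffness": 6, "wca": 5}

#: which parameters sit on which axis, and the axis kinds, per layout
_LAYOUT_AXES: dict[str, tuple[tuple[str, tuple[str, ...]], tuple[str, tuple[str, ...]], dict[str, float]]] = {
    # name: (u axis (kind, params), v axis (kind, params), fixed values)
    "S-W": (("stiffness", ("stiffness",)), ("wettability", ("wca",)),
            {"wavelength": 0.0, "amplitude": 0.0}),
    "T-S": (("topography", ("wavelength", "amplitude")),
            ("stiffness", ("stiffness",)), {"wca": TS_FIXED_WCA}),
    # T-W's stiffness range is a mild side effect of the wettability
    # treatment; it rides the v axis without changing the 5-division rule
    "T-W": (("topography", ("wavelength", "amplitude")),
            ("wettability", ("wca", "stiffness")), {}),
    "T-S|W": (("topography", ("wavelength", "amplitude")),
              ("stiffness|wettability", ("stiffness", "wca")), {}),
}

CALIBRATION_COLUMNS = ["parameter", "position_mm", "mean", "sd", "n"]


def generate_calibrations(
    layout_name: str,
    seed: int | np.random.SeedSequence = 0,
    jitter_scale: float = 0.3,
    side_mm: float = 20.0,
) -> dict[str, pd.DataFrame]:
    """Synthetic calibration tables for every varying parameter of a layout.

    Endpoint means and SDs equal the published gradient ranges; interior
    positions interpolate linearly, with seeded Gaussian jitter of
    ``jitter_scale`` times the local SD added to interior means
    (``jitter_scale=0`` gives exactly linear tables).  Positions are equally
    spaced over the sample side, using the published number of measurement
    points per parameter (11 topography, 6 stiffness, 5 WCA).
    """
    if layout_name not in LAYOUT_NAMES:
        raise ValueError(f"unknown layout {layout_name!r}")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    tables: dict[str, pd.DataFrame] = {}
    for param, ((mu0, sd0), (mu1, sd1)) in TABLE1[layout_name].items():
        # independent, order-stable substream per parameter
        rng = np.random.default_rng(
            np.random.SeedSequence(
                entropy=ss.entropy,
                spawn_key=(zlib.crc32(f"{layout_name}/{param}".encode()),),
            )
        )
        k = N_POSITIONS[param]
        pos = np.linspace(0.0, side_mm, k)
        frac = pos / side_mm
        mean = mu0 + (mu1 - mu0) * frac
        sd = sd0 + (sd1 - sd0) * frac
        jitter = rng.normal(0.0, 1.0, size=k) * sd * jitter_scale
        jitter[0] = jitter[-1] = 0.0  # endpoints stay on the published values
        tables[param] = pd.DataFrame(
            {
                "parameter": param,
                "position_mm": pos,
                "mean": mean + jitter,
                "sd": sd,
                "n": 3,
            }
        )
    return tables


def build_layout(
    name: str,
    calibration_tables: dict[str, pd.DataFrame] | None = None,
    seed: int | np.random.SeedSequence = 0,
    jitter_scale: float = 0.3,
    fit_order: int = 1,
) -> DOGLayout:
    """Construct a DOGLayout with trendlines fitted to calibration tables.

    When no tables are passed they are generated with
    :func:`generate_calibrations`.
    """
    if calibration_tables is None:
        calibration_tables = generate_calibrations(name, seed, jitter_scale)
    (u_kind, u_params), (v_kind, v_params), fixed = _LAYOUT_AXES[name]

    def fit(param: str) -> AxisCalibration:
        t = calibration_tables[param]
        return fit_axis_calibration(
            param, t["position_mm"], t["mean"], t["sd"], t["n"], fit_order
        )

    return DOGLayout(
        name=name,
        axis_u=Axis(u_kind, {p: fit(p) for p in u_params}),
        axis_v=Axis(v_kind, {p: fit(p) for p in v_params}),
        fixed_values=dict(fixed),
    )


# ---------------------------------------------------------------------------
# planted biological response


@dataclass
class ResponseConfig:
    """Planted cell behavior for one (cell type, timepoint) condition.

    ``ki67_prob_flat`` / ``ki67_prob_topo`` are per-cell Bernoulli
    positivity probabilities on flat vs wrinkled surfaces.  The expected
    single-cell density is ``density_base_per_mm2`` times a quadratic
    wettability factor ``1 - wca_curvature * (wca - wca_opt)^2`` clipped to
    [0.2, 1].  Cluster parents (MCF7 only) follow a Thomas process at the
    flat/topography parent rate with 2 + Poisson(offspring_mean - 2)
    offspring (a cluster has at least two cells) scattered isotropically
    with SD ``offspring_sigma_um``.
    """

    cell_type: str  # MCF10a | MCF7
    timepoint_h: int  # 24 | 72
    ki67_prob_flat: float
    ki67_prob_topo: float
    density_base_per_mm2: float
    wca_opt_deg: float = 35.0
    wca_curvature: float = 2e-4  # per deg^2
    cluster_rate_flat_per_mm2: float = 0.0
    cluster_rate_topo_per_mm2: float = 0.0
    offspring_mean: float = 5.0
    offspring_sigma_um: float = 12.0
    area_lognormal_mu_um2: float = float(np.log(800.0))
    area_lognormal_sigma: float = 0.30
    nucleus_r_min_um: float = 4.0
    nucleus_r_max_um: float = 6.0
    #: hard-core distance between single cells (um); a planted "single" is
    #: by definition not in contact with another cell, so singles repel at
    #: roughly one cell diameter
    single_min_dist_um: float = 34.0
    #: excluded-volume distance between cells of one aggregate (um): piled
    #: cells tile together instead of superposing, so the clump footprint
    #: grows with cell count rather than saturating
    offspring_min_dist_um: float = 26.0

    def __post_init__(self):
        if self.cell_type not in ("MCF10a", "MCF7"):
            raise ValueError(f"unknown cell type {self.cell_type!r}")
        for p in (self.ki67_prob_flat, self.ki67_prob_topo):
            if not 0 <= p <= 1:
                raise ValueError("Ki-67 probabilities must lie in [0, 1]")
        if min(
            self.density_base_per_mm2,
            self.cluster_rate_flat_per_mm2,
            self.cluster_rate_topo_per_mm2,
        ) < 0:
            raise ValueError("rates must be >= 0")
        if self.cell_type == "MCF10a" and (
            self.cluster_rate_flat_per_mm2 or self.cluster_rate_topo_per_mm2
        ):
            raise ValueError("MCF10a cells do not form clusters")

    def ki67_prob(self, material: MaterialPoint) -> float:
        return self.ki67_prob_flat if material.is_flat else self.ki67_prob_topo

    def cluster_rate(self, material: MaterialPoint) -> float:
        return (
            self.cluster_rate_flat_per_mm2
            if material.is_flat
            else self.cluster_rate_topo_per_mm2
        )

    def density_factor(self, wca_deg: float) -> float:
        return float(
            np.clip(1.0 - self.wca_curvature * (wca_deg - self.wca_opt_deg) ** 2,
                    0.2, 1.0)
        )

    def expected_density(self, material: MaterialPoint) -> float:
        return self.density_base_per_mm2 * self.density_factor(material.wca_deg)


#: published flat/topography Ki-67 means at 72 h; 24 h values are generator
#: choices reflecting the lower, cell-type-dependent early proliferation
_RESPONSES = {
    ("MCF10a", 72): dict(ki67_prob_flat=0.73, ki67_prob_topo=0.47,
                         density_base_per_mm2=100.0),
    ("MCF7", 72): dict(ki67_prob_flat=0.78, ki67_prob_topo=0.44,
                       density_base_per_mm2=100.0,
                       cluster_rate_flat_per_mm2=9.1,
                       cluster_rate_topo_per_mm2=3.6),
    ("MCF10a", 24): dict(ki67_prob_flat=0.35, ki67_prob_topo=0.25,
                         density_base_per_mm2=45.0),
    ("MCF7", 24): dict(ki67_prob_flat=0.50, ki67_prob_topo=0.35,
                       density_base_per_mm2=45.0,
                       cluster_rate_flat_per_mm2=3.0,
                       cluster_rate_topo_per_mm2=1.2),
}


def default_response(cell_type: str, timepoint_h: int) -> ResponseConfig:
    """Default planted response for a (cell type, timepoint) condition."""
    key = (cell_type, int(timepoint_h))
    if key not in _RESPONSES:
        raise ValueError(f"no default response for {key}")
    return ResponseConfig(cell_type=cell_type, timepoint_h=int(timepoint_h),
                          **_RESPONSES[key])


# ---------------------------------------------------------------------------
# truth realization

TRUTH_COLUMNS = [
    "tile_i", "tile_j", "cell_id", "x_um", "y_um",
    "nucleus_r_um", "cyto_area_um2", "ki67", "cluster_id",
]


@dataclass
class TileTruth:
    """Planted ground truth for one tile: expectations plus the realized
    per-cell table (positions in tile-local um)."""

    index: tuple[int, int]
    material: MaterialPoint
    expected_density: float
    expected_ki67_pct: float
    expected_cluster_density: float
    expected_single_density: float
    cells: pd.DataFrame  # TRUTH_COLUMNS

    def __post_init__(self):
        clustered = self.cells[self.cells["cluster_id"] >= 0]
        if len(clustered):
            sizes = clustered.groupby("cluster_id").size()
            if sizes.sum() != len(clustered):
                raise ValueError("cluster ids must partition clustered cells")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _realize_tile(
    window: GridWindow,
    material: MaterialPoint,
    response: ResponseConfig,
    rng: np.random.Generator,
) -> TileTruth:
    w_um = window.width_mm * 1000.0
    h_um = window.height_mm * 1000.0
    area_mm2 = window.area_mm2
    p = response.ki67_prob(material)
    density = response.expected_density(material)
    cluster_rate = response.cluster_rate(material)

    rows = []
    cell_id = 0

    def draw_cell(x, y, cluster_id):
        nonlocal cell_id
        rows.append(
            (
                window.index[0], window.index[1], cell_id, x, y,
                rng.uniform(response.nucleus_r_min_um, response.nucleus_r_max_um),
                float(rng.lognormal(response.area_lognormal_mu_um2,
                                    response.area_lognormal_sigma)),
                int(rng.random() < p),
                cluster_id,
            )
        )
        cell_id += 1

    # simple sequential inhibition: singles keep a hard-core distance from
    # each other (a cell in contact with another would be a cluster member,
    # not a single); after too many rejections a point is accepted anyway,
    # so the realized count stays Poisson
    n_single = rng.poisson(density * area_mm2)
    placed_x = np.empty(n_single)
    placed_y = np.empty(n_single)
    d2_min = response.single_min_dist_um**2
    for k in range(n_single):
        for _ in range(30):
            x, y = rng.uniform(0, w_um), rng.uniform(0, h_um)
            if k == 0 or np.min(
                (placed_x[:k] - x) ** 2 + (placed_y[:k] - y) ** 2
            ) >= d2_min:
                break
        placed_x[k], placed_y[k] = x, y
        draw_cell(x, y, -1)

    # Thomas-like process; a cluster is by definition two or more cells, so
    # the offspring count is 2 + Poisson(mean - 2) (mean preserved) rather
    # than a bare Poisson that could leave a parent with 0 or 1 cells
    n_parents = rng.poisson(cluster_rate * area_mm2)
    off_d2 = response.offspring_min_dist_um**2
    for parent in range(n_parents):
        px, py = rng.uniform(0, w_um), rng.uniform(0, h_um)
        n_off = 2 + rng.poisson(max(response.offspring_mean - 2.0, 0.0))
        ox, oy = np.empty(n_off), np.empty(n_off)
        for k in range(n_off):
            for _ in range(30):  # excluded volume within the clump
                dx, dy = rng.normal(0.0, response.offspring_sigma_um, size=2)
                if k == 0 or np.min(
                    (ox[:k] - (px + dx)) ** 2 + (oy[:k] - (py + dy)) ** 2
                ) >= off_d2:
                    break
            ox[k], oy[k] = px + dx, py + dy
            draw_cell(ox[k], oy[k], parent)

    cells = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    cells = cells.astype(
        {"tile_i": int, "tile_j": int, "cell_id": int, "ki67": int,
         "cluster_id": int}
    )
    return TileTruth(
        index=window.index,
        material=material,
        expected_density=density + cluster_rate * response.offspring_mean,
        expected_ki67_pct=100.0 * p,
        expected_cluster_density=cluster_rate,
        expected_single_density=density,
        cells=cells,
    )


def plant_truth(
    layout: DOGLayout,
    response: ResponseConfig,
    tile_grid: list[GridWindow],
    seed: int | np.random.SeedSequence = 0,
) -> list[TileTruth]:
    """Realize planted cells for every tile of a grid.

    Each tile gets the material at its center, the matching expected
    density/Ki-67 probability/cluster rate, and an independent substream of
    the seed (keyed by tile index, so subsetting the grid leaves per-tile
    realizations unchanged).
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    truths = []
    for window in tile_grid:
        cu, cv = window.center_mm
        cu = min(max(cu, 0.0), layout.side_mm)
        cv = min(max(cv, 0.0), layout.side_mm)
        material = material_at(layout, cu, cv)
        rng = np.random.default_rng(
            np.random.SeedSequence(
                entropy=ss.entropy,
                spawn_key=(1 + window.index[0], 1 + window.index[1]),
            )
        )
        truths.append(_realize_tile(window, material, response, rng))
    return truths


# ---------------------------------------------------------------------------
# rendering


@dataclass
class NoiseConfig:
    """Imaging model parameters (16-bit counts unless noted)."""

    background_offset: float = 2000.0
    background_gradient: float = 1000.0  # peak-to-peak of a smooth ramp
    nuclei_amp: float = 20000.0
    cyto_amp: float = 12000.0
    ki67_amp: float = 20000.0
    psf_sigma_um: float = 1.0
    read_sigma: float = 0.02 * 65535.0
    shot_noise: bool = True

    @classmethod
    def noiseless(cls) -> "NoiseConfig":
        """No background, PSF blur only, no noise: for exact-recovery tests."""
        return cls(background_offset=0.0, background_gradient=0.0,
                   read_sigma=0.0, shot_noise=False)


@dataclass
class TileRaster:
    """One rendered microscope field: 3 16-bit channels plus geometry."""

    nuclei: np.ndarray
    cytoskeleton: np.ndarray
    proliferation: np.ndarray
    pixel_size_um: float
    origin_mm: tuple[float, float]
    index: tuple[int, int] = (0, 0)

    def __post_init__(self):
        shapes = {self.nuclei.shape, self.cytoskeleton.shape,
                  self.proliferation.shape}
        if len(shapes) != 1:
            raise ValueError("all channels must share one shape")

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.nuclei.shape

    @property
    def channels(self) -> dict[str, np.ndarray]:
        return {
            "nuclei": self.nuclei,
            "cytoskeleton": self.cytoskeleton,
            "proliferation": self.proliferation,
        }


def _paint_disks(canvas: np.ndarray, xs, ys, radii_px, amp: float) -> None:
    """Max-composite anti-aliased disks onto a float canvas (local px coords)."""
    h, w = canvas.shape
    for x, y, r in zip(xs, ys, radii_px):
        x0, x1 = int(np.floor(x - r - 1)), int(np.ceil(x + r + 1))
        y0, y1 = int(np.floor(y - r - 1)), int(np.ceil(y + r + 1))
        if x1 < 0 or y1 < 0 or x0 >= w or y0 >= h:
            continue
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, w - 1), min(y1, h - 1)
        yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
        dist = np.sqrt((xx - x) ** 2 + (yy - y) ** 2)
        cover = np.clip(r + 0.5 - dist, 0.0, 1.0)  # soft 1-px edge
        patch = canvas[y0 : y1 + 1, x0 : x1 + 1]
        np.maximum(patch, amp * cover, out=patch)


def render_tile(
    truth: TileTruth,
    noise: NoiseConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    pixel_size_um: float = 0.85,
    tile_um: tuple[float, float] = (TILE_WIDTH_UM, TILE_HEIGHT_UM),
    origin_mm: tuple[float, float] | None = None,
) -> TileRaster:
    """Render a realized tile into a noisy 3-channel 16-bit raster.

    Nuclei are disks at the planted radius, cytoplasm disks carry the
    planted spread area (cluster members overlap into merged objects), and
    the proliferation channel shows only Ki-67-positive nuclei.  All
    channels are blurred with a Gaussian PSF, given a constant-plus-ramp
    background, Poisson shot noise and Gaussian read noise, then clipped to
    16 bits.  Cells falling outside the tile are cropped silently (they
    belong to neighboring tiles).
    """
    from scipy.ndimage import gaussian_filter

    noise = noise or NoiseConfig()
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng = np.random.default_rng(ss)
    w_px = int(round(tile_um[0] / pixel_size_um))
    h_px = int(round(tile_um[1] / pixel_size_um))
    shape = (h_px, w_px)

    cells = truth.cells
    xs = cells["x_um"].to_numpy() / pixel_size_um
    ys = cells["y_um"].to_numpy() / pixel_size_um
    nuc_r = cells["nucleus_r_um"].to_numpy() / pixel_size_um
    cyto_r = np.sqrt(cells["cyto_area_um2"].to_numpy() / np.pi) / pixel_size_um
    pos = cells["ki67"].to_numpy().astype(bool)

    nuclei = np.zeros(shape, dtype=float)
    cyto = np.zeros(shape, dtype=float)
    ki67 = np.zeros(shape, dtype=float)
    _paint_disks(nuclei, xs, ys, nuc_r, noise.nuclei_amp)
    _paint_disks(cyto, xs, ys, cyto_r, noise.cyto_amp)
    _paint_disks(ki67, xs[pos], ys[pos], nuc_r[pos], noise.ki67_amp)

    sigma_px = noise.psf_sigma_um / pixel_size_um
    out = {}
    for name, img in (("nuclei", nuclei), ("cytoskeleton", cyto),
                      ("proliferation", ki67)):
        img = gaussian_filter(img, sigma_px)
        if noise.background_offset or noise.background_gradient:
            gy, gx = np.mgrid[0:h_px, 0:w_px]
            angle = rng.uniform(0, 2 * np.pi)
            ramp = (np.cos(angle) * gx / w_px + np.sin(angle) * gy / h_px)
            ramp = (ramp - ramp.min()) / max(np.ptp(ramp), 1e-12)
            img = img + noise.background_offset + noise.background_gradient * ramp
        if noise.shot_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if noise.read_sigma > 0:
            img = img + rng.normal(0.0, noise.read_sigma, size=shape)
        out[name] = np.clip(np.round(img), 0, 65535).astype(np.uint16)

    origin = origin_mm
    if origin is None:
        origin = (
            truth.index[0] * tile_um[0] / 1000.0,
            truth.index[1] * tile_um[1] / 1000.0,
        )
    return TileRaster(
        nuclei=out["nuclei"],
        cytoskeleton=out["cytoskeleton"],
        proliferation=out["proliferation"],
        pixel_size_um=pixel_size_um,
        origin_mm=origin,
        index=truth.index,
    )


# ---------------------------------------------------------------------------
# full screens


@dataclass
class ScreenConfig:
    """Factorial screen design: layouts x cell types x timepoints x reps.

    ``tile_cols``/``tile_rows`` and ``pixel_size_um`` allow desk-scale runs
    (e.g. 2 x 3 tiles at 2 um/px) that exercise the full pipeline quickly;
    the defaults are the published acquisition geometry.
    """

    layouts: tuple[str, ...] = LAYOUT_NAMES
    cell_types: tuple[str, ...] = ("MCF10a", "MCF7")
    timepoints_h: tuple[int, ...] = (24, 72)
    replicates: int = 3
    pixel_size_um: float = 0.85
    tile_cols: int | None = None  # None = full 12 x 17 grid
    tile_rows: int | None = None
    jitter_scale: float = 0.3
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def tile_grid(self, layout: DOGLayout) -> list[GridWindow]:
        grid = make_tile_grid(layout)
        if self.tile_cols is None and self.tile_rows is None:
            return grid
        cols = self.tile_cols if self.tile_cols is not None else TILE_COLS
        rows = self.tile_rows if self.tile_rows is not None else TILE_ROWS
        return [g for g in grid if g.index[0] < cols and g.index[1] < rows]


def _condition_seed(ss: np.random.SeedSequence, layout: str, cell_type: str,
                    timepoint_h: int, replicate: int) -> np.random.SeedSequence:
    key = f"{layout}/{cell_type}/{timepoint_h}/{replicate}"
    return np.random.SeedSequence(
        entropy=ss.entropy, spawn_key=(zlib.crc32(key.encode()),)
    )


def generate_screen(
    config: ScreenConfig,
    seed: int = 0,
    out_dir: str | Path | None = None,
    write_rasters: bool = True,
) -> pd.DataFrame:
    """Generate a full factorial synthetic screen.

    Returns a manifest DataFrame with one row per condition replicate
    (layout, cell type, timepoint, replicate, directory, truth CSV).  When
    ``out_dir`` is given, per-condition directories receive calibration
    tables, one multi-page TIFF per tile (pages: nuclei, cytoskeleton,
    proliferation), a tile-origin sidecar CSV, and the planted truth CSV.
    """
    ss = np.random.SeedSequence(seed)
    out_dir = Path(out_dir) if out_dir is not None else None
    manifest = []
    for layout_name in config.layouts:
        calib = generate_calibrations(layout_name, ss, config.jitter_scale)
        layout = build_layout(layout_name, calib)
        grid = None
        for cell_type in config.cell_types:
            for timepoint in config.timepoints_h:
                response = default_response(cell_type, timepoint)
                for rep in range(1, config.replicates + 1):
                    cond_ss = _condition_seed(ss, layout_name, cell_type,
                                              timepoint, rep)
                    grid = config.tile_grid(layout)
                    truths = plant_truth(layout, response, grid, cond_ss)
                    rec = {
                        "layout": layout_name,
                        "cell_type": cell_type,
                        "timepoint_h": timepoint,
                        "replicate": rep,
                        "n_tiles": len(truths),
                        "n_cells": int(sum(t.n_cells for t in truths)),
                    }
                    if out_dir is not None:
                        cond_dir = (
                            out_dir
                            / layout_name.replace("|", "")
                            / f"{cell_type}_{timepoint}h_rep{rep}"
                        )
                        cond_dir.mkdir(parents=True, exist_ok=True)
                        _write_condition(
                            cond_dir, layout_name, calib, truths, config,
                            cond_ss, write_rasters, seed,
                        )
                        rec["path"] = str(cond_dir)
                    manifest.append(rec)
    return pd.DataFrame(manifest)


def _write_condition(
    cond_dir: Path,
    layout_name: str,
    calib: dict[str, pd.DataFrame],
    truths: list[TileTruth],
    config: ScreenConfig,
    cond_ss: np.random.SeedSequence,
    write_rasters: bool,
    master_seed: int,
) -> None:
    header = f"# seed={master_seed}\n"
    calib_df = pd.concat(calib.values(), ignore_index=True)
    with open(cond_dir / "calibrations.csv", "w") as fh:
        fh.write(header)
        calib_df.to_csv(fh, index=False)

    truth_df = pd.concat([t.cells for t in truths], ignore_index=True)
    with open(cond_dir / "truth.csv", "w") as fh:
        fh.write(header)
        truth_df.to_csv(fh, index=False)

    sidecar = []
    for k, truth in enumerate(truths):
        i, j = truth.index
        origin = (i * TILE_WIDTH_UM / 1000.0, j * TILE_HEIGHT_UM / 1000.0)
        sidecar.append(
            {"tile_i": i, "tile_j": j,
             "origin_u_mm": origin[0], "origin_v_mm": origin[1]}
        )
        if write_rasters:
            raster = render_tile(
                truth,
                config.noise,
                np.random.SeedSequence(entropy=cond_ss.entropy,
                                       spawn_key=(10_000 + i, j)),
                config.pixel_size_um,
            )
            stack = np.stack(
                [raster.nuclei, raster.cytoskeleton, raster.proliferation]
            )
            tifffile.imwrite(
                cond_dir / f"tile_{i:02d}_{j:02d}.tif",
                stack,
                photometric="minisblack",
                resolution=(1e4 / config.pixel_size_um,
                            1e4 / config.pixel_size_um),
                metadata={
                    "axes": "CYX",
                    "pixel_size_um": config.pixel_size_um,
                    "origin_u_mm": origin[0],
                    "origin_v_mm": origin[1],
                    "tile_i": i,
                    "tile_j": j,
                },
            )
    with open(cond_dir / "tiles.csv", "w") as fh:
        fh.write(header)
        pd.DataFrame(sidecar).to_csv(fh, index=False)
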