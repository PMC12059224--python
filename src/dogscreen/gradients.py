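"""Double-orthogonal-gradient (DOG) sample model.

A DOG sample is a 20 x 20 mm PDMS substrate carrying two orthogonal,
continuous gradients of surface properties, so that every (u, v) position is
a unique combination of wrinkled topography (wavelength lambda in um,
amplitude A in nm), Young's modulus (MPa) and water contact angle (deg).
Four sample types exist:

=========  =====================  ==================================
name       u axis                 v axis
=========  =====================  ==================================
S-W        stiffness              wettability
T-S        topography             stiffness
T-W        topography             wettability (with a mild passenger
                                  stiffness variation)
T-S|W      topography             double-linear stiffness|wettability
=========  =====================  ==================================

This module maps measured calibration profiles (position along an axis vs
mean +/- SD of a property) to fitted trendlines, evaluates the material
properties at any position on the sample, and builds the two sampling grids
used for quantification: the 2 x 2 mm "datapoint" windows (7 divisions per
topography/stiffness axis, 5 per wettability axis) and the 12 x 17 grid of
1741 x 1298 um microscope tiles.

It also contains the surface-characterization math: the Sneddon conical-
indentation modulus fit for AFM force curves and wrinkle wavelength/
amplitude metrology for AFM height profiles.

Coordinate convention: origin at the sample corner where both plasma
treatments are weakest (softest / most hydrophobic / smallest wrinkles);
u and v in mm, increasing with oxidation dose.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "MaterialPoint",
    "AxisCalibration",
    "Axis",
    "DOGLayout",
    "GridWindow",
    "ForceCurve",
    "HeightProfile",
    "SneddonFit",
    "fit_axis_calibration",
    "material_at",
    "make_datapoint_grid",
    "make_tile_grid",
    "sneddon_modulus",
    "wrinkle_metrics",
    "LAYOUT_NAMES",
    "SIDE_MM",
    "TILE_WIDTH_UM",
    "TILE_HEIGHT_UM",
    "TILE_COLS",
    "TILE_ROWS",
]

SIDE_MM = 20.0
WINDOW_MM = 2.0
TILE_WIDTH_UM = 1741.0
TILE_HEIGHT_UM = 1298.0
TILE_COLS = 12
TILE_ROWS = 17

LAYOUT_NAMES = ("S-W", "T-S", "T-W", "T-S|W")

#: number of datapoint divisions per axis kind
_DIVISIONS = {
    "topography": 7,
    "stiffness": 7,
    "stiffness|wettability": 7,
    "wettability": 5,
}

PARAMETERS = ("wavelength", "amplitude", "stiffness", "wca")


@dataclass(frozen=True)
class MaterialPoint:
    """Surface condition at one position: lambda (um, 0 = flat), A (nm),
    Young's modulus (MPa), water contact angle (deg)."""

    wavelength_um: float
    amplitude_nm: float
    stiffness_mpa: float
    wca_deg: float

    def __post_init__(self):
        if self.wavelength_um < 0 or self.amplitude_nm < 0:
            raise ValueError("wavelength and amplitude must be >= 0")
        if self.stiffness_mpa <= 0:
            raise ValueError("stiffness must be > 0")
        if not 0 <= self.wca_deg <= 180:
            raise ValueError("water contact angle must lie in [0, 180] deg")
        if (self.wavelength_um == 0) != (self.amplitude_nm == 0):
            raise ValueError("a flat surface has wavelength 0 AND amplitude 0")

    @property
    def is_flat(self) -> bool:
        return self.wavelength_um == 0


@dataclass
class AxisCalibration:
    """Polynomial trendline fitted to measured means along one axis.

    Predictions are clamped to the envelope of the measured means so that
    evaluating slightly beyond the outermost measurement position cannot
    extrapolate outside the characterized range.
    """

    parameter: str
    positions_mm: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    n_per_position: np.ndarray
    fit_order: int
    coefficients: np.ndarray  # highest order first (np.polyval convention)
    r_squared: float
    warning: str | None = None

    def __post_init__(self):
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not (len(self.positions_mm) == len(self.means) == len(self.sds)):
            raise ValueError("positions, means and sds must have equal length")
        if np.any(np.diff(self.positions_mm) <= 0):
            raise ValueError("positions must be strictly increasing")

    def predict(self, position_mm) -> np.ndarray | float:
        value = np.polyval(self.coefficients, position_mm)
        lo, hi = float(self.means.min()), float(self.means.max())
        clipped = np.clip(value, lo, hi)
        return float(clipped) if np.isscalar(position_mm) else clipped


def fit_axis_calibration(
    parameter: str,
    positions_mm: Sequence[float],
    means: Sequence[float],
    sds: Sequence[float],
    n_per_position: Sequence[int] | int = 3,
    fit_order: int = 1,
) -> AxisCalibration:
    """Fit an order-1 or order-2 trendline to a measured gradient profile.

    Ordinary least squares on (position, mean).  An order-1 fit whose slope
    conflicts with the overall direction of the measured means (non-monotone
    data) is allowed but flagged in ``warning``.
    """
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}")
    if fit_order not in (1, 2):
        raise ValueError("fit_order must be 1 or 2")
    pos = np.asarray(positions_mm, dtype=float)
    mu = np.asarray(means, dtype=float)
    sd = np.asarray(sds, dtype=float)
    if np.any(sd < 0):
        raise ValueError("sds must be >= 0")
    if np.unique(pos).size < fit_order + 1:
        raise ValueError(
            f"degenerate fit: need >= {fit_order + 1} distinct positions, "
            f"got {np.unique(pos).size}"
        )
    n = np.broadcast_to(np.asarray(n_per_position, dtype=int), pos.shape).copy()

    coef = np.polyfit(pos, mu, fit_order)
    pred = np.polyval(coef, pos)
    ss_res = float(np.sum((mu - pred) ** 2))
    ss_tot = float(np.sum((mu - mu.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot

    warning = None
    if fit_order == 1 and np.any(np.diff(mu) * np.sign(coef[0]) < 0):
        warning = "measured means are not monotone along the axis"

    return AxisCalibration(
        parameter=parameter,
        positions_mm=pos,
        means=mu,
        sds=sd,
        n_per_position=n,
        fit_order=fit_order,
        coefficients=coef,
        r_squared=r2,
        warning=warning,
    )


@dataclass
class Axis:
    """One gradient axis: its kind (decides the 7-vs-5 datapoint rule) and
    the calibrations of every parameter varying along it."""

    kind: str  # topography | stiffness | wettability | stiffness|wettability
    calibrations: dict[str, AxisCalibration]

    def __post_init__(self):
        if self.kind not in _DIVISIONS:
            raise ValueError(f"unknown axis kind {self.kind!r}")

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(self.calibrations)

    @property
    def divisions(self) -> int:
        return _DIVISIONS[self.kind]


@dataclass
class DOGLayout:
    """One DOG sample: two orthogonal gradient axes plus fixed values.

    Every material parameter (wavelength, amplitude, stiffness, wca) must
    appear exactly once: on the u axis, on the v axis, or in
    ``fixed_values``.
    """

    name: str
    axis_u: Axis
    axis_v: Axis
    fixed_values: dict[str, float] = field(default_factory=dict)
    side_mm: float = SIDE_MM

    def __post_init__(self):
        if self.name not in LAYOUT_NAMES:
            raise ValueError(f"unknown layout name {self.name!r}")
        seen = (
            list(self.axis_u.parameters)
            + list(self.axis_v.parameters)
            + list(self.fixed_values)
        )
        if sorted(seen) != sorted(PARAMETERS):
            raise ValueError(
                f"every parameter must appear exactly once; got {sorted(seen)}"
            )


def material_at(layout: DOGLayout, u_mm: float, v_mm: float) -> MaterialPoint:
    """Material properties at position (u, v) on the sample.

    Each varying parameter is evaluated from its axis calibration at the
    coordinate of that axis (clamped to the calibration envelope); fixed
    parameters are copied.  On T-S|W the double-linear axis evaluates both
    stiffness and wettability from the same coordinate.
    """
    if not (0 <= u_mm <= layout.side_mm and 0 <= v_mm <= layout.side_mm):
        raise ValueError(
            f"position ({u_mm}, {v_mm}) mm outside the "
            f"{layout.side_mm} mm sample"
        )
    values = dict(layout.fixed_values)
    for axis, coord in ((layout.axis_u, u_mm), (layout.axis_v, v_mm)):
        for name, cal in axis.calibrations.items():
            values[name] = cal.predict(coord)
    return MaterialPoint(
        wavelength_um=values["wavelength"],
        amplitude_nm=values["amplitude"],
        stiffness_mpa=values["stiffness"],
        wca_deg=values["wca"],
    )


@dataclass(frozen=True)
class GridWindow:
    """One sampling window on the DOG plane (half-open [lo, hi) extent)."""

    index: tuple[int, int]
    center_mm: tuple[float, float]
    width_mm: float
    height_mm: float
    partial: bool = False

    @property
    def lo_mm(self) -> tuple[float, float]:
        return (
            self.center_mm[0] - self.width_mm / 2,
            self.center_mm[1] - self.height_mm / 2,
        )

    @property
    def hi_mm(self) -> tuple[float, float]:
        return (
            self.center_mm[0] + self.width_mm / 2,
            self.center_mm[1] + self.height_mm / 2,
        )

    @property
    def area_mm2(self) -> float:
        return self.width_mm * self.height_mm

    def clipped_area_mm2(self, side_mm: float = SIDE_MM) -> float:
        """Window area inside the [0, side]^2 sample."""
        (u0, v0), (u1, v1) = self.lo_mm, self.hi_mm
        du = max(0.0, min(u1, side_mm) - max(u0, 0.0))
        dv = max(0.0, min(v1, side_mm) - max(v0, 0.0))
        return du * dv

    def contains(self, u_mm: float, v_mm: float) -> bool:
        (u0, v0), (u1, v1) = self.lo_mm, self.hi_mm
        return u0 <= u_mm < u1 and v0 <= v_mm < v1


def make_datapoint_grid(layout: DOGLayout) -> list[GridWindow]:
    """The 2 x 2 mm datapoint windows drawn along the gradients.

    7 divisions along a topography, stiffness, or combined
    stiffness|wettability axis; 5 along a wettability axis.  Window centers
    are evenly spaced at (k + 0.5) * side / K, so the 2 mm windows are
    separated by gaps.  S-W and T-W give 35 windows, T-S and T-S|W give 49.
    """
    ku = layout.axis_u.divisions
    kv = layout.axis_v.divisions
    windows = []
    for i in range(ku):
        for j in range(kv):
            cu = (i + 0.5) * layout.side_mm / ku
            cv = (j + 0.5) * layout.side_mm / kv
            windows.append(
                GridWindow(
                    index=(i, j),
                    center_mm=(cu, cv),
                    width_mm=WINDOW_MM,
                    height_mm=WINDOW_MM,
                )
            )
    return windows


def make_tile_grid(layout: DOGLayout) -> list[GridWindow]:
    """The 12 x 17 grid of 1741 x 1298 um microscope tiles.

    Tiles are anchored at the sample origin; the scanned area slightly
    exceeds the 20 mm sample, so tiles crossing (or beyond) the boundary are
    flagged ``partial`` and carry a clipped analyzed area.
    """
    w = TILE_WIDTH_UM / 1000.0
    h = TILE_HEIGHT_UM / 1000.0
    tiles = []
    for i in range(TILE_COLS):
        for j in range(TILE_ROWS):
            u0, v0 = i * w, j * h
            partial = u0 + w > layout.side_mm or v0 + h > layout.side_mm
            tiles.append(
                GridWindow(
                    index=(i, j),
                    center_mm=(u0 + w / 2, v0 + h / 2),
                    width_mm=w,
                    height_mm=h,
                    partial=partial,
                )
            )
    return tiles


# ---------------------------------------------------------------------------
# surface characterization math


@dataclass
class ForceCurve:
    """AFM indentation curve: depths delta (nm) and forces F (nN)."""

    indentation_nm: np.ndarray
    force_nn: np.ndarray
    tip_half_angle_deg: float = 18.0
    poisson: float = 0.3

    def __post_init__(self):
        self.indentation_nm = np.asarray(self.indentation_nm, dtype=float)
        self.force_nn = np.asarray(self.force_nn, dtype=float)
        if self.indentation_nm.shape != self.force_nn.shape:
            raise ValueError("indentation and force arrays must match")
        if self.indentation_nm.size < 3:
            raise ValueError("need at least 3 points")
        if np.any(self.indentation_nm < 0):
            raise ValueError("indentation depths must be >= 0")


@dataclass(frozen=True)
class SneddonFit:
    modulus_mpa: float
    residual: float
    degenerate: bool = False


def sneddon_modulus(curve: ForceCurve) -> SneddonFit:
    """Young's modulus from a conical-indenter (Sneddon) force curve.

    The contact model is F = (2/pi) tan(alpha) E / (1 - nu^2) * delta^2 with
    tip half angle alpha and Poisson ratio nu; E follows from a linear
    least-squares fit of F against delta^2 through the origin (the contact
    point is taken at delta = 0).  With F in nN and delta in nm the fitted
    slope is in GPa, converted to MPa.
    """
    delta2 = curve.indentation_nm**2
    force = curve.force_nn
    mask = curve.indentation_nm > 0
    if not np.any(mask) or np.count_nonzero(mask) < 1 or np.all(force <= 0):
        return SneddonFit(0.0, 0.0, degenerate=True)
    d2, f = delta2[mask], force[mask]
    slope = float(d2 @ f) / float(d2 @ d2)  # nN / nm^2 == GPa
    if slope <= 0:
        return SneddonFit(0.0, float(np.sum(f**2)), degenerate=True)
    resid = float(np.sqrt(np.mean((f - slope * d2) ** 2)))
    alpha = math.radians(curve.tip_half_angle_deg)
    e_gpa = slope * math.pi * (1.0 - curve.poisson**2) / (2.0 * math.tan(alpha))
    return SneddonFit(e_gpa * 1e3, resid)


def sneddon_force_nn(
    indentation_nm, modulus_mpa: float,
    tip_half_angle_deg: float = 18.0, poisson: float = 0.3,
) -> np.ndarray:
    """Forward Sneddon model (nN); the inverse of :func:`sneddon_modulus`."""
    delta = np.asarray(indentation_nm, dtype=float)
    alpha = math.radians(tip_half_angle_deg)
    e_gpa = modulus_mpa / 1e3
    return 2.0 / math.pi * math.tan(alpha) * e_gpa / (1.0 - poisson**2) * delta**2


@dataclass
class HeightProfile:
    """AFM height profile: lateral positions x (um, uniform) and heights z (nm)."""

    x_um: np.ndarray
    z_nm: np.ndarray

    def __post_init__(self):
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.z_nm = np.asarray(self.z_nm, dtype=float)
        if self.x_um.shape != self.z_nm.shape:
            raise ValueError("x and z arrays must match")
        dx = np.diff(self.x_um)
        if np.any(dx <= 0):
            raise ValueError("x must be strictly increasing")
        if dx.size and not np.allclose(dx, dx[0], rtol=1e-9):
            raise ValueError("x must be uniformly spaced")

    @property
    def spacing_um(self) -> float:
        return float(self.x_um[1] - self.x_um[0])


def wrinkle_metrics(
    profile: HeightProfile, noise_floor_nm: float = 1.0
) -> tuple[float, float]:
    """Wrinkle wavelength (um) and amplitude (nm) of a height profile.

    The wavelength estimate starts from the dominant peak of the power
    spectrum and is refined by the mean spacing of detected crests; the
    amplitude is (mean crest height - mean trough height) / 2.  A profile
    whose height variation is below ``noise_floor_nm`` (standard deviation)
    is reported flat: (0, 0).

    Requires at least 16 samples covering at least 2 full periods.
    """
    z = profile.z_nm
    if z.size < 16:
        raise ValueError("need at least 16 samples")
    if float(np.std(z)) < noise_floor_nm:
        return 0.0, 0.0

    dx = profile.spacing_um
    zc = z - z.mean()
    freqs = np.fft.rfftfreq(z.size, d=dx)
    power = np.abs(np.fft.rfft(zc)) ** 2
    k = int(np.argmax(power[1:])) + 1  # skip DC
    wavelength = 1.0 / freqs[k]
    if wavelength > (profile.x_um[-1] - profile.x_um[0]) / 2.0:
        raise ValueError("profile must cover at least 2 full periods")

    # refine by mean crest-to-crest spacing, then measure amplitude
    min_dist = max(1, int(0.5 * wavelength / dx))
    prominence = 0.5 * float(np.std(zc))
    crests, _ = signal.find_peaks(zc, distance=min_dist, prominence=prominence)
    troughs, _ = signal.find_peaks(-zc, distance=min_dist, prominence=prominence)
    if crests.size >= 2:
        wavelength = float(np.mean(np.diff(profile.x_um[crests])))
    if crests.size and troughs.size:
        amplitude = float((zc[crests].mean() - zc[troughs].mean()) / 2.0)
    else:  # pathological profile; fall back to a spectral amplitude
        warnings.warn("no crests/troughs found; using RMS amplitude estimate")
        amplitude = float(np.sqrt(2.0) * np.std(zc))
    return float(wavelength), amplitude
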