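"""Synthetic osmoscan curves with exactly known ground-truth indices.

An osmoscan sweeps extracellular osmolality (0-500 mOsm/kg) at fixed shear
stress (30 Pa) while recording the elongation index (EI) of red blood cells.
The informative trace rises through a small sub-lysis bump, falls to a
hypoosmotic valley at ``O_min``, climbs to its global maximum ``EI_max`` at
``O_EI_max``, and descends through the half-maximum level at ``O_hyper``.

The generator builds the noiseless trace as a monotone piecewise cubic
(PCHIP) through those named control features, so every ground-truth index is
an explicit input: the valley, peak and bump knots get zero slope
automatically (secant sign change), the descending arm passes through
``(O_hyper, EI_max/2)`` exactly, and ground-truth Area is the exact integral
of the spline between ``O_min`` and ``O_hyper``.  Gaussian EI noise of
configurable standard deviation is added on top.

No functional form for the physical curve is implied; the construction is
chosen so that index-extraction accuracy can be tested against exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import ConstructionError, ParameterError

__all__ = [
    "OsmoscanCurve",
    "CurveParams",
    "FractionPreset",
    "synth_curve",
    "fraction_presets",
    "preset_params",
    "random_curve_params",
    "FRACTIONS",
]

FRACTIONS = ("WB", "WBP", "L", "M", "H")
_VALID_FRACTIONS = FRACTIONS + ("NA",)

OSM_MAX = 500.0  # instrument sweep ceiling, mOsm/kg


@dataclass
class OsmoscanCurve:
    """Ordered (osmolality, EI) samples plus acquisition metadata.

    ``preprocessed`` marks a curve that has already been sorted,
    de-duplicated and smoothed; preprocessing is a no-op on such curves.
    """

    osmolality: np.ndarray
    ei: np.ndarray
    sample_id: str = ""
    fraction: str = "NA"
    shear_stress_Pa: float = 30.0
    temperature_C: float = 37.0
    preprocessed: bool = False

    def __post_init__(self):
        self.osmolality = np.asarray(self.osmolality, dtype=float)
        self.ei = np.asarray(self.ei, dtype=float)
        if self.osmolality.ndim != 1 or self.osmolality.shape != self.ei.shape:
            raise ParameterError("osmolality and ei must be 1-D arrays of equal length")
        if self.fraction not in _VALID_FRACTIONS:
            raise ParameterError(f"fraction must be one of {_VALID_FRACTIONS}, got {self.fraction!r}")

    def __len__(self) -> int:
        return self.osmolality.size

    def __eq__(self, other) -> bool:
        if not isinstance(other, OsmoscanCurve):
            return NotImplemented
        return (
            np.array_equal(self.osmolality, other.osmolality)
            and np.array_equal(self.ei, other.ei)
            and self.sample_id == other.sample_id
            and self.fraction == other.fraction
            and self.shear_stress_Pa == other.shear_stress_Pa
            and self.temperature_C == other.temperature_C
        )


@dataclass(frozen=True)
class CurveParams:
    """Ground-truth control features of a synthetic osmoscan curve.

    Osmolalities in mOsm/kg, EI dimensionless.  Defaults are the
    whole-blood preset.
    """

    o_min_true: float = 140.0
    ei_min_true: float = 0.18
    o_eimax_true: float = 300.0
    ei_max_true: float = 0.60
    o_hyper_true: float = 460.0
    bump_osm: float = 90.0
    bump_ei: float = 0.30
    start_osm: float = 50.0
    end_ei: float = 0.10
    noise_sd: float = 0.0
    grid_step: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        p = self
        if not (p.start_osm < p.bump_osm < p.o_min_true < p.o_eimax_true < p.o_hyper_true <= OSM_MAX):
            raise ParameterError(
                "require start_osm < bump_osm < o_min_true < o_eimax_true < o_hyper_true <= 500, got "
                f"{p.start_osm}, {p.bump_osm}, {p.o_min_true}, {p.o_eimax_true}, {p.o_hyper_true}"
            )
        if not (0.0 <= p.ei_min_true < p.ei_max_true < 1.0):
            raise ParameterError(f"require 0 <= ei_min_true < ei_max_true < 1, got {p.ei_min_true}, {p.ei_max_true}")
        if not (p.ei_min_true < p.bump_ei < p.ei_max_true):
            raise ParameterError(f"bump_ei must lie in (ei_min_true, ei_max_true), got {p.bump_ei}")
        if not (0.0 <= p.end_ei < p.ei_max_true / 2):
            raise ParameterError(f"end_ei must lie in [0, ei_max_true/2), got {p.end_ei}")
        if p.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if p.grid_step <= 0:
            raise ParameterError("grid_step must be > 0")


@dataclass(frozen=True)
class FractionPreset:
    """A density-fraction phenotype: label plus noiseless curve parameters."""

    label: str
    params: CurveParams


def _noiseless_spline(params: CurveParams) -> PchipInterpolator:
    """Monotone piecewise cubic through the control knots.

    PCHIP gives zero derivative at interior knots where the secant slopes
    change sign (the bump, valley and peak) and is monotone between knots.
    """
    p = params
    # Symmetric shoulder knots pin a definite, locally symmetric curvature
    # at the valley and the peak, so each extremum's location is well posed
    # (a bare zero-slope PCHIP knot can be nearly flat on one side).
    w_v = min(12.0, 0.4 * (p.o_min_true - p.bump_osm), 0.4 * (p.o_eimax_true - p.o_min_true))
    h_v = min(0.008, 0.4 * (p.bump_ei - p.ei_min_true), 0.4 * (p.ei_max_true - p.ei_min_true))
    w_p = min(15.0, 0.4 * (p.o_eimax_true - p.o_min_true), 0.4 * (p.o_hyper_true - p.o_eimax_true))
    h_p = min(0.01, 0.4 * (p.ei_max_true - p.ei_min_true) - h_v, 0.4 * p.ei_max_true / 2.0)
    knots_x = [
        p.start_osm, p.bump_osm,
        p.o_min_true - w_v, p.o_min_true, p.o_min_true + w_v,
        p.o_eimax_true - w_p, p.o_eimax_true, p.o_eimax_true + w_p,
    ]
    knots_y = [
        0.0, p.bump_ei,
        p.ei_min_true + h_v, p.ei_min_true, p.ei_min_true + h_v,
        p.ei_max_true - h_p, p.ei_max_true, p.ei_max_true - h_p,
    ]
    if p.o_hyper_true < OSM_MAX:
        knots_x += [p.o_hyper_true, OSM_MAX]
        knots_y += [p.ei_max_true / 2.0, p.end_ei]
    else:
        knots_x.append(p.o_hyper_true)
        knots_y.append(p.ei_max_true / 2.0)
    spline = PchipInterpolator(knots_x, knots_y, extrapolate=False)
    _check_monotone_segments(spline, knots_x, knots_y)
    return spline


_SEGMENT_NAMES = ("start-to-bump", "bump-to-valley", "valley-to-peak", "peak-to-hyper", "hyper-to-end")


def _check_monotone_segments(spline, knots_x, knots_y) -> None:
    for i in range(len(knots_x) - 1):
        xs = np.linspace(knots_x[i], knots_x[i + 1], 25)
        ys = spline(xs)
        d = np.diff(ys)
        sign = np.sign(knots_y[i + 1] - knots_y[i])
        if np.any(sign * d < -1e-12):
            name = _SEGMENT_NAMES[min(i, len(_SEGMENT_NAMES) - 1)]
            raise ConstructionError(f"segment {name} is not monotone for the given control points")


def true_indices(params: CurveParams):
    """Exact LorrcaIndices implied by the generator control features."""
    from .indices import LorrcaIndices  # local import to avoid a cycle

    spline = _noiseless_spline(params)
    area = float(spline.integrate(params.o_min_true, params.o_hyper_true))
    return LorrcaIndices(
        o_min=params.o_min_true,
        ei_min=params.ei_min_true,
        o_eimax=params.o_eimax_true,
        ei_max=params.ei_max_true,
        o_hyper=params.o_hyper_true,
        ei_hyper=params.ei_max_true / 2.0,
        area=area,
        qc_flags=frozenset(),
    )


def synth_curve(params: CurveParams, sample_id: str = "", fraction: str = "NA"):
    """Sample a synthetic osmoscan curve and return it with its exact truth.

    Returns ``(OsmoscanCurve, LorrcaIndices)``.  The curve is sampled every
    ``grid_step`` mOsm/kg from ``start_osm`` to 500 (endpoint included) with
    additive Gaussian EI noise of sd ``noise_sd``; the indices are the exact
    ground truth of the noiseless trace.
    """
    params.validate()
    spline = _noiseless_spline(params)
    grid = np.arange(params.start_osm, OSM_MAX + params.grid_step / 2.0, params.grid_step)
    grid = np.minimum(grid, OSM_MAX)
    ei = np.asarray(spline(grid), dtype=float)
    # beyond o_hyper == 500 there is nothing to extrapolate
    ei = np.nan_to_num(ei, nan=params.ei_max_true / 2.0)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        ei = ei + rng.normal(0.0, params.noise_sd, size=ei.size)
    curve = OsmoscanCurve(grid, ei, sample_id=sample_id, fraction=fraction)
    return curve, true_indices(params)


# Density-fraction presets.  The paper-scale constraints are orderings only
# (O_hyper L > M > H, Area smallest for H, EI_max M > L > H, EI_min largest
# for H, O_EI_max largest for M, O_min equal across L/M/H, and the
# centrifugation artifact raising O_min and O_hyper for WBP); the absolute
# levels are plausible-range implementation constants.
_WB = CurveParams()
_PRESET_PARAMS: dict[str, CurveParams] = {
    "WB": _WB,
    "WBP": replace(_WB, o_min_true=155.0, o_hyper_true=475.0, end_ei=0.15),
    "L": replace(_WB, o_min_true=150.0, ei_min_true=0.17, o_eimax_true=290.0, ei_max_true=0.58, o_hyper_true=455.0),
    "M": replace(_WB, o_min_true=150.0, ei_min_true=0.17, o_eimax_true=300.0, ei_max_true=0.61, o_hyper_true=440.0),
    "H": replace(_WB, o_min_true=150.0, ei_min_true=0.22, o_eimax_true=285.0, ei_max_true=0.52, o_hyper_true=415.0),
}


def preset_params(label: str) -> CurveParams:
    """Noiseless curve parameters for one fraction label."""
    try:
        return _PRESET_PARAMS[label]
    except KeyError:
        raise ParameterError(f"unknown fraction preset {label!r}; choose from {FRACTIONS}") from None


def fraction_presets() -> list[FractionPreset]:
    """The five phenotype presets: WB, WBP (mock-centrifuged), L, M, H."""
    return [FractionPreset(label, _PRESET_PARAMS[label]) for label in FRACTIONS]


def random_curve_params(rng: np.random.Generator, noise_sd: float = 0.0, grid_step: float = 1.0) -> CurveParams:
    """Draw a random valid parameter set (for property tests and calibration).

    Ranges keep the valley comfortably inside the default search window
    (>100 mOsm/kg) and all invariants satisfied by construction.
    """
    o_min = rng.uniform(120.0, 180.0)
    ei_min = rng.uniform(0.05, 0.25)
    o_eimax = o_min + rng.uniform(90.0, 180.0)
    o_hyper = rng.uniform(o_eimax + 80.0, 490.0)
    ei_max = ei_min + rng.uniform(0.25, 0.55)
    ei_max = min(ei_max, 0.9)
    bump_osm = rng.uniform(65.0, min(95.0, o_min - 25.0))
    bump_ei = rng.uniform(ei_min + 0.02, ei_min + 0.8 * (ei_max - ei_min))
    end_ei = rng.uniform(0.02, 0.7 * ei_max / 2.0)
    params = CurveParams(
        o_min_true=o_min, ei_min_true=ei_min, o_eimax_true=o_eimax, ei_max_true=ei_max,
        o_hyper_true=o_hyper, bump_osm=bump_osm, bump_ei=bump_ei, start_osm=50.0,
        end_ei=end_ei, noise_sd=noise_sd, grid_step=grid_step,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    params.validate()
    return params
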