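"""Extraction of the seven Lorrca indices from a raw osmoscan curve.

The indices are: ``O_min``/``EI_min`` (hypoosmotic valley, the point
physiologically linked to 50% osmotic lysis), ``EI_max`` at ``O_EI_max``
(global deformability maximum), ``O_hyper`` (osmolality on the descending
hyperosmotic arm where EI falls to ``EI_hyper = EI_max/2``, a hydration
marker), and ``Area`` (trapezoidal area under the curve between ``O_min``
and ``O_hyper``; EI is dimensionless so Area carries mOsm/kg units).

Degenerate shapes never raise: every undefined index is reported as ``None``
together with a QC flag.  The only hard error is a curve with fewer than 20
usable points.

Conventions (the instrument vendor's exact definitions are proprietary):
smoothing is a centred moving average (default width 5) that shrinks
symmetrically at the ends; peak/valley plateaus resolve to the run's mean
osmolality; O_hyper is the first downward half-maximum crossing after the
peak, located by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import OsmoscanCurve
from .errors import ParameterError, TooFewPointsError

__all__ = [
    "LorrcaIndices",
    "ExtractionConfig",
    "preprocess",
    "find_peak",
    "find_valley",
    "find_hyper",
    "compute_area",
    "extract_indices",
    "QC_FLAGS",
]

QC_FLAGS = ("TOO_FEW_POINTS", "NO_VALLEY", "HYPER_NOT_REACHED", "LOW_SIGNAL", "DUPLICATE_OSM")

MIN_POINTS = 20


@dataclass(frozen=True)
class LorrcaIndices:
    """The seven osmoscan indices plus QC flags; undefined values are None."""

    o_min: float | None
    ei_min: float | None
    o_eimax: float | None
    ei_max: float | None
    o_hyper: float | None
    ei_hyper: float | None
    area: float | None
    qc_flags: frozenset[str] = frozenset()

    def to_dict(self) -> dict:
        return {
            "o_min": self.o_min, "ei_min": self.ei_min,
            "o_eimax": self.o_eimax, "ei_max": self.ei_max,
            "o_hyper": self.o_hyper, "ei_hyper": self.ei_hyper,
            "area": self.area, "qc_flags": sorted(self.qc_flags),
        }


INDEX_NAMES = ("o_min", "ei_min", "o_eimax", "ei_max", "o_hyper", "ei_hyper", "area")


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable extraction settings.

    smooth_window : odd moving-average width in samples (1 disables).
    plateau_tol   : EI tolerance defining peak/valley plateaus.
    search_lo     : lower osmolality bound of the valley search window,
                    excluding the sub-lysis bump (mOsm/kg).
    low_signal_threshold : EI_max below this flags LOW_SIGNAL.
    """

    smooth_window: int = 5
    plateau_tol: float = 0.001
    search_lo: float = 100.0
    low_signal_threshold: float = 0.05

    def validate(self) -> None:
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ParameterError(f"smooth_window must be a positive odd integer, got {self.smooth_window}")
        if self.plateau_tol < 0:
            raise ParameterError("plateau_tol must be >= 0")


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average, shrinking symmetrically near the ends."""
    if window <= 1:
        return y.copy()
    half = window // 2
    out = np.empty_like(y)
    n = y.size
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = y[i - k : i + k + 1].mean()
    return out


def preprocess(curve: OsmoscanCurve, smooth_window: int = 5) -> OsmoscanCurve:
    """Sort, de-duplicate, clip to [0, 500] and smooth a raw curve.

    Duplicate osmolalities are replaced by their mean EI; points outside
    [0, 500] mOsm/kg are dropped.  Idempotent: a curve already marked
    ``preprocessed`` is returned unchanged.
    """
    out, _ = _preprocess(curve, smooth_window)
    return out


def _preprocess(curve: OsmoscanCurve, smooth_window: int = 5) -> tuple[OsmoscanCurve, set[str]]:
    if curve.preprocessed:
        return curve, set()
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ParameterError(f"smooth_window must be a positive odd integer, got {smooth_window}")
    flags: set[str] = set()
    osm = curve.osmolality
    ei = curve.ei
    if osm.size < MIN_POINTS:
        raise TooFewPointsError(f"need >= {MIN_POINTS} raw points, got {osm.size}")
    keep = (osm >= 0.0) & (osm <= 500.0) & np.isfinite(osm) & np.isfinite(ei)
    osm, ei = osm[keep], ei[keep]
    order = np.argsort(osm, kind="stable")
    osm, ei = osm[order], ei[order]
    uniq, inverse, counts = np.unique(osm, return_inverse=True, return_counts=True)
    if uniq.size < osm.size:
        flags.add("DUPLICATE_OSM")
        mean_ei = np.bincount(inverse, weights=ei) / counts
        osm, ei = uniq, mean_ei
    if osm.size < MIN_POINTS:
        raise TooFewPointsError(f"fewer than {MIN_POINTS} points survive preprocessing ({osm.size})")
    ei = _moving_average(ei, smooth_window)
    out = OsmoscanCurve(
        osm, ei, sample_id=curve.sample_id, fraction=curve.fraction,
        shear_stress_Pa=curve.shear_stress_Pa, temperature_C=curve.temperature_C,
        preprocessed=True,
    )
    return out, flags


def _plateau_mean(osm: np.ndarray, member: np.ndarray, anchor: int) -> float:
    """Mean osmolality of the contiguous member-run containing ``anchor``."""
    lo = anchor
    while lo > 0 and member[lo - 1]:
        lo -= 1
    hi = anchor
    while hi < member.size - 1 and member[hi + 1]:
        hi += 1
    return float(osm[lo : hi + 1].mean())


def find_peak(
    curve: OsmoscanCurve, plateau_tol: float = 0.001, low_signal_threshold: float = 0.05
) -> tuple[float, float, set[str]]:
    """Global EI maximum.  Returns (o_eimax, ei_max, flags).

    A plateau of near-maximal points (within ``plateau_tol``) containing the
    argmax resolves to its mean osmolality.  ``ei_max`` below
    ``low_signal_threshold`` adds a LOW_SIGNAL flag; indices are still
    returned.
    """
    osm, ei = curve.osmolality, curve.ei
    flags: set[str] = set()
    anchor = int(np.argmax(ei))
    ei_max = float(ei[anchor])
    o_eimax = _plateau_mean(osm, ei >= ei_max - plateau_tol, anchor)
    if ei_max < low_signal_threshold:
        flags.add("LOW_SIGNAL")
    return o_eimax, ei_max, flags


def find_valley(
    curve: OsmoscanCurve, o_eimax: float, search_lo: float = 100.0, plateau_tol: float = 0.001
) -> tuple[float | None, float | None, set[str]]:
    """Hypoosmotic valley: global EI minimum on [search_lo, o_eimax].

    The minimum must be interior to the window (a boundary minimum means the
    curve has no valley there); otherwise returns (None, None, {NO_VALLEY}).
    """
    osm, ei = curve.osmolality, curve.ei
    idx = np.nonzero((osm >= search_lo) & (osm <= o_eimax))[0]
    if idx.size < 3:
        return None, None, {"NO_VALLEY"}
    w_osm, w_ei = osm[idx], ei[idx]
    anchor = int(np.argmin(w_ei))
    ei_min = float(w_ei[anchor])
    member = w_ei <= ei_min + plateau_tol
    if member[0] or member[-1]:
        return None, None, {"NO_VALLEY"}
    o_min = _plateau_mean(w_osm, member, anchor)
    return o_min, ei_min, set()


def find_hyper(curve: OsmoscanCurve, ei_max: float, o_eimax: float) -> tuple[float | None, set[str]]:
    """First downward crossing of EI_max/2 beyond the peak.

    Located by linear interpolation between the bracketing samples; if the
    curve never falls to half-maximum before the last sample, returns
    (None, {HYPER_NOT_REACHED}).
    """
    osm, ei = curve.osmolality, curve.ei
    level = ei_max / 2.0
    start = int(np.searchsorted(osm, o_eimax, side="left"))
    for i in range(max(start, 0), osm.size - 1):
        if ei[i] >= level > ei[i + 1]:
            frac = (ei[i] - level) / (ei[i] - ei[i + 1])
            return float(osm[i] + frac * (osm[i + 1] - osm[i])), set()
    return None, {"HYPER_NOT_REACHED"}


def compute_area(curve: OsmoscanCurve, o_min: float, o_hyper: float) -> float:
    """Trapezoidal integral of smoothed EI over [o_min, o_hyper].

    EI at the two bounds is obtained by linear interpolation between the
    neighbouring samples.
    """
    if o_min is None or o_hyper is None:
        raise ParameterError("both area bounds must be defined")
    if not o_min < o_hyper:
        raise ParameterError(f"require o_min < o_hyper, got {o_min} >= {o_hyper}")
    osm, ei = curve.osmolality, curve.ei
    inner = (osm > o_min) & (osm < o_hyper)
    xs = np.concatenate(([o_min], osm[inner], [o_hyper]))
    ys = np.concatenate(([np.interp(o_min, osm, ei)], ei[inner], [np.interp(o_hyper, osm, ei)]))
    return float(np.trapezoid(ys, xs))


def extract_indices(curve: OsmoscanCurve, config: ExtractionConfig | None = None) -> LorrcaIndices:
    """Run the full extraction pipeline on a raw curve.

    preprocess -> find_peak -> find_valley -> find_hyper -> compute_area.
    Degenerate shapes yield None indices with QC flags; only a curve with
    fewer than 20 usable points raises (TooFewPointsError).
    """
    cfg = config or ExtractionConfig()
    cfg.validate()
    work, flags = _preprocess(curve, cfg.smooth_window)
    o_eimax, ei_max, f = find_peak(work, cfg.plateau_tol, cfg.low_signal_threshold)
    flags |= f
    o_min, ei_min, f = find_valley(work, o_eimax, cfg.search_lo, cfg.plateau_tol)
    flags |= f
    o_hyper, f = find_hyper(work, ei_max, o_eimax)
    flags |= f
    area = None
    if o_min is not None and o_hyper is not None and o_min < o_hyper:
        area = compute_area(work, o_min, o_hyper)
    return LorrcaIndices(
        o_min=o_min, ei_min=ei_min, o_eimax=o_eimax, ei_max=ei_max,
        o_hyper=o_hyper, ei_hyper=ei_max / 2.0, area=area,
        qc_flags=frozenset(flags),
    )
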