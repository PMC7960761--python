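"""Small bespoke marker computations: gravimetric water fraction, band
4.1a:b densitometric ratio from a gel-lane profile, geometric-mean
fluorescence, and the red-cell-age marker-ordering report."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import FractionSample, MARKER_ORDERINGS
from .errors import MeasurementError, PairingError, ParameterError

__all__ = [
    "LaneProfile",
    "water_fraction",
    "band41_ratio",
    "geo_mean_fluor",
    "marker_ordering_check",
]


@dataclass
class LaneProfile:
    """1-D densitometry trace of one gel lane.

    ``window_a`` and ``window_b`` are disjoint (lo, hi) position intervals
    for the 4.1a and 4.1b bands, with 4.1a migrating first.
    """

    position: np.ndarray
    intensity: np.ndarray
    window_a: tuple[float, float]
    window_b: tuple[float, float]

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.position.shape != self.intensity.shape or self.position.ndim != 1:
            raise ParameterError("position and intensity must be 1-D arrays of equal length")
        if np.any(np.diff(self.position) <= 0):
            raise ParameterError("position must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ParameterError("intensity must be >= 0")
        a_lo, a_hi = self.window_a
        b_lo, b_hi = self.window_b
        if not (a_lo < a_hi <= b_lo < b_hi):
            raise ParameterError("windows must be disjoint with window_a preceding window_b")


def water_fraction(wet_mg: float, dry_mg: float) -> tuple[float, float]:
    """Cellular water content from pellet wet and dry weights.

    Returns ``(fraction, percent)`` where fraction = 1 - dry/wet.
    """
    if dry_mg <= 0 or wet_mg <= 0:
        raise MeasurementError("weights must be positive")
    if dry_mg >= wet_mg:
        raise MeasurementError(f"dry weight ({dry_mg}) must be below wet weight ({wet_mg})")
    frac = 1.0 - dry_mg / wet_mg
    return frac, 100.0 * frac


def _band_integral(profile: LaneProfile, window: tuple[float, float]) -> float:
    pos, inten = profile.position, profile.intensity
    lo, hi = window
    inside = (pos >= lo) & (pos <= hi)
    if inside.sum() < 3:
        raise ParameterError(f"band window {window} contains fewer than 3 samples")
    # local linear baseline between the minimum intensities just outside the window
    left = inten[pos < lo]
    right = inten[pos > hi]
    left_anchor = float(left[-min(left.size, 5):].min()) if left.size else float(inten[inside][0])
    right_anchor = float(right[:min(right.size, 5)].min()) if right.size else float(inten[inside][-1])
    x = pos[inside]
    baseline = np.interp(x, [lo, hi], [left_anchor, right_anchor])
    y = np.clip(inten[inside] - baseline, 0.0, None)
    return float(np.trapezoid(y, x))


def band41_ratio(profile: LaneProfile) -> float:
    """Baseline-subtracted 4.1a / 4.1b band-area ratio.

    The ratio rises with mean red-cell age (spontaneous deamidation of
    protein 4.1a accrues over the cell's lifetime).  Invariant under overall
    intensity scaling and constant baseline offsets.
    """
    a = _band_integral(profile, profile.window_a)
    b = _band_integral(profile, profile.window_b)
    # a band carrying a negligible share of the summed signal is noise, not a band
    if b <= 0.0 or b < 1e-9 * (a + b):
        raise MeasurementError("band 4.1b integral is zero; ratio undefined")
    return a / b


def geo_mean_fluor(values) -> float:
    """Geometric mean of positive fluorescence values: exp(mean(log v))."""
    v = np.asarray(values, dtype=float)
    if v.size == 0 or np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise MeasurementError("all fluorescence values must be positive and finite")
    return float(np.exp(np.mean(np.log(v))))


def marker_ordering_check(samples: list[FractionSample]) -> dict[str, float]:
    """Fraction of donors satisfying each expected red-cell-age ordering.

    ``samples`` must contain L, M and H fractions for every donor.  Returns
    ``{ordering_name: pass_rate}`` over donors for each of the ten expected
    marker orderings.
    """
    by_donor: dict[str, dict[str, FractionSample]] = {}
    for s in samples:
        by_donor.setdefault(s.donor_id, {})[s.fraction] = s
    donors = sorted(by_donor)
    if not donors:
        raise PairingError("no samples given")
    for d in donors:
        missing = {"L", "M", "H"} - set(by_donor[d])
        if missing:
            raise PairingError(f"donor {d} lacks fractions {sorted(missing)}")
    report: dict[str, float] = {}
    for name, (marker, comparisons) in MARKER_ORDERINGS.items():
        ok = 0
        for d in donors:
            fr = by_donor[d]
            if all(fr[hi].markers[marker] > fr[lo].markers[marker] for hi, lo in comparisons):
                ok += 1
        report[name] = ok / len(donors)
    return report
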