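"""Per-cell morphometry from labelled segmentation masks.

Downstream of single-cell segmentation (which is external to this package),
each labelled component is reduced to a projected area and a sphericity.
Sphericity here is the minor/major axis ratio of the moment-equivalent
ellipse (1 = circular), matching the "shortest to longest diameter" notion
used for projected red-cell outlines.  A synthetic ellipse-mask generator
with exact per-cell ground truth serves as the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import regionprops

from .errors import PackingError, PairingError, ParameterError
from .stats import StatResult, paired_compare

__all__ = [
    "CellShape",
    "LabeledMask",
    "measure_cells",
    "area_histogram",
    "synth_mask",
    "compare_fraction_morphology",
]


@dataclass(frozen=True)
class CellShape:
    """One segmented cell: area (length units²), moment-ellipse axes, sphericity."""

    label: int
    area: float
    major_axis: float
    minor_axis: float
    sphericity: float       # minor_axis / major_axis, in (0, 1]
    centroid: tuple[float, float]  # (row, col) pixels
    touches_border: bool = False


@dataclass
class LabeledMask:
    """Integer raster: 0 = background, k >= 1 = cell k.  pixel_size in um/px."""

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or not np.issubdtype(self.pixels.dtype, np.integer):
            raise ParameterError("mask must be a 2-D integer raster")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be > 0")


def measure_cells(mask: LabeledMask, min_area_px: int = 50) -> list[CellShape]:
    """Measure every labelled component of a mask.

    Area is pixel count x pixel_size²; the axes come from the eigenvalues of
    the second central moments (axis length = 4 sqrt(eigenvalue)).
    Components below ``min_area_px`` pixels are dropped; cells touching the
    image border are flagged (aggregate helpers exclude them by default,
    since truncated outlines bias areas and axis ratios).
    """
    if not isinstance(mask, LabeledMask):
        mask = LabeledMask(np.asarray(mask))
    px = mask.pixels
    h, w = px.shape
    out: list[CellShape] = []
    n_dropped = 0
    for rp in regionprops(px):
        if rp.area < min_area_px:
            n_dropped += 1
            continue
        minr, minc, maxr, maxc = rp.bbox
        border = minr == 0 or minc == 0 or maxr == h or maxc == w
        major = rp.axis_major_length * mask.pixel_size
        minor = rp.axis_minor_length * mask.pixel_size
        out.append(CellShape(
            label=int(rp.label),
            area=float(rp.area) * mask.pixel_size**2,
            major_axis=float(major),
            minor_axis=float(minor),
            sphericity=float(minor / major) if major > 0 else 1.0,
            centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            touches_border=bool(border),
        ))
    return out


def area_histogram(shapes: list[CellShape], binwidth: float = 500.0) -> tuple[np.ndarray, np.ndarray]:
    """Projected-area histogram with left-closed bins [k*binwidth, (k+1)*binwidth).

    Returns (edges, counts); counts sum to the number of shapes.
    """
    if binwidth <= 0:
        raise ParameterError("binwidth must be > 0")
    if not shapes:
        raise ParameterError("shapes must be non-empty")
    areas = np.array([s.area for s in shapes])
    n_bins = int(np.floor(areas.max() / binwidth)) + 1
    edges = np.arange(n_bins + 1) * binwidth
    counts = np.zeros(n_bins, dtype=int)
    idx = np.minimum((areas // binwidth).astype(int), n_bins - 1)
    np.add.at(counts, idx, 1)
    return edges, counts


def _rasterize_ellipse(shape, cy, cx, a, b, theta):
    """Boolean raster of a rotated ellipse with semi-axes (a, b)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def synth_mask(
    n_cells: int,
    area_dist=None,
    sphericity_dist=None,
    image_shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    pixel_size: float = 1.0,
    max_attempts_per_cell: int = 200,
) -> tuple[LabeledMask, list[dict]]:
    """Pack non-overlapping rotated ellipses into a labelled mask.

    ``area_dist`` and ``sphericity_dist`` are scipy frozen distributions (or
    anything with ``rvs(random_state=...)``); defaults are uniform areas in
    [600, 1400] px² and axis ratios in [0.5, 0.95].  Returns the mask and a
    per-cell ground-truth list with the analytic area, semi-axes, axis
    ratio, orientation and centre.  Raises PackingError if the requested
    total area exceeds 40% of the image or placement fails.
    """
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    if area_dist is None:
        area_dist = sps.uniform(600.0, 800.0)
    if sphericity_dist is None:
        sphericity_dist = sps.uniform(0.5, 0.45)
    h, w = image_shape
    px = np.zeros((h, w), dtype=np.int32)
    truth: list[dict] = []
    budget = 0.4 * h * w
    total = 0.0
    for label in range(1, n_cells + 1):
        area = float(area_dist.rvs(random_state=rng))
        s = float(np.clip(sphericity_dist.rvs(random_state=rng), 0.05, 1.0))
        total += area
        if total > budget:
            raise PackingError(
                f"requested total cell area exceeds 40% of a {h}x{w} image; use a larger image"
            )
        a = np.sqrt(area / (np.pi * s))  # major semi-axis, px
        b = s * a
        placed = False
        for _ in range(max_attempts_per_cell):
            theta = rng.uniform(0.0, np.pi)
            margin = a + 2.0
            if 2 * margin >= min(h, w):
                break
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            ell = _rasterize_ellipse((h, w), cy, cx, a, b, theta)
            # one-pixel clearance keeps neighbouring labels from touching
            grown = _rasterize_ellipse((h, w), cy, cx, a + 1.5, b + 1.5, theta)
            if not np.any(px[grown]):
                px[ell] = label
                truth.append({
                    "label": label, "area": area * pixel_size**2, "sphericity": s,
                    "semi_major": a * pixel_size, "semi_minor": b * pixel_size,
                    "theta": theta, "center": (cy, cx),
                })
                placed = True
                break
        if not placed:
            raise PackingError(
                f"could not place cell {label} after {max_attempts_per_cell} attempts; use a larger image"
            )
    return LabeledMask(px, pixel_size=pixel_size), truth


def compare_fraction_morphology(
    shape_sets: dict[str, list[list[CellShape]]], alpha: float = 0.05
) -> dict[tuple[str, str, str], StatResult]:
    """Gated paired comparison of per-donor mean area and sphericity.

    ``shape_sets[fraction][donor]`` is that donor's list of CellShape for
    the fraction; donor lists must be aligned (same donors, same order)
    across fractions.  Border-touching cells are excluded from the
    aggregates.  Returns ``{(metric, frac_a, frac_b): StatResult}`` for all
    fraction pairs, estimates oriented as a - b.
    """
    labels = list(shape_sets)
    if len(labels) < 2:
        raise PairingError("need at least 2 fractions to compare")
    n_donors = {lab: len(shape_sets[lab]) for lab in labels}
    if len(set(n_donors.values())) != 1:
        raise PairingError(f"fractions have unequal donor counts: {n_donors}")

    def agg(cells: list[CellShape], attr: str) -> float:
        vals = [getattr(c, attr) for c in cells if not c.touches_border]
        if not vals:
            raise PairingError("a donor has no interior cells in one fraction")
        return float(np.mean(vals))

    results: dict[tuple[str, str, str], StatResult] = {}
    for metric in ("area", "sphericity"):
        per = {lab: np.array([agg(cells, metric) for cells in shape_sets[lab]]) for lab in labels}
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                results[(metric, a, b)] = paired_compare(per[a], per[b], alpha=alpha)
    return results
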