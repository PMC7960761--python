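"""File dialects and run configuration.

Curve CSV dialect::

    # sample_id=D001
    # fraction=WB
    # shear_stress_Pa=30.0
    # temperature_C=37.0
    osmolality_mOsm_kg,EI
    50.0,0.0012
    ...

The writer emits exactly this layout; the reader tolerates missing metadata
lines (defaults applied with a logged warning) but rejects malformed headers
and non-numeric cells with the offending line number.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import yaml

from .cohort import CohortConfig
from .curves import OsmoscanCurve
from .errors import FormatError, ParameterError
from .indices import ExtractionConfig

logger = logging.getLogger("osmoscan")

__all__ = ["read_curve_csv", "write_curve_csv", "RunConfig"]

_META_FIELDS = {
    "sample_id": str,
    "fraction": str,
    "shear_stress_Pa": float,
    "temperature_C": float,
}
_HEADER = "osmolality_mOsm_kg,EI"


def write_curve_csv(curve: OsmoscanCurve, path) -> None:
    """Write a curve in the package CSV dialect (bit-exact layout)."""
    path = Path(path)
    lines = [
        f"# sample_id={curve.sample_id}",
        f"# fraction={curve.fraction}",
        f"# shear_stress_Pa={curve.shear_stress_Pa!r}",
        f"# temperature_C={curve.temperature_C!r}",
        _HEADER,
    ]
    lines += [f"{float(o)!r},{float(e)!r}" for o, e in zip(curve.osmolality, curve.ei)]
    path.write_text("\n".join(lines) + "\n")


def read_curve_csv(path) -> OsmoscanCurve:
    """Read a curve CSV; round-trips ``write_curve_csv`` bit-for-bit."""
    path = Path(path)
    meta: dict = {}
    osm: list[float] = []
    ei: list[float] = []
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" not in body:
                raise FormatError(f"metadata line without '=': {line!r}", line=lineno)
            key, _, value = body.partition("=")
            key = key.strip()
            if key not in _META_FIELDS:
                raise FormatError(f"unknown metadata key {key!r}", line=lineno)
            try:
                meta[key] = _META_FIELDS[key](value.strip())
            except ValueError:
                raise FormatError(f"bad value for {key!r}: {value!r}", line=lineno) from None
            continue
        if not header_seen:
            cols = [c.strip() for c in line.split(",")]
            if cols != _HEADER.split(","):
                raise FormatError(f"expected header {_HEADER!r}, got {line!r}", line=lineno)
            header_seen = True
            continue
        cells = line.split(",")
        if len(cells) != 2:
            raise FormatError(f"expected 2 columns, got {len(cells)}", line=lineno)
        try:
            osm.append(float(cells[0]))
            ei.append(float(cells[1]))
        except ValueError:
            raise FormatError(f"non-numeric cell in {line!r}", line=lineno) from None
    if not header_seen:
        raise FormatError(f"{path}: no '{_HEADER}' header found")
    missing = set(_META_FIELDS) - set(meta)
    if missing:
        logger.warning("%s: missing metadata %s; defaults applied", path, sorted(missing))
    return OsmoscanCurve(np.array(osm), np.array(ei), **meta)


@dataclasses.dataclass
class RunConfig:
    """End-to-end pipeline configuration; every field has a documented default.

    extraction  : index-extraction settings (ExtractionConfig).
    cohort      : synthetic-cohort settings (CohortConfig).
    alpha       : significance / normality-gate level.
    ri_lo_q, ri_hi_q, ri_min_n : reference-interval quantiles and the
                  minimum stratum size.
    pixel_size, min_area_px, binwidth : morphometry settings (um/px, px, um²).
    seed        : single global seed; stages draw named substreams from it.
    out_dir     : output directory for tables and the manifest.
    """

    extraction: ExtractionConfig = dataclasses.field(default_factory=ExtractionConfig)
    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    alpha: float = 0.05
    ri_lo_q: float = 0.025
    ri_hi_q: float = 0.975
    ri_min_n: int = 20
    pixel_size: float = 1.0
    min_area_px: int = 50
    binwidth: float = 500.0
    seed: int = 0
    out_dir: str = "osmoscan_out"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        kwargs = {}
        for sub_name, sub_cls in (("extraction", ExtractionConfig), ("cohort", CohortConfig)):
            sub = data.pop(sub_name, {})
            if isinstance(sub, dict):
                known = {f.name for f in dataclasses.fields(sub_cls)}
                unknown = set(sub) - known
                if unknown:
                    raise ParameterError(f"unknown {sub_name} config key(s): {sorted(unknown)}")
                kwargs[sub_name] = sub_cls(**sub)
            else:
                kwargs[sub_name] = sub
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**kwargs, **data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise FormatError(f"{path}: config must be a mapping")
        return cls.from_dict(data)
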