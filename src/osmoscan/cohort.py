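"""Synthetic donor cohorts, whole-blood indices, and density-fraction panels.

The generator emulates the statistical structure of a healthy-donor study:

* a 45-donor cohort (28 women aged 18-61, 17 men aged 23-51) with red-cell
  indices drawn from published-calibration normals (haemoglobin and
  haematocrit gender-specific; MCV, MCHC and RDW shared);
* a positive age effect on O_hyper, a positive O_hyper-RDW residual
  correlation, and a positive coupling between O_hyper and red-cell water
  fraction (water fraction itself negatively coupled to MCHC, which is
  inversely related to cell hydration);
* Percoll density fractions L/M/H (enriched in young, mature, senescent
  cells) whose Lorrca-index offsets reproduce the qualitative fraction
  profile, plus a mock-centrifugation sample (WBP) with the handling
  artifact: a rightward swelling shift of O_min and O_hyper only;
* a flow-cytometry / densitometry marker panel per fraction, log-normal
  around fraction-specific geometric means, whose expected values satisfy
  the ten red-cell-age marker orderings (band 4.1a:b ratio rising with
  density; reticulocyte and CD71 positivity, oxidant (DHR) and NO (DAF)
  production maximal in the youngest fraction; EMA, forward scatter and
  reduced thiols (mBBr, ThiolTracker) declining with density; side scatter
  maximal in the densest fraction; NO in H exceeding M).

Only orderings and the published cohort table constrain the defaults;
absolute marker levels are implementation constants in arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .curves import FRACTIONS, OsmoscanCurve, preset_params, synth_curve, true_indices
from .errors import ParameterError
from .indices import INDEX_NAMES, LorrcaIndices

__all__ = [
    "DonorRecord",
    "CohortConfig",
    "FractionSample",
    "STUDY_CALIBRATION",
    "MARKER_NAMES",
    "MARKER_ORDERINGS",
    "simulate_cohort",
    "replica_cohort",
    "simulate_fractions",
    "simulate_donor_curves",
    "default_fraction_offsets",
]

#: Default calibration of the replica cohort: (mean, sd) of each red-cell
#: index, plus the study composition (counts and age ranges per gender).
STUDY_CALIBRATION = {
    "n_female": 28,
    "n_male": 17,
    "age_range_female": (18.0, 61.0),
    "age_range_male": (23.0, 51.0),
    "hb_female": (136.6, 7.67),   # g/L
    "hb_male": (151.5, 8.92),
    "hct_female": (41.4, 2.69),   # %
    "hct_male": (46.2, 3.07),
    "mcv": (89.6, 2.58),          # fL
    "mchc": (334.0, 11.9),        # g/L
    "rdw": (13.2, 0.51),          # %
}

MARKER_NAMES = (
    "ratio_41ab", "retic_pct", "cd71_pct", "ema_gmean", "fs_gmean",
    "ss_gmean", "mbbr_gmean", "thiol_gmean", "dhr_gmean", "daf_gmean",
)

# Fraction-specific geometric means; adjacent log-gaps are wide relative to
# the default log-scale noise so every ordering also holds per donor.
_MARKER_GMEANS = {
    #            L      M      H
    "ratio_41ab": (0.45, 0.65, 0.95),
    "retic_pct": (4.0, 0.8, 0.5),
    "cd71_pct": (1.5, 0.3, 0.2),
    "ema_gmean": (100.0, 84.0, 70.0),
    "fs_gmean": (540.0, 460.0, 390.0),
    "ss_gmean": (100.0, 95.0, 130.0),
    "mbbr_gmean": (210.0, 170.0, 135.0),
    "thiol_gmean": (160.0, 130.0, 105.0),
    "dhr_gmean": (85.0, 55.0, 45.0),
    "daf_gmean": (90.0, 50.0, 65.0),
}

#: The ten expected marker orderings, each as (marker, pairwise greater-than
#: comparisons over fraction labels).
MARKER_ORDERINGS: dict[str, tuple[str, tuple[tuple[str, str], ...]]] = {
    "ratio_41ab L<M<H": ("ratio_41ab", (("M", "L"), ("H", "M"))),
    "retic_pct max in L": ("retic_pct", (("L", "M"), ("L", "H"))),
    "cd71_pct max in L": ("cd71_pct", (("L", "M"), ("L", "H"))),
    "ema decreasing L>M>H": ("ema_gmean", (("L", "M"), ("M", "H"))),
    "fs decreasing L>M>H": ("fs_gmean", (("L", "M"), ("M", "H"))),
    "ss max in H": ("ss_gmean", (("H", "L"), ("H", "M"))),
    "mbbr decreasing L>M>H": ("mbbr_gmean", (("L", "M"), ("M", "H"))),
    "thiol decreasing L>M>H": ("thiol_gmean", (("L", "M"), ("M", "H"))),
    "dhr max in L": ("dhr_gmean", (("L", "M"), ("L", "H"))),
    "daf L>H>M": ("daf_gmean", (("L", "H"), ("H", "M"))),
}


@dataclass
class DonorRecord:
    """One healthy donor: demographics, red-cell indices, latent hydration."""

    donor_id: str
    age: float            # years
    gender: str           # "F" or "M"
    hb: float             # g/L
    hct: float            # %
    mcv: float            # fL
    mchc: float           # g/L
    rdw: float            # %
    hypochromic_pct: float
    water_fraction: float  # dimensionless, in (0.55, 0.75)

    def validate(self) -> None:
        if self.gender not in ("F", "M"):
            raise ParameterError(f"gender must be F or M, got {self.gender!r}")
        if not 18.0 <= self.age <= 75.0:
            raise ParameterError(f"age {self.age} outside [18, 75]")
        if self.hb <= 0 or not 20.0 < self.hct < 60.0 or self.rdw <= 0:
            raise ParameterError("hb, hct or rdw out of range")
        if not 0.55 < self.water_fraction < 0.75:
            raise ParameterError(f"water_fraction {self.water_fraction} outside (0.55, 0.75)")


def default_fraction_offsets() -> dict[str, dict[str, float]]:
    """Additive per-index shifts of each fraction relative to whole blood.

    Derived from the curve presets, so the cohort generator and the curve
    generator encode the same phenotypes.
    """
    wb = true_indices(preset_params("WB"))
    out: dict[str, dict[str, float]] = {}
    for label in ("L", "M", "H"):
        tr = true_indices(preset_params(label))
        out[label] = {k: getattr(tr, k) - getattr(wb, k) for k in INDEX_NAMES}
    return out


@dataclass
class CohortConfig:
    """Generating parameters of the synthetic cohort.

    O_hyper model: ``O_hyper = intercept + beta_age*age +
    beta_water*(water_fraction - water_mean) + sigma_ohyper*eps`` with
    ``corr(eps, RDW) = rho_rdw``, so O_hyper rises with donor age and shares
    a positive residual association with RDW.  ``beta_age`` defaults to a
    positive value (direction inferred from the reported upward trend).
    """

    n_female: int = STUDY_CALIBRATION["n_female"]
    n_male: int = STUDY_CALIBRATION["n_male"]
    age_range_female: tuple[float, float] = STUDY_CALIBRATION["age_range_female"]
    age_range_male: tuple[float, float] = STUDY_CALIBRATION["age_range_male"]
    hb_female: tuple[float, float] = STUDY_CALIBRATION["hb_female"]
    hb_male: tuple[float, float] = STUDY_CALIBRATION["hb_male"]
    hct_female: tuple[float, float] = STUDY_CALIBRATION["hct_female"]
    hct_male: tuple[float, float] = STUDY_CALIBRATION["hct_male"]
    mcv: tuple[float, float] = STUDY_CALIBRATION["mcv"]
    mchc: tuple[float, float] = STUDY_CALIBRATION["mchc"]
    rdw: tuple[float, float] = STUDY_CALIBRATION["rdw"]
    beta_age: float = 0.3          # mOsm/kg per year on O_hyper
    beta_water: float = 300.0      # mOsm/kg per unit water fraction
    rho_rdw: float = 0.5           # corr(RDW, O_hyper residual)
    sigma_ohyper: float = 8.0      # mOsm/kg
    ohyper_intercept: float = 448.4  # centres O_hyper near the WB preset at the mean age
    water_mean: float = 0.65
    water_sd: float = 0.008
    water_mchc_slope: float = -0.0009  # water fraction per g/L MCHC
    index_noise_osm: float = 2.0   # sd of donor-level noise on osmolality indices
    index_noise_ei: float = 0.008  # sd on EI indices
    area_sd: float = 3.0
    fraction_offsets: dict = field(default_factory=default_fraction_offsets)
    percoll_shift: float = 15.0    # mOsm/kg added to O_min and O_hyper for WBP
    marker_sigma_log: float = 0.04
    seed: int = 0

    def validate(self) -> None:
        if self.n_female < 0 or self.n_male < 0:
            raise ParameterError("donor counts must be >= 0")
        if self.n_female + self.n_male == 0:
            raise ParameterError("empty cohort: n_female and n_male are both 0")
        for name in ("hb_female", "hb_male", "hct_female", "hct_male", "mcv", "mchc", "rdw"):
            if getattr(self, name)[1] <= 0:
                raise ParameterError(f"{name} sd must be > 0")
        if not -1.0 < self.rho_rdw < 1.0:
            raise ParameterError("rho_rdw must be in (-1, 1)")
        if self.sigma_ohyper < 0 or self.water_sd < 0:
            raise ParameterError("sigma_ohyper and water_sd must be >= 0")


@dataclass
class FractionSample:
    """One fraction of one donor: Lorrca indices plus the marker panel."""

    donor_id: str
    fraction: str
    indices: LorrcaIndices
    markers: dict[str, float]

    def validate(self) -> None:
        if self.fraction not in FRACTIONS:
            raise ParameterError(f"fraction must be one of {FRACTIONS}")
        if any(v <= 0 for v in self.markers.values()):
            raise ParameterError("marker values must be > 0")
        if not 0.0 <= self.markers.get("retic_pct", 0.0) <= 100.0:
            raise ParameterError("retic_pct must be in [0, 100]")


def _draw_donors(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    groups = [("F", config.n_female, config.age_range_female, config.hb_female, config.hct_female),
            ("M", config.n_male, config.age_range_male, config.hb_male, config.hct_male)]
    i = 0
    for gender, n, age_rng, hb_ms, hct_ms in groups:
        for _ in range(n):
            i += 1
            age = rng.uniform(*age_rng)
            mchc = rng.normal(*config.mchc)
            water = (
                config.water_mean
                + config.water_mchc_slope * (mchc - config.mchc[0])
                + rng.normal(0.0, config.water_sd)
            )
            water = float(np.clip(water, 0.551, 0.749))
            rows.append({
                "donor_id": f"D{i:03d}",
                "age": age,
                "gender": gender,
                "hb": rng.normal(*hb_ms),
                "hct": rng.normal(*hct_ms),
                "mcv": rng.normal(*config.mcv),
                "mchc": mchc,
                "hypochromic_pct": rng.uniform(0.0, 4.9),
                "water_fraction": water,
            })
    return pd.DataFrame(rows)


def simulate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Simulate donors and their whole-blood Lorrca indices.

    Returns one row per donor with demographic columns, red-cell indices,
    and the seven whole-blood osmoscan indices.  RDW is drawn jointly with
    the O_hyper residual (correlation ``rho_rdw``) so the marginal RDW
    distribution keeps its calibrated mean and sd.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    df = _draw_donors(config, rng)
    n = len(df)

    # bivariate standard normals: z1 drives the O_hyper residual, z2 the RDW
    z1 = rng.normal(size=n)
    z2 = config.rho_rdw * z1 + np.sqrt(1.0 - config.rho_rdw**2) * rng.normal(size=n)
    df["rdw"] = config.rdw[0] + config.rdw[1] * z2
    df["o_hyper"] = (
        config.ohyper_intercept
        + config.beta_age * df["age"].to_numpy()
        + config.beta_water * (df["water_fraction"].to_numpy() - config.water_mean)
        + config.sigma_ohyper * z1
    )

    wb = true_indices(preset_params("WB"))
    df["o_min"] = wb.o_min + rng.normal(0.0, config.index_noise_osm, n)
    df["o_eimax"] = wb.o_eimax + rng.normal(0.0, config.index_noise_osm, n)
    df["ei_min"] = wb.ei_min + rng.normal(0.0, config.index_noise_ei, n)
    df["ei_max"] = wb.ei_max + rng.normal(0.0, config.index_noise_ei, n)
    df["ei_hyper"] = df["ei_max"] / 2.0
    df["area"] = wb.area + rng.normal(0.0, config.area_sd, n)
    cols = ["donor_id", "age", "gender", "hb", "hct", "mcv", "mchc", "rdw",
            "hypochromic_pct", "water_fraction", *INDEX_NAMES]
    return df[cols]


def replica_cohort(seed: int = 0) -> pd.DataFrame:
    """A 45-donor replica of the study cohort (28 F aged 18-61, 17 M 23-51).

    Red-cell indices follow the calibration normals; every donor passes the
    <5% hypochromic-RBC quality gate by construction.  Returns the donor
    table only (no osmoscan indices).
    """
    cfg = CohortConfig(seed=seed)
    df = simulate_cohort(cfg)
    return df[["donor_id", "age", "gender", "hb", "hct", "mcv", "mchc", "rdw",
               "hypochromic_pct", "water_fraction"]]


def _donor_wb_indices(donor: DonorRecord, config: CohortConfig, rng: np.random.Generator) -> dict[str, float]:
    wb = true_indices(preset_params("WB"))
    o_hyper = (
        config.ohyper_intercept
        + config.beta_age * donor.age
        + config.beta_water * (donor.water_fraction - config.water_mean)
        + config.sigma_ohyper * rng.normal()
    )
    return {
        "o_min": wb.o_min + rng.normal(0.0, config.index_noise_osm),
        "ei_min": wb.ei_min + rng.normal(0.0, config.index_noise_ei),
        "o_eimax": wb.o_eimax + rng.normal(0.0, config.index_noise_osm),
        "ei_max": wb.ei_max + rng.normal(0.0, config.index_noise_ei),
        "o_hyper": o_hyper,
        "area": wb.area + rng.normal(0.0, config.area_sd),
    }


def _indices_from_dict(d: dict[str, float]) -> LorrcaIndices:
    return LorrcaIndices(
        o_min=d["o_min"], ei_min=d["ei_min"], o_eimax=d["o_eimax"], ei_max=d["ei_max"],
        o_hyper=d["o_hyper"], ei_hyper=d["ei_max"] / 2.0, area=d["area"],
        qc_flags=frozenset(),
    )


def _draw_markers(label: str, config: CohortConfig, rng: np.random.Generator) -> dict[str, float]:
    col = {"L": 0, "M": 1, "H": 2}.get(label)
    out = {}
    for name in MARKER_NAMES:
        gms = _MARKER_GMEANS[name]
        gm = gms[1] if col is None else gms[col]  # WB/WBP behave like the bulk M fraction
        out[name] = float(gm * np.exp(rng.normal(0.0, config.marker_sigma_log)))
    out["retic_pct"] = min(out["retic_pct"], 100.0)
    return out


def simulate_fractions(
    donor: DonorRecord, config: CohortConfig | None = None, rng: np.random.Generator | None = None
) -> list[FractionSample]:
    """Emit WB, WBP, L, M and H samples for one donor.

    WBP carries the centrifugation artifact only (+``percoll_shift`` on
    O_min and O_hyper); L/M/H indices are the donor's whole-blood indices
    plus the fraction offsets plus small independent noise; the marker
    panel is log-normal around fraction-specific geometric means.
    """
    config = config or CohortConfig()
    config.validate()
    donor.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    wb = _donor_wb_indices(donor, config, rng)
    samples = [FractionSample(donor.donor_id, "WB", _indices_from_dict(wb), _draw_markers("WB", config, rng))]

    wbp = dict(wb)
    wbp["o_min"] += config.percoll_shift
    wbp["o_hyper"] += config.percoll_shift
    samples.append(FractionSample(donor.donor_id, "WBP", _indices_from_dict(wbp), _draw_markers("WBP", config, rng)))

    for label in ("L", "M", "H"):
        off = config.fraction_offsets[label]
        d = {}
        for k in ("o_min", "o_eimax", "o_hyper"):
            d[k] = wb[k] + off[k] + rng.normal(0.0, config.index_noise_osm * 0.75)
        for k in ("ei_min", "ei_max"):
            d[k] = wb[k] + off[k] + rng.normal(0.0, config.index_noise_ei * 0.75)
        d["area"] = wb["area"] + off["area"] + rng.normal(0.0, config.area_sd * 0.75)
        samples.append(FractionSample(donor.donor_id, label, _indices_from_dict(d), _draw_markers(label, config, rng)))
    return samples


def simulate_donor_curves(
    config: CohortConfig | None = None,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.0,
    grid_step: float = 1.0,
    wb_anchors: dict[str, float] | None = None,
) -> dict[str, tuple[OsmoscanCurve, LorrcaIndices]]:
    """Synthesize one donor's WB/WBP/L/M/H osmoscan curves.

    The donor's whole-blood anchors are the WB preset plus shared jitter, or
    ``wb_anchors`` (keys among o_min, ei_min, o_eimax, ei_max, o_hyper) when
    the caller already has donor-level indices, e.g. from a cohort table;
    each density fraction adds its preset offsets plus smaller independent
    jitter, and WBP adds the centrifugation shift to O_min and O_hyper only.
    Returns ``{label: (curve, ground_truth_indices)}``.
    """
    config = config or CohortConfig()
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    wb_pp = preset_params("WB")
    anchors = {
        "o_min": wb_pp.o_min_true, "o_eimax": wb_pp.o_eimax_true, "o_hyper": wb_pp.o_hyper_true,
        "ei_min": wb_pp.ei_min_true, "ei_max": wb_pp.ei_max_true,
    }
    donor_josm = rng.normal(0.0, config.index_noise_osm, 3)   # o_min, o_eimax, o_hyper
    donor_jei = rng.normal(0.0, config.index_noise_ei, 2)     # ei_min, ei_max
    anchors["o_min"] += donor_josm[0]
    anchors["o_eimax"] += donor_josm[1]
    anchors["o_hyper"] += donor_josm[2]
    anchors["ei_min"] += donor_jei[0]
    anchors["ei_max"] += donor_jei[1]
    if wb_anchors:
        anchors.update(wb_anchors)
    out: dict[str, tuple[OsmoscanCurve, LorrcaIndices]] = {}
    for label in FRACTIONS:
        pp = preset_params(label)
        if label == "WBP":
            off = {"o_min": config.percoll_shift, "o_eimax": 0.0, "o_hyper": config.percoll_shift,
                   "ei_min": 0.0, "ei_max": 0.0}
        else:
            off = {k: getattr(pp, f"{k}_true") - getattr(wb_pp, f"{k}_true")
                   for k in ("o_min", "o_eimax", "o_hyper", "ei_min", "ei_max")}
        if label in ("L", "M", "H"):
            josm = rng.normal(0.0, config.index_noise_osm * 0.75, 3)
            jei = rng.normal(0.0, config.index_noise_ei * 0.75, 2)
        else:
            josm = np.zeros(3)
            jei = np.zeros(2)
        seed = int(rng.integers(0, 2**31 - 1))
        for attempt in range(10):  # rare jitter draws can break anchor ordering; retry
            params = replace(
                pp,
                o_min_true=anchors["o_min"] + off["o_min"] + josm[0],
                o_eimax_true=anchors["o_eimax"] + off["o_eimax"] + josm[1],
                o_hyper_true=min(anchors["o_hyper"] + off["o_hyper"] + josm[2], 495.0),
                ei_min_true=anchors["ei_min"] + off["ei_min"] + jei[0],
                ei_max_true=anchors["ei_max"] + off["ei_max"] + jei[1],
                noise_sd=noise_sd,
                grid_step=grid_step,
                seed=seed,
            )
            try:
                params.validate()
                break
            except ParameterError:
                josm = rng.normal(0.0, config.index_noise_osm, 3)
                jei = rng.normal(0.0, config.index_noise_ei, 2)
        else:
            params.validate()
        out[label] = synth_curve(params, sample_id=f"{label}", fraction=label)
    return out


def fractions_to_frame(samples: list[FractionSample]) -> pd.DataFrame:
    """Flatten FractionSample records into a tidy table."""
    rows = []
    for s in samples:
        row = {"donor_id": s.donor_id, "fraction": s.fraction}
        row.update({k: getattr(s.indices, k) for k in INDEX_NAMES})
        row.update(s.markers)
        rows.append(row)
    return pd.DataFrame(rows)
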