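"""End-to-end reproduction pipeline: simulate -> extract -> analyse.

``run_pipeline`` generates a replica cohort with per-donor osmoscan curves,
extracts the Lorrca indices from the curves, applies the hypochromic-RBC
quality gate, fits index ~ age + gender linear models, runs the gated
paired fraction comparisons (all L/M/H pairs and WB vs WBP), and computes
age-decade reference intervals for O_hyper.  All outputs are written as CSV
or JSON plus a manifest; the run is byte-reproducible from the single seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._rng import substream
from .cohort import simulate_cohort, simulate_donor_curves
from .errors import OsmoscanError
from .indices import INDEX_NAMES, extract_indices
from .io import RunConfig, write_curve_csv
from .stats import fit_index_model, paired_compare, qc_filter, reference_interval

__all__ = ["run_pipeline"]

_OSM_INDICES = ("o_min", "ei_min", "o_eimax", "ei_max", "o_hyper", "ei_hyper", "area")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except OsmoscanError as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc
        return inner
    return wrap


def _age_decade(age: float) -> str:
    lo = int(age // 10) * 10
    return f"{lo}-{lo + 9}"


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Run the full synthetic study and return the output manifest."""
    config = config or RunConfig()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "outputs": {},
        "qc": {},
        "substreams": ["cohort", "curves"],
    }

    # --- cohort with whole-blood indices ------------------------------------
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
    # the cohort table draws from the 'cohort' substream of the global seed
    cohort_seed = int(substream(config.seed, "cohort").integers(0, 2**31 - 1))
    cohort = _stage("simulate-cohort")(simulate_cohort)(cohort_cfg, seed=cohort_seed)
    if len(cohort) == 0:
        raise OsmoscanError("empty cohort")
    cohort_path = out_dir / "cohort.csv"
    cohort.to_csv(cohort_path, index=False)
    manifest["outputs"]["cohort"] = cohort_path.name

    # --- per-donor curves for every fraction, index extraction --------------
    curve_rng = substream(config.seed, "curves")
    frac_rows = []
    curves_dir = out_dir / "curves"
    curves_dir.mkdir(exist_ok=True)
    for _, donor_row in cohort.iterrows():
        donor_id = donor_row["donor_id"]
        wb_anchors = {k: float(donor_row[k]) for k in ("o_min", "ei_min", "o_eimax", "ei_max", "o_hyper")}
        curve_set = simulate_donor_curves(cohort_cfg, rng=curve_rng, noise_sd=0.003, wb_anchors=wb_anchors)
        for label, (curve, _truth) in curve_set.items():
            curve.sample_id = str(donor_id)
            extracted = _stage("extract")(extract_indices)(curve, config.extraction)
            row = {"donor_id": donor_id, "fraction": label, "qc_flags": ";".join(sorted(extracted.qc_flags))}
            row.update({k: getattr(extracted, k) for k in INDEX_NAMES})
            frac_rows.append(row)
            if label == "WB":
                write_curve_csv(curve, curves_dir / f"{donor_id}_WB.csv")
    fractions = pd.DataFrame(frac_rows)
    frac_path = out_dir / "fraction_indices.csv"
    fractions.to_csv(frac_path, index=False)
    manifest["outputs"]["fraction_indices"] = frac_path.name

    # --- QC gate ------------------------------------------------------------
    kept, dropped = _stage("qc-filter")(qc_filter)(cohort)
    manifest["qc"]["dropped_hypochromic"] = dropped

    # --- linear models: each index ~ age + gender ---------------------------
    models = {}
    for index_name in _OSM_INDICES:
        coefs, overall = _stage("fit-index-model")(fit_index_model)(kept, index_name)
        models[index_name] = {
            "coefficients": [c.to_dict() for c in coefs],
            "anova_F": overall.to_dict(),
        }
    models_path = out_dir / "index_models.json"
    models_path.write_text(json.dumps(models, indent=2, sort_keys=True) + "\n")
    manifest["outputs"]["index_models"] = models_path.name

    # --- paired fraction comparisons ----------------------------------------
    wide = fractions.pivot(index="donor_id", columns="fraction")
    comparisons = {}
    pairs = [("L", "M"), ("M", "H"), ("L", "H"), ("WB", "WBP")]
    for index_name in _OSM_INDICES:
        for a, b in pairs:
            x = wide[(index_name, a)].to_numpy(dtype=float)
            y = wide[(index_name, b)].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            res = _stage("compare-fractions")(paired_compare)(x[ok], y[ok], alpha=config.alpha)
            comparisons[f"{index_name}:{a}-{b}"] = res.to_dict()
    comp_path = out_dir / "fraction_comparisons.json"
    comp_path.write_text(json.dumps(comparisons, indent=2, sort_keys=True) + "\n")
    manifest["outputs"]["fraction_comparisons"] = comp_path.name

    # --- age-decade reference intervals for O_hyper -------------------------
    strata = kept["age"].map(_age_decade).to_numpy()
    # a pilot-sized cohort has small decades; report them with LOW_N flags
    ris = _stage("reference-intervals")(reference_interval)(
        kept["o_hyper"].to_numpy(), strata, config.ri_lo_q, config.ri_hi_q, config.ri_min_n
    )
    ri_path = out_dir / "reference_intervals.json"
    ri_path.write_text(json.dumps([dataclasses.asdict(r) for r in sorted(ris, key=lambda r: r.stratum)],
                                  indent=2) + "\n")
    manifest["outputs"]["reference_intervals"] = ri_path.name

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
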