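"""End-to-end orchestration: population -> drug scans -> fits -> verdicts.

Per-compound failures are isolated: the run continues and the summary lists
what failed. All artefacts carry the seed and a configuration digest so a
run is reproducible bit-for-bit (MCMC summaries up to Monte-Carlo error).
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import classification, dose_response, drug_block, population
from .errors import InosimError
from .io import (
    RunConfig,
    load_calibration_ranges,
    load_compound_panel,
    load_mechanism_config,
    write_json,
)
from .mechanisms import mechanism_report
from .surrogate import get_backend


def build_population(config: RunConfig):
    """Sample, calibrate and return the population; writes nothing."""
    backend = get_backend(config.backend)
    spec = config.population
    ranges = (spec.calibration_ranges
              or load_calibration_ranges(config.calibration_path))
    models = population.sample_population(spec)
    return population.calibrate(models, ranges, backend, config.simulation,
                                provenance=config.provenance())


def scan_compound(pop, compound, config: RunConfig, control_at=None):
    backend = get_backend(config.backend)
    table = drug_block.scan_concentrations(
        pop.models, compound, backend, config.simulation,
        model_ids=pop.model_ids, control_at=control_at)
    return drug_block.extend_grid_if_needed(
        table, compound, pop.models, backend, config.simulation,
        model_ids=pop.model_ids, control_at=control_at)


def fit_compound(table, config: RunConfig) -> dict:
    out: dict = {"compound": table.compound}
    if config.fit_method in ("median", "both"):
        fit = dose_response.fit_median(table)
        out["median"] = dose_response.ic50_summary(fit)
    if config.fit_method in ("bayes", "both"):
        mcmc = dose_response.McmcConfig(seed=config.seed, **config.mcmc)
        fit = dose_response.fit_bayes(table, mcmc)
        out["bayes"] = dose_response.ic50_summary(fit)
        out["bayes"]["rhat"] = fit.rhat
        out["bayes"]["warnings"] = fit.warnings
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute build-population -> scan -> extend -> fit -> classify -> report.

    Returns a result bundle (also written under ``config.output_dir``):
    population provenance, per-compound verdicts and IC50 fits, the
    mechanism report, and the reference-set agreement summary.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    compounds = (load_compound_panel(config.compounds_path)
                 if config.compounds_path else [])
    if config.compounds_path and not compounds:
        raise InosimError("compound panel is empty")

    pop = build_population(config)
    pop.biomarker_table.to_csv(out_dir / "population_biomarkers.csv",
                               index=False)

    rows, fits, failures = [], {}, {}
    control_at = None
    for compound in compounds:
        try:
            table = scan_compound(pop, compound, config)
            table.medians().rename("median_at_fraction").to_csv(
                out_dir / f"dose_response_{compound.name}.csv")
            verdict = classification.inotropy_verdict(table)
            fit = fit_compound(table, config)
            fits[compound.name] = fit
            rows.append({
                "compound": compound.name,
                "eftpc_max_uM": compound.eftpc_max,
                "verdict": verdict,
                "ic50_median_uM": fit.get("median", {}).get("ic50_um"),
                "ic50_bayes_mean_uM": fit.get("bayes", {}).get("ic50_um_mean"),
            })
        except Exception as exc:
            failures[compound.name] = f"{type(exc).__name__}: {exc}"

    verdicts = pd.DataFrame(rows)
    if not verdicts.empty:
        verdicts.to_csv(out_dir / "verdicts.csv", index=False)

    specs, effects = load_mechanism_config(config.mechanisms_path)
    backend = get_backend(config.backend)
    mech = mechanism_report(specs, effects, pop.models, backend,
                            config.simulation)
    mech.to_csv(out_dir / "mechanism_report.csv", index=False)

    ref = classification.classify_reference()
    agreement = classification.agreement_summary(ref["delta_median"])

    bundle = {
        "provenance": {**config.provenance(),
                       "population": pop.provenance},
        "n_compounds": len(compounds),
        "verdicts": rows,
        "fits": fits,
        "failures": failures,
        "reference_agreement": agreement,
        "simulation": asdict(config.simulation),
    }
    write_json(bundle, out_dir / "run_summary.json")
    return bundle
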