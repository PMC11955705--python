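"""Experimentally calibrated population of virtual ventricular cells.

The population-of-models workflow: sample an initial ensemble by drawing the
11 conductance/flux scale factors uniformly in [50-150]% of baseline, pace
each cell, and retain only the models whose biomarkers fall inside healthy
human ventricular calibration ranges and that show no depolarisation or
repolarisation abnormality. The baseline cell is always carried along with
the accepted set (model id 0), so a run over the calibrated population
returns one electrophysiological profile per accepted model plus baseline.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from . import biomarkers as bmx
from .errors import CalibrationError
from .model import ModelParameters, SimulationConfig, SCALE_FIELDS


@dataclass
class PopulationSpec:
    """Sampling design for the initial population."""

    n_models: int = 1000
    scale_range: tuple[float, float] = (0.5, 1.5)
    seed: int = 0
    calibration_ranges: dict | None = None
    latin_hypercube: bool = False

    def __post_init__(self):
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise ValueError("scale_range must satisfy 0 < low <= high")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.calibration_ranges is not None:
            for name, (a, b) in self.calibration_ranges.items():
                if not a < b:
                    raise ValueError(f"empty calibration interval for {name}")


def sample_population(spec: PopulationSpec) -> list[ModelParameters]:
    """Draw the initial ensemble of parameter sets (mechanism parameters stay
    at baseline). Independent-uniform by default; optional Latin hypercube."""
    lo, hi = spec.scale_range
    n, d = spec.n_models, len(SCALE_FIELDS)
    if spec.latin_hypercube:
        sampler = qmc.LatinHypercube(d=d, seed=spec.seed)
        u = sampler.random(n)
    else:
        u = np.random.default_rng(spec.seed).uniform(size=(n, d))
    scales = lo + (hi - lo) * u
    return [ModelParameters(**dict(zip(SCALE_FIELDS, row))) for row in scales]


@dataclass
class CalibratedPopulation:
    """Accepted models (baseline prepended as id 0) plus calibration record."""

    models: list[ModelParameters]
    model_ids: list[int]
    biomarker_table: pd.DataFrame
    acceptance_rate: float
    rejection_counts: dict
    baseline_in_range: bool
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.models)


def _within(value: float, interval) -> bool:
    lo, hi = interval
    return bool(np.isfinite(value)) and lo <= value <= hi


def calibrate(models: list[ModelParameters], calibration_ranges: dict,
              backend, config: SimulationConfig,
              provenance: dict | None = None) -> CalibratedPopulation:
    """Filter the sampled ensemble against biomarker calibration ranges.

    A model is accepted iff its beat shows no abnormality flag and every
    calibrated biomarker lies inside its interval. The baseline model is
    prepended regardless (id 0) and marked ``baseline_in_range`` in the
    provenance if it passes its own calibration check.
    """
    rejection_counts: dict[str, int] = {"abnormality": 0}
    accepted: list[tuple[int, ModelParameters, bmx.BiomarkerSet]] = []

    def check(params: ModelParameters):
        trace = backend.simulate(params, config)
        bm = bmx.extract_all(trace, config)
        if bm.flags.any():
            return bm, False, "abnormality"
        for name, interval in calibration_ranges.items():
            if not _within(getattr(bm, name), interval):
                return bm, False, name
        return bm, True, None

    baseline = ModelParameters()
    baseline_bm, baseline_ok, _ = check(baseline)

    for i, params in enumerate(models, start=1):
        bm, ok, reason = check(params)
        if ok:
            accepted.append((i, params, bm))
        else:
            rejection_counts[reason] = rejection_counts.get(reason, 0) + 1

    if not accepted:
        raise CalibrationError(
            "calibration rejected every sampled model",
            rejection_counts=rejection_counts,
        )

    rows = []
    all_models = [baseline] + [p for _, p, _ in accepted]
    ids = [0] + [i for i, _, _ in accepted]
    for mid, params, bm in [(0, baseline, baseline_bm)] + accepted:
        row = {"model_id": mid}
        row.update(params.as_dict())
        row.update(bm.as_dict())
        rows.append(row)

    prov = dict(provenance or {})
    prov.update({
        "baseline_in_range": baseline_ok,
        "n_sampled": len(models),
        "n_accepted": len(accepted),
        "calibration_ranges": {k: list(v) for k, v in calibration_ranges.items()},
    })
    return CalibratedPopulation(
        models=all_models,
        model_ids=ids,
        biomarker_table=pd.DataFrame(rows),
        acceptance_rate=len(accepted) / len(models),
        rejection_counts=rejection_counts,
        baseline_in_range=baseline_ok,
        provenance=prov,
    )


@dataclass
class PopulationRunResult:
    """Biomarkers of every model under one (optionally perturbed) condition.

    Flagged models keep their row (flags recorded) but carry NaN biomarkers,
    mirroring the rule that biomarkers are only computed for beats without
    predicted abnormalities.
    """

    table: pd.DataFrame
    provenance: dict


def run_population(models: list[ModelParameters], backend,
                   config: SimulationConfig, perturbation=None,
                   model_ids: list[int] | None = None) -> PopulationRunResult:
    """Simulate every model, optionally under a perturbation.

    ``perturbation`` is a callable mapping ModelParameters to the perturbed
    ModelParameters (drug block or mechanism scaling applied on top of each
    model's own parameter set). Backend failures are recorded per model and
    the run continues.
    """
    if not models:
        raise ValueError("models must be non-empty")
    ids = model_ids if model_ids is not None else list(range(len(models)))
    rows = []
    for mid, params in zip(ids, models):
        row: dict = {"model_id": mid, "error": ""}
        try:
            p = perturbation(params) if perturbation is not None else params
            trace = backend.simulate(p, config)
            flags = bmx.detect_abnormalities(trace, config)
            row.update(flags.as_dict())
            if not flags.any():
                bm = bmx.extract_all(trace, config)
                row.update({k: v for k, v in bm.as_dict().items()
                            if not k.startswith("flag_")})
        except Exception as exc:  # isolate per-model failures
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    table = pd.DataFrame(rows)
    return PopulationRunResult(table=table, provenance={
        "backend": getattr(backend, "name", type(backend).__name__),
        "n_models": len(models),
    })


def config_digest(obj) -> str:
    """Short stable digest of a configuration mapping, for provenance."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
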