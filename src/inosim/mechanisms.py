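"""Dose-independent mechanism perturbation for positive inotropes.

Each mechanism names one (or, for beta-adrenergic stimulation, two) model
parameters and a scaling-factor range over which a one-at-a-time scan is
run on the calibrated population. The median peak-tension fraction of
control across the scan is fitted with a degree-2 polynomial (parabola),
and the sarcomere-shortening effect observed in vitro at a compound's EC50
is projected onto the parabola to find the scaling factor that reproduces
it in silico; when no intersection exists inside the scanned range the
mechanism cannot reproduce the observation (reported as not reachable).

The beta-adrenergic mechanism co-scales the L-type calcium and slow
potassium conductances; the tension response is calcium-driven, so the
projection is reported as the I_CaL scaling factor. A 2-D grid scan over
both factors is also available for mean/SD maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import biomarkers as bmx
from .errors import FitError, InvalidParameterError
from .model import ModelParameters, SimulationConfig

#: Mechanism name -> (targeted parameters, allowed scan interval).
MECHANISM_PARAMS = {
    "extracellular_ca_increase": (("cao",), (1.0, 3.0)),
    "ical_activation": (("sCaL",), (1.0, 3.0)),
    "ryr_activation": (("sJrel",), (1.0, 3.0)),
    "serca_activation": (("sJup",), (1.0, 3.0)),
    "ncx_inactivation": (("sNCX",), (0.1, 1.0)),
    "beta_adrenergic": (("sCaL", "sKs"), (1.0, 3.0)),
    "ca_sensitivity_decrease": (("ca50_scale",), (0.1, 1.0)),
    "nak_inactivation": (("sNaK",), (0.1, 1.0)),
    "myosin_activation": (("kuw_scale",), (1.0, 5.0)),
}


@dataclass(frozen=True)
class MechanismSpec:
    """One mode of action: targeted parameter(s) and scan range."""

    name: str
    params: tuple[str, ...]
    scan_range: tuple[float, float]
    direction: str = "increase"

    def __post_init__(self):
        if self.name in MECHANISM_PARAMS:
            allowed_params, allowed_range = MECHANISM_PARAMS[self.name]
            if tuple(self.params) != allowed_params:
                raise InvalidParameterError(
                    f"{self.name}: expected parameters {allowed_params}")
            lo, hi = self.scan_range
            if lo < allowed_range[0] - 1e-9 or hi > allowed_range[1] + 1e-9:
                raise InvalidParameterError(
                    f"{self.name}: scan range outside {allowed_range}")
        for p in self.params:
            if p not in ModelParameters().as_dict():
                raise InvalidParameterError(f"unknown parameter {p!r}")

    def perturbation(self, factor: float):
        """Callable applying this mechanism's scaling on top of a model."""
        def apply(params: ModelParameters) -> ModelParameters:
            changes = {p: getattr(params, p) * factor for p in self.params}
            return params.replace(**changes)
        return apply


def default_specs() -> list[MechanismSpec]:
    return [MechanismSpec(name=k, params=v[0], scan_range=v[1],
                          direction="decrease" if v[1][0] < 1 else "increase")
            for k, v in MECHANISM_PARAMS.items()]


@dataclass
class PerturbationCurve:
    """Median peak-tension fraction of control across a mechanism scan."""

    mechanism: str
    factors: np.ndarray
    median_fraction: np.ndarray
    iqr: np.ndarray
    coefficients: tuple[float, float, float] | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def max_fraction(self) -> float:
        return float(np.nanmax(self.median_fraction))


def _at_peaks(models, backend, config, perturbation=None) -> np.ndarray:
    """AT_peak for every model (NaN for flagged beats)."""
    out = np.empty(len(models))
    for i, params in enumerate(models):
        p = perturbation(params) if perturbation is not None else params
        trace = backend.simulate(p, config)
        if bmx.detect_abnormalities(trace, config).any():
            out[i] = np.nan
        else:
            out[i] = bmx.extract_at_biomarkers(trace)["ATpeak"]
    return out


def scan_mechanism(models: list[ModelParameters], spec: MechanismSpec,
                   backend, config: SimulationConfig,
                   n_points: int = 11) -> PerturbationCurve:
    """Evaluate the population's median AT_peak fraction of control at
    ``n_points`` equally spaced scaling factors over the mechanism's range.

    The factor 1 (control identity) is always included in the scan grid.
    """
    lo, hi = spec.scan_range
    factors = np.linspace(lo, hi, n_points)
    if not np.any(np.isclose(factors, 1.0)):
        factors = np.sort(np.append(factors, 1.0))
    control = _at_peaks(models, backend, config)
    med, iqr = [], []
    for factor in factors:
        at = _at_peaks(models, backend, config, spec.perturbation(factor))
        frac = at / control
        med.append(np.nanmedian(frac))
        q = np.nanpercentile(frac, [25, 75]) if np.any(np.isfinite(frac)) \
            else (np.nan, np.nan)
        iqr.append(q[1] - q[0])
    curve = PerturbationCurve(
        mechanism=spec.name, factors=factors,
        median_fraction=np.asarray(med), iqr=np.asarray(iqr),
        provenance={"n_models": len(models), "n_points": len(factors)},
    )
    curve.coefficients = fit_parabola(list(zip(curve.factors,
                                               curve.median_fraction)))
    return curve


def beta_adrenergic_grid(models, backend, config,
                         n_points: int = 5) -> pd.DataFrame:
    """2-D (sCaL x sKs) scan: mean and SD of the AT_peak fraction of control
    over the population at each grid node."""
    grid = np.linspace(1.0, 3.0, n_points)
    control = _at_peaks(models, backend, config)
    rows = []
    for f_cal in grid:
        for f_ks in grid:
            def perturb(p, f_cal=f_cal, f_ks=f_ks):
                return p.replace(sCaL=p.sCaL * f_cal, sKs=p.sKs * f_ks)
            frac = _at_peaks(models, backend, config, perturb) / control
            rows.append({"sCaL_factor": f_cal, "sKs_factor": f_ks,
                         "mean_fraction": np.nanmean(frac),
                         "sd_fraction": np.nanstd(frac),
                         "flagged_fraction": np.mean(~np.isfinite(frac))})
    return pd.DataFrame(rows)


def fit_parabola(points) -> tuple[float, float, float]:
    """Ordinary least-squares quadratic y = a x^2 + b x + c."""
    pts = [(float(x), float(y)) for x, y in points if np.isfinite(y)]
    if len({x for x, _ in pts}) < 3:
        raise FitError("parabola fit needs >= 3 distinct scan points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    a, b, c = np.polyfit(x, y, 2)
    return float(a), float(b), float(c)


def project_effect(parabola, target_fraction: float,
                   scan_range) -> float | None:
    """Scaling factor at which the fitted parabola meets ``target_fraction``.

    Solves a x^2 + b x + c = target by the quadratic formula; admissible
    roots are real and inside the scan range. With two admissible roots the
    one nearest 1.0 (no perturbation) is returned; with none, None
    (the in vitro observation is not reachable by this mechanism).
    """
    if target_fraction <= 0:
        raise InvalidParameterError("target fraction must be > 0")
    a, b, c = parabola
    lo, hi = min(scan_range), max(scan_range)
    tol = 1e-9
    if abs(a) < 1e-14:
        if abs(b) < 1e-14:
            return 1.0 if abs(c - target_fraction) < tol else None
        root = (target_fraction - c) / b
        return float(root) if lo - tol <= root <= hi + tol else None
    disc = b * b - 4.0 * a * (c - target_fraction)
    if disc < 0:
        return None
    sq = np.sqrt(disc)
    roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    admissible = [r for r in roots if lo - tol <= r <= hi + tol]
    if not admissible:
        return None
    return float(min(admissible, key=lambda r: abs(r - 1.0)))


def mechanism_report(specs: list[MechanismSpec], in_vitro_effects,
                     models, backend, config,
                     n_points: int = 11) -> pd.DataFrame:
    """One row per (mechanism, compound): scan maximum, the in vitro EC50
    effect, and the projected scaling factor (NaN = not reachable).

    ``in_vitro_effects`` is an iterable of dicts with keys ``mechanism``,
    ``compound`` and ``ec50_fraction`` (the sarcomere-shortening fraction of
    control observed in vitro at the compound's EC50).
    """
    by_name = {s.name: s for s in specs}
    curves: dict[str, PerturbationCurve] = {}
    rows = []
    for effect in in_vitro_effects:
        name = effect["mechanism"]
        compound = effect.get("compound", "?")
        if name not in by_name:
            rows.append({"mechanism": name, "compound": compound,
                         "incomplete": True})
            continue
        spec = by_name[name]
        if name not in curves:
            curves[name] = scan_mechanism(models, spec, backend, config,
                                          n_points=n_points)
        curve = curves[name]
        target = effect.get("ec50_fraction")
        if target is None:
            rows.append({"mechanism": name, "compound": compound,
                         "incomplete": True})
            continue
        sf = project_effect(curve.coefficients, float(target), spec.scan_range)
        rows.append({
            "mechanism": name,
            "compound": compound,
            "parameters": "+".join(spec.params),
            "scan_low": spec.scan_range[0],
            "scan_high": spec.scan_range[1],
            "max_insilico_fraction": curve.max_fraction,
            "ec50_fraction_invitro": float(target),
            "scaling_factor": np.nan if sf is None else sf,
            "reachable": sf is not None,
            "incomplete": False,
        })
    return pd.DataFrame(rows)
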