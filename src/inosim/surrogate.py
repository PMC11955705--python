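"""Analytic phenomenological cell backend.

The pipeline's backend contract is ``simulate(params, config) -> BeatTraces``.
This module implements it with a closed-form surrogate: a deterministic
log-linear map from model parameters to latent biomarkers, abnormality
injection rules, and piecewise-analytic trace synthesis that exhibits those
biomarkers exactly up to grid resolution. A biophysical ODE backend (e.g. a
full electromechanical ventricular model) can be registered under the same
contract later; everything downstream only consumes ``BeatTraces``.

The surrogate's baselines and power-law sensitivities are design constants
chosen so that effect *directions* match ventricular physiology: L-type
calcium activation, NCX/NaK inhibition and extracellular calcium raise the
calcium transient and hence tension; hERG block prolongs the action
potential; myosin activation and calcium sensitisation raise tension with
saturation. Quantitative values from any particular ODE model are *not*
reproduced. Tension follows a Hill function of the calcium-transient peak,

    AT_peak = AT_MAX * c^2 / (c^2 + k^2) * g(kuw),

with ``c = CT_peak``, ``k = CA50_REF * ca50_scale`` and a saturating myosin
gain ``g(kuw) = 3*kuw / (2*(kuw + 0.5))`` (g(1) = 1, g(inf) = 1.5).
``CA50_REF`` is fixed so the baseline cell develops 25 kPa.

The Na+/K+-pump sensitivity of CT_peak is deliberately mild (exponent -0.10):
glycoside-like NaK inhibition acts indirectly through sodium loading and in
the reference physiology produces only a modest tension gain, so the
surrogate caps the NaK mechanism well below the responses of the direct
calcium-pathway mechanisms.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator

from .biomarkers import BiomarkerSet
from .errors import InvalidParameterError, SynthesisError
from .model import (
    AbnormalityFlags,
    BeatTraces,
    ModelParameters,
    SimulationConfig,
)

# --- surrogate design constants -------------------------------------------

#: Baseline (all scale factors 1, cao = 1.8 mM) latent biomarkers.
BASELINE = {
    "RMP": -88.0,       # mV
    "Vpeak": 40.0,      # mV
    "dVdtmax": 300.0,   # mV/ms
    "APD40": 180.0,     # ms
    "APD50": 210.0,     # ms
    "APD90": 270.0,     # ms
    "CaiD": 1.0e-4,     # mM
    "CTpeak": 5.0e-4,   # mM
    "CTD50": 250.0,     # ms
    "CTD90": 420.0,     # ms
    "ATttp": 150.0,     # ms
    "ATrt50": 110.0,    # ms
    "ATrt90": 250.0,    # ms
}

#: Tension Hill half-activation (mM) at ca50_scale = 1; fixed so that the
#: baseline CT_peak of 5e-4 mM develops AT_peak = 25 kPa.
CA50_REF = 9.7468e-4

#: Maximal tension (kPa) at full calcium saturation and unit myosin gain.
AT_MAX = 120.0

#: Power-law exponents of each latent biomarker in the scale factors.
#: APD exponents apply to APD40/50/90 alike; cao enters as (cao/1.8)^e.
EXPONENTS = {
    "APD": {"sKr": -0.35, "sKs": -0.08, "sK1": -0.06, "sCaL": 0.22,
            "sNaL": 0.12},
    "CTpeak": {"sCaL": 0.80, "sNCX": -0.35, "sNaK": -0.10, "sJup": 0.15,
               "sJrel": 0.10, "cao": 0.70},
    "CaiD": {"sNCX": -0.25, "sNaK": -0.35, "sJup": -0.20, "cao": 0.40},
    "CTD": {"sJup": -0.30, "sNCX": -0.10, "sCaL": 0.10},
    "ATrt": {"sJup": -0.25, "kuw_scale": -0.10},
}

#: Abnormality-injection thresholds.
REPOL_FAILURE_APD_FRACTION = 0.95  # APD90 >= 0.95 * cycle length
EAD_CAL_KR_RATIO = 6.0             # sCaL / sKr at or above this triggers EADs
DEPOL_SNA_THRESHOLD = 0.15         # sNa at or below this compromises upstroke

# Fixed trace-layout times (ms from the stimulus).
_T_UPSTROKE = 5.0       # AP upstroke onset
_CA_LAG = 2.0           # calcium foot starts after the AP upstroke
_CA_ONSET_RISE = 3.0    # foot -> 10%-amplitude onset
_CA_TTP = 25.0          # onset -> calcium peak
_AT_LAG = 8.0           # tension 1%-onset after the AP upstroke
_V_TAIL = 80.0          # AP returns to RMP this long after APD90
_CA_TAIL = 120.0        # CaT returns to diastole this long after CTD90
_AT_TAIL = 100.0        # AT returns to zero this long after ATrt90


def _powerlaw(base: float, params: ModelParameters, exponents: dict) -> float:
    value = base
    for name, expo in exponents.items():
        if name == "cao":
            value *= (params.cao / 1.8) ** expo
        else:
            value *= getattr(params, name) ** expo
    return value


def latent_biomarkers(params: ModelParameters) -> BiomarkerSet:
    """Deterministic biomarker map of the surrogate cell.

    This is the surrogate's replacement for solving the electromechanical
    ODE system and post-processing its last beat.
    """
    params.validate()
    p = params
    apd = {f"APD{x}": _powerlaw(BASELINE[f"APD{x}"], p, EXPONENTS["APD"])
           for x in (40, 50, 90)}
    ctd = {f"CTD{x}": _powerlaw(BASELINE[f"CTD{x}"], p, EXPONENTS["CTD"])
           for x in (50, 90)}
    ct_peak = _powerlaw(BASELINE["CTpeak"], p, EXPONENTS["CTpeak"])
    cai_d = _powerlaw(BASELINE["CaiD"], p, EXPONENTS["CaiD"])
    # diastolic calcium cannot exceed the transient peak: under extreme
    # calcium-entry block the diastolic level collapses along with it
    cai_d = min(cai_d, 0.8 * ct_peak)
    k_half = CA50_REF * p.ca50_scale
    gain = 3.0 * p.kuw_scale / (2.0 * (p.kuw_scale + 0.5))
    at_peak = AT_MAX * ct_peak**2 / (ct_peak**2 + k_half**2) * gain
    at_ttp = BASELINE["ATttp"] * p.kuw_scale ** -0.30
    atrt = {f"ATrt{x}": _powerlaw(BASELINE[f"ATrt{x}"], p, EXPONENTS["ATrt"])
            for x in (50, 90)}
    return BiomarkerSet(
        **apd,
        Tri90_40=apd["APD90"] - apd["APD40"],
        dVdtmax=BASELINE["dVdtmax"] * p.sNa**0.9,
        Vpeak=BASELINE["Vpeak"] * p.sNa**0.15,
        RMP=BASELINE["RMP"] + 4.0 * (1.0 - p.sK1),
        **ctd,
        CaiD=cai_d,
        CTpeak=ct_peak,
        ATpeak=at_peak,
        ATttp=at_ttp,
        **atrt,
        EMw=ctd["CTD90"] - apd["APD90"],
    )


def detect_latent_abnormalities(params: ModelParameters,
                                config: SimulationConfig) -> AbnormalityFlags:
    """Abnormality injection rules of the surrogate.

    Repolarisation failure when the latent APD90 exceeds 95% of the cycle
    length; EADs when the calcium-to-hERG balance sCaL/sKr reaches 6; a
    compromised upstroke when sNa falls to 0.15 or below.
    """
    params.validate()
    bm = latent_biomarkers(params)
    return AbnormalityFlags(
        ead=params.sCaL / params.sKr >= EAD_CAL_KR_RATIO,
        repol_failure=bm.APD90 >= REPOL_FAILURE_APD_FRACTION * config.cycle_length,
        depol_abnormal=params.sNa <= DEPOL_SNA_THRESHOLD,
    )


def _grid(config: SimulationConfig, critical: list[float]) -> np.ndarray:
    cl, dt = config.cycle_length, config.dt
    base = np.arange(0.0, cl + dt / 2, dt)
    base[-1] = min(base[-1], cl)
    extra = np.asarray([tc for tc in critical if 0.0 < tc < cl], float)
    t = np.union1d(base, extra)
    # drop near-duplicate samples so the grid stays strictly increasing
    keep = np.concatenate([[True], np.diff(t) > 1e-9])
    return t[keep]


def _decline_knots(anchors, cl, floor_value):
    """Truncate a decreasing anchor sequence at the cycle end.

    Anchors at or beyond the cycle length are dropped; the trace is pinned at
    the cycle end to the first dropped anchor's value (so beats whose tail
    would outlast the cycle stay elevated there) or to ``floor_value`` when
    every anchor fits.
    """
    kept_t, kept_y = [], []
    dropped_value = None
    for ta, ya in anchors:
        if ta < cl - 1e-9:
            kept_t.append(ta)
            kept_y.append(ya)
        else:
            dropped_value = ya
            break
    if not kept_t:
        raise SynthesisError("trace peak lies beyond the end of the beat")
    kept_t.append(cl)
    kept_y.append(floor_value if dropped_value is None else dropped_value)
    if np.any(np.diff(kept_t) <= 0) or np.any(np.diff(kept_y) > 0):
        raise SynthesisError(f"anchor sequence not monotone: {kept_t} {kept_y}")
    return np.asarray(kept_t), np.asarray(kept_y)


def synthesize_traces(biomarkers: BiomarkerSet, flags: AbnormalityFlags,
                      config: SimulationConfig) -> BeatTraces:
    """Piecewise-analytic AP/CaT/AT traces exhibiting the given biomarkers.

    The AP rises linearly at dV/dt_max from RMP to V_peak and declines
    monotonically (shape-preserving PCHIP) through the APDx anchor points,
    measured from the upstroke; CaT and AT are built analogously from their
    own anchors. Flagged beats are deformed so that the trace-level
    abnormality detector reproduces the latent flags: EAD beats get a +10 mV
    bump after the plateau, repolarisation failures are held at least 15 mV
    above RMP to the end of the beat, and depolarisation abnormalities have
    the peak clipped below 0 mV.
    """
    bm = biomarkers
    try:
        bm.check_consistency()
    except Exception as exc:
        raise SynthesisError(str(exc)) from exc
    cl = config.cycle_length
    rmp, vpeak = bm.RMP, bm.Vpeak
    if not (bm.APD40 < bm.APD50 < bm.APD90):
        raise SynthesisError("APD anchors must be strictly ordered")
    tau = (vpeak - rmp) / bm.dVdtmax
    if tau <= 0 or tau >= bm.APD40:
        raise SynthesisError("upstroke duration inconsistent with APD40")
    t_up = _T_UPSTROKE
    t_peak_v = t_up + tau

    dv = vpeak - rmp
    v_t, v_y = _decline_knots(
        [(t_peak_v, vpeak),
         (t_up + bm.APD40, vpeak - 0.40 * dv),
         (t_up + bm.APD50, vpeak - 0.50 * dv),
         (t_up + bm.APD90, vpeak - 0.90 * dv),
         (t_up + bm.APD90 + _V_TAIL, rmp)],
        cl, rmp)
    v_decline = PchipInterpolator(v_t, v_y)

    # Calcium anchors (onset = 10%-amplitude crossing during the rise).
    cai_d = bm.CaiD
    ct_peak = max(bm.CTpeak, cai_d * 1.001)  # floor amplitude under extreme block
    ca_amp = ct_peak - cai_d
    t_ca_foot = t_up + _CA_LAG
    t_ca_on = t_ca_foot + _CA_ONSET_RISE
    t_ca_peak = t_ca_on + _CA_TTP
    if not (bm.CTD50 < bm.CTD90) or t_ca_peak >= t_ca_on + bm.CTD50:
        raise SynthesisError("calcium anchors inconsistent")
    ca_t, ca_y = _decline_knots(
        [(t_ca_peak, ct_peak),
         (t_ca_on + bm.CTD50, cai_d + 0.5 * ca_amp),
         (t_ca_on + bm.CTD90, cai_d + 0.1 * ca_amp),
         (t_ca_on + bm.CTD90 + _CA_TAIL, cai_d)],
        cl, cai_d)
    ca_decline = PchipInterpolator(ca_t, ca_y)

    # Tension anchors (onset = 1%-amplitude crossing).
    at_amp = bm.ATpeak
    if at_amp <= 0:
        raise SynthesisError("ATpeak must be positive")
    if not (bm.ATrt50 < bm.ATrt90):
        raise SynthesisError("tension relaxation anchors inconsistent")
    t_at_pre = t_up + _AT_LAG - 1.0
    t_at_on = t_up + _AT_LAG
    t_at_peak = t_at_on + bm.ATttp
    at_t, at_y = _decline_knots(
        [(t_at_peak, at_amp),
         (t_at_peak + bm.ATrt50, 0.5 * at_amp),
         (t_at_peak + bm.ATrt90, 0.1 * at_amp),
         (t_at_peak + bm.ATrt90 + _AT_TAIL, 0.0)],
        cl, 0.0)
    at_decline = PchipInterpolator(at_t, at_y)

    critical = (
        [t_up, t_up + tau / 3, t_up + 2 * tau / 3] + list(v_t)
        + [t_ca_foot, t_ca_on, (t_ca_on + t_ca_peak) / 2] + list(ca_t)
        + [t_at_pre, t_at_on, (t_at_on + t_at_peak) / 2] + list(at_t)
    )
    t = _grid(config, critical)

    v = np.full_like(t, rmp)
    rise = (t > t_up) & (t < t_peak_v)
    v[rise] = rmp + bm.dVdtmax * (t[rise] - t_up)
    v[t >= t_peak_v] = v_decline(t[t >= t_peak_v])

    cai = np.full_like(t, cai_d)
    ca_rise1 = (t > t_ca_foot) & (t < t_ca_on)
    cai[ca_rise1] = cai_d + 0.1 * ca_amp * (t[ca_rise1] - t_ca_foot) / _CA_ONSET_RISE
    ca_rise2 = (t >= t_ca_on) & (t < t_ca_peak)
    cai[ca_rise2] = (cai_d + 0.1 * ca_amp
                     + 0.9 * ca_amp * (t[ca_rise2] - t_ca_on) / _CA_TTP)
    cai[t >= t_ca_peak] = ca_decline(t[t >= t_ca_peak])

    at = np.zeros_like(t)
    at_rise = (t >= t_at_on) & (t < t_at_peak)
    at[at_rise] = (0.01 * at_amp
                   + 0.99 * at_amp * (t[at_rise] - t_at_on) / bm.ATttp)
    at[t >= t_at_peak] = at_decline(t[t >= t_at_peak])
    at = np.maximum(at, 0.0)

    if flags.ead:
        bump_centre = t_up + 0.5 * (bm.APD50 + bm.APD90)
        bump = 10.0 * np.exp(-(((t - bump_centre) / 15.0) ** 2))
        v = np.where(t > t_peak_v, v + bump, v)
    if flags.repol_failure:
        v = np.where(t >= t_peak_v, np.maximum(v, rmp + 15.0), v)
    if flags.depol_abnormal:
        v = rmp + (v - rmp) * ((-5.0 - rmp) / (vpeak - rmp))

    return BeatTraces(t=t, v=v, cai=cai, at=at)


def simulate(params: ModelParameters, config: SimulationConfig) -> BeatTraces:
    """Backend entry point: latent map -> abnormality rules -> synthesis.

    The surrogate is algebraic, so the returned beat is steady by
    construction; ``config.n_beats`` is honoured only by ODE backends.
    """
    bm = latent_biomarkers(params)
    flags = detect_latent_abnormalities(params, config)
    return synthesize_traces(bm, flags, config)


class SurrogateBackend:
    """Default cell-model backend implementing the analytic surrogate."""

    name = "surrogate"

    def simulate(self, params: ModelParameters,
                 config: SimulationConfig) -> BeatTraces:
        return simulate(params, config)

    def latent_biomarkers(self, params: ModelParameters) -> BiomarkerSet:
        return latent_biomarkers(params)

    def latent_flags(self, params: ModelParameters,
                     config: SimulationConfig) -> AbnormalityFlags:
        return detect_latent_abnormalities(params, config)


_REGISTRY = {"surrogate": SurrogateBackend}


def register_backend(name: str, factory) -> None:
    _REGISTRY[name] = factory


def get_backend(name: str = "surrogate"):
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise InvalidParameterError(
            f"unknown backend {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None
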