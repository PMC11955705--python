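"""Electromechanical biomarker extraction from single-beat traces.

Fifteen trace biomarkers characterise the action potential (APD40/50/90,
Tri90-40, dV/dt_max, V_peak, RMP), the calcium transient (CTD50/90, CaiD,
CT_peak) and the active tension (AT_peak, AT_ttp, ATrt50/90), together with
the electromechanical window EMw = CTD90 - APD90 and, when per-current series
are available, the net charge qNet. Threshold crossings use linear
interpolation between samples; ties are broken by the first crossing.

Conventions (the source protocols leave these open, so they are fixed here):

* APDx is measured from the instant of maximum upstroke velocity to the first
  downward crossing of ``V_peak - x/100 * (V_peak - RMP)``.
* CTDx is measured from calcium upstroke onset, defined as the first upward
  crossing of ``CaiD + 10%`` of the transient amplitude.
* AT onset is the first upward crossing of 1% of the tension amplitude;
  relaxation times are measured from the tension peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .errors import ExtractionError
from .model import AbnormalityFlags, BeatTraces, SimulationConfig

#: Derivative guard (mV/ms) above which a post-peak upstroke counts as an EAD.
EAD_SLOPE_GUARD = 0.01

#: A beat "reaches the resting condition" if the final voltage is within this
#: many mV of the pre-upstroke diastolic reference.
REPOL_TOLERANCE_MV = 5.0

#: Minimum upstroke velocity (mV/ms) for a trace to count as a real beat.
MIN_UPSTROKE_SLOPE = 10.0

#: The six currents entering qNet.
QNET_CURRENTS = ("INaL", "ICaL", "Ito", "IKr", "IKs", "IK1")


@dataclass
class BiomarkerSet:
    """The biomarkers of one beat (durations ms, voltages mV, calcium mM,
    tension kPa, qNet uC/uF), plus abnormality flags."""

    APD40: float
    APD50: float
    APD90: float
    Tri90_40: float
    dVdtmax: float
    Vpeak: float
    RMP: float
    CTD50: float
    CTD90: float
    CaiD: float
    CTpeak: float
    ATpeak: float
    ATttp: float
    ATrt50: float
    ATrt90: float
    EMw: float
    qNet: float | None = None
    flags: AbnormalityFlags = field(default_factory=AbnormalityFlags)

    NUMERIC_FIELDS = (
        "APD40", "APD50", "APD90", "Tri90_40", "dVdtmax", "Vpeak", "RMP",
        "CTD50", "CTD90", "CaiD", "CTpeak", "ATpeak", "ATttp", "ATrt50",
        "ATrt90", "EMw",
    )

    def as_dict(self) -> dict:
        out = {name: getattr(self, name) for name in self.NUMERIC_FIELDS}
        out["qNet"] = self.qNet
        out.update(self.flags.as_dict())
        return out

    def check_consistency(self) -> "BiomarkerSet":
        """Raise if the defining inequalities are violated (NaNs pass)."""
        pairs = [("APD40", "APD50"), ("APD50", "APD90"),
                 ("CTD50", "CTD90"), ("ATrt50", "ATrt90"),
                 ("CaiD", "CTpeak")]
        for lo, hi in pairs:
            a, b = getattr(self, lo), getattr(self, hi)
            if np.isfinite(a) and np.isfinite(b) and a > b:
                raise ExtractionError(f"inconsistent biomarkers: {lo} > {hi}")
        return self


def _slopes(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Finite-difference slopes on a (possibly non-uniform) grid, one per
    interval, attributed to the interval's left sample."""
    return np.diff(y) / np.diff(t)


def _first_crossing(t, y, threshold, *, rising, start=0):
    """Time of the first linear-interpolated crossing of ``threshold``.

    ``rising`` selects upward (y goes from below to >= threshold) or downward
    (from >= threshold to below) crossings. Returns None if there is none.
    Exact hits on a sample resolve to that sample's time.
    """
    y = y[start:]
    tt = t[start:]
    if rising:
        if y[0] >= threshold:
            return tt[0]
        idx = np.nonzero((y[:-1] < threshold) & (y[1:] >= threshold))[0]
    else:
        idx = np.nonzero((y[:-1] >= threshold) & (y[1:] < threshold))[0]
    if idx.size == 0:
        return None
    i = idx[0]
    y0, y1 = y[i], y[i + 1]
    if y1 == y0:
        return tt[i]
    frac = (threshold - y0) / (y1 - y0)
    return tt[i] + frac * (tt[i + 1] - tt[i])


def _upstroke_index(t, v):
    slopes = _slopes(t, v)
    i_up = int(np.argmax(slopes))
    if slopes[i_up] <= MIN_UPSTROKE_SLOPE:
        raise ExtractionError(
            f"no clear upstroke (max dV/dt = {slopes[i_up]:.3g} mV/ms)"
        )
    return i_up, slopes


def _diastolic(v, i_up):
    """Pre-upstroke diastolic reference: median of samples up to the start of
    the maximal-slope interval."""
    return float(np.median(v[: i_up + 1]))


def extract_ap_biomarkers(trace: BeatTraces) -> dict:
    """APD40/50/90, Tri90-40, dV/dt_max, V_peak and RMP from the AP trace.

    Unreachable repolarisation thresholds yield NaN durations; the caller is
    expected to have flagged such beats as repolarisation failures.
    """
    t, v = trace.t, trace.v
    i_up, slopes = _upstroke_index(t, v)
    dvdt_max = float(slopes[i_up])
    t_up = float(t[i_up])
    i_peak = int(np.argmax(v))
    vpeak = float(v[i_peak])
    rmp = _diastolic(v, i_up)
    out = {"dVdtmax": dvdt_max, "Vpeak": vpeak, "RMP": rmp}
    for x in (40, 50, 90):
        threshold = vpeak - x / 100.0 * (vpeak - rmp)
        tc = _first_crossing(t, v, threshold, rising=False, start=i_peak)
        out[f"APD{x}"] = float(tc - t_up) if tc is not None else np.nan
    out["Tri90_40"] = out["APD90"] - out["APD40"]
    return out


def extract_cat_biomarkers(trace: BeatTraces) -> dict:
    """CTD50/90 (from calcium upstroke onset), CaiD and CT_peak."""
    t, cai = trace.t, trace.cai
    ca_min, ca_max = float(np.min(cai)), float(np.max(cai))
    if ca_max <= ca_min:
        raise ExtractionError("flat calcium trace")
    amp = ca_max - ca_min
    onset = _first_crossing(t, cai, ca_min + 0.1 * amp, rising=True)
    i_peak = int(np.argmax(cai))
    out = {"CaiD": ca_min, "CTpeak": ca_max}
    for x in (50, 90):
        threshold = ca_max - x / 100.0 * amp
        tc = _first_crossing(t, cai, threshold, rising=False, start=i_peak)
        out[f"CTD{x}"] = float(tc - onset) if tc is not None else np.nan
    return out


def extract_at_biomarkers(trace: BeatTraces) -> dict:
    """AT_peak (above diastole), AT_ttp (from 1% onset) and ATrt50/90."""
    t, at = trace.t, trace.at
    at_min, at_max = float(np.min(at)), float(np.max(at))
    if at_max <= at_min:
        raise ExtractionError("flat tension trace")
    amp = at_max - at_min
    onset = _first_crossing(t, at, at_min + 0.01 * amp, rising=True)
    i_peak = int(np.argmax(at))
    t_peak = float(t[i_peak])
    out = {"ATpeak": amp, "ATttp": t_peak - onset}
    for x in (50, 90):
        threshold = at_min + (1.0 - x / 100.0) * amp
        tc = _first_crossing(t, at, threshold, rising=False, start=i_peak)
        out[f"ATrt{x}"] = float(tc - t_peak) if tc is not None else np.nan
    return out


def compute_qnet(currents: dict, t: np.ndarray) -> float | None:
    """Net charge (uC/uF) through the six qNet currents over one beat.

    Inward currents are negative by convention; the result is the trapezoidal
    time-integral of their sum. Returns None when any of the six series is
    missing (the analytic surrogate emits no currents).
    """
    if any(name not in currents for name in QNET_CURRENTS):
        return None
    total = np.sum([np.asarray(currents[name], float) for name in QNET_CURRENTS],
                   axis=0)
    # uA/uF * ms -> nC/uF; divide by 1000 for uC/uF
    return float(np.trapezoid(total, t) / 1000.0)


def detect_abnormalities(trace: BeatTraces,
                         config: SimulationConfig) -> AbnormalityFlags:
    """Depolarisation/repolarisation abnormality rules applied to one beat.

    EAD: any positive dV/dt (above a 0.01 mV/ms noise guard) after the voltage
    peak. Repolarisation failure: final voltage more than 5 mV above the
    pre-upstroke diastolic reference. Depolarisation abnormality: V_peak below
    0 mV, or 0 mV first reached later than 100 ms after the stimulus (taken as
    the start of the trace).
    """
    t, v = trace.t, trace.v
    slopes = _slopes(t, v)
    i_peak = int(np.argmax(v))
    vpeak = float(v[i_peak])
    try:
        i_up, _ = _upstroke_index(t, v)
        rmp_ref = _diastolic(v, i_up)
    except ExtractionError:
        rmp_ref = float(v[0])
    ead = bool(np.any(slopes[i_peak:] > EAD_SLOPE_GUARD))
    repol_failure = bool(v[-1] > rmp_ref + REPOL_TOLERANCE_MV)
    if vpeak < 0.0:
        depol = True
    else:
        t_zero = _first_crossing(t, v, 0.0, rising=True)
        depol = bool(t_zero is None or (t_zero - t[0]) > 100.0)
    return AbnormalityFlags(ead=ead, repol_failure=repol_failure,
                            depol_abnormal=depol)


def extract_all(trace: BeatTraces, config: SimulationConfig) -> BiomarkerSet:
    """All biomarkers plus flags for one beat."""
    flags = detect_abnormalities(trace, config)
    ap = extract_ap_biomarkers(trace)
    cat = extract_cat_biomarkers(trace)
    at = extract_at_biomarkers(trace)
    qnet = compute_qnet(trace.currents, trace.t)
    return BiomarkerSet(
        **ap, **cat, **at,
        EMw=cat["CTD90"] - ap["APD90"],
        qNet=qnet,
        flags=flags,
    )


def biomarker_frame(records: list[dict]):
    """Tidy DataFrame (one row per model x condition) from biomarker dicts."""
    import pandas as pd

    return pd.DataFrame.from_records(records)
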