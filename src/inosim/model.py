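"""Core domain types for the virtual-cell pipeline.

A virtual ventricular cell is parametrised by multiplicative scale factors on
the maximal conductances/fluxes of its main ionic currents and calcium-handling
processes (baseline 1.0), plus three mechanism parameters used to emulate
positive-inotrope modes of action: the extracellular calcium concentration
``cao`` (mM), a calcium-sensitivity scale ``ca50_scale`` applied to the tension
half-activation constant, and a myosin cross-bridge attachment-rate scale
``kuw_scale``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

from .errors import InvalidParameterError

#: Names of the 11 sampled / drug-scalable conductance and flux factors.
SCALE_FIELDS = (
    "sNa", "sNaL", "sCaL", "sTo", "sKr", "sKs",
    "sK1", "sNCX", "sNaK", "sJup", "sJrel",
)

#: Mechanism parameters perturbed for positive inotropes.
MECHANISM_FIELDS = ("cao", "ca50_scale", "kuw_scale")


@dataclass(frozen=True)
class ModelParameters:
    """Per-cell scale factors plus mechanism parameters.

    All scale factors are dimensionless multipliers on the baseline model;
    ``cao`` is in mM (baseline 1.8).
    """

    sNa: float = 1.0
    sNaL: float = 1.0
    sCaL: float = 1.0
    sTo: float = 1.0
    sKr: float = 1.0
    sKs: float = 1.0
    sK1: float = 1.0
    sNCX: float = 1.0
    sNaK: float = 1.0
    sJup: float = 1.0
    sJrel: float = 1.0
    cao: float = 1.8
    ca50_scale: float = 1.0
    kuw_scale: float = 1.0

    def validate(self) -> "ModelParameters":
        for name in SCALE_FIELDS + ("ca50_scale", "kuw_scale"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise InvalidParameterError(
                    f"scale factor {name} must be strictly positive, got {value!r}"
                )
        if not np.isfinite(self.cao) or self.cao <= 0:
            raise InvalidParameterError(f"cao must be > 0 mM, got {self.cao!r}")
        return self

    def replace(self, **changes) -> "ModelParameters":
        return replace(self, **changes)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class SimulationConfig:
    """Pacing protocol settings.

    ``n_beats`` is carried for ODE backends that need to reach diastolic
    steady state (500 beats for calibration, 1000 for drug runs); the analytic
    surrogate is beat-invariant, so it only consumes ``cycle_length`` and the
    output sampling step ``dt`` (both ms).
    """

    cycle_length: float = 1000.0
    n_beats: int = 1000
    dt: float = 0.5

    def __post_init__(self):
        if self.cycle_length <= 0:
            raise InvalidParameterError("cycle_length must be > 0")
        if self.dt <= 0 or self.dt > self.cycle_length / 500.0:
            raise InvalidParameterError(
                "dt must satisfy 0 < dt <= cycle_length/500"
            )


@dataclass(frozen=True)
class AbnormalityFlags:
    """Depolarisation/repolarisation abnormality flags for one beat."""

    ead: bool = False
    repol_failure: bool = False
    depol_abnormal: bool = False

    def any(self) -> bool:
        return self.ead or self.repol_failure or self.depol_abnormal

    def as_dict(self) -> dict:
        return {
            "flag_ead": self.ead,
            "flag_repol_failure": self.repol_failure,
            "flag_depol_abnormal": self.depol_abnormal,
        }


@dataclass
class BeatTraces:
    """One paced beat: time grid (ms) plus AP (mV), CaT (mM) and AT (kPa).

    The grid is strictly increasing and spans [0, cycle_length]; it need not
    be uniform (the surrogate refines it around the upstroke and the anchor
    points so that extracted biomarkers match the generating values).
    ``currents`` optionally carries named per-current series in uA/uF.
    """

    t: np.ndarray
    v: np.ndarray
    cai: np.ndarray
    at: np.ndarray
    currents: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.cai = np.asarray(self.cai, dtype=float)
        self.at = np.asarray(self.at, dtype=float)
        n = self.t.size
        if not (self.v.size == self.cai.size == self.at.size == n):
            raise InvalidParameterError("all trace series must share one grid")
        if n < 2 or np.any(np.diff(self.t) <= 0):
            raise InvalidParameterError("time grid must be strictly increasing")
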