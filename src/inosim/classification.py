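"""Inotropy verdicts and in silico vs in vitro IC50 agreement.

A compound is called a negative inotrope when the population-median peak
tension falls more than 25% below control (fraction < 0.75) at any tested
concentration up to 100x EFTPC_max; a symmetric rule (> 1.25, never < 0.75)
yields a positive call; otherwise the compound is neutral. Predicted and
measured contractility IC50s are compared by "delta", the difference of
their orders of magnitude,

    delta = floor(log10(IC50_insilico)) - floor(log10(IC50_invitro)),

with |delta| <= 1 counting as quantitative agreement. The floor-of-log10
formalisation is deliberate: a rounded log-ratio would misclassify compounds
whose IC50s sit near decade boundaries. Safety margins are IC50 / EFTPC_max.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .drug_block import DoseResponseTable
from .errors import InvalidParameterError

NEGATIVE_THRESHOLD = 0.75
POSITIVE_THRESHOLD = 1.25
DEFAULT_CAP_MULTIPLIER = 100.0


@dataclass
class ClassificationRecord:
    compound: str
    verdict: str                       # negative | neutral | positive
    ic50_insilico_median: float | None = None
    ic50_insilico_bayes: float | None = None
    ic50_invitro: float | None = None
    delta_median: int | None = None
    delta_bayes: int | None = None
    margin_insilico: float | None = None
    margin_invitro: float | None = None


def inotropy_verdict(table: DoseResponseTable,
                     cap_multiplier: float = DEFAULT_CAP_MULTIPLIER) -> str:
    """Negative / neutral / positive call from a dose-response table.

    Only concentrations up to ``cap_multiplier`` x EFTPC_max enter the call:
    effects appearing solely beyond that range are outside the exposure
    window the in vitro comparison speaks to.
    """
    med = table.medians().dropna()
    med = med[med.index <= cap_multiplier * table.eftpc_max * (1 + 1e-9)]
    if med.empty:
        return "neutral"
    if (med < NEGATIVE_THRESHOLD).any():
        return "negative"
    if (med > POSITIVE_THRESHOLD).any():
        return "positive"
    return "neutral"


def delta(ic50_insilico: float, ic50_invitro: float) -> int:
    """Order-of-magnitude difference between predicted and measured IC50."""
    if not (ic50_insilico > 0 and ic50_invitro > 0):
        raise InvalidParameterError("IC50 values must be > 0")
    return int(math.floor(math.log10(ic50_insilico))
               - math.floor(math.log10(ic50_invitro)))


def safety_margin(ic50: float, eftpc_max: float) -> float:
    """IC50 over EFTPC_max, the exposure-normalised safety margin."""
    if not (ic50 > 0 and eftpc_max > 0):
        raise InvalidParameterError("ic50 and eftpc_max must be > 0")
    return ic50 / eftpc_max


def agreement_summary(deltas) -> dict:
    """Delta histogram, the count with |delta| <= 1 and the agreement percent
    (rounded to the nearest integer)."""
    values = [int(d) for d in deltas if d is not None and np.isfinite(d)]
    if not values:
        raise InvalidParameterError("no defined deltas to summarise")
    hist = dict(sorted(Counter(values).items()))
    n = len(values)
    n_within = sum(1 for d in values if abs(d) <= 1)
    return {
        "histogram": hist,
        "n": n,
        "n_within_one": n_within,
        "agreement_percent": round(100.0 * n_within / n),
    }


def load_table2_reference() -> pd.DataFrame:
    """Packaged reference table of in vitro and in silico contractility IC50s
    (uM) with bracketed IC50/EFTPC_max ratios, for the 22 compounds with
    negative inotropic effects in both settings."""
    with resources.files("inosim.data").joinpath(
            "table2_reference.csv").open() as fh:
        return pd.read_csv(fh)


def classify_reference(reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """Delta classification of the packaged reference IC50 pairs, for both
    the median-fit and the Bayesian-posterior-mean in silico estimates."""
    ref = load_table2_reference() if reference is None else reference
    out = ref.copy()
    out["delta_median"] = [
        delta(a, b) for a, b in zip(ref["insilico_median_ic50_uM"],
                                    ref["invitro_ic50_uM"])]
    out["delta_bayes"] = [
        delta(a, b) for a, b in zip(ref["insilico_bayes_mean_uM"],
                                    ref["invitro_ic50_uM"])]
    out["implied_eftpc_uM"] = ref["invitro_ic50_uM"] / ref["invitro_ratio"]
    out["margin_invitro"] = [
        safety_margin(ic, ef) for ic, ef in zip(ref["invitro_ic50_uM"],
                                                out["implied_eftpc_uM"])]
    out["margin_insilico_median"] = [
        safety_margin(ic, ef) for ic, ef in zip(ref["insilico_median_ic50_uM"],
                                                out["implied_eftpc_uM"])]
    return out
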