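"""Surrogate backend: latent map, abnormality rules, trace synthesis."""

import numpy as np
import pytest

from inosim import (
    ModelParameters,
    SimulationConfig,
    detect_latent_abnormalities,
    latent_biomarkers,
    simulate,
    synthesize_traces,
)
from inosim.biomarkers import detect_abnormalities, extract_all, extract_at_biomarkers
from inosim.errors import InvalidParameterError, SynthesisError
from inosim.surrogate import BASELINE, get_backend


BASELINE_EXPECTED = {
    "RMP": -88.0, "Vpeak": 40.0, "dVdtmax": 300.0,
    "APD40": 180.0, "APD50": 210.0, "APD90": 270.0, "Tri90_40": 90.0,
    "CaiD": 1.0e-4, "CTpeak": 5.0e-4, "CTD50": 250.0, "CTD90": 420.0,
    "ATttp": 150.0, "ATrt50": 110.0, "ATrt90": 250.0, "EMw": 150.0,
}


class TestLatentBiomarkers:
    def test_baseline_fixed_point(self):
        """All-ones parameters reproduce the documented baseline table."""
        bm = latent_biomarkers(ModelParameters())
        for name, expected in BASELINE_EXPECTED.items():
            assert getattr(bm, name) == expected, name
        # ATpeak is defined through the tension Hill; 25 kPa by construction
        assert bm.ATpeak == pytest.approx(25.0, rel=1e-5)

    @pytest.mark.parametrize("changes, name, expected", [
        # oracle: evaluate the stated power laws directly
        ({"sKr": 0.5}, "APD90", 270.0 * 0.5 ** -0.35),
        ({"sKr": 0.5}, "APD40", 180.0 * 0.5 ** -0.35),
        ({"sNa": 0.8}, "dVdtmax", 300.0 * 0.8 ** 0.9),
        ({"sNa": 0.8}, "Vpeak", 40.0 * 0.8 ** 0.15),
        ({"sK1": 0.5}, "RMP", -88.0 + 4.0 * 0.5),
        ({"kuw_scale": 2.0}, "ATttp", 150.0 * 2.0 ** -0.30),
        ({"sJup": 0.5}, "CTD50", 250.0 * 0.5 ** -0.30),
        ({"cao": 3.6}, "CaiD", 1.0e-4 * 2.0 ** 0.40),
    ])
    def test_power_laws(self, changes, name, expected):
        bm = latent_biomarkers(ModelParameters(**changes))
        assert getattr(bm, name) == pytest.approx(expected, rel=1e-12)

    def test_herg_block_prolongs_apd(self):
        assert latent_biomarkers(ModelParameters(sKr=0.5)).APD90 == \
            pytest.approx(344.13, abs=0.01)

    def test_myosin_gain_saturates(self):
        """g(kuw) -> 1.5 as kuw -> inf, so ATpeak saturates at 1.5x baseline."""
        base = latent_biomarkers(ModelParameters()).ATpeak
        huge = latent_biomarkers(ModelParameters(kuw_scale=1e9)).ATpeak
        assert huge / base == pytest.approx(1.5, rel=1e-6)

    @pytest.mark.parametrize("bad", [
        {"sCaL": 0.0}, {"sKr": -1.0}, {"cao": 0.0}, {"kuw_scale": -2.0},
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            latent_biomarkers(ModelParameters(**bad))

    def test_tension_directionality(self):
        """ATpeak falls with calcium-channel block and rises with NCX block
        and with extracellular calcium (monotone over parameter grids)."""
        def at(**kw):
            return latent_biomarkers(ModelParameters(**kw)).ATpeak

        scal = [at(sCaL=s) for s in np.linspace(0.3, 1.5, 7)]
        assert np.all(np.diff(scal) > 0)
        sncx = [at(sNCX=s) for s in np.linspace(0.3, 1.5, 7)]
        assert np.all(np.diff(sncx) < 0)
        cao = [at(cao=c) for c in np.linspace(1.8, 5.4, 7)]
        assert np.all(np.diff(cao) > 0)


class TestAbnormalityRules:
    def test_baseline_clean(self, config):
        assert not detect_latent_abnormalities(ModelParameters(), config).any()

    def test_ead_rule(self, config):
        flags = detect_latent_abnormalities(
            ModelParameters(sKr=0.1), config)  # sCaL/sKr = 10 >= 6
        assert flags.ead and not flags.depol_abnormal

    def test_depol_rule(self, config):
        flags = detect_latent_abnormalities(ModelParameters(sNa=0.1), config)
        assert flags.depol_abnormal

    def test_repol_failure_rule(self):
        # APD90 = 270 * 0.18^-0.35 = 491 ms >= 0.95 * 500 ms cycle
        cfg = SimulationConfig(cycle_length=500.0, dt=0.5)
        flags = detect_latent_abnormalities(ModelParameters(sKr=0.18), cfg)
        assert flags.repol_failure


class TestSynthesis:
    def test_baseline_upstroke_slope(self, config):
        trace = simulate(ModelParameters(), config)
        slopes = np.diff(trace.v) / np.diff(trace.t)
        assert slopes.max() == pytest.approx(300.0, rel=1e-9)

    def test_deterministic(self, config):
        a = simulate(ModelParameters(sCaL=1.2, sKr=0.8), config)
        b = simulate(ModelParameters(sCaL=1.2, sKr=0.8), config)
        assert np.array_equal(a.t, b.t) and np.array_equal(a.v, b.v)
        assert np.array_equal(a.cai, b.cai) and np.array_equal(a.at, b.at)

    def test_ead_deformation_detected(self, config):
        p = ModelParameters(sKr=0.1)
        trace = simulate(p, config)
        flags = detect_abnormalities(trace, config)
        assert flags.ead

    def test_repol_failure_deformation_detected(self):
        cfg = SimulationConfig(cycle_length=500.0, dt=0.5)
        trace = simulate(ModelParameters(sKr=0.18), cfg)
        assert detect_abnormalities(trace, cfg).repol_failure

    def test_depol_deformation_detected(self, config):
        trace = simulate(ModelParameters(sNa=0.1), config)
        flags = detect_abnormalities(trace, config)
        assert flags.depol_abnormal
        assert trace.v.max() < 0.0

    def test_full_cal_block_collapses_tension(self, config):
        control = extract_at_biomarkers(simulate(ModelParameters(), config))
        blocked = extract_at_biomarkers(
            simulate(ModelParameters(sCaL=1e-6), config))
        assert blocked["ATpeak"] / control["ATpeak"] < 0.01

    def test_inconsistent_anchors_rejected(self, config):
        bm = latent_biomarkers(ModelParameters())
        bm.APD50 = bm.APD40 - 10.0
        with pytest.raises(SynthesisError):
            synthesize_traces(bm, detect_latent_abnormalities(
                ModelParameters(), config), config)


class TestRoundTrip:
    def test_random_draws_round_trip(self, config):
        """Extraction on synthesized traces recovers the latent biomarkers
        within max(2*dt, 1%) for population-range parameter draws."""
        from inosim.model import SCALE_FIELDS

        rng = np.random.default_rng(11)
        checked = 0
        while checked < 40:
            p = ModelParameters(**{
                f: rng.uniform(0.5, 1.5) for f in SCALE_FIELDS})
            if detect_latent_abnormalities(p, config).any():
                continue
            lat = latent_biomarkers(p)
            bm = extract_all(simulate(p, config), config)
            assert not bm.flags.any()
            for name in ("APD40", "APD50", "APD90", "CTD50", "CTD90",
                         "ATttp", "ATrt50", "ATrt90"):
                tol = max(2 * config.dt, 0.01 * getattr(lat, name))
                assert abs(getattr(bm, name) - getattr(lat, name)) <= tol, name
            for name in ("dVdtmax", "Vpeak", "RMP", "CaiD", "CTpeak",
                         "ATpeak"):
                assert getattr(bm, name) == pytest.approx(
                    getattr(lat, name), rel=0.01), name
            checked += 1


def test_backend_registry():
    backend = get_backend("surrogate")
    assert backend.name == "surrogate"
    with pytest.raises(InvalidParameterError):
        get_backend("no-such-backend")


def test_documented_baseline_matches_constants_table():
    assert BASELINE["APD90"] == 270.0 and BASELINE["CTpeak"] == 5.0e-4
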