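"""Mechanism scans, parabolic fits and EC50-effect projection."""

import numpy as np
import pytest

from inosim import MechanismSpec, fit_parabola, project_effect, scan_mechanism
from inosim.errors import FitError, InvalidParameterError
from inosim.io import load_mechanism_config
from inosim.mechanisms import beta_adrenergic_grid, mechanism_report


@pytest.fixture(scope="module")
def scan_models(small_population):
    return small_population.models[:25]


class TestParabolaFit:
    def test_exact_quadratic(self):
        x = np.linspace(-2, 2, 7)
        a, b, c = fit_parabola(zip(x, x**2))
        assert (a, b, c) == pytest.approx((1.0, 0.0, 0.0), abs=1e-10)

    def test_degenerate_line(self):
        x = np.linspace(0, 3, 5)
        a, b, c = fit_parabola(zip(x, 2 * x + 1))
        assert (a, b, c) == pytest.approx((0.0, 2.0, 1.0), abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        """Least-squares coefficients agree with an independent
        normal-equations solve on noisy quadratic data."""
        rng = np.random.default_rng(3)
        x = np.linspace(1, 3, 11)
        y = 0.4 * x**2 - 0.3 * x + 1.1 + rng.normal(0, 0.05, x.size)
        a, b, c = fit_parabola(zip(x, y))
        X = np.vander(x, 3)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert (a, b, c) == pytest.approx(tuple(beta), abs=1e-9)

    def test_needs_three_distinct_points(self):
        with pytest.raises(FitError):
            fit_parabola([(1.0, 1.0), (1.0, 2.0), (2.0, 3.0)])


class TestProjection:
    def test_square_root_case(self):
        assert project_effect((1.0, 0.0, 0.0), 4.0, (0.0, 3.0)) == \
            pytest.approx(2.0)

    def test_unreachable_target(self):
        # max over [0, 3] is 9 < 20
        assert project_effect((1.0, 0.0, 0.0), 20.0, (0.0, 3.0)) is None

    def test_linear_case(self):
        assert project_effect((0.0, 1.0, 0.0), 1.24, (1.0, 3.0)) == \
            pytest.approx(1.24)

    def test_two_roots_pick_nearest_baseline(self):
        # (x - 2)^2 + 1 = 2 has roots 1 and 3; 1 is nearer to 1.0
        assert project_effect((1.0, -4.0, 5.0), 2.0, (0.0, 4.0)) == \
            pytest.approx(1.0)

    def test_degenerate_constant(self):
        assert project_effect((0.0, 0.0, 1.2), 1.3, (0.0, 3.0)) is None
        assert project_effect((0.0, 0.0, 1.3), 1.3, (0.0, 3.0)) == 1.0

    def test_nonpositive_target_rejected(self):
        with pytest.raises(InvalidParameterError):
            project_effect((1.0, 0.0, 0.0), 0.0, (0.0, 3.0))

    def test_projection_consistency_property(self):
        """Any returned root re-evaluates to its target within 1e-9."""
        rng = np.random.default_rng(17)
        found = 0
        for _ in range(200):
            coeffs = tuple(rng.normal(scale=[0.5, 1.0, 1.0]))
            target = rng.uniform(0.5, 3.0)
            root = project_effect(coeffs, target, (0.1, 5.0))
            if root is None:
                continue
            a, b, c = coeffs
            assert abs(a * root**2 + b * root + c - target) < 1e-9
            found += 1
        assert found > 20  # the property was actually exercised


class TestScans:
    def test_control_identity_at_factor_one(self, scan_models, backend,
                                            config):
        spec = MechanismSpec(name="serca_activation", params=("sJup",),
                             scan_range=(1.0, 3.0))
        curve = scan_mechanism(scan_models, spec, backend, config, n_points=5)
        i = int(np.argmin(np.abs(curve.factors - 1.0)))
        assert curve.factors[i] == 1.0
        assert curve.median_fraction[i] == pytest.approx(1.0, abs=1e-9)

    def test_cao_scan_strictly_increasing(self, scan_models, backend, config):
        spec = MechanismSpec(name="extracellular_ca_increase", params=("cao",),
                             scan_range=(1.0, 3.0))
        curve = scan_mechanism(scan_models, spec, backend, config, n_points=7)
        assert np.all(np.diff(curve.median_fraction) > 0)

    def test_sensitisation_raises_tension(self, scan_models, backend, config):
        """Lower ca50 (higher myofilament calcium sensitivity) means more
        tension: the fraction decreases along increasing ca50_scale."""
        spec = MechanismSpec(name="ca_sensitivity_decrease",
                             params=("ca50_scale",), scan_range=(0.1, 1.0))
        curve = scan_mechanism(scan_models, spec, backend, config, n_points=7)
        assert np.all(np.diff(curve.median_fraction) < 0)

    def test_projection_of_unit_target_is_baseline(self, scan_models,
                                                   backend, config):
        spec = MechanismSpec(name="ical_activation", params=("sCaL",),
                             scan_range=(1.0, 3.0))
        curve = scan_mechanism(scan_models, spec, backend, config)
        sf = project_effect(curve.coefficients, 1.0, spec.scan_range)
        assert sf == pytest.approx(1.0, abs=0.05)

    def test_beta_adrenergic_grid_shape(self, scan_models, backend, config):
        grid = beta_adrenergic_grid(scan_models[:8], backend, config,
                                    n_points=3)
        assert len(grid) == 9
        assert {"mean_fraction", "sd_fraction"} <= set(grid.columns)
        node = grid[(grid.sCaL_factor == 1.0) & (grid.sKs_factor == 1.0)]
        assert node["mean_fraction"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_scan_range_validated_against_allowed(self):
        with pytest.raises(InvalidParameterError):
            MechanismSpec(name="ical_activation", params=("sCaL",),
                          scan_range=(1.0, 10.0))


class TestReport:
    def test_thirteen_compound_rows(self, scan_models, backend, config):
        specs, effects = load_mechanism_config()
        report = mechanism_report(specs, effects, scan_models, backend,
                                  config, n_points=7)
        assert len(report) == 13
        assert not report["incomplete"].any()

    def test_nak_mechanism_cannot_reach_glycoside_targets(
            self, scan_models, backend, config):
        """The NaK scan saturates well below the digoxin/ouabain EC50
        effects, so both project as not reachable (dash semantics)."""
        specs, effects = load_mechanism_config()
        report = mechanism_report(specs, effects, scan_models, backend,
                                  config, n_points=7)
        nak = report[report.mechanism == "nak_inactivation"]
        assert set(nak.compound) == {"Digoxin", "Ouabain"}
        assert not nak.reachable.any()
        assert nak.scaling_factor.isna().all()

    def test_missing_effect_marked_incomplete(self, scan_models, backend,
                                              config):
        specs, _ = load_mechanism_config()
        report = mechanism_report(
            specs, [{"mechanism": "serca_activation", "compound": "X"}],
            scan_models, backend, config, n_points=5)
        assert report["incomplete"].iloc[0]
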