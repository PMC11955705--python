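"""Pore-block arithmetic, concentration grids and population scans."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inosim import (
    ChannelBlock,
    CompoundRecord,
    ModelParameters,
    apply_block,
    concentration_grid,
    extend_grid_if_needed,
    residual_fraction,
    scan_concentrations,
)
from inosim.errors import InvalidParameterError, SchemaError


def pure_blocker(channel, ic50, hill=1.0, eftpc=1.0, name=None):
    return CompoundRecord(name=name or f"pure_{channel}", eftpc_max=eftpc,
                          blocks=(ChannelBlock(channel, ic50=ic50, hill=hill),))


class TestResidualFraction:
    @pytest.mark.parametrize("hill", [0.3, 1.0, 2.5, 7.0])
    def test_midpoint_is_half(self, hill):
        assert residual_fraction(2.0, 2.0, hill) == pytest.approx(0.5)

    def test_no_drug_no_block(self):
        assert residual_fraction(0.0, 1.0, 1.3) == 1.0

    def test_nine_fold_concentration(self):
        assert residual_fraction(9.0, 1.0, 1.0) == pytest.approx(0.1)

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidParameterError):
            residual_fraction(-1.0, 1.0, 1.0)

    @settings(derandomize=True, max_examples=200)
    @given(log_ic50=st.floats(-3, 3), hill=st.floats(0.2, 5.0),
           u1=st.floats(-6, 5), step=st.floats(0.05, 1.0))
    def test_strictly_decreasing_and_bounded(self, log_ic50, hill, u1, step):
        # concentrations placed where the block term is resolvable in double
        # precision (|hill * log10(c/ic50)| <= 6), so strictness is meaningful
        ic50 = 10.0 ** log_ic50
        c1 = ic50 * 10.0 ** (u1 / hill)
        c2 = ic50 * 10.0 ** ((u1 + step) / hill)
        r1 = residual_fraction(c1, ic50, hill)
        r2 = residual_fraction(c2, ic50, hill)
        assert 0.0 < r2 < r1 <= 1.0


class TestApplyBlock:
    def test_zero_concentration_identity(self):
        p = ModelParameters(sCaL=1.2)
        compound = pure_blocker("ICaL", ic50=1.0)
        assert apply_block(p, compound, 0.0) == p

    def test_single_channel_midpoint(self):
        blocked = apply_block(ModelParameters(), pure_blocker("ICaL", 2.0),
                              2.0)
        assert blocked.sCaL == pytest.approx(0.5)
        assert blocked.sKr == 1.0 and blocked.sNa == 1.0

    def test_multichannel_hand_computed(self):
        """Per-channel residuals multiply independently (oracle: direct Hill
        arithmetic)."""
        compound = CompoundRecord(
            name="multi", eftpc_max=0.5,
            blocks=(ChannelBlock("IKr", ic50=1.0, hill=1.0),
                    ChannelBlock("ICaL", ic50=2.0, hill=2.0)))
        blocked = apply_block(ModelParameters(sKr=0.8), compound, 1.0)
        assert blocked.sKr == pytest.approx(0.8 * 0.5)
        assert blocked.sCaL == pytest.approx(1.0 / (1.0 + 0.25))

    def test_unknown_channel_rejected(self):
        with pytest.raises(SchemaError):
            ChannelBlock("IFunny", ic50=1.0, hill=1.0)


class TestConcentrationGrid:
    def test_scalar_multiples(self):
        grid = concentration_grid(0.01, [0.1, 1, 10, 100])
        assert np.allclose(grid, [0.001, 0.01, 0.1, 1.0])

    def test_default_grid_contract(self):
        grid = concentration_grid(2.0)
        assert grid.size == 13
        assert grid[0] == pytest.approx(0.2)
        assert grid[-1] == pytest.approx(200.0)
        assert np.any(np.isclose(grid, 2.0))  # contains EFTPC_max exactly

    def test_empty_multipliers_rejected(self):
        with pytest.raises(InvalidParameterError):
            concentration_grid(1.0, [])


class TestScans:
    def test_inert_compound_is_flat(self, backend, config):
        inert = pure_blocker("IKr", ic50=1e9)
        models = [ModelParameters(), ModelParameters(sCaL=1.2)]
        table = scan_concentrations(models, inert, backend, config)
        assert np.allclose(table.df["at_fraction"], 1.0, atol=1e-6)

    def test_cal_blocker_median_strictly_decreasing(self, backend, config):
        compound = pure_blocker("ICaL", ic50=1.0, eftpc=1.0)
        table = scan_concentrations([ModelParameters()], compound, backend,
                                    config)
        med = table.medians().to_numpy()
        assert np.all(np.diff(med) < 0)

    def test_half_cal_block_oracle_value(self, backend, config):
        """At C = IC50 a pure I_CaL blocker halves sCaL; pushing the half
        calcium transient through the tension Hill gives a fraction of
        control of 0.3834 (hand-evaluated surrogate algebra)."""
        compound = pure_blocker("ICaL", ic50=1.0, eftpc=1.0)
        table = scan_concentrations([ModelParameters()], compound, backend,
                                    config, grid=[1.0])
        frac = table.df["at_fraction"].iloc[0]
        k, c0 = 9.7468e-4, 5.0e-4
        c = c0 * 0.5 ** 0.8
        expected = (c**2 / (c**2 + k**2)) / (c0**2 / (c0**2 + k**2))
        assert expected == pytest.approx(0.3834, abs=5e-4)
        assert frac == pytest.approx(expected, rel=1e-3)

    def test_normalisation_identity_at_zero(self, backend, config):
        compound = pure_blocker("ICaL", ic50=0.5)
        models = [ModelParameters(sCaL=s) for s in (0.8, 1.0, 1.2)]
        table = scan_concentrations(models, compound, backend, config,
                                    grid=[1e-12])
        assert np.allclose(table.df["at_fraction"], 1.0, atol=1e-6)


class TestGridExtension:
    def test_strong_blocker_not_extended(self, backend, config):
        compound = pure_blocker("ICaL", ic50=1.0, eftpc=1.0)
        table = scan_concentrations([ModelParameters()], compound, backend,
                                    config)
        extended = extend_grid_if_needed(table, compound, [ModelParameters()],
                                         backend, config)
        assert extended.grid.size == table.grid.size

    def test_inert_compound_extended_to_1e5(self, backend, config):
        inert = pure_blocker("IKr", ic50=1e12, eftpc=1.0)
        table = scan_concentrations([ModelParameters()], inert, backend,
                                    config)
        extended = extend_grid_if_needed(table, inert, [ModelParameters()],
                                         backend, config)
        assert extended.grid[-1] == pytest.approx(1e5)

    def test_weak_blocker_crosses_half_only_when_extended(self, backend,
                                                          config):
        """A blocker with IC50 = 4500x EFTPC only halves tension around
        3000x, so the default scan triggers the extension and the extended
        median ends below 0.5."""
        weak = pure_blocker("ICaL", ic50=4500.0, eftpc=1.0)
        table = scan_concentrations([ModelParameters()], weak, backend,
                                    config)
        assert table.medians().iloc[-1] > 0.5
        extended = extend_grid_if_needed(table, weak, [ModelParameters()],
                                         backend, config)
        assert extended.grid.size > table.grid.size
        assert extended.medians().iloc[-1] < 0.5


def test_ikr_block_does_not_reduce_tension(backend, config):
    """Surrogate tension has no direct hERG dependence: a pure IKr blocker
    leaves the AT_peak median at 1 up to EAD onset (documented divergence
    from biphasic multichannel behaviour in biophysical models)."""
    compound = pure_blocker("IKr", ic50=1.0, eftpc=1.0)
    table = scan_concentrations([ModelParameters()], compound, backend,
                                config)
    med = table.medians().dropna()
    assert np.all(med.to_numpy() >= 1.0 - 1e-9)
    # at strong block (sCaL/sKr >= 6) beats are EAD-flagged, not negative
    flagged = table.df[table.df["flagged"]]
    assert (flagged["concentration"] >= 5.0).all()
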