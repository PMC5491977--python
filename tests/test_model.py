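"""Unit tests for the single-column model primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from callosim import (
    ColumnState,
    ConnectivityConstants,
    MembranePotentials,
    SigmoidParams,
    SynapticKernelParams,
    column_derivatives,
    column_preset,
    fixed_point,
    membrane_potentials,
    population_rates,
    sigmoid,
)
from callosim.engine import _Kernel


class TestSigmoid:
    @pytest.mark.parametrize(
        "v, expected",
        [
            (6.0, 2.5),  # midpoint: half the 2*e0 ceiling
            (1e6, 5.0),  # saturation
            (-1e6, 0.0),  # silence
            (0.0, 0.16784611640741254),  # 5 / (1 + exp(0.56 * 6))
        ],
    )
    def test_reference_values(self, v, expected):
        assert sigmoid(v) == pytest.approx(expected, abs=1e-12)

    def test_overflow_safe(self):
        with np.errstate(over="raise"):
            assert sigmoid(-1e300) == pytest.approx(0.0, abs=1e-300)
            assert sigmoid(1e300) == pytest.approx(5.0, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=-1e4, max_value=1e4),
           st.floats(min_value=1e-6, max_value=1e4))
    def test_monotone_and_bounded(self, v, dv):
        p = SigmoidParams()
        lo, hi = sigmoid(v, p), sigmoid(v + dv, p)
        assert 0.0 <= lo <= hi <= 2 * p.e0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SigmoidParams(e0=-1.0)
        with pytest.raises(ValueError):
            SigmoidParams(r=0.0)


class TestMembranePotentials:
    def test_zero_state_gives_zero_potentials(self):
        pot = membrane_potentials(ColumnState())
        assert (pot.vp, pot.ve, pot.vs, pot.vf) == (0.0, 0.0, 0.0, 0.0)

    def test_pyramidal_psp_fans_out_with_table_weights(self):
        pot = membrane_potentials(ColumnState(yp=1.0))
        assert pot.ve == pytest.approx(135.0)
        assert pot.vs == pytest.approx(33.75)
        assert pot.vf == pytest.approx(40.5)

    def test_output_combines_excitation_and_inhibition(self):
        pot = membrane_potentials(ColumnState(ye=1.0, ys=1.0, yf=1.0))
        # 0.8 C - 0.25 C - 0.8 C = -0.25 C
        assert pot.vp == pytest.approx(-33.75)

    def test_auxiliary_pathway_adds_to_fast_input(self):
        pot = membrane_potentials(ColumnState(yl=2.0))
        assert pot.vf == pytest.approx(2.0)


class TestPopulationRates:
    def test_centre_potentials_give_half_ceiling(self):
        pot = MembranePotentials(vp=6.0, ve=6.0, vs=6.0, vf=6.0)
        r = population_rates(pot)
        assert all(
            getattr(r, k) == pytest.approx(2.5) for k in ("zp", "ze", "zs", "zf")
        )

    def test_extreme_potentials_saturate(self):
        r = population_rates(MembranePotentials(vp=-1e4, ve=1e4, vs=0.0, vf=0.0))
        assert r.zp == pytest.approx(0.0, abs=1e-12)
        assert r.ze == pytest.approx(5.0, abs=1e-12)
        assert r.zs == pytest.approx(0.16784611640741254)


class TestColumnDerivatives:
    def test_nonfinite_state_raises(self):
        state = ColumnState(yp=np.nan)
        with pytest.raises(FloatingPointError):
            column_derivatives(state, 40.0, 3.0, column_preset("LB"))

    def test_zero_state_rates_drive_kernels(self):
        p = column_preset("LB")
        d = column_derivatives(ColumnState(), 0.0, 0.0, p)
        z0 = sigmoid(0.0, p.sigmoid)
        assert d.xp == pytest.approx(p.kernel_e.G * p.kernel_e.omega * z0)
        assert d.xs == pytest.approx(p.kernel_s.G * p.kernel_s.omega * z0)
        assert d.xf == pytest.approx(p.kernel_f.G * p.kernel_f.omega * z0)
        assert d.xl == 0.0  # no fast-target input
        assert d.yp == d.ye == d.ys == d.yf == d.yl == 0.0

    def test_external_input_scaled_by_cpe(self):
        p = column_preset("LB")
        d0 = column_derivatives(ColumnState(), 0.0, 0.0, p)
        d1 = column_derivatives(ColumnState(), 108.0, 0.0, p)
        assert d1.xe - d0.xe == pytest.approx(p.kernel_e.G * p.kernel_e.omega)


class TestSynapticKernel:
    """The second-order kernel against its closed forms."""

    @pytest.mark.parametrize("G, omega", [(3.9, 55.0), (4.3, 25.0), (25.0, 250.0),
                                          (29.0, 380.0)])
    def test_impulse_response_matches_closed_form(self, G, omega):
        dt = 1e-4
        ker = _Kernel(omega, G, dt)
        n = int(5 / omega / dt)
        y, x = 0.0, G * omega  # unit-area impulse through the drive
        ys = np.empty(n + 1)
        ys[0] = y
        for i in range(n):
            y, x = ker.step(y, x, 0.0)
            ys[i + 1] = y
        t = np.arange(n + 1) * dt
        ref = G * omega * t * np.exp(-omega * t)
        mask = t > 0.1 / omega
        rel = np.abs(ys[mask] - ref[mask]) / ref[mask]
        assert rel.max() < 1e-3
        # peak at t = 1/omega with height G/e (to grid resolution)
        i = int(np.argmax(ys))
        assert t[i] == pytest.approx(1 / omega, abs=2 * dt)
        assert ys[i] == pytest.approx(G / np.e, rel=1e-3)

    def test_constant_drive_reaches_g_over_omega(self):
        G, omega, z = 4.3, 25.0, 2.0
        ker = _Kernel(omega, G, 1e-3)
        y = x = 0.0
        for _ in range(2000):
            y, x = ker.step(y, x, z)
        assert y == pytest.approx(G * z / omega, rel=1e-9)


class TestPresets:
    def test_lb_preset_matches_reference_table(self):
        p = column_preset("LB")
        assert (p.kernel_e.G, p.kernel_s.G, p.kernel_f.G) == (3.9, 4.3, 25.0)
        assert (p.kernel_e.omega, p.kernel_s.omega, p.kernel_f.omega) == (
            55.0,
            25.0,
            250.0,
        )
        assert (p.sigmoid.e0, p.sigmoid.r, p.sigmoid.s0) == (2.5, 0.56, 6.0)
        assert p.conn == ConnectivityConstants()

    @pytest.mark.parametrize(
        "band, gains, omegas",
        [
            ("MB", (3.9, 4.3, 25.0), (75.0, 33.0, 330.0)),
            ("HB", (4.3, 4.6, 29.0), (90.0, 36.0, 380.0)),
        ],
    )
    def test_band_presets(self, band, gains, omegas):
        p = column_preset(band)
        assert (p.kernel_e.G, p.kernel_s.G, p.kernel_f.G) == gains
        assert (p.kernel_e.omega, p.kernel_s.omega, p.kernel_f.omega) == omegas

    def test_unknown_band_rejected(self):
        with pytest.raises(KeyError):
            column_preset("XX")


class TestFixedPoint:
    def test_uncoupled_lb_working_points(self):
        """The stable equilibrium sits where the populations are known to
        operate: pyramidal near the linear/high-saturation transition,
        excitatory fully saturated, fast interneurons near low
        saturation."""
        fps = fixed_point("LB")
        rates = fps[-1].rates[0]
        assert 3.5 <= rates.zp <= 4.5
        assert 4.8 <= rates.ze <= 5.0
        assert 0.4 <= rates.zf <= 0.9

    def test_kernel_params_validate(self):
        with pytest.raises(ValueError):
            SynapticKernelParams(G=0.0, omega=100.0)
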