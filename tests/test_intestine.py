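"""Axial permeability profile, blood chain, capacities, and the coupled
intestinal simulation."""

import math

import numpy as np
import pytest

from gipk import (
    AbsorptionParams,
    Bolus,
    K_from_alpha,
    PeripheralState,
    PhysiologyParams,
    alpha_at,
    bolus_capacity,
    bolus_radius,
    bolus_rhs,
    peripheral_rhs,
    simulate_intestine,
    update_blood_chain,
)
from gipk.core import LAMBDA_SCALE
from gipk.gastroduodenal import BolusEmission


class TestAlphaProfile:
    def test_jejunal_peak_value(self, phys):
        p = AbsorptionParams(5.157, 5.100, 2.012e-5)
        assert alpha_at(phys.Lj / 3.0, p, phys) == pytest.approx(
            5.157e-3 / math.pi, rel=1e-14
        )

    def test_half_width_one_meter(self, phys):
        p = AbsorptionParams(5.157, 5.100, 2.012e-5)
        peak = alpha_at(phys.Lj / 3.0, p, phys)
        assert alpha_at(phys.Lj / 3.0 + 1.0, p, phys) == pytest.approx(
            peak / 2.0, rel=1e-14
        )

    def test_ileocolic_peak_in_segment_coordinate(self, phys):
        p = AbsorptionParams(5.157, 5.100, 2.012e-5)
        # peak sits 1.5 m past the jejunum outlet (global x = 3.5 m)
        assert alpha_at(phys.Lj + phys.L_total / 5.0, p, phys) == pytest.approx(
            5.100e-3 / math.pi, rel=1e-14
        )

    def test_domain_error(self, phys):
        p = AbsorptionParams(1.0, 1.0, 1e-5)
        with pytest.raises(ValueError, match="outside"):
            alpha_at(-0.1, p, phys)
        with pytest.raises(ValueError, match="outside"):
            alpha_at(phys.L_total + 0.1, p, phys)


class TestTransferRatio:
    def test_zero_alpha_zero_k(self, phys):
        assert K_from_alpha(0.0, 0.05, 0.02, phys) == 0.0

    def test_linear_in_alpha(self, phys):
        k1 = K_from_alpha(1e-3, 0.05, 0.02, phys)
        assert K_from_alpha(3e-3, 0.05, 0.02, phys) == pytest.approx(
            3.0 * k1, rel=1e-14
        )

    def test_hand_value(self, phys):
        # Vbol = 0.05 L, alpha at the jejunal peak of the published Aprepitant fit
        rb = bolus_radius(0.05)
        assert rb == pytest.approx(0.022853907486704166, rel=1e-14)
        K = K_from_alpha(5.157e-3 / math.pi, 0.05, rb, phys)
        assert K == pytest.approx(0.00023787734445157536, rel=1e-12)

    def test_zero_radius_rejected(self, phys):
        with pytest.raises(ValueError, match="rbol"):
            K_from_alpha(1e-3, 0.05, 0.0, phys)


class TestBloodChain:
    def _symmetric_pair(self, phys, K_target):
        """Two equal boluses placed symmetrically around the jejunal peak so
        both contacts carry the same transfer ratio K_target."""
        d = 0.25
        ltj = phys.Lj / 3.0
        vol = 0.05
        rb = bolus_radius(vol)
        k_factor = (vol * 1e-3) / (math.pi * rb**2 * (phys.u + phys.vb))
        alpha_needed = K_target / k_factor
        lam = alpha_needed * math.pi * (1.0 + d * d) / LAMBDA_SCALE
        params = AbsorptionParams(lam, lam, 1e-5)
        t = 0.0
        b1 = Bolus(id=0, t_entry=-(ltj + d) / phys.u, Vbol=vol, Ci=1.0)
        b2 = Bolus(id=1, t_entry=-(ltj - d) / phys.u, Vbol=vol, Ci=1.0)
        return [b1, b2], params, t

    def test_two_contact_recursion(self, phys):
        # K = (0.5, 0.5), C = (1, 1), Cb0 = 0 -> chain (0.5, 0.75)
        boluses, params, t = self._symmetric_pair(phys, 0.5)
        state = update_blood_chain(boluses, 0.0, params, phys, t=t)
        assert state.chain[0] == pytest.approx(0.5, rel=1e-12)
        assert state.chain[1] == pytest.approx(0.75, rel=1e-12)
        assert state.outlet == state.chain[-1]

    def test_equilibrium_fixed_point(self, phys):
        boluses, params, t = self._symmetric_pair(phys, 0.3)
        for b in boluses:
            b.Ci = 2.5
        state = update_blood_chain(boluses, 2.5, params, phys, t=t)
        assert np.allclose(state.chain, 2.5, rtol=1e-14)

    def test_impermeable_wall(self, phys):
        boluses, _, t = self._symmetric_pair(phys, 0.5)
        params = AbsorptionParams(0.0, 0.0, 1e-5)
        state = update_blood_chain(boluses, 0.7, params, phys, t=t)
        assert np.all(state.chain == 0.7)

    def test_no_boluses_passthrough(self, phys):
        params = AbsorptionParams(1.0, 1.0, 1e-5)
        state = update_blood_chain([], 0.42, params, phys, t=0.0)
        assert state.outlet == 0.42


class TestPointwiseRates:
    def test_bolus_equilibrium(self, phys):
        p = AbsorptionParams(5.0, 5.0, 1e-5)
        b = Bolus(id=0, t_entry=0.0, Vbol=0.05, Ci=1.0)
        assert bolus_rhs(b, 1.0, p, phys, t=3600.0) == 0.0

    def test_blood_to_bolus_direction(self, phys):
        p = AbsorptionParams(5.0, 5.0, 1e-5)
        b = Bolus(id=0, t_entry=0.0, Vbol=0.05, Ci=0.0)
        assert bolus_rhs(b, 1.0, p, phys, t=3600.0) > 0.0

    def test_peripheral_balance_and_decay(self, phys):
        p = AbsorptionParams(5.0, 5.0, 0.0)
        ps = PeripheralState(Cb_bar=1.0, history_t=np.array([0.0]), history_c=np.array([1.0]))
        assert peripheral_rhs(ps, 1.0, p, phys) == 0.0
        # outlet = 0: pure exponential decay at rate Qb/Vb + kd
        p = AbsorptionParams(5.0, 5.0, 25.343e-5)
        rate = -peripheral_rhs(ps, 0.0, p, phys)
        assert rate == pytest.approx(phys.Qb / phys.Vb + 25.343e-5, rel=1e-14)
        assert math.log(2) / rate == pytest.approx(81.513833895257, rel=1e-12)


class TestCapacity:
    def test_default_capacities(self, phys):
        cap = bolus_capacity(phys)
        assert cap.Nmax_ic == 33  # 5.5 m * 3600 s/m / 600 s
        assert cap.Nmax == 45     # 7.5 m * 3600 s/m / 600 s

    def test_faster_transit_halves_capacity(self):
        cap = bolus_capacity(PhysiologyParams(u=2.0 / 3600.0))
        assert cap.Nmax_ic == 16 and cap.Nmax == 22


class TestIntestinalSimulation:
    def _train(self, n=6, conc=10.0):
        return [
            BolusEmission(tk=600.0 * (k + 2), volume=0.05, concentration=conc)
            for k in range(n)
        ]

    def test_no_absorption_no_signal(self, phys):
        res = simulate_intestine(
            self._train(), phys, AbsorptionParams(0.0, 0.0, 2e-5), t_end=21600.0
        )
        assert np.all(res.series.values == 0.0)

    def test_causality(self, phys, aprepitant_params):
        res = simulate_intestine(
            self._train(), phys, aprepitant_params, t_end=21600.0
        )
        first_entry = 1200.0
        assert np.all(res.series.values[res.series.times <= first_entry] == 0.0)
        assert res.series.values.max() > 0.0

    def test_linearity_in_concentration(self, phys, aprepitant_params):
        r1 = simulate_intestine(self._train(conc=4.0), phys, aprepitant_params, t_end=21600.0)
        r3 = simulate_intestine(self._train(conc=12.0), phys, aprepitant_params, t_end=21600.0)
        mask = r1.series.values > 0
        assert np.allclose(
            r3.series.values[mask] / r1.series.values[mask], 3.0, rtol=1e-12
        )

    def test_chain_order_switch_changes_little_but_runs(self, phys, aprepitant_params):
        kw = dict(t_end=21600.0, dt_out=600.0)
        rd = simulate_intestine(self._train(), phys, aprepitant_params, chain_order="distal-first", **kw)
        rp = simulate_intestine(self._train(), phys, aprepitant_params, chain_order="proximal-first", **kw)
        assert rp.series.values.max() > 0
        # per-contact ratios are tiny, so orientation is a small perturbation
        assert rp.series.values.max() == pytest.approx(rd.series.values.max(), rel=1e-2)

    def test_mass_ledger(self, phys, aprepitant_params):
        # absorption strictly depletes the boluses, and every per-contact
        # blood gain matches the bolus loss rate (flux identity audit)
        ems = self._train(n=3)
        res = simulate_intestine(
            ems, phys, AbsorptionParams(5.157, 5.1, 0.0), t_end=30600.0, audit=True
        )
        lost = sum(e.volume * e.concentration for e in ems) - (
            res.excreted_mass + res.residual_mass
        )
        assert lost > 0
        assert res.audit_max_residual < 1e-10

    def test_capacity_overflow_retires_oldest(self, aprepitant_params):
        # transit covers 5 emptying periods (Nmax = 5), but a denser than
        # physiological train of 8 boluses spaced Te/2 apart overflows it
        p = PhysiologyParams(u=7.5 / 3000.0, Lj=2.0, Li=4.0, Lc=1.5)
        assert bolus_capacity(p).Nmax == 5
        ems = [
            BolusEmission(tk=300.0 * (k + 1), volume=0.05, concentration=5.0)
            for k in range(8)
        ]
        with pytest.warns(RuntimeWarning, match="Nmax"):
            res = simulate_intestine(ems, p, aprepitant_params, t_end=4200.0)
        assert np.all(np.isfinite(res.series.values))
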