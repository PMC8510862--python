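"""Fibrinolysis dynamics: closed forms, conservation, policy ordering."""

import numpy as np
import pytest

from clotlyse.errors import InvalidStateError
from clotlyse.formation import BindingRates
from clotlyse.lysis import (
    IL,
    IPAI,
    IPG,
    IPGB,
    IPN,
    IPNB,
    ITPA,
    ITPAB,
    ClotConstants,
    lysis_rate,
    make_policy,
    porosity,
    run_fibrinolysis,
    synthetic_clot_state,
    update_radius,
)


@pytest.fixture(scope="module")
def constants():
    return ClotConstants(cfr0=2.0, rf0=50.0)


class TestLysisRate:
    def test_zero_plasmin_zero_rate(self, constants):
        assert lysis_rate(0.0, 100.0, constants, BindingRates()) == 0.0
        assert lysis_rate(1.0, 0.0, constants, BindingRates()) == 0.0

    def test_saturation_limit(self, constants):
        r = BindingRates()
        rate = lysis_rate(0.01, 1e9, constants, r)
        assert rate == pytest.approx(constants.gamma * r.k_pn2 * 0.01, rel=1e-6)

    def test_half_saturation_arithmetic(self, constants):
        """pn_b=0.001, Θ=K=250, k=25, γ=0.1 -> 0.1·25·0.001·0.5 = 0.00125."""
        r = BindingRates()
        assert lysis_rate(0.001, 250.0, constants, r) == pytest.approx(0.00125)


class TestRadiusAndPorosity:
    def test_no_lysis_initial_radius(self, constants):
        assert update_radius(0.0, constants) == constants.rf0

    def test_complete_lysis_zero_radius(self, constants):
        assert update_radius(constants.cfr0, constants) == 0.0

    def test_half_lysis_sqrt2(self, constants):
        assert update_radius(constants.cfr0 / 2, constants) == pytest.approx(
            constants.rf0 / np.sqrt(2)
        )

    def test_over_lysis_rejected(self, constants):
        with pytest.raises(InvalidStateError):
            update_radius(constants.cfr0 * 1.01, constants)

    def test_porosity_endpoints_and_midpoint(self, constants):
        assert porosity(constants.rf0, constants) == pytest.approx(constants.eps0)
        assert porosity(0.0, constants) == pytest.approx(1.0)
        mid = porosity(constants.rf0 / np.sqrt(2), constants)
        assert mid == pytest.approx(1.0 - (1.0 - constants.eps0) / 2.0)


class TestTrajectoryInvariants:
    def test_monotone_lysis_radius_porosity(self, fast_clot, fast_constants):
        traj = run_fibrinolysis(fast_clot, 3, constants=fast_constants, t_max=4000)
        assert np.all(np.diff(traj.l) >= 0)
        assert np.all(np.diff(traj.rf) <= 1e-12)
        assert np.all(np.diff(traj.eps) >= -1e-12)

    def test_complete_lysis_anchor(self, fast_clot, fast_constants):
        traj = run_fibrinolysis(fast_clot, "bulk", constants=fast_constants, t_max=4000)
        assert traj.exhausted
        assert traj.rf[-1] <= fast_constants.rf0 * 2e-3
        assert traj.percent[-1] >= 99.99

    def test_gamma_zero_freezes_geometry(self, fast_clot):
        cc = ClotConstants(cfr0=2.0, rf0=50.0, gamma=0.0)
        traj = run_fibrinolysis(fast_clot, "bulk", constants=cc, t_max=500)
        assert np.all(traj.rf == cc.rf0)
        assert np.all(traj.l == 0.0)

    def test_no_plasmin_no_lysis(self, fast_constants):
        clot = synthetic_clot_state(cfr0_uM=2.0, rf0=50.0, pn_b=0.0)
        traj = run_fibrinolysis(clot, "bulk", constants=fast_constants, t_max=500)
        assert traj.percent[-1] == 0.0

    def test_step_halving_changes_tlt_under_half_percent(self, fast_clot, fast_constants):
        t1 = run_fibrinolysis(fast_clot, "bulk", constants=fast_constants,
                              dt=0.1, t_max=4000).total_lysis_time()
        t2 = run_fibrinolysis(fast_clot, "bulk", constants=fast_constants,
                              dt=0.05, t_max=4000).total_lysis_time()
        assert abs(t1 - t2) / t1 < 0.005


class TestPolicyOrdering:
    def test_bulk_dominates_surface_pointwise(self, fast_clot, fast_constants):
        tr_s = run_fibrinolysis(fast_clot, "surface", constants=fast_constants, t_max=3000)
        tr_b = run_fibrinolysis(fast_clot, "bulk", constants=fast_constants, t_max=3000)
        n = min(len(tr_s.l), len(tr_b.l))
        assert np.all(tr_b.l[:n] - tr_s.l[:n] >= -1e-12)

    def test_cumulative_lysis_monotone_in_fixed_kappa(self, fast_clot, fast_constants):
        prev = None
        for k in (0, 2, 5, 10):
            traj = run_fibrinolysis(fast_clot, k, constants=fast_constants, t_max=1500)
            if prev is not None:
                n = min(len(prev), len(traj.l))
                assert np.all(traj.l[:n] - prev[:n] >= -1e-12)
            prev = traj.l

    def test_surface_tlt_longer_than_bulk(self, fast_clot, fast_constants):
        tlt_s = run_fibrinolysis(fast_clot, "surface", constants=fast_constants,
                                 t_max=6000).total_lysis_time()
        tlt_b = run_fibrinolysis(fast_clot, "bulk", constants=fast_constants,
                                 t_max=6000).total_lysis_time()
        assert tlt_s > tlt_b


class TestMassBalance:
    def test_closed_exchange_with_constant_porosity(self):
        """With γ=0 (ε frozen) the published relation [i] + s·[i]_b = [i]_0
        holds along the trajectory to 1e-9."""
        clot = synthetic_clot_state(
            cfr0_uM=2.0, rf0=50.0, tpa=1e-4, tpa_b=0.0, pg=0.14, pg_b=0.0, pn_b=1e-3
        )
        cc = ClotConstants(cfr0=2.0, rf0=50.0, gamma=0.0)
        traj = run_fibrinolysis(clot, "bulk", constants=cc, t_max=800)
        s = (1.0 - cc.eps0) / cc.eps0
        sp = traj.species
        pg_lineage = sp[:, IPG - 1] + sp[:, IPN - 1] + s * (sp[:, IPGB - 1] + sp[:, IPNB - 1])
        np.testing.assert_allclose(pg_lineage, pg_lineage[0], rtol=1e-9)

    def test_species_balance_during_active_lysis(self, fast_constants):
        """During lysis (ε changing), fluid + scaled-bound totals stay equal
        to the initial loads minus inhibited/converted amounts to 1e-7."""
        clot = synthetic_clot_state(
            cfr0_uM=2.0, rf0=50.0, tpa=1e-4, tpa_b=1e-5, pg=0.14,
            pg_b=2e-3, pn_b=5e-3, pai1=2e-4,
        )
        traj = run_fibrinolysis(clot, 4, constants=fast_constants, t_max=2500)
        s = (1.0 - traj.eps) / traj.eps
        sp = traj.species
        # PAI-1 is consumed only by inhibition, so its depletion measures the
        # inhibited tPA exactly.
        inhibited = sp[0, IPAI - 1] - sp[:, IPAI - 1]
        tpa_total = sp[:, ITPA - 1] + s * sp[:, ITPAB - 1] + inhibited
        np.testing.assert_allclose(tpa_total, tpa_total[0], rtol=1e-7)
        pg_total = (
            sp[:, IPG - 1] + sp[:, IPN - 1] + s * (sp[:, IPGB - 1] + sp[:, IPNB - 1])
        )
        np.testing.assert_allclose(pg_total, pg_total[0], rtol=1e-7)

    def test_bound_species_respect_capacity(self, control_clot):
        """tpa_b ≤ Θ_tPA and pg_b + pn_b ≤ Θ_Pg at the end of clotting."""
        b = control_clot.binding
        assert b.tpa_b <= control_clot.theta_tpa + 1e-9
        assert b.pg_b + b.pn_b <= control_clot.theta_pg + 1e-9


class TestPolicyParsing:
    def test_named_and_fixed_policies(self):
        assert make_policy("surface")(0, 50.0, 10) == 0
        assert make_policy("bulk")(0, 50.0, 10) == 10
        assert make_policy(3)(0, 50.0, 10) == 3
        assert make_policy(30)(0, 50.0, 10) == 10  # clamped

    def test_schedule_policy_previous_value(self):
        pol = make_policy(([0.0, 100.0], [2, 7]))
        assert pol(50.0, 50.0, 10) == 2
        assert pol(150.0, 50.0, 10) == 7

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            make_policy("inside-out")
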