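"""Single-cell cascade model: fixed points, energy bookkeeping, phenotypes."""

import dataclasses

import numpy as np
import pytest

from mapkinfo import (
    CascadeState,
    ModelParameters,
    apply_genotype,
    basal_state,
    default_parameters,
    energy_rate_at_endpoint,
    load_parameters,
    rhs,
    save_parameters,
    simulate_cell,
    steady_state,
)
from mapkinfo.cascade import fus3_steady_state, instantaneous_fluxes
from mapkinfo.ensemble import default_dose_grid


def spec_form_params():
    """Parameter set with zero basal activity (kact0 = 0)."""
    p = default_parameters()
    p.kact0 = 0.0
    return p


def activation(p):
    return p.kact * p.theta / (p.theta + p.KR) + p.kact0


class TestRhs:
    def test_no_stimulus_no_activity_no_dissipation(self):
        p = spec_form_params()
        p.theta = 0.0
        s = basal_state(p)
        d = rhs(s, p)
        assert d.A == 0.0 and d.Fpp == 0.0 and d.Tp == 0.0
        assert d.Egtp == 0.0 and d.Eatp == 0.0

    def test_negative_dose_rejected(self):
        p = default_parameters()
        p.theta = -1.0
        with pytest.raises(ValueError):
            rhs(basal_state(default_parameters()), p)

    def test_negative_concentration_rejected(self, params):
        s = basal_state(params)
        s.Fpp = -1.0
        with pytest.raises(ValueError):
            rhs(s, params)

    def test_derivative_matches_hand_formula(self, params):
        p = params.copy()
        p.theta = 10.0
        s = basal_state(p)
        s.Fpp, s.Tp, s.A = 5.0, 40.0, 2.0
        d = rhs(s, p)
        act = activation(p)
        assert d.A == pytest.approx(act * (s.Rtot - s.A)
                                    - (p.kgap0 + p.kgap * s.Sst2) * s.A)
        assert d.Fpp == pytest.approx(p.kf * s.A * (s.Ftot - s.Fpp)
                                      - (p.kd0 + p.kd * s.Msg5) * s.Fpp)
        assert d.Egtp == pytest.approx((p.kgap0 + p.kgap * s.Sst2) * s.A)
        assert d.Eatp == pytest.approx(
            p.natp_fus3 * p.kf * s.A * (s.Ftot - s.Fpp)
            + p.natp_ste12 * p.kt * s.Fpp * (p.Ttot - s.Tp))


class TestFrozenCycles:
    """With synthesis frozen the model is independent push-pull cycles."""

    def test_integrator_reaches_closed_form_fixed_point(self, frozen_cycle_params):
        p = frozen_cycle_params.copy()
        p.theta = 5.0
        y0 = basal_state(p)
        traj = simulate_cell(p, t_end=20000.0, y0=y0)
        end = traj.endpoint()
        act = activation(p)
        A_star = y0.Rtot * act / (act + p.kgap0 + p.kgap * y0.Sst2)
        fpp_star = fus3_steady_state(p, A_star, y0.Ftot, y0.Msg5)
        assert end.Fpp == pytest.approx(fpp_star, rel=1e-3)

    def test_steady_state_atp_rate_equals_dephosphorylation_flux(self, frozen_cycle_params):
        p = frozen_cycle_params.copy()
        p.theta = 5.0
        traj = simulate_cell(p, t_end=20000.0, y0=basal_state(p))
        end = traj.endpoint()
        fl = energy_rate_at_endpoint(traj, window=500.0)
        expected = p.natp_fus3 * (p.kd0 + p.kd * end.Msg5) * end.Fpp
        assert fl.jatp1 == pytest.approx(expected, rel=1e-3)

    def test_flux_balance_at_steady_state(self, frozen_cycle_params):
        p = frozen_cycle_params.copy()
        p.theta = 2.0
        end = simulate_cell(p, t_end=20000.0, y0=basal_state(p)).endpoint()
        influx = p.kf * end.A * (end.Ftot - end.Fpp)
        outflux = (p.kd0 + p.kd * end.Msg5) * end.Fpp
        assert abs(influx - outflux) / outflux < 1e-3

    def test_msg5_compensation_raises_total_flux(self, frozen_cycle_params):
        """Raising Msg5 while adjusting the dose to hold Fpp* constant
        strictly increases total dissipation (the two-level compensation
        argument)."""
        p = frozen_cycle_params.copy()
        p.theta = 2.0
        y0 = basal_state(p)
        act = activation(p)
        A1 = y0.Rtot * act / (act + p.kgap0 + p.kgap * y0.Sst2)
        fpp_target = fus3_steady_state(p, A1, y0.Ftot, y0.Msg5)

        jt = []
        for msg5 in (y0.Msg5, 5 * y0.Msg5 + 10):
            kd_eff = p.kd0 + p.kd * msg5
            # A needed for the same Fpp*
            A_req = kd_eff * fpp_target / (p.kf * (y0.Ftot - fpp_target))
            s = CascadeState(A=A_req, Rtot=y0.Rtot, Ftot=y0.Ftot, Fpp=fpp_target,
                             Ttot=p.Ttot, Tp=0.0, Sst2=y0.Sst2, Msg5=msg5, Rep=y0.Rep)
            jt.append(instantaneous_fluxes(s, p).jtotal)
        assert jt[1] > jt[0]


class TestSimulateCell:
    def test_zero_everything_stays_zero(self):
        p = spec_form_params()
        p.theta = 0.0
        for g in p.genes.values():
            g.beta0 = 0.0
        y0 = CascadeState(A=0, Rtot=10, Ftot=10, Fpp=0, Ttot=p.Ttot, Tp=0,
                          Sst2=0, Msg5=0, Rep=0)
        end = simulate_cell(p, t_end=500.0, y0=y0).endpoint()
        assert end.Fpp == pytest.approx(0.0, abs=1e-12)
        assert end.Eatp == pytest.approx(0.0, abs=1e-9)

    def test_tolerance_halving_changes_endpoint_by_less_than_0p1pct(self, params):
        p = params.copy()
        p.theta = 5.0
        f1 = simulate_cell(p, rtol=1e-7, atol=1e-7).endpoint().Fpp
        f2 = simulate_cell(p, rtol=5e-8, atol=5e-8).endpoint().Fpp
        assert abs(f1 - f2) / f1 < 1e-3

    def test_dose_monotonicity_wild_type(self, params):
        lo, hi = params.copy(), params.copy()
        lo.theta, hi.theta = 1e-4, 480.0
        assert simulate_cell(hi).endpoint().Fpp >= simulate_cell(lo).endpoint().Fpp

    def test_msg5_deletion_raises_fpp_at_every_dose(self, params):
        mut = apply_genotype(params, "msg5d")
        for dose in default_dose_grid()[::2]:
            pw, pm = params.copy(), mut.copy()
            pw.theta = pm.theta = float(dose)
            fw = simulate_cell(pw).endpoint().Fpp
            fm = simulate_cell(pm, y0=basal_state(pm)).endpoint().Fpp
            assert fm > fw

    def test_state_invariants_along_trajectory(self, params):
        p = params.copy()
        p.theta = 50.0
        traj = simulate_cell(p)
        for i in range(len(traj.times)):
            traj.state_at(i).validate()
        # energy counters are non-decreasing
        assert np.all(np.diff(traj.states[:, -2]) >= -1e-9)
        assert np.all(np.diff(traj.states[:, -1]) >= -1e-9)

    def test_cumulative_energy_equals_flux_integral(self, params):
        p = params.copy()
        p.theta = 5.0
        traj = simulate_cell(p, dt_out=2.0)
        comp = np.array([dataclasses.astuple(
            instantaneous_fluxes(traj.state_at(i), p))
            for i in range(len(traj.times))])
        total_by_quadrature = np.trapezoid(comp.sum(axis=1), traj.times)
        end = traj.endpoint()
        assert total_by_quadrature == pytest.approx(end.Egtp + end.Eatp, rel=5e-3)


class TestEnergyRate:
    def test_zero_activity_trajectory_has_zero_fluxes(self):
        p = spec_form_params()
        p.theta = 0.0
        traj = simulate_cell(p, t_end=100.0, y0=basal_state(p))
        fl = energy_rate_at_endpoint(traj, window=50.0)
        assert fl.jtotal == pytest.approx(0.0, abs=1e-12)

    def test_component_sum_is_exact(self, params):
        p = params.copy()
        p.theta = 20.0
        fl = energy_rate_at_endpoint(simulate_cell(p), window=100.0)
        assert fl.jtotal == fl.jgtp + fl.jatp1 + fl.jatp2
        assert min(fl.jgtp, fl.jatp1, fl.jatp2) >= 0

    def test_window_validation(self, params):
        p = params.copy()
        p.theta = 1.0
        traj = simulate_cell(p, t_end=100.0)
        with pytest.raises(ValueError):
            energy_rate_at_endpoint(traj, window=0.0)
        with pytest.raises(ValueError):
            energy_rate_at_endpoint(traj, window=200.0)


class TestBasalState:
    def test_fixed_point_is_stationary(self, params):
        s = basal_state(params)
        p = params.copy()
        p.theta = 0.0
        d = rhs(s, p)
        for f in ("A", "Rtot", "Ftot", "Fpp", "Tp", "Sst2", "Msg5", "Rep"):
            assert abs(getattr(d, f)) < 1e-8

    def test_relaxation_converges_to_fixed_point(self, params):
        """Integrating from a displaced start at theta=0 relaxes onto the
        solved pre-stimulus steady state."""
        p = params.copy()
        p.theta = 0.0
        target = basal_state(p)
        y0 = CascadeState(**{**dataclasses.asdict(target)})
        y0.Rtot *= 1.3
        y0.Fpp = 5.0
        end = simulate_cell(p, t_end=40000.0, y0=y0).endpoint()
        assert end.Fpp == pytest.approx(target.Fpp, rel=2e-2)
        assert end.Sst2 == pytest.approx(target.Sst2, rel=2e-2)

    def test_closed_form_when_no_basal_activity(self):
        p = spec_form_params()
        b = basal_state(p)
        assert b.A == 0 and b.Fpp == 0 and b.Tp == 0
        for gene, attr in [("STE2", "Rtot"), ("FUS3", "Ftot"), ("SST2", "Sst2"),
                           ("MSG5", "Msg5"), ("FUS1", "Rep")]:
            g = p.genes[gene]
            assert getattr(b, attr) == pytest.approx(g.beta0 / g.gamma)

    def test_steady_state_monotone_in_dose(self, params):
        fpps = [steady_state(params, theta=t).Fpp for t in (0.01, 1.0, 100.0)]
        assert fpps[0] < fpps[1] < fpps[2]


class TestParameterIO:
    def test_yaml_round_trip(self, tmp_path, params):
        path = tmp_path / "p.yaml"
        save_parameters(params, path)
        q = load_parameters(path)
        assert q.to_dict() == params.to_dict()

    def test_unknown_keys_rejected(self):
        d = default_parameters().to_dict()
        d["mystery_rate"] = 1.0
        with pytest.raises(ValueError, match="unknown"):
            ModelParameters.from_dict(d)

    def test_unknown_gene_key_rejected(self):
        d = default_parameters().to_dict()
        d["genes"]["STE2"]["foo"] = 2.0
        with pytest.raises(ValueError, match="unknown"):
            ModelParameters.from_dict(d)

    def test_invalid_rate_rejected(self):
        d = default_parameters().to_dict()
        d["kf"] = -1.0
        with pytest.raises(ValueError):
            ModelParameters.from_dict(d)

    def test_trajectory_tsv_sidecar(self, tmp_path, params):
        p = params.copy()
        p.theta = 1.0
        traj = simulate_cell(p, t_end=50.0)
        out = tmp_path / "traj.tsv"
        traj.to_tsv(out, sidecar={"seed": 3})
        assert out.exists() and (tmp_path / "traj.tsv.json").exists()
        df = traj.to_frame()
        assert list(df.columns)[0] == "time_s" and "Eatp" in df.columns


class TestGenotypes:
    def test_deletions_zero_out_synthesis(self, params):
        m = apply_genotype(params, "msg5d")
        assert m.genes["MSG5"].beta0 == 0 and m.genes["MSG5"].beta == 0
        s = apply_genotype(params, "sst2d")
        assert s.genes["SST2"].beta0 == 0 and s.genes["SST2"].beta == 0

    def test_sensitized_lowers_kd_only(self, params):
        m = apply_genotype(params, "msg5_sensitized")
        assert m.genes["MSG5"].KD < params.genes["MSG5"].KD
        assert m.genes["MSG5"].beta == params.genes["MSG5"].beta

    def test_unknown_genotype_rejected(self, params):
        with pytest.raises(ValueError):
            apply_genotype(params, "kss1d")
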