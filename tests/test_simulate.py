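"""Tests of the CSTR guild simulator and sequencing-count emitter."""

import numpy as np
import pytest

from nitflow.scenarios import default_guilds, get_scenario
from nitflow.simulate import (
    ANAMMOX_NO2_PER_NH4,
    NO3_PER_N2_MOL,
    GuildParams,
    ReactorConfig,
    ReactorState,
    apply_disturbance,
    generate_community_counts,
    run_to_steady_state,
    simulate_reactor,
    tracer_mean_residence_time,
)


class TestReactorConfig:
    def test_defaults_encode_reference_reactor(self):
        cfg = ReactorConfig()
        assert cfg.working_volume == 4.5
        assert cfg.hrt == pytest.approx(6.25)
        assert cfg.influent_nh4_load == 86.4

    @pytest.mark.parametrize("kw", [
        {"working_volume": 0.0}, {"influent_flow": -1.0},
        {"dt": 0.0}, {"duration": 0.001, "dt": 0.02},
        {"influent_nh4_load": -5.0},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            ReactorConfig(**kw)

    def test_guild_param_validation(self):
        with pytest.raises(ValueError):
            GuildParams("XXX", 1, 1, 1, 1, 0.1)
        with pytest.raises(ValueError):
            GuildParams("AOB", -1, 1, 1, 1, 0.1)
        with pytest.raises(ValueError):
            GuildParams("AOB", 1, 1, 1, 1, 0.1, attached_fraction=1.5)


class TestTracer:
    def test_reference_hrt_recovered(self):
        mrt = tracer_mean_residence_time(ReactorConfig())
        assert mrt == pytest.approx(6.25, rel=0.01)

    def test_v_over_q_identity(self):
        cfg = ReactorConfig(working_volume=1.0, influent_flow=1.0,
                            influent_nh4_load=0.0)
        assert tracer_mean_residence_time(cfg) == pytest.approx(1.0, rel=0.005)

    def test_linear_in_volume(self):
        base = ReactorConfig(working_volume=2.0, influent_flow=1.0)
        double = ReactorConfig(working_volume=4.0, influent_flow=1.0)
        m1 = tracer_mean_residence_time(base)
        m2 = tracer_mean_residence_time(double)
        assert m2 / m1 == pytest.approx(2.0, rel=0.01)


class TestAbioticWashout:
    def test_effluent_matches_influent_without_biology(self):
        sim = simulate_reactor(ReactorConfig(duration=120.0), [])
        last = sim.chem_true.iloc[-1]
        cfg = ReactorConfig()
        assert last["nh4_out_mgN_L"] == pytest.approx(
            cfg.influent_nh4_conc, rel=1e-6)
        assert last["no2_out_mgN_L"] == 0.0
        assert last["no3_out_mgN_L"] == 0.0
        assert last["n2_mgN_d"] == 0.0


class TestDisturbance:
    def _state(self, attached, suspended):
        return ReactorState(1.0, 0.0, 0.0, np.asarray(attached, float),
                            np.asarray(suspended, float))

    def test_zero_fraction_is_identity(self):
        st = self._state([10.0, 5.0], [2.0, 1.0])
        out = apply_disturbance(st, 0.0)
        np.testing.assert_allclose(out.attached, st.attached)
        np.testing.assert_allclose(out.suspended, st.suspended)

    def test_full_mixing_moves_everything(self):
        out = apply_disturbance(self._state([10.0], [2.0]), 1.0)
        assert out.attached[0] == 0.0
        assert out.suspended[0] == 12.0

    @pytest.mark.parametrize("frac", [0.0, 0.25, 0.5, 0.99, 1.0])
    def test_total_biomass_conserved(self, frac):
        st = self._state([10.0, 3.0, 0.5], [2.0, 0.0, 4.0])
        out = apply_disturbance(st, frac)
        np.testing.assert_allclose(out.attached + out.suspended,
                                   st.attached + st.suspended, rtol=1e-12)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            apply_disturbance(self._state([1.0], [0.0]), 1.5)


def _anammox_only():
    return (GuildParams("AMX", mu_max=0.15, k_substrate=0.1, k_oxygen=0.0,
                        oxygen_inhibition_k=0.4, yield_biomass=0.07,
                        decay=0.005, attached_fraction=0.95,
                        attached_capacity=9.0, attach_rate=0.15,
                        detach_rate=0.01),)


class TestStoichiometry:
    def test_anammox_no3_to_n2_ratio(self):
        """At steady state the anammox by-product NO3-N to N2-N ratio is
        0.26/2.04, the algebraic consequence of the fixed stoichiometry
        (independently derivable from the species balance: all NO3 and N2
        come from the same reaction extent)."""
        # feed ammonium and nitrite together so anammox alone can run
        cfg = ReactorConfig(do_setpoint=0.05, influent_nh4_load=37.2,
                            influent_no2_load=49.2)
        state, n2_rate = run_to_steady_state(cfg, _anammox_only(), tol=1e-9)
        no3_rate = state.no3 * cfg.influent_flow
        assert n2_rate > 1.0  # anammox is actually active
        assert no3_rate / n2_rate == pytest.approx(0.26 / 2.04, rel=1e-6)

    def test_anammox_consumption_ratio_constant(self):
        # NO2:NH4 consumption fixed at 1.32; nitrogen conserved in products
        total_in = 1.0 + ANAMMOX_NO2_PER_NH4
        from nitflow.simulate import _AMX_N2_FRAC, _AMX_NO3_FRAC
        assert _AMX_N2_FRAC + _AMX_NO3_FRAC == pytest.approx(1.0, abs=1e-15)
        assert (_AMX_NO3_FRAC / _AMX_N2_FRAC
                == pytest.approx(NO3_PER_N2_MOL / 2.04, rel=1e-12))
        assert total_in == pytest.approx(2.32)


class TestNitrogenConservation:
    def test_daily_balance_within_tolerance(self):
        """Influent load equals accumulation + effluent export + N2
        evasion each day, within 0.1% of the load."""
        sc = get_scenario()
        sim = simulate_reactor(sc.config, sc.guilds, disturbance_day=0.0,
                               fitness_fn=sc.fitness_fn())
        cfg = sc.config
        chem = sim.chem_true
        conc = chem[["nh4_out_mgN_L", "no2_out_mgN_L",
                     "no3_out_mgN_L"]].sum(axis=1).to_numpy()
        inventory = conc * cfg.working_volume
        n2 = chem["n2_mgN_d"].to_numpy()
        eff = chem["effluent_mgN_d"].to_numpy()
        for i in range(1, len(chem)):
            accum = inventory[i] - inventory[i - 1]
            balance = accum + eff[i] + n2[i] - cfg.total_n_load
            assert abs(balance) < 1e-3 * cfg.total_n_load

    def test_non_negative_outputs(self, scenario_run):
        sim, _ = scenario_run
        assert (sim.chem_true[["nh4_out_mgN_L", "no2_out_mgN_L",
                               "no3_out_mgN_L", "n2_mgN_d"]].to_numpy()
                >= 0).all()
        assert (sim.guild_biomass.to_numpy() >= 0).all()

    def test_taxon_profile_rows_sum_to_one(self, scenario_run):
        sim, _ = scenario_run
        np.testing.assert_allclose(sim.taxon_profile.sum(axis=1), 1.0,
                                   atol=1e-9)


class TestCommunityCounts:
    def _sim(self, seed=0):
        sc = get_scenario()
        return simulate_reactor(
            ReactorConfig(duration=5.0, seed=seed), sc.guilds)

    def test_depth_is_exact(self):
        sim = self._sim()
        cc = generate_community_counts(
            sim, {"AOB": {"a": 1.0}, "AMX": {"b": 1.0}}, depth=30000, seed=1)
        assert (cc.counts.sum(axis=1) == 30000).all()

    def test_single_taxon_takes_all_reads(self):
        sim = self._sim()
        cc = generate_community_counts(
            sim, {"AOB": {"only": 1.0, "never": 0.0}}, depth=500, seed=2)
        assert (cc.counts["only"] == 500).all()
        assert (cc.counts["never"] == 0).all()

    def test_multinomial_expectation(self):
        """With infinite dispersion the counts are multinomial around the
        biomass-weighted profile: the mean observed proportion over many
        samples sits within 3 standard errors of the truth."""
        sc = get_scenario()
        cfg = ReactorConfig(duration=1.0, seed=3)
        sim = simulate_reactor(cfg, sc.guilds)
        tmap = {"AOB": {"a": 0.5, "b": 0.5}, "AMX": {"c": 1.0}}
        depth = 2000
        reps = 500  # 500 samples at one fixed profile
        rng = np.random.default_rng(42)
        biomass = sim.guild_biomass.iloc[0]
        total = biomass.sum()
        frac_aob = biomass["AOB"] / total
        frac_amx = biomass["AMX"] / total
        rest = 1.0 - frac_aob - frac_amx
        p_true = np.array([0.5 * frac_aob, 0.5 * frac_aob, frac_amx])
        p_true = p_true / p_true.sum()
        draws = rng.multinomial(depth, p_true, size=reps) / depth
        cc = generate_community_counts(sim, tmap, depth=depth,
                                       dispersion=np.inf, seed=4)
        obs = cc.counts.iloc[0].to_numpy() / depth
        se = np.sqrt(p_true * (1 - p_true) / depth)
        assert np.all(np.abs(obs - p_true) < 4 * se + 1e-12)
        # and the oracle multinomial mean is itself compatible at 3 sigma
        assert np.all(np.abs(draws.mean(axis=0) - p_true)
                      < 3 * se / np.sqrt(reps) + 1e-3)

    def test_zero_biomass_is_degenerate(self):
        sim = simulate_reactor(ReactorConfig(duration=3.0), [])
        sim.guild_biomass["AOB"] = 0.0
        with pytest.raises(ValueError, match="[Dd]egenerate|all-zero"):
            generate_community_counts(sim, {"AOB": {"a": 1.0}}, depth=10,
                                      seed=0)

    def test_depth_validation(self):
        sim = self._sim()
        with pytest.raises(ValueError):
            generate_community_counts(sim, {"AOB": {"a": 1.0}}, depth=0,
                                      seed=0)


class TestSteadyState:
    def test_total_export_equals_load(self):
        """Total N export (NH4+NO2+NO3 effluent + N2 evasion) balances
        the influent load at steady state."""
        sc = get_scenario()
        state, n2 = run_to_steady_state(sc.config, sc.guilds,
                                        fitness=sc.steady_fitness(),
                                        tol=1e-9)
        export = (state.nh4 + state.no2 + state.no3) * sc.config.influent_flow
        assert export + n2 == pytest.approx(86.4, rel=1e-3)
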