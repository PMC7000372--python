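"""Dynamic ¹³C-bicarbonate labeling model: speciation, titrant demand, ODE."""

import numpy as np
import pytest

from acetotrace.balances import RateSet
from acetotrace.labeling import (
    ChemostatConfig,
    Scenario,
    dic_speciation,
    pool_position_enrichment,
    produced_label_fraction,
    simulate_labeling,
    titrant_dic_input,
)
from acetotrace.network import Pathway


@pytest.fixture(scope="module")
def canonical_series(chemostat_config, reference_rates):
    return simulate_labeling(
        chemostat_config,
        reference_rates,
        Scenario(pathway=Pathway.CANONICAL_WLP, f_wlp=0.2),
    )


class TestSpeciation:
    def test_culture_ph(self):
        assert dic_speciation(7.8) == pytest.approx(0.966, abs=5e-4)

    def test_half_dissociation_at_pka(self):
        assert dic_speciation(6.35) == pytest.approx(0.5, abs=1e-12)

    def test_nearly_all_bicarbonate_at_ph_9(self):
        assert dic_speciation(9.0) >= 0.99


class TestTitrantDemand:
    def test_reference_rates_per_gram_biomass(self, reference_rates):
        cfg = ChemostatConfig(biomass_g_l=1.0)
        demand = titrant_dic_input(reference_rates, cfg)
        assert demand == pytest.approx(6.9 + 0.4 + 4.3 * dic_speciation(7.8), rel=1e-12)
        assert demand == pytest.approx(11.45, abs=0.01)

    def test_zero_rates_demand_nothing(self):
        rates = RateSet(values={"galacturonate": -1.0, "acetate": 0, "formate": 0, "co2": 0})
        assert titrant_dic_input(rates, ChemostatConfig(biomass_g_l=1.0)) == 0.0

    def test_low_ph_limit_counts_acids_only(self, reference_rates):
        cfg = ChemostatConfig(biomass_g_l=1.0, ph=6.0)
        demand = titrant_dic_input(reference_rates, cfg)
        f = dic_speciation(6.0)
        assert demand == pytest.approx(6.9 + 0.4 + 4.3 * f, rel=1e-12)
        # as f_HCO3 → 0 only the acids remain
        assert 7.3 < demand < 11.45


class TestSimulation:
    def test_initial_state_at_natural_abundance(self, canonical_series):
        me, co = pool_position_enrichment(canonical_series, 0.0)
        assert me == pytest.approx(1.0, abs=1e-9)
        assert co == pytest.approx(1.0, abs=1e-9)
        assert canonical_series.e_dic[0] == pytest.approx(0.01, abs=1e-12)

    def test_no_wlp_keeps_acetate_at_natural_abundance(
        self, chemostat_config, reference_rates
    ):
        series = simulate_labeling(
            chemostat_config, reference_rates, Scenario(pathway=Pathway.NO_WLP, f_wlp=0.0)
        )
        assert np.allclose(series.e_methyl, 0.01, atol=1e-10)
        assert np.allclose(series.e_carbonyl, 0.01, atol=1e-10)
        # the DIC pool itself still labels up from the titrant
        assert series.e_dic[-1] > 0.5

    def test_dic_enrichment_approaches_closed_form_steady_state(
        self, chemostat_config, reference_rates
    ):
        """e_DIC(t) → (T + (r+u)·a0) / (T + r + u), independent of pool size."""
        scenario = Scenario(pathway=Pathway.CANONICAL_WLP, f_wlp=0.2)
        cfg = chemostat_config
        c_x = cfg.biomass_concentration(reference_rates)
        t_in = titrant_dic_input(reference_rates, cfg)
        r = c_x * reference_rates.get("co2")
        u = 2 * scenario.f_wlp * c_x * reference_rates.get("acetate")
        a0 = cfg.natural_abundance
        expected = (t_in + (r + u) * a0) / (t_in + r + u)
        series = simulate_labeling(cfg, reference_rates, scenario, t_end=150.0, t_step=1.0)
        assert series.e_dic[-1] == pytest.approx(expected, rel=1e-4)
        # pool-size independence
        big_pool = ChemostatConfig(dic_pool_mmol_l=500.0)
        series2 = simulate_labeling(big_pool, reference_rates, scenario, t_end=400.0, t_step=2.0)
        assert series2.e_dic[-1] == pytest.approx(expected, rel=1e-3)

    def test_dic_relaxation_rate_matches_dilution_plus_turnover(
        self, chemostat_config, reference_rates
    ):
        """Late-time relaxation rate of e_DIC is D + (WLP draw)/pool within 5%."""
        scenario = Scenario(pathway=Pathway.CANONICAL_WLP, f_wlp=0.2)
        cfg = chemostat_config
        series = simulate_labeling(cfg, reference_rates, scenario, t_end=120.0, t_step=0.5)
        c_x = cfg.biomass_concentration(reference_rates)
        t_in = titrant_dic_input(reference_rates, cfg)
        r = c_x * reference_rates.get("co2")
        u = 2 * scenario.f_wlp * c_x * reference_rates.get("acetate")
        e_inf = (t_in + (r + u) * cfg.natural_abundance) / (t_in + r + u)
        pool_inf = (t_in + r) / cfg.dilution_rate
        expected_rate = cfg.dilution_rate + u / pool_inf
        # fit the exponential decay of the deficit on a late window
        mask = (series.time > 60) & (series.time < 110)
        deficit = e_inf - series.e_dic[mask]
        slope = np.polyfit(series.time[mask], np.log(deficit), 1)[0]
        assert -slope == pytest.approx(expected_rate, rel=0.05)

    def test_enrichments_monotone_without_stripping(self, canonical_series):
        for arr in (
            canonical_series.e_dic,
            canonical_series.e_methyl,
            canonical_series.e_carbonyl,
        ):
            assert np.all(np.diff(arr) >= -1e-12)

    def test_label_conservation(self, chemostat_config, reference_rates):
        """Titrant ¹³C = DIC + acetate + effluent + stripped, to 1e-6 relative."""
        for pathway, k_strip in [
            (Pathway.CANONICAL_WLP, 0.0),
            (Pathway.FORMATE_METHYL, 0.0),
            (Pathway.CANONICAL_WLP, 0.3),
        ]:
            cfg = ChemostatConfig(k_strip=k_strip)
            series = simulate_labeling(
                cfg, reference_rates, Scenario(pathway=pathway, f_wlp=0.2)
            )
            assert series.label_balance_gap() < 1e-6

    def test_integrator_convergence_in_output_step_and_tolerance(
        self, chemostat_config, reference_rates
    ):
        scenario = Scenario(pathway=Pathway.CANONICAL_WLP, f_wlp=0.2)
        ref = simulate_labeling(chemostat_config, reference_rates, scenario, t_step=0.1)
        halved = simulate_labeling(chemostat_config, reference_rates, scenario, t_step=0.05)
        tight = simulate_labeling(
            chemostat_config, reference_rates, scenario, t_step=0.1, rtol=1e-10
        )
        e_ref = pool_position_enrichment(ref, 8.0)[1]
        assert abs(pool_position_enrichment(halved, 8.0)[1] - e_ref) < 1e-4
        assert abs(pool_position_enrichment(tight, 8.0)[1] - e_ref) < 1e-4

    def test_formate_methyl_leaves_methyl_position_unlabeled(
        self, chemostat_config, reference_rates
    ):
        series = simulate_labeling(
            chemostat_config,
            reference_rates,
            Scenario(pathway=Pathway.FORMATE_METHYL, f_wlp=0.2),
        )
        me = 100 * series.e_methyl
        assert np.all(np.abs(me - 1.0) < 0.1)  # within 0.1 pp of natural abundance
        assert 100 * series.e_carbonyl[-1] > 4.0

    def test_washout_weight_of_preswitch_acetate(self):
        # at D = 0.1 h⁻¹ and t = 8 h the pre-switch pool weight is exp(-0.8)
        assert np.exp(-0.1 * 8.0) == pytest.approx(0.449, abs=5e-4)


class TestProducedLabelFraction:
    def test_zero_wlp_fraction_labels_nothing(self, chemostat_config, reference_rates):
        series = simulate_labeling(
            chemostat_config,
            reference_rates,
            Scenario(pathway=Pathway.CANONICAL_WLP, f_wlp=0.0),
        )
        assert produced_label_fraction(series, 8.0) == pytest.approx(0.0, abs=1e-9)

    def test_fully_acetogenic_fully_labeled_dic_gives_100pct(self, reference_rates):
        # enormous pre-labeled DIC pool keeps e_DIC ≈ 1 throughout
        cfg = ChemostatConfig(
            natural_abundance=0.0, dic_pool_mmol_l=1e9, initial_dic_enrichment=1.0
        )
        series = simulate_labeling(
            cfg, reference_rates, Scenario(pathway=Pathway.CANONICAL_WLP, f_wlp=1.0)
        )
        assert produced_label_fraction(series, 8.0) == pytest.approx(100.0, abs=1e-3)

    def test_reference_prediction_about_15pct_at_8h(self, canonical_series):
        """Canonical WLP at f=0.2 predicts ~15% of produced acetate labeled by 8 h."""
        value = produced_label_fraction(canonical_series, 8.0)
        assert 13.0 <= value <= 16.0
        assert value == pytest.approx(15.36, abs=0.02)  # frozen regression

    def test_time_before_switch_rejected(self, canonical_series):
        with pytest.raises(ValueError, match="before"):
            produced_label_fraction(canonical_series, -1.0)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dilution_rate": 0.0},
            {"natural_abundance": 1.0},
            {"ph": 5.0},
            {"ph": 9.5},
            {"k_strip": -0.1},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ChemostatConfig(**kwargs)

    @pytest.mark.parametrize("kwargs", [{"f_wlp": -0.1}, {"f_wlp": 1.1}, {"k_exchange": -1}])
    def test_invalid_scenario_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Scenario(**kwargs)

    def test_default_biomass_from_feed_balance(self, chemostat_config, reference_rates):
        c_x = chemostat_config.biomass_concentration(reference_rates)
        # D·S_feed/|q_s| with the 4.3 g/L galacturonate feed
        assert c_x == pytest.approx(0.554, abs=1e-3)
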