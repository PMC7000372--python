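"""Dynamic ¹³C-bicarbonate labeling model for a chemostat culture.

When the NaOH pH titrant of a steady-state chemostat is replaced by fully
labeled NaH¹³CO₃, labeled carbon enters the dissolved inorganic carbon
(DIC) pool at the rate of base consumption. Acetogenesis through the
Wood-Ljungdahl pathway (WLP) then transfers DIC label into acetate, while
dilution washes both pools out at the dilution rate D. The model tracks

* total and labeled DIC (base demand from acid production and CO₂
  retention; metabolic CO₂ release at natural abundance; WLP uptake at the
  instantaneous DIC enrichment; washout, optional first-order stripping);
* position-specific acetate pool enrichments (methyl and carbonyl), fed by
  newly produced acetate whose positional enrichment depends on the
  pathway scenario;
* cumulative acetate produced since the titrant switch and the cumulative
  amount carrying at least one ¹³C above natural abundance.

Scenarios: ``CANONICAL_WLP`` draws both acetate carbons from DIC;
``FORMATE_METHYL`` draws only the carbonyl from DIC (the methyl carbon
comes from intracellular PFL-formate at natural abundance); ``NO_WLP``
produces acetate entirely at natural abundance. Label is conserved
exactly: every ¹³C atom added by the titrant is accounted for in the DIC
pool, the acetate pool, the effluent or the stripped gas.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.integrate
import scipy.optimize

from .balances import RateSet

__all__ = [
    "ChemostatConfig",
    "Scenario",
    "LabelingSeries",
    "NMRObservation",
    "ScenarioFit",
    "IntegrationError",
    "dic_speciation",
    "titrant_dic_input",
    "simulate_labeling",
    "produced_label_fraction",
    "pool_position_enrichment",
    "fit_scenario",
]

from .network import Pathway

#: first dissociation constant of carbonic acid at 30 °C
PKA1 = 6.35

#: molar mass of galacturonic acid, g/mol
GALACTURONATE_MW = 194.139


class IntegrationError(RuntimeError):
    """Raised when the labeling ODE produces non-finite or negative pools."""


@dataclass(frozen=True)
class ChemostatConfig:
    """Reactor configuration for the labeling experiment.

    ``biomass_g_l`` and ``dic_pool_mmol_l`` default to steady-state values
    derived from the rates at simulation time (biomass from the substrate
    balance D·S_feed/|q_s|; DIC from retained CO₂, C_x·q_CO2·f_HCO3/D).
    """

    dilution_rate: float = 0.1          # h⁻¹
    volume_l: float = 0.5
    biomass_g_l: float | None = None
    feed_substrate_mmol_l: float = 4.3 / GALACTURONATE_MW * 1000.0
    ph: float = 7.8
    temperature_c: float = 30.0
    titrant_mol_l: float = 1.0
    natural_abundance: float = 0.01
    headspace_flow_ml_min: float = 120.0
    k_strip: float = 0.0                # h⁻¹, optional first-order CO₂ loss
    dic_pool_mmol_l: float | None = None
    initial_dic_enrichment: float | None = None

    def __post_init__(self) -> None:
        if self.dilution_rate <= 0:
            raise ValueError("dilution rate must be positive")
        if not 0 <= self.natural_abundance < 1:
            raise ValueError("natural abundance must be in [0, 1)")
        if not 6.0 <= self.ph <= 9.0:
            raise ValueError(f"pH {self.ph} outside supported range [6, 9]")
        if self.k_strip < 0:
            raise ValueError("stripping rate constant must be non-negative")

    def biomass_concentration(self, rates: RateSet) -> float:
        if self.biomass_g_l is not None:
            return self.biomass_g_l
        q_s = abs(rates.get(rates.substrate))
        if q_s == 0:
            raise ValueError("cannot derive biomass concentration: zero substrate rate")
        return self.dilution_rate * self.feed_substrate_mmol_l / q_s


@dataclass(frozen=True)
class Scenario:
    """Pathway variant plus the WLP share of acetate production."""

    pathway: Pathway = Pathway.CANONICAL_WLP
    f_wlp: float = 0.2
    k_exchange: float = 0.0  # h⁻¹, optional carboxyl–CO₂ exchange

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_wlp <= 1.0:
            raise ValueError(f"f_wlp must be in [0, 1], got {self.f_wlp}")
        if self.k_exchange < 0:
            raise ValueError("k_exchange must be non-negative")

    @property
    def dic_carbons_per_acetate(self) -> float:
        """DIC carbons drawn per WLP acetate (2 canonical, 1 formate-fed methyl)."""
        if self.pathway is Pathway.CANONICAL_WLP:
            return 2.0
        if self.pathway is Pathway.FORMATE_METHYL:
            return 1.0
        return 0.0


@dataclass(frozen=True)
class NMRObservation:
    """A position-specific ¹³C percentage measurement of total-culture acetate."""

    time_h: float
    pct_methyl: float | None = None
    pct_carbonyl: float | None = None

    def __post_init__(self) -> None:
        for v in (self.pct_methyl, self.pct_carbonyl):
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValueError(f"percentage {v} outside [0, 100]")


@dataclass
class LabelingSeries:
    """Time course of the labeling state (all enrichments as fractions)."""

    time: np.ndarray
    dic: np.ndarray
    e_dic: np.ndarray
    acetate: np.ndarray
    e_methyl: np.ndarray
    e_carbonyl: np.ndarray
    produced: np.ndarray
    produced_labeled: np.ndarray
    titrant_label_in: np.ndarray
    effluent_label_out: np.ndarray
    stripped_label_out: np.ndarray
    config: ChemostatConfig
    scenario: Scenario
    a0: float = field(init=False)

    def __post_init__(self) -> None:
        self.a0 = self.config.natural_abundance

    def _interp(self, arr: np.ndarray, t: float) -> float:
        if t < self.time[0] - 1e-12 or t > self.time[-1] + 1e-12:
            raise ValueError(f"time {t} outside simulated range "
                             f"[{self.time[0]}, {self.time[-1]}]")
        return float(np.interp(t, self.time, arr))

    def label_balance_gap(self) -> float:
        """Max relative gap of the ¹³C ledger over the series.

        Above-background label added by titrant minus label found in the
        DIC pool, acetate pool, effluent and stripped gas, relative to the
        amount added.
        """
        dic_excess = (self.e_dic - self.a0) * self.dic
        ac_excess = self.acetate * (
            (self.e_methyl - self.a0) + (self.e_carbonyl - self.a0)
        )
        stored = dic_excess - dic_excess[0] + ac_excess - ac_excess[0]
        gap = self.titrant_label_in - (
            stored + self.effluent_label_out + self.stripped_label_out
        )
        scale = np.maximum(self.titrant_label_in, 1e-30)
        return float(np.max(np.abs(gap[1:]) / scale[1:])) if len(gap) > 1 else 0.0


def dic_speciation(ph: float, temperature_c: float = 30.0) -> float:
    """Fraction of dissolved inorganic carbon present as bicarbonate.

    Henderson-Hasselbalch with pKa₁ = 6.35 (30 °C); carbonate is neglected,
    valid below pH 9.
    """
    return 1.0 / (1.0 + 10.0 ** (PKA1 - ph))


def titrant_dic_input(rates: RateSet, config: ChemostatConfig) -> float:
    """Labeled bicarbonate input rate from pH titration, mmol L⁻¹ h⁻¹.

    Base demand per liter per hour is C_x·(q_acetate + q_formate +
    q_CO2·f_HCO3): each acid produced is fully dissociated at culture pH
    and each retained CO₂ consumes one base equivalent on hydration to
    bicarbonate. The titrant carbon enters the DIC pool fully labeled.
    """
    c_x = config.biomass_concentration(rates)
    f_hco3 = dic_speciation(config.ph, config.temperature_c)
    demand = c_x * (
        rates.get("acetate") + rates.get("formate") + rates.get("co2") * f_hco3
    )
    if demand < 0:
        raise ValueError(
            f"negative titrant demand ({demand}); check rate signs"
        )
    return demand


def _position_enrichments(scenario: Scenario, e_dic: float, a0: float) -> tuple[float, float]:
    """(methyl, carbonyl) enrichment of newly produced acetate."""
    f = scenario.f_wlp
    if scenario.pathway is Pathway.CANONICAL_WLP:
        e = f * e_dic + (1 - f) * a0
        return e, e
    if scenario.pathway is Pathway.FORMATE_METHYL:
        return a0, f * e_dic + (1 - f) * a0
    return a0, a0


def simulate_labeling(
    config: ChemostatConfig,
    rates: RateSet,
    scenario: Scenario,
    t_end: float = 8.0,
    t_step: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-11,
) -> LabelingSeries:
    """Integrate the labeling balances from the titrant switch to ``t_end``.

    The culture starts at pre-switch steady state: all enrichments at
    natural abundance, acetate pool C_x·q_ac/D, DIC pool from retained CO₂.
    Uses an adaptive explicit Runge-Kutta integrator (RK45) with tight
    relative tolerance; the time grid only controls output sampling.
    """
    a0 = config.natural_abundance
    D = config.dilution_rate
    c_x = config.biomass_concentration(rates)
    f_hco3 = dic_speciation(config.ph, config.temperature_c)
    r_ac = c_x * rates.get("acetate")
    r_co2 = c_x * rates.get("co2")
    t_in = titrant_dic_input(rates, config)
    k_strip = config.k_strip
    k_ex = scenario.k_exchange

    acetate_pool = r_ac / D
    dic0 = (
        config.dic_pool_mmol_l
        if config.dic_pool_mmol_l is not None
        else c_x * rates.get("co2") * f_hco3 / D
    )
    if dic0 <= 0:
        raise ValueError("initial DIC pool must be positive")
    e_dic0 = a0 if config.initial_dic_enrichment is None else config.initial_dic_enrichment
    # DIC carbon drawn from the pool per unit acetate production
    u = scenario.dic_carbons_per_acetate * scenario.f_wlp * r_ac

    def rhs(t: float, y: np.ndarray) -> list[float]:
        dic, l_dic, m_me, m_co, produced, labeled, t_in_cum, eff, stripped = y
        e = l_dic / dic
        e_me_pool = m_me / acetate_pool if acetate_pool > 0 else a0
        e_co_pool = m_co / acetate_pool if acetate_pool > 0 else a0
        exchange = k_ex * acetate_pool * (e - e_co_pool)
        d_dic = t_in + r_co2 - (D + k_strip) * dic
        # gross metabolic CO₂ release (net + WLP draw) enters at natural
        # abundance; the WLP draw leaves at the pool enrichment
        d_l_dic = (
            t_in + (r_co2 + u) * a0 - u * e - (D + k_strip) * l_dic - exchange
        )
        e_me_new, e_co_new = _position_enrichments(scenario, e, a0)
        d_m_me = r_ac * e_me_new - D * m_me
        d_m_co = r_ac * e_co_new - D * m_co + exchange
        if scenario.pathway is Pathway.CANONICAL_WLP:
            p_label = scenario.f_wlp * min(2.0 * max(e - a0, 0.0), 1.0)
        elif scenario.pathway is Pathway.FORMATE_METHYL:
            p_label = scenario.f_wlp * min(max(e - a0, 0.0), 1.0)
        else:
            p_label = 0.0
        d_eff = D * (
            (l_dic - a0 * dic)
            + acetate_pool * (e_me_pool - a0)
            + acetate_pool * (e_co_pool - a0)
        )
        return [
            d_dic,
            d_l_dic,
            d_m_me,
            d_m_co,
            r_ac,
            r_ac * p_label,
            t_in * (1.0 - a0),
            d_eff,
            k_strip * (l_dic - a0 * dic),
        ]

    y0 = np.array(
        [dic0, dic0 * e_dic0, acetate_pool * a0, acetate_pool * a0, 0, 0, 0, 0, 0],
        dtype=float,
    )
    t_eval = np.arange(0.0, t_end + 0.5 * t_step, t_step)
    t_eval = np.clip(t_eval, 0.0, t_end)
    sol = scipy.integrate.solve_ivp(
        rhs, (0.0, t_end), y0, method="RK45", t_eval=t_eval, rtol=rtol, atol=atol
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationError(f"labeling integration failed: {sol.message}")
    dic, l_dic, m_me, m_co, produced, labeled, t_in_cum, eff, stripped = sol.y
    if np.any(dic <= 0) or np.any(l_dic < 0):
        raise IntegrationError("DIC pool became non-positive during integration")
    ac = np.full_like(dic, acetate_pool)
    with np.errstate(invalid="ignore", divide="ignore"):
        e_me = m_me / acetate_pool if acetate_pool > 0 else np.full_like(dic, a0)
        e_co = m_co / acetate_pool if acetate_pool > 0 else np.full_like(dic, a0)
    return LabelingSeries(
        time=sol.t,
        dic=dic,
        e_dic=l_dic / dic,
        acetate=ac,
        e_methyl=np.asarray(e_me),
        e_carbonyl=np.asarray(e_co),
        produced=produced,
        produced_labeled=labeled,
        titrant_label_in=t_in_cum,
        effluent_label_out=eff,
        stripped_label_out=stripped,
        config=config,
        scenario=scenario,
    )


def produced_label_fraction(series: LabelingSeries, t: float) -> float:
    """Percent of acetate produced since the switch carrying ≥1 ¹³C above background."""
    if t < 0:
        raise ValueError(f"time {t} is before the titrant switch")
    produced = series._interp(series.produced, t)
    if produced == 0:
        return 0.0
    return 100.0 * series._interp(series.produced_labeled, t) / produced


def pool_position_enrichment(series: LabelingSeries, t: float) -> tuple[float, float]:
    """(percent methyl, percent carbonyl) ¹³C in total-culture acetate at ``t``.

    Pre-switch acetate still present (weight exp(−D·t)) contributes at
    natural abundance; this washout is inherent in the pool balances.
    """
    return (
        100.0 * series._interp(series.e_methyl, t),
        100.0 * series._interp(series.e_carbonyl, t),
    )


@dataclass
class ScenarioFit:
    """Result of fitting one pathway scenario to NMR observations."""

    scenario: Scenario
    residual: float          # sum of squared percentage-point residuals
    n_free_params: int
    predictions: list[NMRObservation]

    @property
    def pathway(self) -> Pathway:
        return self.scenario.pathway


def _predict(
    config: ChemostatConfig,
    rates: RateSet,
    scenario: Scenario,
    times: np.ndarray,
) -> np.ndarray:
    series = simulate_labeling(config, rates, scenario, t_end=max(float(times[-1]), 1e-6))
    return np.array([pool_position_enrichment(series, float(t)) for t in times])


def fit_scenario(
    observations: list[NMRObservation],
    config: ChemostatConfig,
    rates: RateSet,
    pathways: tuple[Pathway, ...] = (
        Pathway.CANONICAL_WLP,
        Pathway.FORMATE_METHYL,
        Pathway.NO_WLP,
    ),
    fit_k_exchange: bool = False,
    k_exchange_max: float = 2.0,
    grid_points: int = 21,
) -> list[ScenarioFit]:
    """Rank pathway scenarios by least-squares fit to position-specific NMR data.

    For each scenario the WLP fraction (and optionally the carboxyl–CO₂
    exchange constant) is estimated by bounded least squares started from
    the best point of a deterministic grid. Scenarios are ranked by
    residual; residuals closer than 1e-12 rank the scenario with fewer
    free parameters first. ``NO_WLP`` has no free parameters.
    """
    if len(observations) < 2:
        raise ValueError("need at least two observations to fit scenarios")
    obs = sorted(observations, key=lambda o: o.time_h)
    times = np.array([o.time_h for o in obs], dtype=float)
    targets = []  # (row index, column, value)
    for i, o in enumerate(obs):
        if o.pct_methyl is not None:
            targets.append((i, 0, o.pct_methyl))
        if o.pct_carbonyl is not None:
            targets.append((i, 1, o.pct_carbonyl))
    if not targets:
        raise ValueError("observations contain no methyl or carbonyl values")

    def residual_for(scenario: Scenario) -> tuple[float, np.ndarray]:
        pred = _predict(config, rates, scenario, times)
        r = sum((pred[i, j] - v) ** 2 for i, j, v in targets)
        return float(r), pred

    fits: list[ScenarioFit] = []
    failures: dict[Pathway, str] = {}
    for pathway in pathways:
        try:
            if pathway is Pathway.NO_WLP:
                scenario = Scenario(pathway=pathway, f_wlp=0.0)
                resid, pred = residual_for(scenario)
                n_free = 0
            else:
                def loss(theta: np.ndarray) -> float:
                    f = float(np.clip(theta[0], 0.0, 1.0))
                    k = float(np.clip(theta[1], 0.0, k_exchange_max)) if fit_k_exchange else 0.0
                    return residual_for(Scenario(pathway=pathway, f_wlp=f, k_exchange=k))[0]

                grid_f = np.linspace(0.0, 1.0, grid_points)
                grid_k = (
                    np.linspace(0.0, k_exchange_max, 5) if fit_k_exchange else np.array([0.0])
                )
                best = min(
                    ((f, k) for f in grid_f for k in grid_k),
                    key=lambda fk: loss(np.array(fk)),
                )
                if fit_k_exchange:
                    res = scipy.optimize.minimize(
                        loss,
                        x0=np.array(best),
                        method="Nelder-Mead",
                        options={"xatol": 1e-5, "fatol": 1e-10},
                    )
                    f_hat, k_hat = res.x
                    n_free = 2
                else:
                    res = scipy.optimize.minimize_scalar(
                        lambda f: loss(np.array([f, 0.0])),
                        bounds=(0.0, 1.0),
                        method="bounded",
                        options={"xatol": 1e-6},
                    )
                    f_hat, k_hat = res.x, 0.0
                    n_free = 1
                scenario = Scenario(
                    pathway=pathway,
                    f_wlp=float(np.clip(f_hat, 0.0, 1.0)),
                    k_exchange=float(np.clip(k_hat, 0.0, k_exchange_max)),
                )
                resid, pred = residual_for(scenario)
            fits.append(
                ScenarioFit(
                    scenario=scenario,
                    residual=resid,
                    n_free_params=n_free,
                    predictions=[
                        NMRObservation(float(t), float(p[0]), float(p[1]))
                        for t, p in zip(times, pred)
                    ],
                )
            )
        except (IntegrationError, ValueError) as exc:  # pragma: no cover - diagnostics
            failures[pathway] = str(exc)
    if not fits:
        raise RuntimeError(f"all scenario fits failed: {failures}")
    fits.sort(key=lambda f: f.residual)
    # tie-break: prefer fewer free parameters when residuals are numerically equal
    for i in range(len(fits) - 1):
        a, b = fits[i], fits[i + 1]
        if abs(a.residual - b.residual) < 1e-12 and b.n_free_params < a.n_free_params:
            fits[i], fits[i + 1] = b, a
    return fits
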