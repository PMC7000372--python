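"""Synthetic chemostat labeling campaigns with known ground truth.

The generator replaces the bioreactor: it forward-simulates the labeling
model under a chosen pathway scenario and emits the three data streams the
experiment produces — replicate pseudo-steady-state rate measurements,
position-specific NMR enrichments of acetate, and an off-gas CO₂/¹³CO₂
trace — with a simple noise model on each:

* rates: multiplicative log-normal noise (chemostat rate measurements are
  positive and relative-error dominated);
* NMR percentages: additive Gaussian, truncated to [0, 100];
* off-gas percentages: additive Gaussian, truncated at 0.

Regenerating a campaign with the same seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .balances import RateSet
from .io import write_json, write_tsv
from .labeling import (
    ChemostatConfig,
    LabelingSeries,
    NMRObservation,
    Scenario,
    pool_position_enrichment,
    simulate_labeling,
)

__all__ = ["TruthParameters", "SyntheticCampaign", "generate_campaign"]

#: molar volume of an ideal gas at 30 °C, 1 atm (L/mol)
_MOLAR_VOLUME_L = 24.9


@dataclass
class TruthParameters:
    """Ground truth for a synthetic campaign."""

    scenario: Scenario = field(default_factory=Scenario)
    config: ChemostatConfig = field(default_factory=ChemostatConfig)
    rates: RateSet = field(
        default_factory=lambda: RateSet(
            values={
                "galacturonate": -4.0,
                "acetate": 6.9,
                "formate": 0.4,
                "co2": 4.3,
                "h2": 0.2,
            }
        )
    )
    sigma_rate: float = 0.05        # relative (log-normal) noise on rates
    sigma_nmr: float = 0.3          # percentage points on NMR enrichments
    sigma_gas: float = 0.02         # percentage points on off-gas fractions
    n_rate_replicates: int = 3
    nmr_times: tuple[float, ...] = (0.0, 4.0, 8.0)
    gas_interval_h: float = 0.5
    t_end: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_rate", "sigma_nmr", "sigma_gas"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SyntheticCampaign:
    """Generated tables plus the truth record and noiseless model series."""

    rates_table: pd.DataFrame
    nmr_table: pd.DataFrame
    offgas_table: pd.DataFrame
    truth: TruthParameters
    series: LabelingSeries

    def nmr_observations(self) -> list[NMRObservation]:
        return [
            NMRObservation(
                time_h=float(r.time_h),
                pct_methyl=float(r.pct_methyl),
                pct_carbonyl=float(r.pct_carbonyl),
            )
            for r in self.nmr_table.itertuples()
        ]

    def mean_rates(self) -> RateSet:
        """Replicate-averaged RateSet from the noisy rates table."""
        grouped = self.rates_table.groupby("compound")["value"].mean()
        return RateSet(values=grouped.to_dict(), substrate=self.truth.rates.substrate)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_tsv(self.rates_table, directory / "rates.tsv")
        write_tsv(self.nmr_table, directory / "nmr.tsv")
        write_tsv(self.offgas_table, directory / "offgas.tsv")
        truth = asdict(self.truth)
        truth["scenario"]["pathway"] = self.truth.scenario.pathway.value
        truth["rates"] = {"values": self.truth.rates.values, "substrate": self.truth.rates.substrate}
        write_json({"truth": truth}, directory / "truth.json")


def generate_campaign(truth: TruthParameters) -> SyntheticCampaign:
    """Forward-simulate the labeling model and sample noisy observations."""
    rng = np.random.default_rng(truth.seed)
    series = simulate_labeling(
        truth.config, truth.rates, truth.scenario, t_end=truth.t_end
    )

    # replicate rate measurements, multiplicative log-normal noise
    rows = []
    for rep in range(1, truth.n_rate_replicates + 1):
        for name, q in truth.rates.values.items():
            noise = (
                float(rng.lognormal(mean=0.0, sigma=truth.sigma_rate))
                if truth.sigma_rate > 0
                else 1.0
            )
            rows.append({"replicate": rep, "compound": name, "value": q * noise})
    rates_table = pd.DataFrame(rows)

    # NMR enrichments at the configured sampling times, additive noise
    nmr_rows = []
    for t in truth.nmr_times:
        me, co = pool_position_enrichment(series, float(t))
        if truth.sigma_nmr > 0:
            me = float(np.clip(me + rng.normal(0.0, truth.sigma_nmr), 0.0, 100.0))
            co = float(np.clip(co + rng.normal(0.0, truth.sigma_nmr), 0.0, 100.0))
        nmr_rows.append({"time_h": float(t), "pct_methyl": me, "pct_carbonyl": co})
    nmr_table = pd.DataFrame(nmr_rows)

    # off-gas CO₂ / ¹³CO₂ mole percentages in the headspace flush
    c_x = truth.config.biomass_concentration(truth.rates)
    co2_mmol_h = c_x * truth.rates.get("co2") * truth.config.volume_l
    flow_mmol_h = truth.config.headspace_flow_ml_min * 60.0 / 1000.0 / _MOLAR_VOLUME_L * 1000.0
    gas_times = np.arange(0.0, truth.t_end + 1e-9, truth.gas_interval_h)
    co2_pct = np.full_like(gas_times, 100.0 * co2_mmol_h / flow_mmol_h)
    e_dic = np.interp(gas_times, series.time, series.e_dic)
    co2_13_pct = co2_pct * e_dic
    if truth.sigma_gas > 0:
        co2_pct = np.clip(co2_pct + rng.normal(0.0, truth.sigma_gas, co2_pct.shape), 0.0, None)
        co2_13_pct = np.clip(
            co2_13_pct + rng.normal(0.0, truth.sigma_gas, co2_13_pct.shape), 0.0, None
        )
    offgas_table = pd.DataFrame(
        {"time_h": gas_times, "co2_pct": co2_pct, "co2_13_pct": co2_13_pct}
    )

    return SyntheticCampaign(
        rates_table=rates_table,
        nmr_table=nmr_table,
        offgas_table=offgas_table,
        truth=truth,
        series=series,
    )
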