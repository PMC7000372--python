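"""Bundled reference tables from the galacturonate chemostat enrichment study.

These are the printed summary measurements of the anaerobic,
galacturonate-limited chemostat enrichment cultures dominated by
"*Ca.* Galacturonibacter soehngenii": biomass-specific conversion rates and
yields, position-specific ¹³C-NMR acetate enrichments during
¹³C-bicarbonate titrant feeding, and transcript RPKM levels for key gene
panels. They serve as default inputs for the balance, flux-inference and
labeling stages.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .balances import RateSet, YieldSet
from .expression import GenePanel
from .formulas import Compound
from .io import read_nmr_tsv, read_rates_tsv, read_yields_tsv, load_registry_yaml
from .labeling import ChemostatConfig, NMRObservation

__all__ = [
    "data_path",
    "reference_rates",
    "reference_yields",
    "reference_nmr",
    "reference_transcripts",
    "reference_panels",
    "default_registry",
    "default_config",
]


def data_path(name: str) -> Path:
    return Path(str(resources.files("acetotrace").joinpath("data", name)))


def reference_rates() -> RateSet:
    """Measured biomass-specific conversion rates (mmol g⁻¹ h⁻¹)."""
    return read_rates_tsv(data_path("chemostat_rates.tsv"))


def reference_yields() -> YieldSet:
    """Measured product yields (Cmol/Cmol substrate; H₂ in mol/Cmol)."""
    return read_yields_tsv(data_path("chemostat_yields.tsv"))


def reference_nmr() -> list[NMRObservation]:
    """Position-specific ¹³C percentages of total-culture acetate (0/4/8 h)."""
    return read_nmr_tsv(data_path("nmr_enrichment.tsv"))


def reference_transcripts() -> pd.DataFrame:
    """Transcript RPKM table with panel annotations."""
    return pd.read_csv(data_path("transcript_rpkm.tsv"), sep="\t")


def reference_panels(exclude_formate_dehydrogenase: bool = True) -> dict[str, GenePanel]:
    """Gene panels for fold comparisons.

    The WLP panel optionally drops the near-zero formate-dehydrogenase
    entry, reflecting that the formate-fed methyl branch does not require
    it; this is the default panel definition used for the roughly
    order-of-magnitude ED-vs-WLP comparison.
    """
    df = reference_transcripts()
    panels: dict[str, GenePanel] = {}
    for name, group in df.groupby("panel"):
        ids = list(group["gene_id"])
        if name == "wood_ljungdahl" and exclude_formate_dehydrogenase:
            fdh = set(group.loc[group["protein_function"].str.contains("Formate dehydrogenase"), "gene_id"])
            ids = [g for g in ids if g not in fdh]
        panels[name] = GenePanel(name=name, gene_ids=tuple(ids))
    return panels


def default_registry() -> dict[str, Compound]:
    """Compound registry for the galacturonate fermentation balances."""
    return load_registry_yaml(data_path("compounds.yaml"))


def default_config() -> ChemostatConfig:
    """Reactor configuration of the labeling experiment (D 0.1 h⁻¹, pH 7.8)."""
    return ChemostatConfig()
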