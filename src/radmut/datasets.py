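"""Bundled reference datasets and study constants.

Small plain-text tables from the Arabidopsis proton-beam / gamma-ray
mutagenesis study this toolkit is built around: phenotypic mutant counts per
M2 population, the validated structural-rearrangement event table, the
inversion-junction feature counts, and the per-group gene-impact means.
Loaders return plain pandas frames or the toolkit's domain objects.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .summary_tables import PhenotypeTable, RearrangementEvent, read_sv_events

__all__ = [
    "PROTON_DOSES_GY",
    "GAMMA_DOSES_GY",
    "PROTON_DQ_GY",
    "PROTON_LD50_GY",
    "GAMMA_DQ_GY",
    "GAMMA_LD50_GY",
    "load_phenotype_table",
    "load_sv_events",
    "load_inversion_junction_counts",
    "load_gene_impact_means",
]

# irradiation dose grids of the survival assay (Gy)
PROTON_DOSES_GY = (113.7, 190.3, 280.6, 393.4, 493.4, 574.0, 682.1, 786.9, 994.9, 1188.4)
GAMMA_DOSES_GY = (200.0, 400.0, 600.0, 900.0, 1200.0, 1500.0)

# published summary doses from the fitted survival curves (Gy)
PROTON_DQ_GY = 754.0
PROTON_LD50_GY = 1051.0
GAMMA_DQ_GY = 860.0
GAMMA_LD50_GY = 1086.0


def _path(name: str):
    return resources.files("radmut.data").joinpath(name)


def load_phenotype_table() -> PhenotypeTable:
    """Phenotypic mutant counts and screened M2 line numbers per population."""
    with resources.as_file(_path("phenotype_counts.tsv")) as counts, resources.as_file(
        _path("phenotype_lines.tsv")
    ) as lines:
        return PhenotypeTable.from_tsv(counts, lines)


def load_sv_events() -> list[RearrangementEvent]:
    """Validated rearrangement events (41 events over 39 processes)."""
    with resources.as_file(_path("sv_events.tsv")) as p:
        return read_sv_events(p)


def load_inversion_junction_counts() -> pd.DataFrame:
    """Per-group inversion-junction feature counts."""
    with resources.as_file(_path("inversion_junction_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_gene_impact_means() -> pd.DataFrame:
    """Per-group mean +/- SE gene counts by coding consequence."""
    with resources.as_file(_path("gene_impact_means.tsv")) as p:
        return pd.read_csv(p, sep="\t")
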