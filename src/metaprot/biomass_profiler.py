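"""Species proteinaceous-biomass profiles from protein quantities.

A taxon's proteinaceous biomass is the sum of spectral counts of its
qualifying proteins — those with at least two protein-unique peptides.
Counts route into either a species group or one of the non-species
partitions (ambiguous, low-quality-bin, unbinned, host, diet).  Species
percentages use species-assigned counts only as the denominator; the
microbe-to-host ratio uses the broader microbial numerator (species +
ambiguous + low-quality + unbinned) over host counts.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .database_builder import AMBIGUOUS, DIET, HOST, LOWQ, UNBINNED, ProteinDatabase
from .psm_processing import ProteinQuant

PARTITIONS = (AMBIGUOUS, LOWQ, UNBINNED, HOST, DIET)


@dataclass(frozen=True)
class BiomassProfile:
    """Species x sample biomass counts plus non-species partitions.

    ``species_counts`` and ``partition_counts`` hold summed spectral
    counts of qualifying proteins; ``percent`` expresses each species as
    a share (%) of the summed species counts in its sample.
    """

    species_counts: pd.DataFrame
    partition_counts: pd.DataFrame
    percent: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.species_counts.columns)

    @property
    def species(self) -> list[str]:
        return list(self.species_counts.index)

    def total_counts(self) -> pd.Series:
        """All qualifying-protein counts per sample (all partitions)."""
        return self.species_counts.sum() + self.partition_counts.sum()


def quantify_biomass(
    quant: ProteinQuant,
    database: ProteinDatabase,
    min_unique_peptides: int = 2,
    per_sample: bool = False,
) -> BiomassProfile:
    """Sum qualifying-protein spectra into their assigned taxonomy.

    Only proteins with >= ``min_unique_peptides`` protein-unique
    peptides contribute.  The evidence is pooled across the study by
    default (``per_sample=False``); with ``per_sample=True`` a protein
    must meet the bar within each sample separately.  Proteins coded
    ``AMBIGUOUS`` (matching more than one species) are excluded from
    species sums but kept in the ambiguous partition.
    """
    table = quant.table
    if table.empty:
        warnings.warn("empty protein quantification; returning empty profile",
                      stacklevel=2)
        empty = pd.DataFrame(dtype=int)
        return BiomassProfile(
            empty,
            pd.DataFrame(0, index=list(PARTITIONS), columns=[], dtype=int),
            pd.DataFrame(dtype=float),
        )

    if per_sample:
        qualified = table.loc[table["n_unique_peptides"] >= min_unique_peptides]
    else:
        ok = quant.study_unique_peptides[
            quant.study_unique_peptides >= min_unique_peptides
        ].index
        qualified = table.loc[table["accession"].isin(ok)]

    samples = sorted(table["sample_id"].unique())
    taxon_counts = (
        qualified.pivot_table(
            index="taxon_code",
            columns="sample_id",
            values="spectral_count",
            aggfunc="sum",
            fill_value=0,
        )
        .reindex(columns=samples, fill_value=0)
        .astype(int)
    )
    partition_counts = (
        taxon_counts.reindex(list(PARTITIONS), fill_value=0)
        .rename_axis(index=None, columns=None)
    )
    species_counts = (
        taxon_counts.loc[~taxon_counts.index.isin(PARTITIONS)]
        .sort_index()
        .rename_axis(index=None, columns=None)
    )

    totals = species_counts.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = species_counts / totals.replace(0, np.nan) * 100.0
    return BiomassProfile(species_counts, partition_counts, percent)


def microbe_host_ratio(profile: BiomassProfile) -> pd.Series:
    """Per-sample microbial-to-host spectral count ratio.

    Numerator: species + ambiguous + low-quality + unbinned counts;
    denominator: host counts.  Diet counts enter neither side.  Samples
    with zero host counts yield a missing value with a warning.
    """
    microbial = (
        profile.species_counts.sum()
        + profile.partition_counts.loc[[AMBIGUOUS, LOWQ, UNBINNED]].sum()
    )
    host = profile.partition_counts.loc[HOST]
    if (host == 0).any():
        missing = list(host.index[host == 0])
        warnings.warn(
            f"no host spectra in sample(s) {missing}; ratio undefined there",
            stacklevel=2,
        )
    return (microbial / host.replace(0, np.nan)).rename("microbe_host_ratio")


def abundant_species(
    profile: BiomassProfile, threshold_percent: float = 5.0
) -> list[str]:
    """Species reaching >= threshold % of microbial species biomass in
    at least one sample."""
    if profile.percent.empty:
        return []
    peak = profile.percent.max(axis=1)
    return list(peak.index[peak >= threshold_percent])


def class_rollup(
    profile: BiomassProfile, taxonomy: Mapping[str, str]
) -> pd.DataFrame:
    """Sum species counts by taxonomic class.

    ``taxonomy`` maps every quantified species group to its class; a
    missing label is an error naming the species.
    """
    missing = [sp for sp in profile.species if sp not in taxonomy]
    if missing:
        raise ValueError(f"species {missing[0]!r} has no class label")
    classes = pd.Series({sp: taxonomy[sp] for sp in profile.species})
    return (
        profile.species_counts.groupby(classes)
        .sum()
        .rename_axis(index=None, columns=None)
        .sort_index()
    )


def richness(profile: BiomassProfile) -> pd.Series:
    """Per-sample count of species with nonzero qualifying signal."""
    if profile.species_counts.empty:
        return pd.Series(dtype=int, name="richness")
    return (profile.species_counts > 0).sum().astype(int).rename("richness")
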