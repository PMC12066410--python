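"""NSAF% functional profiles, annotation consensus and category rollups.

The normalized spectral abundance factor of protein i in a sample is

    NSAF%_i = 100 * (c_i / L_i) / sum_j (c_j / L_j)

with spectral count c and protein length L (in residues); the sum runs
over microbial proteins only, so host and dietary proteins enter
neither numerator nor denominator.  ``org_nsaf`` restricts both to one
organism's proteins, giving the within-species functional profile.
Annotation labels come from a precedence cascade (curated label >
curated label extrapolated by shared tool signature > tool consensus >
unannotated); rollups sum member-protein NSAF% per category, glycoside
hydrolase family, PUL or amino-acid pathway direction, with the
unannotated remainder kept explicit so columns still total 100%.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping
from importlib import resources

import numpy as np
import pandas as pd

from .database_builder import DIET, HOST, ProteinDatabase
from .psm_processing import ProteinQuant

MANUAL = "manual"
EXTRAPOLATED = "extrapolated"
CONSENSUS = "consensus"
UNANNOTATED = "unannotated"

LEVEL_COLUMNS = {
    "broad": "broad_category",
    "detailed": "detailed_category",
    "enzyme": "enzyme_name",
    "gh_family": "gh_family",
    "pul": "pul_id",
}

DIRECTIONS = ("degradation", "synthesis", "interconversion", "reversible")


def load_enzyme_vocab() -> pd.DataFrame:
    """Editable enzyme vocabulary shipped with the package.

    Columns: enzyme_name, broad_category, detailed_category, gh_family,
    pul_associated.
    """
    path = resources.files("metaprot.data").joinpath("enzyme_vocab.tsv")
    vocab = pd.read_csv(path, sep="\t")
    vocab["pul_associated"] = vocab["pul_associated"].astype(bool)
    return vocab


def load_aa_pathway_map() -> pd.DataFrame:
    """Amino-acid pathway map: enzyme_name, amino_acid, direction,
    ammonia_product."""
    path = resources.files("metaprot.data").joinpath("aa_pathways.tsv")
    table = pd.read_csv(path, sep="\t")
    table["ammonia_product"] = table["ammonia_product"].astype(bool)
    return table


def nsaf(
    quant: ProteinQuant,
    database: ProteinDatabase,
    exclude_codes: tuple = (HOST, DIET),
) -> pd.DataFrame:
    """Protein x sample NSAF% over the microbial denominator scope."""
    counts = quant.counts_matrix()
    keep = [a for a in counts.index if database.taxon_of(a) not in exclude_codes]
    counts = counts.loc[keep]
    lengths = database.lengths().reindex(counts.index)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"non-positive length for protein {bad!r}")
    saf = counts.div(lengths, axis=0)
    totals = saf.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        return saf / totals.replace(0, np.nan) * 100.0


def org_nsaf(
    quant: ProteinQuant, database: ProteinDatabase, species_code: str
) -> pd.DataFrame:
    """NSAF% restricted to one species' proteins (orgNSAF)."""
    counts = quant.counts_matrix()
    keep = [a for a in counts.index if database.taxon_of(a) == species_code]
    if not keep:
        raise ValueError(f"no quantified proteins for species {species_code!r}")
    sub = ProteinQuant(
        quant.table.loc[quant.table["accession"].isin(keep)],
        quant.study_unique_peptides.loc[
            quant.study_unique_peptides.index.isin(keep)
        ],
    )
    all_codes = {database.taxon_of(a) for a in database.accessions}
    return nsaf(sub, database, exclude_codes=tuple(all_codes - {species_code}))


def consensus_annotate(
    tool_labels: pd.DataFrame,
    manual_labels: Mapping[str, str] | pd.Series | None = None,
) -> pd.DataFrame:
    """Resolve per-tool labels into one label per protein with provenance.

    ``tool_labels`` is indexed by accession with one column per tool
    (missing calls as NaN/None).  Precedence: a curated (manual) label;
    else a curated label extrapolated to proteins sharing the exact
    tool-label signature of a curated protein; else the consensus when
    all tools that produced a label agree; else unannotated.  Each
    decision is tagged with its tier.  Conflicting manual labels for one
    protein are an error.
    """
    if manual_labels is None:
        manual_labels = {}
    manual = pd.Series(manual_labels, dtype=object).dropna()
    if manual.index.has_duplicates:
        dupes = manual.index[manual.index.duplicated()]
        conflicting = {
            acc
            for acc in dupes
            if len(set(manual.loc[[acc]])) > 1
        }
        if conflicting:
            raise ValueError(
                f"conflicting manual labels for protein {sorted(conflicting)[0]!r}"
            )
        manual = manual[~manual.index.duplicated()]

    def signature(row) -> tuple:
        return tuple(None if pd.isna(v) else str(v) for v in row)

    signatures = {acc: signature(row) for acc, row in tool_labels.iterrows()}

    # Curated signature -> label, dropped if two curated proteins with the
    # same signature disagree.
    sig_label: dict[tuple, str] = {}
    sig_conflict: set = set()
    for acc, label in manual.items():
        if acc not in signatures:
            continue
        sig = signatures[acc]
        if all(v is None for v in sig):
            continue
        if sig in sig_label and sig_label[sig] != label:
            sig_conflict.add(sig)
        else:
            sig_label.setdefault(sig, str(label))
    for sig in sig_conflict:
        sig_label.pop(sig, None)
        warnings.warn(
            "curated proteins with identical tool signatures disagree; "
            "signature not extrapolated",
            stacklevel=2,
        )

    rows = []
    for acc in tool_labels.index:
        sig = signatures[acc]
        present = [v for v in sig if v is not None]
        if acc in manual.index:
            label, tier = str(manual[acc]), MANUAL
        elif sig in sig_label:
            label, tier = sig_label[sig], EXTRAPOLATED
        elif present and len(set(present)) == 1:
            label, tier = present[0], CONSENSUS
        else:
            label, tier = None, UNANNOTATED
        rows.append({"accession": acc, "label": label, "tier": tier})
    return pd.DataFrame(rows).set_index("accession")


def rollup(
    nsaf_matrix: pd.DataFrame,
    annotations: pd.DataFrame,
    level: str,
) -> pd.DataFrame:
    """Sum protein NSAF% into features at an annotation level.

    ``annotations`` is indexed by accession (or has an ``accession``
    column) and must carry the level's column (see ``LEVEL_COLUMNS``).
    Proteins without a label at the level, or absent from the table,
    accumulate into an explicit ``unannotated`` feature so each sample
    column still sums to the protein-level total.  A protein mapped to
    two PULs (duplicate conflicting rows) is an error: locus membership
    must partition.
    """
    if level not in LEVEL_COLUMNS:
        raise ValueError(f"unknown rollup level {level!r}")
    column = LEVEL_COLUMNS[level]
    ann = annotations.reset_index() if annotations.index.name else annotations.copy()
    if "accession" not in ann.columns:
        ann = annotations.reset_index().rename(
            columns={annotations.index.name or "index": "accession"}
        )
    if column not in ann.columns:
        raise ValueError(f"annotations lack column {column!r}")
    dup = ann.dropna(subset=[column]).groupby("accession")[column].nunique()
    conflicted = dup.index[dup > 1]
    if len(conflicted):
        raise ValueError(
            f"protein {conflicted[0]!r} mapped to multiple {level} features"
        )
    mapping = (
        ann.dropna(subset=[column])
        .drop_duplicates("accession")
        .set_index("accession")[column]
    )
    labels = pd.Series(
        [mapping.get(acc, UNANNOTATED) for acc in nsaf_matrix.index],
        index=nsaf_matrix.index,
    ).fillna(UNANNOTATED)
    out = nsaf_matrix.groupby(labels).sum()
    out.index.name = level
    return out


def amino_acid_class_rollup(
    nsaf_matrix: pd.DataFrame,
    annotations: pd.DataFrame,
    aa_pathway_map: pd.DataFrame,
) -> pd.DataFrame:
    """Sum enzyme NSAF% by (direction, amino acid).

    ``aa_pathway_map`` has columns enzyme_name, amino_acid, direction
    (one of degradation / synthesis / interconversion / reversible) and
    ammonia_product.  Unknown directions are an error.  The result is a
    (direction, amino_acid) x sample matrix.
    """
    bad = set(aa_pathway_map["direction"]) - set(DIRECTIONS)
    if bad:
        raise ValueError(f"unknown pathway direction {sorted(bad)[0]!r}")
    enzyme_level = rollup(nsaf_matrix, annotations, "enzyme")
    merged = aa_pathway_map.merge(
        enzyme_level, left_on="enzyme_name", right_index=True, how="inner"
    )
    samples = list(nsaf_matrix.columns)
    grouped = merged.groupby(["direction", "amino_acid"])[samples].sum()
    return grouped


def ammonia_producing_panel(
    nsaf_matrix: pd.DataFrame,
    annotations: pd.DataFrame,
    aa_pathway_map: pd.DataFrame,
) -> pd.Series:
    """Summed abundance of enzymes likely to release ammonia.

    Degrading or reversible enzymes count as long as ammonia is one of
    their potential products.
    """
    enzyme_level = rollup(nsaf_matrix, annotations, "enzyme")
    eligible = aa_pathway_map.loc[
        aa_pathway_map["direction"].isin(["degradation", "reversible"])
        & aa_pathway_map["ammonia_product"],
        "enzyme_name",
    ].unique()
    members = [e for e in eligible if e in enzyme_level.index]
    return enzyme_level.loc[members].sum().rename("ammonia_producing")


def enzyme_panel(
    nsaf_matrix: pd.DataFrame, annotations: pd.DataFrame, enzyme_name: str
) -> pd.Series:
    """Summed abundance of all proteins carrying one enzyme name."""
    enzyme_level = rollup(nsaf_matrix, annotations, "enzyme")
    if enzyme_name not in enzyme_level.index:
        return pd.Series(0.0, index=nsaf_matrix.columns, name=enzyme_name)
    return enzyme_level.loc[enzyme_name].rename(enzyme_name)


def annotated_mass_fraction(
    nsaf_matrix: pd.DataFrame, annotations: pd.DataFrame, level: str = "broad"
) -> pd.Series:
    """Fraction (%) of microbial protein abundance carrying a label."""
    rolled = rollup(nsaf_matrix, annotations, level)
    total = rolled.sum()
    unann = (
        rolled.loc[UNANNOTATED]
        if UNANNOTATED in rolled.index
        else pd.Series(0.0, index=rolled.columns)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        return ((total - unann) / total * 100.0).rename("annotated_pct")
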