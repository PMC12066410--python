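"""PSM filtering, peptide-to-protein resolution and spectral counting.

False-discovery control uses target-decoy competition at the PSM level:
at a score threshold s the estimated FDR is

    FDR(s) = #decoys(score >= s) / max(1, #targets(score >= s))

and per-PSM q-values are the monotone non-increasing envelope of FDR
over score, i.e. the smallest estimated FDR at which the PSM would be
accepted.  Proteins are quantified by spectral counting; a protein is
reported only when at least one of its peptides is protein-unique
(occurs in exactly one database accession), and by default a PSM counts
only toward proteins for which its peptide is protein-unique, which
prevents shared peptides from being counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .database_builder import ProteinDatabase

#: Shared-peptide counting policies for :func:`count_spectra`.
UNIQUE_ONLY = "unique-only"
COUNT_TO_ALL = "count-to-all"


def estimate_psm_fdr(psms: pd.DataFrame) -> pd.Series:
    """Per-PSM q-values from target-decoy competition.

    Requires ``score`` and ``is_decoy`` columns.  With zero decoys every
    q-value is 0; an all-decoy table is an error.  Row order never
    affects the result.
    """
    if "score" not in psms or "is_decoy" not in psms:
        raise ValueError("PSM table needs 'score' and 'is_decoy' columns")
    is_decoy = psms["is_decoy"].to_numpy(dtype=bool)
    if is_decoy.all():
        raise ValueError("PSM table contains only decoys")
    scores = psms["score"].to_numpy(dtype=float)
    if not is_decoy.any():
        return pd.Series(0.0, index=psms.index, name="q_value")

    # Unique thresholds, descending; counts are cumulative at >= s.
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_decoy = is_decoy[order]
    cum_decoys = np.cumsum(sorted_decoy)
    cum_targets = np.cumsum(~sorted_decoy)
    # Positions where the next score differs: counts there are the
    # totals at that threshold (ties all share one threshold).
    is_last = np.ones(len(scores), dtype=bool)
    is_last[:-1] = sorted_scores[:-1] != sorted_scores[1:]
    thr_scores = sorted_scores[is_last]
    fdr = cum_decoys[is_last] / np.maximum(1, cum_targets[is_last])
    q = np.minimum.accumulate(fdr[::-1])[::-1]

    # Map each PSM's score to its threshold's q-value.  thr_scores is
    # descending; searchsorted needs ascending.
    idx = len(thr_scores) - 1 - np.searchsorted(thr_scores[::-1], scores, side="left")
    return pd.Series(q[idx], index=psms.index, name="q_value")


def filter_psms(psms: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Retain target PSMs with q <= threshold; decoys are removed."""
    if not 0.0 <= q_threshold <= 1.0:
        raise ValueError(f"q_threshold {q_threshold} outside [0, 1]")
    q = estimate_psm_fdr(psms)
    keep = (~psms["is_decoy"].astype(bool)) & (q <= q_threshold)
    out = psms.loc[keep].copy()
    out["q_value"] = q.loc[keep]
    return out


def resolve_peptides(
    psms: pd.DataFrame, database: ProteinDatabase
) -> pd.DataFrame:
    """Resolve each observed peptide against the database.

    Returns a frame indexed by peptide with columns ``proteins`` (sorted
    tuple of accessions containing the peptide), ``protein_unique``
    (exactly one accession), ``taxa`` (sorted tuple of taxon codes of
    those accessions) and ``taxon_unique``.  Resolution is by in-silico
    tryptic digest of the database; every accession a target PSM lists
    must exist in the database.
    """
    targets = psms.loc[~psms["is_decoy"].astype(bool)]
    listed = set()
    for ids in targets["protein_ids"].dropna():
        listed.update(ids.split(";"))
    unknown = sorted(acc for acc in listed if acc not in database)
    if unknown:
        raise ValueError(f"PSM table references unknown accession {unknown[0]!r}")

    index = database.tryptic_peptide_index()
    rows = []
    for peptide in pd.unique(targets["peptide"]):
        accs = index.get(peptide)
        if accs is None:
            # Peptide absent from the digest (e.g. a non-tryptic search
            # artifact); fall back to the accessions the search listed.
            accs = frozenset(
                a
                for ids in targets.loc[targets["peptide"] == peptide, "protein_ids"]
                for a in ids.split(";")
            )
        proteins = tuple(sorted(accs))
        taxa = tuple(sorted({database.taxon_of(a) for a in proteins}))
        rows.append(
            {
                "peptide": peptide,
                "proteins": proteins,
                "protein_unique": len(proteins) == 1,
                "taxa": taxa,
                "taxon_unique": len(taxa) == 1,
            }
        )
    return pd.DataFrame(rows).set_index("peptide")


@dataclass(frozen=True)
class ProteinQuant:
    """Per-sample protein spectral counts plus unique-peptide evidence.

    ``table`` has one row per (sample_id, accession) with columns
    ``taxon_code``, ``spectral_count`` and ``n_unique_peptides`` (the
    distinct protein-unique peptides observed for the accession in that
    sample).  ``study_unique_peptides`` counts distinct protein-unique
    peptides per accession across all samples — the evidence base for
    the two-unique-peptide biomass rule applied study-wide.
    """

    table: pd.DataFrame
    study_unique_peptides: pd.Series

    def counts_matrix(self) -> pd.DataFrame:
        """Protein x sample spectral-count matrix (absent = 0)."""
        return (
            self.table.pivot_table(
                index="accession",
                columns="sample_id",
                values="spectral_count",
                aggfunc="sum",
                fill_value=0,
            )
            .rename_axis(index=None, columns=None)
            .astype(int)
        )

    @property
    def samples(self) -> list[str]:
        return sorted(self.table["sample_id"].unique())


def count_spectra(
    filtered_psms: pd.DataFrame,
    database: ProteinDatabase,
    policy: str = UNIQUE_ONLY,
) -> ProteinQuant:
    """Spectral counting of FDR-filtered PSMs.

    Under the default ``unique-only`` policy a PSM counts only toward
    the protein for which its peptide is protein-unique; shared-peptide
    PSMs are not counted (no double counting).  Under ``count-to-all`` a
    shared PSM increments every matching protein.  In both policies a
    protein enters the output only if it has at least one protein-unique
    peptide observed anywhere in the table.
    """
    if policy not in (UNIQUE_ONLY, COUNT_TO_ALL):
        raise ValueError(f"unknown counting policy {policy!r}")
    targets = filtered_psms.loc[~filtered_psms["is_decoy"].astype(bool)]
    if targets.empty:
        empty = pd.DataFrame(
            columns=[
                "sample_id",
                "accession",
                "taxon_code",
                "spectral_count",
                "n_unique_peptides",
            ]
        )
        return ProteinQuant(empty, pd.Series(dtype=int))

    resolution = resolve_peptides(targets, database)
    merged = targets[["sample_id", "peptide"]].join(
        resolution[["proteins", "protein_unique"]], on="peptide"
    )

    unique_rows = merged.loc[merged["protein_unique"]].copy()
    unique_rows["accession"] = unique_rows["proteins"].str[0]
    study_unique = (
        unique_rows.groupby("accession")["peptide"].nunique().astype(int)
    )
    per_sample_unique = (
        unique_rows.groupby(["sample_id", "accession"])["peptide"]
        .nunique()
        .rename("n_unique_peptides")
    )
    unique_counts = (
        unique_rows.groupby(["sample_id", "accession"])
        .size()
        .rename("spectral_count")
    )

    if policy == UNIQUE_ONLY:
        counts = unique_counts
    else:
        exploded = merged.explode("proteins").rename(
            columns={"proteins": "accession"}
        )
        exploded = exploded.loc[exploded["accession"].isin(study_unique.index)]
        counts = (
            exploded.groupby(["sample_id", "accession"])
            .size()
            .rename("spectral_count")
        )

    table = (
        pd.concat([counts, per_sample_unique], axis=1)
        .fillna({"n_unique_peptides": 0})
        .astype({"spectral_count": int, "n_unique_peptides": int})
        .reset_index()
    )
    table = table.loc[table["accession"].isin(study_unique.index)].copy()
    table["taxon_code"] = [database.taxon_of(a) for a in table["accession"]]
    table = table[
        ["sample_id", "accession", "taxon_code", "spectral_count", "n_unique_peptides"]
    ].sort_values(["sample_id", "accession"], ignore_index=True)
    return ProteinQuant(table, study_unique.sort_index())


def quantify(
    psms: pd.DataFrame,
    database: ProteinDatabase,
    fdr: float = 0.05,
    policy: str = UNIQUE_ONLY,
) -> ProteinQuant:
    """FDR-filter and count in one step (the `quantify` CLI surface)."""
    return count_spectra(filter_psms(psms, fdr), database, policy)
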