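"""Assembly of the taxon-coded protein sequence database.

Every protein in the search database carries exactly one taxon code:
either a species-group identifier (from 95%-ANI clustering of
metagenome-assembled genomes, provided as an input map) or one of five
reserved codes:

``AMBIGUOUS``
    identical sequence found in bins of more than one species group,
``LOWQ``
    sequence from a bin that passed only the relaxed quality tier,
``UNBINNED``
    gene call absent from every accepted bin,
``HOST`` / ``DIET``
    appended host and dietary reference proteomes.

Assembly, binning, ANI clustering and gene prediction are upstream tools
whose outputs are inputs here; this module implements the merging,
quality screening and coding logic that turns them into one database.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMBIGUOUS = "AMBIGUOUS"
LOWQ = "LOWQ"
UNBINNED = "UNBINNED"
HOST = "HOST"
DIET = "DIET"

#: Codes that may never be used as a species-group identifier.
RESERVED_CODES = frozenset({AMBIGUOUS, LOWQ, UNBINNED, HOST, DIET})

#: Microbial codes that are not species-specific.
MICROBIAL_POOL_CODES = frozenset({AMBIGUOUS, LOWQ, UNBINNED})

ACCEPT_SPECIES = "ACCEPT_SPECIES"
ACCEPT_LOWQ_TIER = "ACCEPT_LOWQ_TIER"
REJECT = "REJECT"


@dataclass(frozen=True)
class ProteinRecord:
    """One database entry: an accession, its sequence and its taxon code."""

    accession: str
    sequence: str
    taxon_code: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("empty accession")
        if not self.sequence:
            raise ValueError(f"empty sequence for accession {self.accession!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProteinDatabase:
    """Immutable collection of taxon-coded protein records."""

    records: tuple[ProteinRecord, ...]
    _by_accession: dict[str, ProteinRecord] = field(
        init=False, repr=False, compare=False, hash=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        index: dict[str, ProteinRecord] = {}
        for rec in self.records:
            if rec.accession in index:
                raise ValueError(f"duplicate accession {rec.accession!r}")
            index[rec.accession] = rec
        object.__setattr__(self, "_by_accession", index)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_accession

    def get(self, accession: str) -> ProteinRecord:
        try:
            return self._by_accession[accession]
        except KeyError:
            raise KeyError(f"unknown accession {accession!r}") from None

    def taxon_of(self, accession: str) -> str:
        return self.get(accession).taxon_code

    @property
    def accessions(self) -> list[str]:
        return [r.accession for r in self.records]

    def species_codes(self) -> list[str]:
        """Species-group codes present, in first-seen order."""
        seen: dict[str, None] = {}
        for rec in self.records:
            if rec.taxon_code not in RESERVED_CODES:
                seen.setdefault(rec.taxon_code, None)
        return list(seen)

    def code_counts(self) -> pd.Series:
        return pd.Series([r.taxon_code for r in self.records]).value_counts()

    def lengths(self) -> pd.Series:
        return pd.Series(
            {r.accession: r.length for r in self.records}, name="length", dtype=int
        )

    def microbial_records(self) -> list[ProteinRecord]:
        return [r for r in self.records if r.taxon_code not in (HOST, DIET)]

    def with_records(self, records: Iterable[ProteinRecord]) -> "ProteinDatabase":
        return ProteinDatabase(tuple(records))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "accession": [r.accession for r in self.records],
                "taxon_code": [r.taxon_code for r in self.records],
                "length": [r.length for r in self.records],
                "sequence": [r.sequence for r in self.records],
            }
        )

    def to_fasta(self, path) -> None:
        """Write FASTA with ``accession|taxon_code`` headers."""
        seq_records = [
            SeqRecord(Seq(r.sequence), id=f"{r.accession}|{r.taxon_code}", description="")
            for r in self.records
        ]
        SeqIO.write(seq_records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path) -> "ProteinDatabase":
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            accession, _, code = rec.id.rpartition("|")
            if not accession:
                raise ValueError(
                    f"header {rec.id!r} lacks the accession|taxon_code form"
                )
            records.append(ProteinRecord(accession, str(rec.seq), code))
        return cls(tuple(records))

    def tryptic_peptide_index(
        self, min_length: int = 7, max_length: int = 30
    ) -> dict[str, frozenset]:
        """Map each tryptic peptide to the accessions that contain it."""
        index: dict[str, set] = {}
        for rec in self.records:
            for pep in digest_tryptic(rec.sequence, min_length, max_length):
                index.setdefault(pep, set()).add(rec.accession)
        return {pep: frozenset(accs) for pep, accs in index.items()}


def digest_tryptic(
    sequence: str, min_length: int = 7, max_length: int = 30
) -> list[str]:
    """In-silico tryptic digest: cleave after K/R, no missed cleavages.

    Peptides outside ``[min_length, max_length]`` residues are discarded,
    matching the mass range a spectrometer effectively samples.
    """
    peptides, start = [], 0
    for i, aa in enumerate(sequence):
        if aa in "KR":
            peptides.append(sequence[start : i + 1])
            start = i + 1
    if start < len(sequence):
        peptides.append(sequence[start:])
    return [p for p in peptides if min_length <= len(p) <= max_length]


# ---------------------------------------------------------------------------
# Pairwise identity


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.5
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def percent_identity(a: str, b: str) -> float:
    """Global-alignment identity: matched columns / shorter sequence length.

    This mirrors CD-HIT's ``-c`` semantics, where identity is relative to
    the shorter sequence.  Identical strings short-circuit to 1.0.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if a == b:
        return 1.0
    alignment = _ALIGNER.align(a, b)[0]
    identities = alignment.counts().identities
    return identities / min(len(a), len(b))


def _kmers(seq: str, k: int) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def has_match_above(
    query: str,
    subjects: Sequence[str],
    threshold: float,
    prefilter_k: int = 4,
) -> bool:
    """True if ``query`` aligns at >= threshold identity to any subject.

    A shared-k-mer prefilter skips hopeless pairs; any pair at the
    identity levels screened here (>= 90%) shares 4-mers with certainty
    for all but adversarial sequences, and the exact DP is still run for
    every pair that passes.
    """
    qk = _kmers(query, prefilter_k)
    for subject in subjects:
        if len(query) >= prefilter_k and len(subject) >= prefilter_k:
            if not qk & _kmers(subject, prefilter_k):
                continue
        if percent_identity(query, subject) >= threshold:
            return True
    return False


# ---------------------------------------------------------------------------
# Bin screening and species coding


@dataclass(frozen=True)
class BinRecord:
    """A metagenomic bin with its quality scores and gene calls.

    ``proteins`` holds (accession, sequence) gene calls from the bin's
    annotation; ``species_group_id`` comes from the upstream 95%-ANI
    clustering and ``species_class`` from the taxonomy assignment.
    """

    bin_id: str
    species_group_id: str
    completeness: float
    contamination: float
    proteins: tuple[tuple[str, str], ...] = ()
    species_class: str | None = None

    def __post_init__(self) -> None:
        for name, value in (
            ("completeness", self.completeness),
            ("contamination", self.contamination),
        ):
            if not 0.0 <= value <= 100.0:
                raise ValueError(
                    f"bin {self.bin_id!r}: {name}={value} outside [0, 100]"
                )
        object.__setattr__(self, "proteins", tuple(tuple(p) for p in self.proteins))


def classify_bins(
    bins: Sequence[BinRecord],
    species_tier: tuple[float, float] = (50.0, 10.0),
    lowq_tier: tuple[float, float] = (30.0, 5.0),
) -> dict[str, str]:
    """Screen bins against the two acceptance tiers.

    A bin is species-grade when completeness > 50% and contamination
    < 10% (medium quality); bins that miss that bar but are > 30%
    complete and < 5% contaminated are kept at a low-quality tier so
    their proteins still enter the database under the ``LOWQ`` code.
    Both thresholds are strict inequalities.
    """
    result: dict[str, str] = {}
    for b in bins:
        min_comp, max_cont = species_tier
        if b.completeness > min_comp and b.contamination < max_cont:
            result[b.bin_id] = ACCEPT_SPECIES
            continue
        min_comp, max_cont = lowq_tier
        if b.completeness > min_comp and b.contamination < max_cont:
            result[b.bin_id] = ACCEPT_LOWQ_TIER
        else:
            result[b.bin_id] = REJECT
    return result


def assign_species_codes(
    bins: Sequence[BinRecord],
    tier_map: Mapping[str, str] | None = None,
    bin_map: Mapping[str, str] | None = None,
) -> ProteinDatabase:
    """Code binned gene calls by species group.

    A sequence observed in species-grade bins of exactly one species
    group receives that group's code; in two or more groups it is coded
    ``AMBIGUOUS``; a sequence seen only in low-quality-tier bins is coded
    ``LOWQ``.  A sequence present in both a species-grade and a
    low-quality bin follows the species code (species > LOWQ precedence,
    logged).  Identical sequences collapse to a single record under the
    lexicographically first accession.
    """
    if tier_map is None:
        tier_map = classify_bins(bins)
    known = {b.bin_id for b in bins}
    for bin_id in tier_map:
        if bin_id not in known:
            raise ValueError(f"tier map references unknown bin {bin_id!r}")

    seq_species: dict[str, set] = {}
    seq_lowq: dict[str, bool] = {}
    seq_accession: dict[str, str] = {}
    for b in bins:
        tier = tier_map.get(b.bin_id, REJECT)
        if tier == REJECT:
            continue
        group = bin_map[b.bin_id] if bin_map is not None else b.species_group_id
        if not group:
            raise ValueError(f"bin {b.bin_id!r} has no species group id")
        for accession, sequence in b.proteins:
            prev = seq_accession.get(sequence)
            if prev is None or accession < prev:
                seq_accession[sequence] = accession
            if tier == ACCEPT_SPECIES:
                seq_species.setdefault(sequence, set()).add(group)
            else:
                seq_lowq[sequence] = True

    records = []
    n_precedence = 0
    for sequence, accession in sorted(seq_accession.items(), key=lambda kv: kv[1]):
        groups = seq_species.get(sequence, set())
        if len(groups) > 1:
            code = AMBIGUOUS
        elif len(groups) == 1:
            code = next(iter(groups))
            if sequence in seq_lowq:
                n_precedence += 1
        else:
            code = LOWQ
        records.append(ProteinRecord(accession, sequence, code))
    if n_precedence:
        warnings.warn(
            f"{n_precedence} sequence(s) found in both species-grade and "
            "low-quality bins; species code takes precedence",
            stacklevel=2,
        )
    return ProteinDatabase(tuple(records))


def merge_binned_unbinned(
    binned: ProteinDatabase | Sequence[ProteinRecord],
    unbinned: Sequence[tuple[str, str]],
    identity_threshold: float = 0.90,
) -> list[ProteinRecord]:
    """Select unbinned gene calls that add new sequence content.

    An unbinned sequence is added (code ``UNBINNED``) only when no binned
    sequence matches it at >= ``identity_threshold`` over the shorter
    sequence; redundant sequences are dropped.  Returns the additions.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError(f"identity_threshold {identity_threshold} outside (0, 1]")
    binned_seqs = [r.sequence for r in binned]
    additions = []
    for accession, sequence in unbinned:
        if not has_match_above(sequence, binned_seqs, identity_threshold):
            additions.append(ProteinRecord(accession, sequence, UNBINNED))
    return additions


def relabel_by_reference(
    database: ProteinDatabase,
    reference_sequences: Sequence[tuple[str, str]],
    new_code: str,
    identity_threshold: float = 0.95,
) -> ProteinDatabase:
    """Recode database sequences matching a reference proteome.

    Any microbial record aligning at >= ``identity_threshold`` identity
    to a reference sequence (e.g. a named species' UniProt set) has its
    species code replaced with ``new_code``.
    """
    if new_code in RESERVED_CODES:
        raise ValueError(f"new_code {new_code!r} collides with a reserved code")
    if not reference_sequences:
        raise ValueError("reference set is empty")
    ref_seqs = [seq for _, seq in reference_sequences]
    records = []
    for rec in database:
        if rec.taxon_code not in (HOST, DIET) and has_match_above(
            rec.sequence, ref_seqs, identity_threshold
        ):
            records.append(replace(rec, taxon_code=new_code))
        else:
            records.append(rec)
    return ProteinDatabase(tuple(records))


def _greedy_cluster(
    records: Sequence[tuple[str, str]], identity_threshold: float
) -> list[tuple[str, str]]:
    """Greedy representative selection, longest sequence first.

    First-seen order breaks length ties, mirroring the CD-HIT convention
    and keeping output deterministic.
    """
    ordered = sorted(
        enumerate(records), key=lambda item: (-len(item[1][1]), item[0])
    )
    reps: list[tuple[str, str]] = []
    rep_seqs: list[str] = []
    for _, (accession, sequence) in ordered:
        if not has_match_above(sequence, rep_seqs, identity_threshold):
            reps.append((accession, sequence))
            rep_seqs.append(sequence)
    return reps


def append_host_diet(
    database: ProteinDatabase,
    host_sequences: Sequence[tuple[str, str]] = (),
    diet_sequences: Sequence[tuple[str, str]] = (),
    cluster_identity: float = 0.95,
) -> ProteinDatabase:
    """Append host and dietary reference proteomes.

    Each proteome is collapsed individually at >= ``cluster_identity``
    (greedy, longest-first) before being coded ``HOST`` or ``DIET``.
    Microbial records are untouched.  Any ``HOST``/``DIET`` records
    already present are replaced, which makes the operation idempotent
    for identical inputs.  Accession collisions with the database are
    renamed with a source prefix and logged.
    """
    if not host_sequences and not diet_sequences:
        raise ValueError("at least one of host/diet proteomes must be provided")
    microbial = [r for r in database if r.taxon_code not in (HOST, DIET)]
    taken = {r.accession for r in microbial}
    records = list(microbial)
    for code, prefix, sequences in (
        (HOST, "host", host_sequences),
        (DIET, "diet", diet_sequences),
    ):
        for accession, sequence in _greedy_cluster(sequences, cluster_identity):
            if accession in taken:
                renamed = f"{prefix}_{accession}"
                warnings.warn(
                    f"accession {accession!r} already present; renamed to {renamed!r}",
                    stacklevel=2,
                )
                accession = renamed
            taken.add(accession)
            records.append(ProteinRecord(accession, sequence, code))
    return ProteinDatabase(tuple(records))


def assemble_database(
    bins: Sequence[BinRecord],
    unbinned: Sequence[tuple[str, str]] = (),
    host_sequences: Sequence[tuple[str, str]] = (),
    diet_sequences: Sequence[tuple[str, str]] = (),
    identity_merge: float = 0.90,
    cluster_identity: float = 0.95,
) -> ProteinDatabase:
    """End-to-end database assembly from bins + unbinned + references."""
    tier_map = classify_bins(bins)
    db = assign_species_codes(bins, tier_map)
    if unbinned:
        additions = merge_binned_unbinned(db, unbinned, identity_merge)
        db = db.with_records(list(db.records) + additions)
    if host_sequences or diet_sequences:
        db = append_host_diet(db, host_sequences, diet_sequences, cluster_identity)
    return db
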