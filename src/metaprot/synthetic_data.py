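"""Ground-truth community and PSM-table simulation.

The generator emulates the statistical structure a metaproteomic
quantification pipeline assumes: spectral counts drawn multinomially
with per-protein weight proportional to species biomass x relative
expression x protein length, tryptic peptides shared among related
species (creating taxonomic ambiguity), host and dietary protein
contamination, signal diverted to low-quality-bin and unbinned
partitions, and decoy PSMs whose scores follow the null distribution of
incorrect matches.  It does not model spectrum-level physics (m/z,
retention time) or post-translational modifications.

Target/decoy scores follow the standard target-decoy generative model:
a configurable fraction of target PSMs are incorrect matches scoring
from the null distribution, and the decoy count is drawn with the same
expectation, which is the regime in which decoy counts estimate false
target counts and the downstream FDR estimate is calibrated.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .database_builder import (
    DIET,
    HOST,
    LOWQ,
    UNBINNED,
    ProteinDatabase,
    ProteinRecord,
)

#: Interior residues exclude K/R so that an in-silico tryptic digest of a
#: concatenated protein reproduces exactly the peptides it was built from.
_INTERIOR_ALPHABET = np.array(list("ACDEFGHILMNPQSTVWY"))
_CLEAVAGE_RESIDUES = np.array(list("KR"))

#: Taxonomic classes sampled for synthetic species (GTDB class names
#: common in mouse gut communities).
CLASS_PALETTE = (
    "Bacteroidia",
    "Clostridia",
    "Bacilli",
    "Actinomycetia",
    "Verrucomicrobiae",
    "Coriobacteriia",
)

PSM_COLUMNS = [
    "sample_id",
    "spectrum_id",
    "peptide",
    "score",
    "is_decoy",
    "protein_ids",
    "is_false",
]


@dataclass(frozen=True)
class ContaminationFractions:
    """Non-species signal fractions.

    ``host`` and ``diet`` are fractions of total PSMs; ``lowq`` and
    ``unbinned`` are fractions of the microbial signal routed to the
    corresponding database partitions.
    """

    host: float = 0.20
    diet: float = 0.04
    lowq: float = 0.03
    unbinned: float = 0.08

    def __post_init__(self) -> None:
        for name in ("host", "diet", "lowq", "unbinned"):
            value = getattr(self, name)
            if not 0.0 <= value < 1.0:
                raise ValueError(f"{name} fraction {value} outside [0, 1)")
        if self.host + self.diet >= 1.0:
            raise ValueError("host_fraction + diet_fraction must be < 1")
        if self.lowq + self.unbinned >= 1.0:
            raise ValueError("lowq + unbinned fractions must be < 1")


@dataclass(frozen=True)
class GroundTruthCommunity:
    """True composition of a simulated community."""

    species_ids: tuple[str, ...]
    biomass_fractions: np.ndarray
    class_labels: tuple[str, ...]
    host_fraction: float
    diet_fraction: float
    lowq_fraction: float
    unbinned_fraction: float
    seed: int

    def __post_init__(self) -> None:
        fractions = np.asarray(self.biomass_fractions, dtype=float)
        object.__setattr__(self, "biomass_fractions", fractions)
        if len(fractions) != len(self.species_ids):
            raise ValueError("biomass_fractions and species_ids length mismatch")
        if len(self.class_labels) != len(self.species_ids):
            raise ValueError("class_labels and species_ids length mismatch")
        if np.any(fractions <= 0):
            raise ValueError("biomass fractions must all be > 0")
        if abs(fractions.sum() - 1.0) > 1e-12:
            raise ValueError("biomass fractions must sum to 1 within 1e-12")
        if self.host_fraction + self.diet_fraction >= 1.0:
            raise ValueError("host_fraction + diet_fraction must be < 1")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species_id": self.species_ids,
                "biomass_fraction": self.biomass_fractions,
                "class_label": self.class_labels,
            }
        )


@dataclass
class SyntheticProteinSpec:
    """Ground truth for one simulated protein."""

    protein_id: str
    taxon_code: str
    relative_expression: float
    tryptic_peptides: list[str]
    shared_with: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.relative_expression <= 0:
            raise ValueError("relative_expression must be > 0")
        for pep in self.tryptic_peptides:
            if not 7 <= len(pep) <= 30:
                raise ValueError(f"peptide {pep!r} outside tryptic length 7-30")

    @property
    def sequence(self) -> str:
        return "".join(self.tryptic_peptides)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DecoyScoreModel:
    """Score-generating model for targets, false targets and decoys.

    Correct target PSMs score Normal(target_loc, scale); incorrect
    matches — both the ``false_target_rate`` fraction of targets and the
    appended decoys — score Normal(null_loc, scale).  The expected decoy
    count equals ``false_target_rate * decoy_to_false_ratio`` per target
    PSM; at the default ratio of 1 the decoys are an unbiased stand-in
    for the false targets.
    """

    target_loc: float = 4.0
    null_loc: float = 0.0
    scale: float = 1.0
    false_target_rate: float = 0.1
    decoy_to_false_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if not 0.0 <= self.false_target_rate < 1.0:
            raise ValueError("false_target_rate outside [0, 1)")
        if self.decoy_to_false_ratio < 0:
            raise ValueError("decoy_to_false_ratio must be >= 0")


def generate_community(
    n_species: int,
    dirichlet_alpha: float = 0.5,
    fractions: ContaminationFractions | None = None,
    seed: int = 0,
) -> GroundTruthCommunity:
    """Draw species biomass fractions from a symmetric Dirichlet.

    ``dirichlet_alpha`` controls evenness: small alpha gives a few
    dominant species (realistic for gut communities), large alpha tends
    to the uniform composition.
    """
    if n_species < 1:
        raise ValueError(f"n_species must be >= 1, got {n_species}")
    if dirichlet_alpha <= 0:
        raise ValueError(f"dirichlet_alpha must be > 0, got {dirichlet_alpha}")
    if fractions is None:
        fractions = ContaminationFractions()
    rng = np.random.default_rng(seed)
    biomass = rng.dirichlet(np.full(n_species, dirichlet_alpha))
    # Guard against numerically zero fractions from extreme draws.
    biomass = np.clip(biomass, 1e-12, None)
    biomass = biomass / biomass.sum()
    width = max(3, len(str(n_species)))
    species_ids = tuple(f"S{i + 1:0{width}d}" for i in range(n_species))
    class_labels = tuple(rng.choice(CLASS_PALETTE, size=n_species))
    return GroundTruthCommunity(
        species_ids=species_ids,
        biomass_fractions=biomass,
        class_labels=class_labels,
        host_fraction=fractions.host,
        diet_fraction=fractions.diet,
        lowq_fraction=fractions.lowq,
        unbinned_fraction=fractions.unbinned,
        seed=seed,
    )


def _random_peptide(rng: np.random.Generator, taken: set) -> str:
    """One tryptic peptide, unique across the catalog."""
    while True:
        length = int(rng.integers(7, 31))
        body = rng.choice(_INTERIOR_ALPHABET, size=length - 1)
        end = rng.choice(_CLEAVAGE_RESIDUES)
        pep = "".join(body) + str(end)
        if pep not in taken:
            taken.add(pep)
            return pep


def _make_protein(
    rng: np.random.Generator,
    taken: set,
    protein_id: str,
    taxon_code: str,
    length_median: float,
    length_sigma: float,
    expression_sigma: float,
) -> SyntheticProteinSpec:
    target_length = float(rng.lognormal(np.log(length_median), length_sigma))
    peptides: list[str] = []
    total = 0
    while total < max(target_length, 7):
        pep = _random_peptide(rng, taken)
        peptides.append(pep)
        total += len(pep)
    expression = float(rng.lognormal(0.0, expression_sigma))
    return SyntheticProteinSpec(
        protein_id=protein_id,
        taxon_code=taxon_code,
        relative_expression=expression,
        tryptic_peptides=peptides,
    )


def generate_protein_catalog(
    community: GroundTruthCommunity,
    proteins_per_species: int = 15,
    shared_peptide_rate: float = 0.0,
    length_median: float = 300.0,
    length_sigma: float = 0.35,
    expression_sigma: float = 1.0,
    n_host_proteins: int = 40,
    n_diet_proteins: int = 20,
    n_lowq_proteins: int = 15,
    n_unbinned_proteins: int = 15,
    seed: int = 0,
) -> tuple[ProteinDatabase, list[SyntheticProteinSpec]]:
    """Generate the protein database and its ground-truth catalog.

    Proteins are concatenations of unique random tryptic peptides
    (ending K/R, no interior K/R), with log-normal lengths (median
    ``length_median`` aa) and log-normal within-taxon expression
    weights.  A fraction ``shared_peptide_rate`` of species peptides is
    duplicated into a randomly chosen second species' protein, creating
    the shared-peptide ambiguity the pipeline must resolve.  Host and
    diet proteins never share peptides with microbial proteins.
    """
    if proteins_per_species < 2:
        raise ValueError(
            "proteins_per_species must be >= 2 so the two-unique-peptide "
            "biomass rule is exercised"
        )
    if not 0.0 <= shared_peptide_rate < 1.0:
        raise ValueError(f"shared_peptide_rate {shared_peptide_rate} outside [0, 1)")
    rng = np.random.default_rng(seed)
    taken: set = set()
    catalog: list[SyntheticProteinSpec] = []

    for sp_index, species in enumerate(community.species_ids):
        for j in range(proteins_per_species):
            catalog.append(
                _make_protein(
                    rng,
                    taken,
                    f"{species}_P{j + 1:03d}",
                    species,
                    length_median,
                    length_sigma,
                    expression_sigma,
                )
            )
    for code, prefix, count in (
        (LOWQ, "LQ", n_lowq_proteins),
        (UNBINNED, "UB", n_unbinned_proteins),
        (HOST, "HOST", n_host_proteins),
        (DIET, "DIET", n_diet_proteins),
    ):
        for j in range(count):
            catalog.append(
                _make_protein(
                    rng,
                    taken,
                    f"{prefix}_P{j + 1:03d}",
                    code,
                    length_median,
                    length_sigma,
                    expression_sigma,
                )
            )

    if shared_peptide_rate > 0 and community.n_species > 1:
        by_species: dict[str, list[int]] = {}
        for idx, spec in enumerate(catalog):
            if spec.taxon_code in community.species_ids:
                by_species.setdefault(spec.taxon_code, []).append(idx)
        peptide_slots = [
            (idx, pep_idx)
            for idx, spec in enumerate(catalog)
            if spec.taxon_code in community.species_ids
            for pep_idx in range(len(spec.tryptic_peptides))
        ]
        n_shared = int(round(shared_peptide_rate * len(peptide_slots)))
        chosen = rng.choice(len(peptide_slots), size=n_shared, replace=False)
        species_list = list(community.species_ids)
        for slot in chosen:
            src_idx, pep_idx = peptide_slots[slot]
            source = catalog[src_idx]
            others = [s for s in species_list if s != source.taxon_code]
            target_species = others[int(rng.integers(len(others)))]
            target_idx = by_species[target_species][
                int(rng.integers(len(by_species[target_species])))
            ]
            target = catalog[target_idx]
            pep = source.tryptic_peptides[pep_idx]
            if pep in target.tryptic_peptides:
                continue
            target.tryptic_peptides.append(pep)
            source.shared_with.add(target_species)
            target.shared_with.add(source.taxon_code)

    database = ProteinDatabase(
        tuple(
            ProteinRecord(spec.protein_id, spec.sequence, spec.taxon_code)
            for spec in catalog
        )
    )
    return database, catalog


def peptide_to_proteins(catalog: Sequence[SyntheticProteinSpec]) -> dict[str, list]:
    """Map each catalog peptide to every protein id containing it."""
    mapping: dict[str, list] = {}
    for spec in catalog:
        for pep in spec.tryptic_peptides:
            mapping.setdefault(pep, []).append(spec.protein_id)
    return {pep: sorted(ids) for pep, ids in mapping.items()}


def _partition_weights(
    community: GroundTruthCommunity,
    catalog: Sequence[SyntheticProteinSpec],
    species_fractions: np.ndarray | None,
) -> np.ndarray:
    """Per-protein sampling weights.

    The weight of taxon partition T is its configured fraction of the
    sample; within T each protein's weight is proportional to
    relative_expression x length.  Normalizing within the partition
    makes a taxon's expected PSM share equal its fraction exactly, which
    is the ground-truth recovery contract the profiler is tested
    against.
    """
    host, diet = community.host_fraction, community.diet_fraction
    microbial = 1.0 - host - diet
    lowq = microbial * community.lowq_fraction
    unbinned = microbial * community.unbinned_fraction
    species_total = microbial - lowq - unbinned

    if species_fractions is None:
        species_fractions = community.biomass_fractions
    species_fractions = np.asarray(species_fractions, dtype=float)
    species_fractions = species_fractions / species_fractions.sum()
    taxon_fraction = {
        code: frac
        for code, frac in zip(
            community.species_ids, species_total * species_fractions
        )
    }
    taxon_fraction[LOWQ] = lowq
    taxon_fraction[UNBINNED] = unbinned
    taxon_fraction[HOST] = host
    taxon_fraction[DIET] = diet

    base = np.array(
        [spec.relative_expression * spec.length for spec in catalog], dtype=float
    )
    codes = [spec.taxon_code for spec in catalog]
    weights = np.zeros(len(catalog))
    for code in set(codes):
        mask = np.array([c == code for c in codes])
        frac = taxon_fraction.get(code, 0.0)
        if frac > 0 and mask.any():
            weights[mask] = frac * base[mask] / base[mask].sum()
    if weights.sum() <= 0:
        raise ValueError("no protein received positive sampling weight")
    return weights / weights.sum()


def simulate_psm_table(
    community: GroundTruthCommunity,
    catalog: Sequence[SyntheticProteinSpec],
    depth: int = 20000,
    n_samples: int = 1,
    decoy_model: DecoyScoreModel | None = None,
    seed: int = 0,
    sample_ids: Sequence[str] | None = None,
    species_fractions: Sequence[np.ndarray] | np.ndarray | None = None,
) -> list[pd.DataFrame]:
    """Simulate per-sample PSM tables.

    Each sample receives exactly ``depth`` target PSMs drawn
    multinomially over proteins (see :func:`_partition_weights`), plus
    decoy PSMs.  ``species_fractions`` optionally overrides the
    community's biomass fractions per sample (one vector per sample) to
    simulate condition effects.  Columns follow :data:`PSM_COLUMNS`;
    ``is_false`` is simulation ground truth used to audit FDR
    calibration and is ignored by the quantification pipeline.
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    if not catalog:
        raise ValueError("empty protein catalog")
    if decoy_model is None:
        decoy_model = DecoyScoreModel()
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = [f"sample{i + 1:03d}" for i in range(n_samples)]
    if len(sample_ids) != n_samples:
        raise ValueError("sample_ids length must equal n_samples")

    pep_map = peptide_to_proteins(catalog)
    pep_ids = {pep: ";".join(ids) for pep, ids in pep_map.items()}
    peptides_flat: list[str] = []
    offsets = np.zeros(len(catalog) + 1, dtype=int)
    for i, spec in enumerate(catalog):
        peptides_flat.extend(spec.tryptic_peptides)
        offsets[i + 1] = len(peptides_flat)
    peptides_flat = np.array(peptides_flat, dtype=object)
    n_peps = np.diff(offsets)
    accessions = np.array([spec.protein_id for spec in catalog], dtype=object)

    per_sample_fractions: list[np.ndarray | None]
    if species_fractions is None:
        per_sample_fractions = [None] * n_samples
    else:
        species_fractions = np.asarray(species_fractions, dtype=float)
        if species_fractions.ndim == 1:
            per_sample_fractions = [species_fractions] * n_samples
        else:
            if species_fractions.shape[0] != n_samples:
                raise ValueError("species_fractions rows must equal n_samples")
            per_sample_fractions = list(species_fractions)

    tables = []
    for sample_id, fracs in zip(sample_ids, per_sample_fractions):
        weights = _partition_weights(community, catalog, fracs)
        n_false = rng.binomial(depth, decoy_model.false_target_rate)
        n_true = depth - n_false
        true_counts = rng.multinomial(n_true, weights)
        false_counts = (
            rng.multinomial(n_false, np.full(len(catalog), 1.0 / len(catalog)))
            if n_false
            else np.zeros(len(catalog), dtype=int)
        )

        rows_protein = []
        rows_false = []
        for counts, false_flag in ((true_counts, False), (false_counts, True)):
            nz = np.nonzero(counts)[0]
            reps = np.repeat(nz, counts[nz])
            rows_protein.append(reps)
            rows_false.append(np.full(len(reps), false_flag))
        protein_idx = np.concatenate(rows_protein)
        is_false = np.concatenate(rows_false)

        pep_choice = (rng.random(len(protein_idx)) * n_peps[protein_idx]).astype(int)
        peptides = peptides_flat[offsets[protein_idx] + pep_choice]
        scores = np.where(
            is_false,
            rng.normal(decoy_model.null_loc, decoy_model.scale, len(protein_idx)),
            rng.normal(decoy_model.target_loc, decoy_model.scale, len(protein_idx)),
        )

        n_decoys = rng.binomial(
            depth, decoy_model.false_target_rate * decoy_model.decoy_to_false_ratio
        )
        decoy_source = rng.integers(0, len(catalog), size=n_decoys)
        decoy_pep_choice = (rng.random(n_decoys) * n_peps[decoy_source]).astype(int)
        decoy_peptides = np.array(
            [
                pep[::-1]
                for pep in peptides_flat[offsets[decoy_source] + decoy_pep_choice]
            ],
            dtype=object,
        )
        decoy_scores = rng.normal(decoy_model.null_loc, decoy_model.scale, n_decoys)

        frame = pd.DataFrame(
            {
                "sample_id": sample_id,
                "peptide": np.concatenate([peptides, decoy_peptides]),
                "score": np.concatenate([scores, decoy_scores]),
                "is_decoy": np.concatenate(
                    [np.zeros(len(protein_idx), bool), np.ones(n_decoys, bool)]
                ),
                "protein_ids": np.concatenate(
                    [
                        np.array(
                            [pep_ids[p] for p in peptides], dtype=object
                        ),
                        np.char.add(
                            "DECOY_", accessions[decoy_source].astype(str)
                        ).astype(object),
                    ]
                ),
                "is_false": np.concatenate(
                    [is_false, np.ones(n_decoys, bool)]
                ),
            }
        )
        frame = frame.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(
            drop=True
        )
        frame.insert(
            1,
            "spectrum_id",
            [f"{sample_id}:scan{i + 1:07d}" for i in range(len(frame))],
        )
        tables.append(frame[PSM_COLUMNS])
    return tables


def write_psm_tsv(tables: Sequence[pd.DataFrame], path) -> None:
    """Write concatenated PSM tables as TSV (deterministic formatting)."""
    combined = pd.concat(tables, ignore_index=True)
    combined.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_psm_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"peptide": str, "protein_ids": str})
    frame["is_decoy"] = frame["is_decoy"].astype(bool)
    if "is_false" in frame:
        frame["is_false"] = frame["is_false"].astype(bool)
    return frame


# ---------------------------------------------------------------------------
# Study-level simulation


@dataclass(frozen=True)
class ExperimentDesign:
    """Feeding-study layout: mice in groups/cages fed a series of diets.

    Mirrors a two-group repeated-measures design where every mouse is
    sampled once per diet; ``diets`` maps diet name -> (protein_source,
    protein_amount).
    """

    n_mice: int = 12
    n_groups: int = 2
    mice_per_cage: int = 3
    diets: tuple[tuple[str, str, int], ...] = (
        ("soy_20", "soy", 20),
        ("casein_20", "casein", 20),
        ("rice_20", "rice", 20),
        ("soy_40", "soy", 40),
        ("yeast_20", "yeast", 20),
        ("casein_40", "casein", 40),
        ("pea_20", "pea", 20),
        ("egg_20", "egg", 20),
    )

    def metadata(self) -> pd.DataFrame:
        rows = []
        per_group = self.n_mice // self.n_groups
        for d_index, (diet, source, amount) in enumerate(self.diets):
            for m in range(self.n_mice):
                group = m // per_group + 1
                cage = m // self.mice_per_cage + 1
                mouse = f"mouse{m + 1:02d}"
                rows.append(
                    {
                        "sample_id": f"{mouse}_{diet}",
                        "mouse_id": mouse,
                        "mouse_group": f"group{group}",
                        "cage": f"cage{cage}",
                        "diet": diet,
                        "protein_source": source,
                        "protein_amount": amount,
                        "mouse_age": d_index + 1,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class SyntheticExperiment:
    """Bundle of everything one simulated feeding study produces."""

    community: GroundTruthCommunity
    catalog: list[SyntheticProteinSpec]
    database: ProteinDatabase
    metadata: pd.DataFrame
    psm_tables: list[pd.DataFrame]
    sample_fractions: pd.DataFrame  # species x sample ground truth


def simulate_experiment(
    n_species: int = 30,
    dirichlet_alpha: float = 0.5,
    design: ExperimentDesign | None = None,
    depth: int = 3000,
    proteins_per_species: int = 10,
    shared_peptide_rate: float = 0.05,
    diet_effect_sigma: float = 0.9,
    group_effect_sigma: float = 0.7,
    noise_sigma: float = 0.25,
    fractions: ContaminationFractions | None = None,
    decoy_model: DecoyScoreModel | None = None,
    seed: int = 0,
) -> SyntheticExperiment:
    """Simulate a full feeding study.

    Per-sample species fractions follow a log-linear model: log base
    biomass plus a per-(protein_source, species) effect, a
    per-(group, species) effect, and per-sample log-normal noise, then
    renormalized.  This generates compositional data where diet and
    mouse group are genuine sources of between-sample variance, the
    structure the PERMANOVA and mixed-model layers are tested on.
    """
    if design is None:
        design = ExperimentDesign()
    rng = np.random.default_rng(seed)
    community = generate_community(
        n_species, dirichlet_alpha, fractions, seed=int(rng.integers(2**31))
    )
    database, catalog = generate_protein_catalog(
        community,
        proteins_per_species=proteins_per_species,
        shared_peptide_rate=shared_peptide_rate,
        seed=int(rng.integers(2**31)),
    )
    metadata = design.metadata()

    sources = sorted({source for _, source, _ in design.diets})
    source_effects = {
        source: rng.normal(0.0, diet_effect_sigma, n_species) for source in sources
    }
    groups = sorted(metadata["mouse_group"].unique())
    group_effects = {
        group: rng.normal(0.0, group_effect_sigma, n_species) for group in groups
    }

    log_base = np.log(community.biomass_fractions)
    fraction_rows = {}
    for row in metadata.itertuples(index=False):
        logw = (
            log_base
            + source_effects[row.protein_source]
            + group_effects[row.mouse_group]
            + rng.normal(0.0, noise_sigma, n_species)
        )
        w = np.exp(logw - logw.max())
        fraction_rows[row.sample_id] = w / w.sum()
    sample_fractions = pd.DataFrame(
        fraction_rows, index=list(community.species_ids)
    )

    psm_tables = simulate_psm_table(
        community,
        catalog,
        depth=depth,
        n_samples=len(metadata),
        decoy_model=decoy_model,
        seed=int(rng.integers(2**31)),
        sample_ids=list(metadata["sample_id"]),
        species_fractions=sample_fractions.to_numpy().T,
    )
    return SyntheticExperiment(
        community=community,
        catalog=catalog,
        database=database,
        metadata=metadata,
        psm_tables=psm_tables,
        sample_fractions=sample_fractions,
    )


def generate_annotations(
    catalog: Sequence[SyntheticProteinSpec],
    vocab: pd.DataFrame,
    manual_coverage: float = 0.3,
    tool_error_rate: float = 0.1,
    tool_missing_rate: float = 0.1,
    pul_species: str | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign synthetic functional annotations to microbial proteins.

    Each microbial protein receives a true enzyme function drawn from
    ``vocab`` (see :func:`metaprot.functional_profiler.load_enzyme_vocab`).
    Three simulated annotation tools report that function with
    independent error and dropout, and a ``manual_coverage`` fraction of
    proteins carries a curated label — the raw material for the
    consensus/extrapolation machinery.  Proteins of ``pul_species``
    annotated with PUL-associated enzymes get a PUL id so locus rollups
    are exercised.
    """
    rng = np.random.default_rng(seed)
    enzymes = vocab["enzyme_name"].to_numpy()
    wrong_pool = enzymes
    microbial = [
        spec for spec in catalog if spec.taxon_code not in (HOST, DIET)
    ]
    rows = []
    pul_cycle = ("PUL68", "PUL69", "PUL56", "PUL14", "PUL72")
    pul_counter = 0
    for spec in microbial:
        true_enzyme = str(rng.choice(enzymes))
        tool_labels = {}
        for tool in ("tool_eggnog", "tool_mantis", "tool_microbeannotator"):
            if rng.random() < tool_missing_rate:
                tool_labels[tool] = None
            elif rng.random() < tool_error_rate:
                tool_labels[tool] = str(rng.choice(wrong_pool))
            else:
                tool_labels[tool] = true_enzyme
        manual = true_enzyme if rng.random() < manual_coverage else None
        vrow = vocab.loc[vocab["enzyme_name"] == true_enzyme].iloc[0]
        pul_id = None
        if (
            pul_species is not None
            and spec.taxon_code == pul_species
            and bool(vrow.get("pul_associated", False))
        ):
            pul_id = pul_cycle[pul_counter % len(pul_cycle)]
            pul_counter += 1
        rows.append(
            {
                "accession": spec.protein_id,
                **tool_labels,
                "manual_label": manual,
                "true_enzyme": true_enzyme,
                "broad_category": vrow["broad_category"],
                "detailed_category": vrow["detailed_category"],
                "enzyme_name": true_enzyme,
                "gh_family": vrow["gh_family"] if pd.notna(vrow["gh_family"]) else None,
                "pul_id": pul_id,
            }
        )
    return pd.DataFrame(rows)


def write_metadata_tsv(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def write_ground_truth_tsv(
    community: GroundTruthCommunity, path, sample_fractions: pd.DataFrame | None = None
) -> None:
    """Write the true biomass fractions (per community or per sample)."""
    if sample_fractions is None:
        community.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
    else:
        out = sample_fractions.copy()
        out.insert(0, "species_id", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")
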