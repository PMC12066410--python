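"""End-to-end orchestration of the quantification pipeline.

Stages run in dependency order on a simulated study (or on previously
written stage outputs): simulate -> quantify -> biomass -> diversity ->
functions -> stats.  Every stage writes TSV/FASTA/Newick artifacts into
its own directory under the run directory, and a JSON manifest records
the configuration, seeds and SHA-256 checksums of every output so a
re-run with the same configuration is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .biomass_profiler import (
    abundant_species,
    class_rollup,
    microbe_host_ratio,
    quantify_biomass,
    richness,
)
from .config import RunConfig
from .database_builder import ProteinDatabase
from .diversity import bray_curtis, clr_pca, pairwise_permanova, permanova, shannon_index, ward_cluster
from .functional_profiler import (
    amino_acid_class_rollup,
    ammonia_producing_panel,
    annotated_mass_fraction,
    consensus_annotate,
    load_aa_pathway_map,
    load_enzyme_vocab,
    nsaf,
    org_nsaf,
    rollup,
)
from .modeling import differential_features, fit_feature_lmm
from .psm_processing import filter_psms, count_spectra
from .synthetic_data import (
    ContaminationFractions,
    ExperimentDesign,
    generate_annotations,
    read_psm_tsv,
    simulate_experiment,
    write_psm_tsv,
)

logger = logging.getLogger("metaprot")

_FLOAT_FORMAT = "%.10g"


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FORMAT)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory.

    Raises FileNotFoundError naming the stage and path when an expected
    input is missing (fail-fast).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    # --- simulate -------------------------------------------------------
    sim_dir = outdir / "simulate"
    sim_dir.mkdir(exist_ok=True)
    syn = config.synthetic
    experiment = simulate_experiment(
        n_species=syn.n_species,
        dirichlet_alpha=syn.dirichlet_alpha,
        depth=syn.depth,
        proteins_per_species=syn.proteins_per_species,
        shared_peptide_rate=syn.shared_peptide_rate,
        diet_effect_sigma=syn.diet_effect_sigma,
        group_effect_sigma=syn.group_effect_sigma,
        noise_sigma=syn.noise_sigma,
        design=ExperimentDesign(n_mice=syn.n_mice),
        fractions=ContaminationFractions(
            host=syn.host_fraction,
            diet=syn.diet_fraction,
            lowq=syn.lowq_fraction,
            unbinned=syn.unbinned_fraction,
        ),
        seed=config.seed,
    )
    database = experiment.database
    db_path = sim_dir / "database.fasta"
    database.to_fasta(db_path)
    psm_path = sim_dir / "psms.tsv"
    write_psm_tsv(experiment.psm_tables, psm_path)
    meta_path = sim_dir / "metadata.tsv"
    experiment.metadata.to_csv(meta_path, sep="\t", index=False)
    truth = experiment.sample_fractions.copy()
    _write_tsv(truth, sim_dir / "true_fractions.tsv")
    vocab = load_enzyme_vocab()
    annotations = generate_annotations(
        experiment.catalog,
        vocab,
        pul_species=experiment.community.species_ids[0],
        seed=config.seed + 1,
    )
    ann_path = sim_dir / "annotations.tsv"
    annotations.to_csv(ann_path, sep="\t", index=False)
    outputs += [db_path, psm_path, meta_path, sim_dir / "true_fractions.tsv", ann_path]
    logger.info("simulate: %d samples, %d proteins", len(experiment.metadata), len(database))

    # --- quantify -------------------------------------------------------
    quant_dir = outdir / "quantify"
    quant_dir.mkdir(exist_ok=True)
    for stage, path in (("quantify", psm_path), ("quantify", db_path)):
        if not path.exists():
            raise FileNotFoundError(f"stage {stage}: missing input {path}")
    psms = read_psm_tsv(psm_path)
    db = ProteinDatabase.from_fasta(db_path)
    filtered = filter_psms(psms, config.thresholds.fdr)
    quant = count_spectra(filtered, db)
    _write_tsv(quant.table, quant_dir / "protein_quant.tsv", index=False)
    _write_tsv(
        quant.study_unique_peptides.rename("n_unique_peptides").to_frame(),
        quant_dir / "study_unique_peptides.tsv",
    )
    outputs += [quant_dir / "protein_quant.tsv", quant_dir / "study_unique_peptides.tsv"]
    logger.info(
        "quantify: %d/%d PSMs retained at FDR %.2f",
        len(filtered),
        int((~psms["is_decoy"]).sum()),
        config.thresholds.fdr,
    )

    # --- biomass --------------------------------------------------------
    bio_dir = outdir / "biomass"
    bio_dir.mkdir(exist_ok=True)
    profile = quantify_biomass(
        quant, db, min_unique_peptides=config.thresholds.biomass_min_unique
    )
    _write_tsv(profile.species_counts, bio_dir / "species_counts.tsv")
    _write_tsv(profile.percent, bio_dir / "species_percent.tsv")
    _write_tsv(profile.partition_counts, bio_dir / "partition_counts.tsv")
    _write_tsv(microbe_host_ratio(profile).to_frame(), bio_dir / "microbe_host_ratio.tsv")
    _write_tsv(richness(profile).to_frame(), bio_dir / "richness.tsv")
    taxonomy = dict(
        zip(experiment.community.species_ids, experiment.community.class_labels)
    )
    _write_tsv(class_rollup(profile, taxonomy), bio_dir / "class_counts.tsv")
    abundant = abundant_species(profile, config.thresholds.abundant_pct)
    (bio_dir / "abundant_species.txt").write_text("\n".join(abundant) + "\n")
    outputs += [
        bio_dir / p
        for p in (
            "species_counts.tsv",
            "species_percent.tsv",
            "partition_counts.tsv",
            "microbe_host_ratio.tsv",
            "richness.tsv",
            "class_counts.tsv",
            "abundant_species.txt",
        )
    ]

    # --- diversity ------------------------------------------------------
    div_dir = outdir / "diversity"
    div_dir.mkdir(exist_ok=True)
    _write_tsv(shannon_index(profile.percent).to_frame(), div_dir / "shannon.tsv")
    dm = bray_curtis(profile.percent.fillna(0.0))
    _write_tsv(dm, div_dir / "bray_curtis.tsv")
    meta = experiment.metadata.set_index("sample_id")
    factors = meta.loc[list(dm.index), list(config.permanova_factors)]
    result = permanova(
        dm, factors, n_permutations=config.n_permutations, seed=config.seed + 2
    )
    perm_table = result.table.reset_index(names="Factor")
    _write_tsv(perm_table, div_dir / "permanova.tsv", index=False)
    pairwise = pairwise_permanova(
        dm,
        meta.loc[list(dm.index), "protein_source"],
        n_permutations=config.n_permutations,
        seed=config.seed + 3,
    )
    _write_tsv(pairwise, div_dir / "pairwise_permanova.tsv", index=False)
    pca = clr_pca(profile.percent.fillna(0.0))
    _write_tsv(pca.scores, div_dir / "clr_pca_scores.tsv")
    if abundant:
        ward = ward_cluster(profile.percent.fillna(0.0).loc[abundant].T)
        (div_dir / "samples_ward.nwk").write_text(ward.newick + "\n")
        outputs.append(div_dir / "samples_ward.nwk")
    outputs += [
        div_dir / p
        for p in (
            "shannon.tsv",
            "bray_curtis.tsv",
            "permanova.tsv",
            "pairwise_permanova.tsv",
            "clr_pca_scores.tsv",
        )
    ]

    # --- functions ------------------------------------------------------
    fun_dir = outdir / "functions"
    fun_dir.mkdir(exist_ok=True)
    tool_cols = [c for c in annotations.columns if c.startswith("tool_")]
    resolved = consensus_annotate(
        annotations.set_index("accession")[tool_cols],
        annotations.set_index("accession")["manual_label"],
    )
    final_ann = annotations.set_index("accession").copy()
    final_ann["label"] = resolved["label"]
    final_ann["tier"] = resolved["tier"]
    labeled = final_ann.loc[final_ann["label"].notna()]
    vocab_map = vocab.set_index("enzyme_name")
    for col in ("broad_category", "detailed_category", "gh_family"):
        final_ann.loc[labeled.index, col] = (
            vocab_map[col].reindex(labeled["label"]).to_numpy()
        )
    final_ann.loc[final_ann["label"].isna(), ["broad_category", "detailed_category", "gh_family"]] = None
    final_ann["enzyme_name"] = final_ann["label"]

    nsaf_matrix = nsaf(quant, db)
    _write_tsv(nsaf_matrix, fun_dir / "nsaf_protein.tsv")
    for level in ("broad", "detailed", "enzyme", "gh_family", "pul"):
        _write_tsv(rollup(nsaf_matrix, final_ann, level), fun_dir / f"nsaf_{level}.tsv")
    aa_map = load_aa_pathway_map()
    _write_tsv(
        amino_acid_class_rollup(nsaf_matrix, final_ann, aa_map),
        fun_dir / "nsaf_aa_pathways.tsv",
    )
    _write_tsv(
        ammonia_producing_panel(nsaf_matrix, final_ann, aa_map).to_frame(),
        fun_dir / "ammonia_panel.tsv",
    )
    _write_tsv(
        annotated_mass_fraction(nsaf_matrix, final_ann).to_frame(),
        fun_dir / "annotated_mass.tsv",
    )
    outputs += [fun_dir / "nsaf_protein.tsv", fun_dir / "nsaf_broad.tsv",
                fun_dir / "nsaf_detailed.tsv", fun_dir / "nsaf_enzyme.tsv",
                fun_dir / "nsaf_gh_family.tsv", fun_dir / "nsaf_pul.tsv",
                fun_dir / "nsaf_aa_pathways.tsv", fun_dir / "ammonia_panel.tsv",
                fun_dir / "annotated_mass.tsv"]

    # --- stats ----------------------------------------------------------
    stat_dir = outdir / "stats"
    stat_dir.mkdir(exist_ok=True)
    broad = rollup(nsaf_matrix, final_ann, "broad")
    stats_df, means_df = fit_feature_lmm(broad, experiment.metadata)
    _write_tsv(stats_df, stat_dir / "broad_category_lmm.tsv")
    _write_tsv(means_df, stat_dir / "broad_category_means.tsv", index=False)

    # Yeast vs egg within-species comparison for the focal organism.
    focal = experiment.community.species_ids[0]
    try:
        org = org_nsaf(quant, db, focal)
    except ValueError:
        org = None
    if org is not None:
        yeast = [s for s in org.columns if meta.loc[s, "protein_source"] == "yeast"]
        egg = [s for s in org.columns if meta.loc[s, "protein_source"] == "egg"]
        if len(yeast) >= 2 and len(egg) >= 2:
            volcano = differential_features(
                org[egg], org[yeast], q_threshold=config.thresholds.q_threshold
            )
            _write_tsv(volcano, stat_dir / "focal_species_egg_vs_yeast.tsv")
            outputs.append(stat_dir / "focal_species_egg_vs_yeast.tsv")
    outputs += [stat_dir / "broad_category_lmm.tsv", stat_dir / "broad_category_means.tsv"]

    # --- manifest -------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "fdr": config.thresholds.fdr,
            "biomass_min_unique": config.thresholds.biomass_min_unique,
            "abundant_pct": config.thresholds.abundant_pct,
            "q_threshold": config.thresholds.q_threshold,
        },
        "n_permutations": config.n_permutations,
        "checksums": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(outputs))
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
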