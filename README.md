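# metaprot

Integrated metagenomics–metaproteomics quantification of gut microbiota
composition and function.

`metaprot` is for microbiome researchers who measure a community by
shotgun metaproteomics against a genome-resolved metagenomic database
and want a tested, reproducible implementation of the downstream
quantification: taxon-coded database assembly, target-decoy FDR
filtering of peptide-spectrum matches (PSMs), species *proteinaceous
biomass* estimation, diversity statistics with PERMANOVA, NSAF%
functional profiles, and per-feature mixed-effects inference.  A
first-class synthetic-data generator reproduces the statistical
structure of such studies (multinomial PSM sampling, shared peptides,
host/diet contamination, decoy scores), so the entire pipeline is
testable without any raw mass-spectrometry data.

## The quantities at the core

**Proteinaceous biomass.** Each protein in the search database carries
one taxon code (a species group from 95%-ANI MAG clustering, or
`AMBIGUOUS` / `LOWQ` / `UNBINNED` / `HOST` / `DIET`).  After filtering
PSMs at 5% FDR by target-decoy competition,

```
FDR(s) = #decoys(score ≥ s) / max(1, #targets(score ≥ s)),
q = monotone envelope of FDR over score,
```

proteins with ≥ 2 protein-unique peptides have their spectral counts
summed into their taxon.  A species' biomass percent is its share of
the summed species-assigned counts; the microbe:host ratio is
(species + ambiguous + low-quality + unbinned) / host counts.

**NSAF%.** The normalized spectral abundance factor of protein *i* with
count *c* and length *L* is `NSAF%_i = 100 · (c_i/L_i) / Σ_j (c_j/L_j)`
over microbial proteins; `orgNSAF` restricts numerator and denominator
to one organism.  Category, glycoside-hydrolase-family and
polysaccharide-utilization-locus (PUL) abundances are sums of member
NSAF%.

**Statistics.** Bray–Curtis dissimilarities are partitioned by a
sequential (Type-I) PERMANOVA implemented here from the Gower-centered
matrix, with permutation p-values `(b+1)/(m+1)`.  Per-feature inference
uses `value ~ group * diet + (1 | mouse)` mixed models (REML,
sum-to-zero contrasts) with per-diet marginal means and 95% CIs, Welch
t-tests with log₂ fold-changes for two-condition comparisons, and
Benjamini–Hochberg q-values throughout.

## Worked example

```python
import pandas as pd
from metaprot import synthetic_data as sd
from metaprot.psm_processing import filter_psms, count_spectra
from metaprot.biomass_profiler import quantify_biomass, microbe_host_ratio, abundant_species
from metaprot.diversity import shannon_index, bray_curtis, permanova

exp = sd.simulate_experiment(n_species=20, depth=2000, proteins_per_species=8,
                             design=sd.ExperimentDesign(n_mice=6), seed=42)
psms = pd.concat(exp.psm_tables, ignore_index=True)
quant = count_spectra(filter_psms(psms, 0.05), exp.database)
profile = quantify_biomass(quant, exp.database)
dm = bray_curtis(profile.percent.fillna(0))
meta = exp.metadata.set_index("sample_id")
factors = meta.loc[list(dm.index),
                   ["protein_source", "protein_amount", "mouse_group", "mouse_age"]]
print(permanova(dm, factors, n_permutations=999, seed=1).table.round(3))
```

prints

```
                df  SumOfSqs     R2        F      P
protein_source   5     1.842  0.350   16.529  0.001
protein_amount   1     0.008  0.002    0.359  0.829
mouse_group      1     2.539  0.482  113.921  0.001
mouse_age        1     0.011  0.002    0.489  0.706
Residual        39     0.869  0.165      NaN    NaN
Total           47     5.268  1.000      NaN    NaN
```

i.e. in this simulated feeding study the protein source and the mouse
group explain most of the between-sample variance in community
composition (R² = 0.35 and 0.48, both p = 0.001 from 999 label
permutations), while the amount of protein and mouse age explain
essentially none — the factor table one would report for a real study.
The same run gives 20 quantified species across 48 samples, a median
microbe:host ratio of 3.45, 11 abundant species (≥ 5% of species
biomass in ≥ 1 sample) and Shannon indices between 1.24 and 2.39 nats.

A full run (`metaprot run-all --seed 1 --out run/`) chains
simulate → quantify → biomass → diversity → functions → stats and
writes TSV/FASTA/Newick artifacts plus a SHA-256 manifest; re-running
with the same configuration reproduces identical checksums.  Each stage
is also exposed individually (`metaprot simulate | build-db | quantify |
biomass | diversity | functions | stats`).

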