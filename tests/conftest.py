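import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from metaprot import synthetic_data as sd  # noqa: E402
from metaprot.database_builder import ProteinDatabase, ProteinRecord  # noqa: E402


@pytest.fixture(scope="session")
def small_community():
    return sd.generate_community(6, dirichlet_alpha=0.8, seed=11)


@pytest.fixture(scope="session")
def small_catalog(small_community):
    return sd.generate_protein_catalog(
        small_community, proteins_per_species=4, shared_peptide_rate=0.1, seed=12
    )


@pytest.fixture(scope="session")
def small_psms(small_community, small_catalog):
    _, catalog = small_catalog
    return sd.simulate_psm_table(
        small_community, catalog, depth=4000, n_samples=2, seed=13
    )


@pytest.fixture()
def toy_database():
    """Three proteins, two species, one peptide shared between B and C.

    A (S1) = AAAAAAK + CCCCCCR        (two unique peptides)
    B (S1) = DDDDDDK + EEEEEER        (one unique + one shared)
    C (S2) = FFFFFFK + EEEEEER        (one unique + one shared)
    """
    return ProteinDatabase(
        (
            ProteinRecord("A", "AAAAAAKCCCCCCR", "S1"),
            ProteinRecord("B", "DDDDDDKEEEEEER", "S1"),
            ProteinRecord("C", "FFFFFFKEEEEEER", "S2"),
        )
    )


def make_psm_frame(rows):
    """Build a PSM table from (peptide, score, is_decoy, protein_ids) rows."""
    return pd.DataFrame(
        {
            "sample_id": "s1",
            "spectrum_id": [f"s1:{i}" for i in range(len(rows))],
            "peptide": [r[0] for r in rows],
            "score": [float(r[1]) for r in rows],
            "is_decoy": [bool(r[2]) for r in rows],
            "protein_ids": [r[3] for r in rows],
        }
    )


@pytest.fixture()
def psm_builder():
    return make_psm_frame
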