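"""NSAF normalization, annotation consensus, category rollups."""

import numpy as np
import pandas as pd
import pytest

from metaprot import functional_profiler as fp
from metaprot.database_builder import ProteinDatabase, ProteinRecord
from metaprot.psm_processing import ProteinQuant


def make_quant(rows):
    table = pd.DataFrame(
        rows,
        columns=["sample_id", "accession", "taxon_code", "spectral_count", "n_unique_peptides"],
    )
    unique = table.groupby("accession")["n_unique_peptides"].max()
    return ProteinQuant(table, unique)


def db_with_lengths(entries):
    """entries: (accession, taxon, length); sequences are poly-A of the
    requested length."""
    return ProteinDatabase(
        tuple(ProteinRecord(acc, "A" * length, code) for acc, code, length in entries)
    )


class TestNsaf:
    def test_single_protein_hundred_percent(self):
        quant = make_quant([("s1", "p1", "S1", 12, 2)])
        db = db_with_lengths([("p1", "S1", 200)])
        out = fp.nsaf(quant, db)
        assert out.loc["p1", "s1"] == pytest.approx(100.0, abs=1e-9)

    def test_length_normalization_worked_pair(self):
        quant = make_quant([("s1", "p1", "S1", 10, 2), ("s1", "p2", "S1", 10, 2)])
        db = db_with_lengths([("p1", "S1", 100), ("p2", "S1", 200)])
        out = fp.nsaf(quant, db)
        assert out.loc["p1", "s1"] == pytest.approx(200 / 3, abs=1e-9)
        assert out.loc["p2", "s1"] == pytest.approx(100 / 3, abs=1e-9)

    def test_host_proteins_change_nothing(self):
        rows = [("s1", "p1", "S1", 10, 2), ("s1", "p2", "S2", 30, 2)]
        db = db_with_lengths([("p1", "S1", 100), ("p2", "S2", 100), ("ph", "HOST", 50)])
        base = fp.nsaf(make_quant(rows), db)
        with_host = fp.nsaf(make_quant(rows + [("s1", "ph", "HOST", 500, 2)]), db)
        pd.testing.assert_frame_equal(base, with_host.loc[base.index])
        assert "ph" not in with_host.index

    def test_columns_sum_to_hundred(self):
        rng = np.random.default_rng(0)
        rows = [
            ("s1", f"p{i}", "S1", int(rng.integers(1, 50)), 2) for i in range(20)
        ] + [("s2", f"p{i}", "S1", int(rng.integers(1, 50)), 2) for i in range(20)]
        db = db_with_lengths(
            [(f"p{i}", "S1", int(rng.integers(50, 500))) for i in range(20)]
        )
        out = fp.nsaf(make_quant(rows), db)
        assert np.allclose(out.sum(), 100.0, atol=1e-9)

    def test_doubling_lengths_invariant(self):
        rows = [("s1", "p1", "S1", 10, 2), ("s1", "p2", "S1", 7, 2)]
        db1 = db_with_lengths([("p1", "S1", 100), ("p2", "S1", 300)])
        db2 = db_with_lengths([("p1", "S1", 200), ("p2", "S1", 600)])
        pd.testing.assert_frame_equal(
            fp.nsaf(make_quant(rows), db1), fp.nsaf(make_quant(rows), db2)
        )


class TestOrgNsaf:
    def test_single_protein_species(self):
        quant = make_quant([("s1", "p1", "S1", 5, 2), ("s1", "p2", "S2", 50, 2)])
        db = db_with_lengths([("p1", "S1", 100), ("p2", "S2", 100)])
        out = fp.org_nsaf(quant, db, "S1")
        assert list(out.index) == ["p1"]
        assert out.loc["p1", "s1"] == pytest.approx(100.0)

    def test_profile_invariant_to_other_species(self):
        base = [("s1", "p1", "S1", 5, 2), ("s1", "p1b", "S1", 15, 2)]
        other = [("s1", "p2", "S2", 7, 2)]
        perturbed = [("s1", "p2", "S2", 700, 2)]
        db = db_with_lengths(
            [("p1", "S1", 100), ("p1b", "S1", 300), ("p2", "S2", 100)]
        )
        a = fp.org_nsaf(make_quant(base + other), db, "S1")
        b = fp.org_nsaf(make_quant(base + perturbed), db, "S1")
        pd.testing.assert_frame_equal(a, b)

    def test_columns_sum_to_hundred_per_sample(self):
        rows = [
            ("s1", "p1", "S1", 5, 2), ("s1", "p1b", "S1", 9, 2),
            ("s2", "p1", "S1", 2, 2),
        ]
        db = db_with_lengths([("p1", "S1", 100), ("p1b", "S1", 250)])
        out = fp.org_nsaf(make_quant(rows), db, "S1")
        sums = out.sum()
        assert sums["s1"] == pytest.approx(100.0)
        assert sums["s2"] == pytest.approx(100.0)

    def test_absent_species_rejected(self):
        quant = make_quant([("s1", "p1", "S1", 5, 2)])
        db = db_with_lengths([("p1", "S1", 100)])
        with pytest.raises(ValueError, match="S9"):
            fp.org_nsaf(quant, db, "S9")


class TestConsensusAnnotate:
    def _tools(self, rows):
        return pd.DataFrame(rows).set_index("accession")

    def test_manual_then_extrapolated(self):
        tools = self._tools(
            [
                {"accession": "X", "t1": "urease", "t2": "urease"},
                {"accession": "Y", "t1": "urease", "t2": "urease"},
            ]
        )
        out = fp.consensus_annotate(tools, {"X": "urease"})
        assert out.loc["X"].tolist() == ["urease", fp.MANUAL]
        assert out.loc["Y"].tolist() == ["urease", fp.EXTRAPOLATED]

    def test_disagreement_without_anchor_unannotated(self):
        tools = self._tools([{"accession": "Z", "t1": "urease", "t2": "enolase"}])
        out = fp.consensus_annotate(tools)
        assert out.loc["Z", "tier"] == fp.UNANNOTATED
        assert out.loc["Z", "label"] is None

    def test_three_tool_agreement_consensus(self):
        tools = self._tools(
            [{"accession": "W", "t1": "chitinase", "t2": "chitinase", "t3": "chitinase"}]
        )
        out = fp.consensus_annotate(tools)
        assert out.loc["W"].tolist() == ["chitinase", fp.CONSENSUS]

    def test_partial_tool_dropout_still_consensus(self):
        tools = self._tools([{"accession": "V", "t1": None, "t2": "enolase", "t3": "enolase"}])
        out = fp.consensus_annotate(tools)
        assert out.loc["V", "tier"] == fp.CONSENSUS

    def test_conflicting_manual_labels_rejected(self):
        tools = self._tools([{"accession": "X", "t1": "urease"}])
        manual = pd.Series(["urease", "enolase"], index=["X", "X"])
        with pytest.raises(ValueError, match="X"):
            fp.consensus_annotate(tools, manual)


class TestRollup:
    def _nsaf(self):
        return pd.DataFrame(
            {"s1": [40.0, 30.0, 20.0, 10.0], "s2": [10.0, 20.0, 30.0, 40.0]},
            index=["p1", "p2", "p3", "p4"],
        )

    def _annotations(self):
        return pd.DataFrame(
            {
                "accession": ["p1", "p2", "p3"],
                "broad_category": ["amino acid metabolism", "amino acid metabolism", "glycan degradation"],
                "detailed_category": ["urea hydrolysis", "tryptophan degradation", "mannan degradation"],
                "enzyme_name": ["urease", "tryptophanase", "alpha-mannosidase"],
                "gh_family": [None, None, "GH92"],
                "pul_id": [None, None, "PUL68"],
            }
        ).set_index("accession")

    def test_single_category_sums_to_hundred(self):
        nsaf = self._nsaf()
        ann = self._annotations()
        ann["broad_category"] = "amino acid metabolism"
        ann = pd.concat(
            [ann, pd.DataFrame({"broad_category": ["amino acid metabolism"]}, index=["p4"])]
        )
        out = fp.rollup(nsaf, ann, "broad")
        assert out.loc["amino acid metabolism", "s1"] == pytest.approx(100.0)

    def test_hand_summed_member_abundance(self):
        out = fp.rollup(self._nsaf(), self._annotations(), "broad")
        assert out.loc["amino acid metabolism", "s1"] == pytest.approx(70.0)
        assert out.loc["glycan degradation", "s1"] == pytest.approx(20.0)
        assert out.loc[fp.UNANNOTATED, "s1"] == pytest.approx(10.0)

    def test_unannotated_mass_conserves_total(self):
        out = fp.rollup(self._nsaf(), self._annotations(), "gh_family")
        assert np.allclose(out.sum(), 100.0, atol=1e-9)
        assert out.loc["GH92", "s2"] == pytest.approx(30.0)

    def test_annotated_mass_fraction(self):
        frac = fp.annotated_mass_fraction(self._nsaf(), self._annotations())
        assert frac["s1"] == pytest.approx(90.0)
        assert frac["s2"] == pytest.approx(60.0)

    def test_duplicate_pul_membership_rejected(self):
        ann = pd.DataFrame(
            {
                "accession": ["p1", "p1"],
                "pul_id": ["PUL1", "PUL2"],
            }
        )
        with pytest.raises(ValueError, match="p1"):
            fp.rollup(self._nsaf(), ann, "pul")


class TestAminoAcidRollup:
    def _setup(self):
        nsaf = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0, 94.0]},
            index=["p1", "p2", "p3", "p4"],
        )
        ann = pd.DataFrame(
            {
                "accession": ["p1", "p2", "p3"],
                "enzyme_name": ["urease", "tryptophanase", "glutamine synthetase"],
            }
        ).set_index("accession")
        aa_map = pd.DataFrame(
            {
                "enzyme_name": ["urease", "tryptophanase", "glutamine synthetase"],
                "amino_acid": ["arginine", "tryptophan", "glutamine"],
                "direction": ["degradation", "degradation", "synthesis"],
                "ammonia_product": [True, True, False],
            }
        )
        return nsaf, ann, aa_map

    def test_degradation_sum_arithmetic(self):
        nsaf, ann, aa_map = self._setup()
        out = fp.amino_acid_class_rollup(nsaf, ann, aa_map)
        assert out.loc[("degradation", "arginine"), "s1"] == pytest.approx(1.0)
        assert out.xs("degradation", level="direction")["s1"].sum() == pytest.approx(3.0)

    def test_synthesis_only_map_gives_zero_degradation(self):
        nsaf, ann, aa_map = self._setup()
        synth_only = aa_map[aa_map.direction == "synthesis"]
        out = fp.amino_acid_class_rollup(nsaf, ann, synth_only)
        assert "degradation" not in out.index.get_level_values("direction")

    def test_unknown_direction_rejected(self):
        nsaf, ann, aa_map = self._setup()
        aa_map.loc[0, "direction"] = "sideways"
        with pytest.raises(ValueError, match="sideways"):
            fp.amino_acid_class_rollup(nsaf, ann, aa_map)

    def test_ammonia_panel_includes_degrading_producers_only(self):
        nsaf, ann, aa_map = self._setup()
        panel = fp.ammonia_producing_panel(nsaf, ann, aa_map)
        assert panel["s1"] == pytest.approx(3.0)  # urease + tryptophanase

    def test_urease_panel_sums_urease_only(self):
        nsaf, ann, aa_map = self._setup()
        panel = fp.enzyme_panel(nsaf, ann, "urease")
        assert panel["s1"] == pytest.approx(1.0)

    def test_shipped_vocab_loads(self):
        vocab = fp.load_enzyme_vocab()
        aa_map = fp.load_aa_pathway_map()
        assert {"enzyme_name", "broad_category"} <= set(vocab.columns)
        assert set(aa_map["direction"]) <= set(fp.DIRECTIONS)
        assert "urease" in set(aa_map["enzyme_name"])
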