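"""Structural mutual-exclusivity: superposition, filters, classification."""

import numpy as np
import pandas as pd
import pytest

import complexkit as ck
from complexkit.simulate import DimerSpec, random_rigid_transform, simulate_dimer_models
from complexkit.structure import Atom, Chain, Residue, StructuralModel, pdockq_from_model


def make_chain(acc, chain_id, ca_positions, plddt=85.0):
    residues = [
        Residue(i + 1, "ALA", [Atom("CA", "C", np.asarray(p, dtype=float))], plddt)
        for i, p in enumerate(ca_positions)
    ]
    return Chain(acc, chain_id, residues)


def helical(n, spacing=3.8):
    i = np.arange(n)
    return np.column_stack([i * spacing, np.sin(i), np.cos(i)])


def two_chain_model(model_id, acc1, acc2, pos1, pos2, pdockq=0.5, if_plddt=85.0):
    return StructuralModel(
        model_id,
        [make_chain(acc1, "A", pos1), make_chain(acc2, "B", pos2)],
        pdockq=pdockq,
        if_plddt=if_plddt,
    )


class TestSuperposition:
    def test_identity_superposition_is_exact(self):
        common = helical(25)
        m = two_chain_model("m", "C1", "U1", common, common + [0, 5, 0])
        moved, fit = ck.superpose_on_common(m, m, "C1")
        assert fit.rmsd < 1e-9
        assert fit.n_matched == 25

    def test_recovers_applied_rigid_transform(self):
        rng = np.random.default_rng(5)
        common = helical(30)
        m1 = two_chain_model("m1", "C1", "U1", common, common + [0, 5, 0])
        R, t = random_rigid_transform(rng)
        m2 = m1.transformed(R, t)
        moved, fit = ck.superpose_on_common(m1, m2, "C1")
        assert fit.rmsd < 1e-6
        # recovered transform inverts the applied one
        assert np.allclose(fit.rotation @ R, np.eye(3), atol=1e-8)
        for ch_m, ch_o in zip(moved.chains, m1.chains):
            for rm, ro in zip(ch_m.residues, ch_o.residues):
                assert np.allclose(rm.atoms[0].xyz, ro.atoms[0].xyz, atol=1e-6)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(8)
        common = helical(30)
        m1 = two_chain_model("m1", "C1", "U1", common, common + [0, 5, 0])
        for _ in range(5):
            R, t = random_rigid_transform(rng)
            _, fit = ck.superpose_on_common(m1, m1.transformed(R, t), "C1")
            assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-9)
            assert np.allclose(fit.rotation @ fit.rotation.T, np.eye(3), atol=1e-9)

    def test_too_few_matches_errors(self):
        common = helical(10)
        m = two_chain_model("m", "C1", "U1", common, common + [0, 5, 0])
        with pytest.raises(ValueError, match="insufficient alignment"):
            ck.superpose_on_common(m, m, "C1")

    def test_missing_common_chain_errors(self):
        common = helical(25)
        m = two_chain_model("m", "C1", "U1", common, common + [0, 5, 0])
        with pytest.raises(KeyError):
            ck.superpose_on_common(m, m, "NOPE")


class TestFilters:
    def good_model(self):
        common = helical(25)
        return two_chain_model("m", "C1", "U1", common, common + [0, 3.5, 0],
                               pdockq=0.25, if_plddt=75.0)

    def test_passing_model_retained(self):
        assert ck.filter_models([self.good_model()]) != []

    def test_pdockq_boundary_is_strict(self):
        m = self.good_model()
        m.pdockq = 0.23
        assert ck.filter_models([m]) == []
        m.pdockq = 0.231
        assert ck.filter_models([m]) != []

    def test_if_plddt_boundary_is_strict(self):
        m = self.good_model()
        m.if_plddt = 70.0
        assert ck.filter_models([m]) == []

    def test_clash_count_boundary(self):
        common = np.column_stack([np.arange(25) * 3.8, np.zeros(25), np.zeros(25)])
        # place k unique residues within 2.0 Å of the common chain
        def model_with_clashes(k):
            pos = np.column_stack([np.arange(12) * 3.8, np.full(12, 5.0), np.zeros(12)])
            pos[:k, 1] = 1.5  # within the 2.0 Å clash distance
            return two_chain_model("m", "C1", "U1", common, pos, pdockq=0.5, if_plddt=85)

        # each clashing unique residue also marks one common residue: count = 2k
        m2 = model_with_clashes(2)  # 4 clashing residues < 5: retained
        assert ck.count_clashing_residues(m2) == 4
        assert ck.filter_models([m2]) != []
        m3 = model_with_clashes(3)  # 6 >= 5: excluded
        assert ck.count_clashing_residues(m3) == 6
        assert ck.filter_models([m3]) == []

    def test_pdockq_computed_when_metadata_absent(self):
        m = self.good_model()
        m.pdockq = None
        m.if_plddt = None
        pdq, ifp = pdockq_from_model(m)
        assert 0.018 <= pdq <= 0.742
        assert 0 <= ifp <= 100


def overlapping_pair(offset=(0.0, 0.0, 1.0)):
    """Two models whose unique chains dock over the same common segment."""
    common = helical(30)
    dock = common[8:20] + np.array([0.0, 3.0, 0.0])
    m1 = two_chain_model("m1", "C0", "UA", common, dock)
    m2 = two_chain_model("m2", "C0", "UB", common, dock + np.asarray(offset))
    return m1, m2


def disjoint_pair():
    common = helical(30)
    m1 = two_chain_model("m1", "C0", "UA", common, common[8:20] + [0, 3.0, 0])
    m2 = two_chain_model("m2", "C0", "UB", common, common[8:20] + [0, -3.0, 0])
    return m1, m2


class TestClassification:
    def test_overlapping_interfaces_called_exclusive(self):
        call = ck.classify_pair(*overlapping_pair(), "C0")
        assert call.label == "mutually_exclusive"
        assert call.overlap_interface_residues > 10

    def test_opposite_faces_called_consistent(self):
        call = ck.classify_pair(*disjoint_pair(), "C0")
        assert call.label == "structurally_consistent"
        assert call.overlap_interface_residues == 0

    def test_band_boundaries(self):
        # brute-force the overlap count from raw coordinates as an oracle
        m1, m2 = overlapping_pair()
        call = ck.classify_pair(m1, m2, "C0", superpose=False)
        u1 = m1.other_chain("C0")
        u2 = m2.other_chain("C0")
        c1 = m1.chain_for("C0")
        if1 = {
            i for i, r in enumerate(u1.residues)
            if any(np.linalg.norm(a.xyz - b.xyz) <= 4.0
                   for a in r.atoms for rr in c1.residues for b in rr.atoms)
        }
        assert if1  # interfaces exist by construction
        assert call.overlap_interface_residues > 10

    def test_overlap_count_ten_is_inconclusive(self):
        # exactly 10 overlapping interface residues falls in the (0, 10] band
        common = np.column_stack([np.arange(30) * 3.8, np.sin(np.arange(30)), np.cos(np.arange(30))])
        dock = common[8:20] + np.array([0.0, 3.0, 0.0])
        other = dock.copy() + np.array([0.0, 0.0, 1.0])
        other[5:, 2] += 50.0  # only first 5 residues of each chain overlap -> count 10
        m1 = two_chain_model("m1", "C0", "UA", common, dock)
        m2 = two_chain_model("m2", "C0", "UB", common, other)
        call = ck.classify_pair(m1, m2, "C0", superpose=False)
        assert call.overlap_interface_residues == 10
        assert call.label == "inconclusive"

    def test_zero_interface_overlap_but_massive_clash_excluded(self):
        # unique chains overlap far from the common subunit: excluded when > 100
        common = helical(30)
        far = np.column_stack(
            [np.arange(150) * 1.0, np.full(150, 500.0), np.zeros(150)]
        )
        m1 = StructuralModel("m1", [make_chain("C0", "A", common), make_chain("UA", "B", far)])
        m2 = StructuralModel("m2", [make_chain("C0", "A", common), make_chain("UB", "B", far + [0, 0, 1.0])])
        call = ck.classify_pair(m1, m2, "C0", superpose=False)
        assert call.overlap_interface_residues == 0
        assert call.overlap_total_residues > 100
        assert call.label == "excluded"

    def test_symmetric_in_model_order(self):
        m1, m2 = overlapping_pair()
        a = ck.classify_pair(m1, m2, "C0")
        b = ck.classify_pair(m2, m1, "C0")
        assert a.label == b.label
        assert a.pair == b.pair
        assert a.overlap_interface_residues == b.overlap_interface_residues

    def test_invariant_under_rigid_pretransform(self):
        rng = np.random.default_rng(13)
        m1, m2 = overlapping_pair()
        base = ck.classify_pair(m1, m2, "C0")
        R, t = random_rigid_transform(rng)
        moved = ck.classify_pair(m1, m2.transformed(R, t), "C0")
        assert moved.label == base.label
        assert moved.overlap_interface_residues == base.overlap_interface_residues

    def test_same_unique_protein_errors(self):
        common = helical(30)
        m1 = two_chain_model("m1", "C0", "UA", common, common[8:20] + [0, 3, 0])
        with pytest.raises(ValueError, match="not a pair"):
            ck.classify_pair(m1, m1, "C0")


class TestAnnotatePairs:
    def test_joins(self):
        call = ck.classify_pair(*disjoint_pair(), "C0")
        rna = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0]],
            index=["UA", "UB"],
            columns=["t1", "t2", "t3", "t4"],
        )
        table = ck.annotate_pairs(
            [call],
            ortholog_groups={"UA": "KOG1234", "UB": "KOG1234"},
            covariation={("UA", "UB"): 0.87},
            rna_matrix=rna,
            localization={"UA": {"nucleus", "cytosol"}, "UB": {"nucleus", "cytosol"}},
        )
        row = table.iloc[0]
        assert row["paralog"] == True  # noqa: E712
        assert row["covariation"] == pytest.approx(0.87)
        assert row["ntpm_pearson"] == pytest.approx(1.0)
        assert row["localization_jaccard"] == pytest.approx(1.0)

    def test_missing_lookups_yield_nan(self):
        call = ck.classify_pair(*disjoint_pair(), "C0")
        table = ck.annotate_pairs([call])
        row = table.iloc[0]
        assert np.isnan(row["covariation"]) and np.isnan(row["ntpm_pearson"])


class TestGeneratedSuite:
    def test_all_hundred_calls_correct(self, dimer_fixture):
        instances, truth = dimer_fixture
        for (m1, m2, common), row in zip(instances, truth.itertuples()):
            call = ck.classify_pair(m1, m2, common)
            assert call.label == row.planted_label

    def test_generated_models_pass_quality_filters(self, dimer_fixture):
        instances, _ = dimer_fixture
        models = [m for inst in instances for m in inst[:2]]
        assert len(ck.filter_models(models)) == len(models)


def test_pdb_round_trip(tmp_path, dimer_fixture):
    instances, _ = dimer_fixture
    model = instances[0][0]
    path = tmp_path / f"{model.model_id}.pdb"
    ck.write_model(model, path)
    back = ck.read_model(path)
    assert [c.accession for c in back.chains] == [c.accession for c in model.chains]
    for cb, cm in zip(back.chains, model.chains):
        assert len(cb.residues) == len(cm.residues)
        for rb, rm in zip(cb.residues, cm.residues):
            assert np.allclose(rb.atoms[0].xyz, rm.atoms[0].xyz, atol=1e-3)
            assert rb.plddt == pytest.approx(rm.plddt, abs=0.01)
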