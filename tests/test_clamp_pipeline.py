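"""Composite-model assembly, contact mapping and mutant reporting."""

import numpy as np
import pytest

from clampdna.clamp_pipeline import (
    AnchorError,
    basic_residue_inventory,
    build_composite_model,
    duplex_from_structure,
    find_contacts,
    mutation_set_report,
    replay_composite,
)
from clampdna.geometry import fit_helical_axis, ring_axis, tilt_angle
from clampdna.structio import Atom, Residue, Structure, select
from clampdna.synthetic_data import (
    SyntheticClampSpec,
    make_composite_fixture,
    make_synthetic_clamp,
    make_tilted_duplex,
)


@pytest.fixture(scope="module")
def fixture_pair():
    return make_composite_fixture(seed=3)


@pytest.fixture(scope="module")
def composite(fixture_pair):
    return build_composite_model(fixture_pair.loader_dna_complex,
                                 fixture_pair.loader_clamp_complex,
                                 ("V", "V"))


class TestCompositeBuild:
    def test_same_complex_identity_transfer(self):
        fx = make_composite_fixture(seed=5, identity_transforms=True)
        s = fx.loader_dna_complex
        model = build_composite_model(s, s, ("V", "V"))
        assert model.anchor_rmsd < 1e-9
        dna_in = select(s, "kind dna").coords(primary_only=False)
        np.testing.assert_allclose(
            model.duplex.atoms.coords(primary_only=False), dna_in, atol=1e-9)

    def test_ground_truth_placement_recovered(self, fixture_pair, composite):
        got = composite.duplex.atoms.coords(primary_only=False)
        want = fixture_pair.true_dna_in_clamp_frame.atoms.coords(
            primary_only=False)
        assert np.abs(got - want).max() < 1e-6

    def test_known_tilt_reproduced(self, fixture_pair, composite):
        meta = fixture_pair.loader_clamp_complex.metadata
        clamp = select(fixture_pair.loader_clamp_complex,
                       "chain " + ",".join(meta["clamp_chains"]))
        ax = ring_axis(clamp, meta["n_fold"])
        h = fit_helical_axis(composite.duplex.bp_centers)
        assert abs(tilt_angle(h, ax) - fixture_pair.true_tilt) < 0.5

    def test_deterministic_and_replayable(self, fixture_pair):
        a = build_composite_model(fixture_pair.loader_dna_complex,
                                  fixture_pair.loader_clamp_complex,
                                  ("V", "V"), extension_length=8)
        b = build_composite_model(fixture_pair.loader_dna_complex,
                                  fixture_pair.loader_clamp_complex,
                                  ("V", "V"), extension_length=8)
        assert np.array_equal(a.duplex.atoms.coords(primary_only=False),
                              b.duplex.atoms.coords(primary_only=False))
        c = replay_composite(a.log, fixture_pair.loader_dna_complex,
                             fixture_pair.loader_clamp_complex)
        assert np.array_equal(a.duplex.atoms.coords(primary_only=False),
                              c.duplex.atoms.coords(primary_only=False))
        assert a.log == c.log

    def test_extension_seam_continuity(self, fixture_pair):
        model = build_composite_model(fixture_pair.loader_dna_complex,
                                      fixture_pair.loader_clamp_complex,
                                      ("V", "V"), extension_length=12)
        spacing = np.linalg.norm(np.diff(model.duplex.bp_centers, axis=0),
                                 axis=1)
        rise = model.duplex.rise
        assert np.all(spacing > 0.85 * rise)
        assert np.all(spacing < 1.15 * rise)

    def test_missing_anchor_chain_rejected(self, fixture_pair):
        with pytest.raises(AnchorError, match="absent"):
            build_composite_model(fixture_pair.loader_dna_complex,
                                  fixture_pair.loader_clamp_complex,
                                  ("Z", "V"))

    def test_wrong_anchor_chain_large_rmsd_rejected(self, fixture_pair):
        # chains U and W are genuinely different pseudo-subunits
        with pytest.raises(AnchorError, match="rmsd"):
            build_composite_model(fixture_pair.loader_dna_complex,
                                  fixture_pair.loader_clamp_complex,
                                  ("U", "W"))


class TestDuplexFromStructure:
    def test_round_trip_of_built_duplex(self):
        from clampdna.dna_builder import build_bform_duplex
        d = build_bform_duplex("ACGTTGCAAC")
        d2 = duplex_from_structure(d.atoms)
        assert d2.duplex_seq1 == "ACGTTGCAAC"
        np.testing.assert_allclose(d2.bp_centers, d.bp_centers, atol=1e-9)

    def test_non_complementary_chains_rejected(self):
        from clampdna.dna_builder import build_bform_duplex
        d = build_bform_duplex("ACGTACGTAC")
        broken = d.atoms.copy()
        broken.chains["2"][0].name = "DA"   # falsify one base (was DG)
        with pytest.raises(ValueError):
            duplex_from_structure(broken)


def _two_atom_structures(distance):
    prot = Structure("p", {"A": [Residue("A", 1, "LYS", [
        Atom(1, "NZ", "N", np.zeros(3))])]})
    dna = Structure("d", {"1": [Residue("1", 1, "DA", [
        Atom(1, "P", "P", np.array([distance, 0.0, 0.0]))])]})
    return prot, dna


class TestContacts:
    def test_closed_interval_at_cutoff(self):
        prot, dna = _two_atom_structures(4.0)
        assert len(find_contacts(prot, dna, cutoff=4.0)) == 1
        prot, dna = _two_atom_structures(4.001)
        assert len(find_contacts(prot, dna, cutoff=4.0)) == 0

    def test_monotone_in_cutoff(self, ring3):
        d = make_tilted_duplex(ring3, tilt=20.0, offset=0.0, length=25, seed=2)
        small = find_contacts(ring3, d.atoms, cutoff=6.0)
        large = find_contacts(ring3, d.atoms, cutoff=12.0)
        assert len(large) >= len(small)
        key = ["protein_chain", "residue_number", "protein_atom",
               "dna_strand", "base_index", "dna_atom"]
        small_keys = set(map(tuple, small[key].itertuples(index=False)))
        large_keys = set(map(tuple, large[key].itertuples(index=False)))
        assert small_keys <= large_keys

    def test_swap_symmetry(self, ring3):
        d = make_tilted_duplex(ring3, tilt=20.0, offset=0.0, length=25, seed=2)
        ab = find_contacts(ring3, d.atoms, cutoff=8.0)
        ba = find_contacts(d.atoms, ring3, cutoff=8.0)
        assert len(ab) == len(ba)
        assert sorted(ab["distance"]) == pytest.approx(sorted(ba["distance"]))

    def test_phosphate_filter(self, ring3):
        d = make_tilted_duplex(ring3, tilt=20.0, offset=0.0, length=25, seed=2)
        table = find_contacts(ring3, d.atoms, cutoff=10.0,
                              dna_atom_filter="phosphate")
        assert set(table["dna_atom"]) <= {"P", "OP1", "OP2", "O5'", "O3'"}

    def test_sidechain_polar_filter_excludes_backbone(self):
        prot = Structure("p", {"A": [Residue("A", 1, "LYS", [
            Atom(1, "N", "N", np.zeros(3)),          # backbone amide
            Atom(2, "NZ", "N", np.array([0.5, 0, 0])),
            Atom(3, "CB", "C", np.array([1.0, 0, 0])),
        ])]})
        dna = Structure("d", {"1": [Residue("1", 1, "DA", [
            Atom(1, "P", "P", np.array([2.0, 0.0, 0.0]))])]})
        table = find_contacts(prot, dna, cutoff=5.0,
                              protein_atom_filter="sidechain_polar")
        assert list(table["protein_atom"]) == ["NZ"]

    def test_empty_selection_gives_empty_table(self, ring3):
        empty = Structure("empty")
        table = find_contacts(ring3, empty, cutoff=4.0)
        assert len(table) == 0

    def test_nonpositive_cutoff_rejected(self, ring3):
        with pytest.raises(ValueError):
            find_contacts(ring3, ring3, cutoff=0.0)


class TestInventory:
    def test_pseudo_sequence_inventory(self, ring3):
        # PSEUDO_SEQUENCE has K at positions 3, 8, 15 and R at 5, 11, 18
        inv = basic_residue_inventory(ring3, [(1, 20)])
        per_chain = inv.groupby("chain")["residue_number"].apply(
            lambda s: sorted(s))
        for chain in ("A", "B", "C"):
            assert per_chain[chain] == [3, 5, 8, 11, 15, 18]

    def test_identical_across_subunits(self, ring3):
        inv = basic_residue_inventory(ring3, [(1, 40)])
        groups = {chain: sorted(zip(g["residue_number"], g["residue_name"]))
                  for chain, g in inv.groupby("chain")}
        assert groups["A"] == groups["B"] == groups["C"]

    def test_empty_range_gives_empty_inventory(self, ring3):
        assert len(basic_residue_inventory(ring3, [(1, 2)])) == 0

    def test_range_outside_structure_rejected(self, ring3):
        with pytest.raises(ValueError, match="outside"):
            basic_residue_inventory(ring3, [(500, 600)])


class TestMutationReport:
    def test_contact_and_proximity_flags(self, ring3):
        d = make_tilted_duplex(ring3, tilt=20.0, offset=0.0, length=25, seed=2)
        contacts = find_contacts(ring3, d.atoms, cutoff=12.0)
        sets = {"inner_basics": ["K3A", "R5A", "K8A"]}
        report = mutation_set_report(ring3, sets, contact_table=contacts,
                                     dna=d.atoms, proximity_cutoff=15.0)
        assert len(report) == 3
        assert report["min_distance"].notna().all()
        flagged = report[report["within_cutoff"]]
        assert len(flagged) >= 1
        contact_rows = set(contacts["residue_number"])
        for _, row in report.iterrows():
            assert row["in_contact"] == (row["residue_number"] in contact_rows)

    def test_unknown_residue_rejected(self, ring3):
        # residue 4 of the pseudo-sequence is SER, not LYS
        with pytest.raises(ValueError, match="not found"):
            mutation_set_report(ring3, {"bad": ["K4A"]})

    def test_empty_set_gives_empty_report(self, ring3):
        report = mutation_set_report(ring3, {"none": []})
        assert len(report) == 0
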