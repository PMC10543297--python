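"""Structure parsing, ASA, contact extraction and sequence mapping."""
from __future__ import annotations

import numpy as np
import pytest

from zeppi import (
    FixtureSpec,
    compute_surface,
    extract_contacts,
    make_toy_dimer,
    map_structure_to_msa,
    parse_dimer,
    query_sequences,
    write_toy_dimer,
)
from zeppi.errors import (
    ChainNotFoundError,
    EmptyInterfaceError,
    SequenceStructureMismatchError,
)
from zeppi.structure import ChainStructure, require_contacts

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.sequence import ProteinSequence


def _write_pdb(atoms: struc.AtomArray, path) -> str:
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))
    return str(path)


def _point_chain(chain_id: str, coords, seq=None) -> struc.AtomArray:
    """One CA atom per residue at the given coordinates."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    seq = seq or "A" * n
    arr = struc.AtomArray(n)
    for i in range(n):
        arr.coord[i] = coords[i]
        arr.chain_id[i] = chain_id
        arr.res_id[i] = i + 1
        arr.res_name[i] = ProteinSequence.convert_letter_1to3(seq[i])
        arr.atom_name[i] = "CA"
        arr.element[i] = "C"
        arr.hetero[i] = False
    return arr


def _two_point_chains(tmp_path, coords1, coords2, seq1=None, seq2=None):
    arr = _point_chain("A", coords1, seq1) + _point_chain("B", coords2, seq2)
    path = _write_pdb(arr, tmp_path / "toy.pdb")
    return parse_dimer(path, "A", "B")


class TestParseDimer:
    def test_toy_dimer_round_trip(self, tmp_path):
        spec = FixtureSpec(seed=5)
        path = write_toy_dimer(spec, tmp_path / "d.pdb")
        c1, c2 = parse_dimer(path, "A", "B")
        s1, s2 = query_sequences(spec)
        assert c1.sequence == s1
        assert c2.sequence == s2
        assert c1.res_keys[0] == (1, "")

    def test_missing_chain_raises(self, tmp_path):
        path = write_toy_dimer(FixtureSpec(seed=5), tmp_path / "d.pdb")
        with pytest.raises(ChainNotFoundError, match="chain not found"):
            parse_dimer(path, "A", "Z")

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        pdb_text = "\n".join(
            [
                "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.70  0.00           C  ",
                "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.30  0.00           C  ",
                "ATOM      3  CA  GLY B   1      20.000   0.000   0.000  1.00  0.00           C  ",
                "END",
            ]
        )
        path = tmp_path / "alt.pdb"
        path.write_text(pdb_text + "\n")
        c1, _ = parse_dimer(path, "A", "B")
        assert c1.n_residues == 1
        np.testing.assert_allclose(c1.atoms.coord[0], [0.0, 0.0, 0.0])

    def test_hydrogens_dropped_and_mse_is_met(self, tmp_path):
        pdb_text = "\n".join(
            [
                "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C  ",
                "ATOM      2  HA  ALA A   1       0.500   0.500   0.500  1.00  0.00           H  ",
                "HETATM    3  CA  MSE A   2       3.800   0.000   0.000  1.00  0.00           C  ",
                "HETATM    4  O   HOH A   3       9.000   9.000   9.000  1.00  0.00           O  ",
                "ATOM      5  CA  GLY B   1      30.000   0.000   0.000  1.00  0.00           C  ",
                "END",
            ]
        )
        path = tmp_path / "mse.pdb"
        path.write_text(pdb_text + "\n")
        c1, _ = parse_dimer(path, "A", "B")
        assert c1.sequence == "AM"
        assert c1.atoms.array_length() == 2  # no H, no water


class TestSurface:
    def test_isolated_tripeptide_all_surface(self, tmp_path):
        # an extended peptide with a partner >50 A away: nothing buried
        c1, c2 = _two_point_chains(
            tmp_path,
            [(0, 0, 0), (3.8, 0, 0), (7.6, 0, 0)],
            [(0, 100, 0), (3.8, 100, 0)],
        )
        s1, s2 = compute_surface(c1, c2, rel_asa_threshold=0.05)
        assert s1.is_surface.all()
        np.testing.assert_allclose(s1.buried_asa, 0.0)
        np.testing.assert_allclose(s2.buried_asa, 0.0)
        assert not s1.is_interface.any()

    def test_contacting_chains_bury_facing_residues(self, tmp_path):
        spec = FixtureSpec(seed=5)
        path = write_toy_dimer(spec, tmp_path / "d.pdb")
        c1, c2 = parse_dimer(path, "A", "B")
        s1, _ = compute_surface(c1, c2)
        contacts = extract_contacts(c1, c2)
        iface_idx = [c1.res_keys.index(k) for k in contacts.iface1]
        assert all(s1.buried_asa[i] > 0 for i in iface_idx)
        others = [i for i in range(c1.n_residues) if i not in iface_idx]
        np.testing.assert_allclose(s1.buried_asa[others], 0.0, atol=1e-9)

    def test_asa_matches_independent_shrake_rupley(self, tmp_path):
        """Backbone-mode helices vs mdtraj's Shrake-Rupley (960 points)."""
        mdtraj = pytest.importorskip("mdtraj")
        spec = FixtureSpec(seed=7, backbone=True)
        path = write_toy_dimer(spec, tmp_path / "bb.pdb")
        c1, c2 = parse_dimer(path, "A", "B")
        s1, s2 = compute_surface(c1, c2)
        traj = mdtraj.load(str(path))
        def ref_asa(t):
            return mdtraj.shrake_rupley(
                t, probe_radius=0.14, n_sphere_points=960, mode="residue"
            )[0] * 100.0  # nm^2 -> A^2

        # complexed ASA against the full model, isolated against each chain
        got_complex = np.concatenate([s1.asa_complexed, s2.asa_complexed])
        np.testing.assert_allclose(got_complex, ref_asa(traj), atol=1.0)
        n_atoms1 = c1.atoms.array_length()
        chain1 = traj.atom_slice(range(n_atoms1))
        chain2 = traj.atom_slice(range(n_atoms1, traj.n_atoms))
        np.testing.assert_allclose(s1.asa_isolated, ref_asa(chain1), atol=1.0)
        np.testing.assert_allclose(s2.asa_isolated, ref_asa(chain2), atol=1.0)

    def test_rigid_motion_invariance(self, tmp_path):
        spec = FixtureSpec(seed=9)
        path = write_toy_dimer(spec, tmp_path / "d.pdb")
        c1, c2 = parse_dimer(path, "A", "B")
        s1, s2 = compute_surface(c1, c2)
        contacts = extract_contacts(c1, c2)
        # rotate + translate the whole complex
        rot = struc.rotate(c1.atoms + c2.atoms, [0.3, 1.1, -0.7])
        rot.coord += np.array([13.0, -7.0, 42.0])
        n1 = c1.atoms.array_length()
        c1r = ChainStructure(
            c1.chain_id, rot[:n1], c1.res_keys, c1.sequence, c1.res_starts
        )
        c2r = ChainStructure(
            c2.chain_id, rot[n1:], c2.res_keys, c2.sequence,
            c2.res_starts,
        )
        s1r, s2r = compute_surface(c1r, c2r)
        np.testing.assert_allclose(s1r.asa_isolated, s1.asa_isolated, atol=0.5)
        np.testing.assert_allclose(s2r.buried_asa, s2.buried_asa, atol=0.5)
        assert extract_contacts(c1r, c2r).contacts == contacts.contacts


class TestContacts:
    @pytest.mark.parametrize(
        "distance,n_expected",
        [(5.99, 1), (6.00, 0), (6.01, 0), (1.0, 1)],
    )
    def test_strict_cutoff_boundary(self, tmp_path, distance, n_expected):
        c1, c2 = _two_point_chains(
            tmp_path, [(0, 0, 0)], [(distance, 0, 0)]
        )
        contacts = extract_contacts(c1, c2, cutoff=6.0)
        assert contacts.n_contacts == n_expected
        if n_expected == 0:
            assert contacts.is_empty
            with pytest.raises(EmptyInterfaceError):
                require_contacts(contacts)

    def test_minimum_atom_distance_governs(self, tmp_path):
        # residue B1 has atoms at 7 A and 5 A from A1: still a contact
        arr = _point_chain("A", [(0, 0, 0)])
        b = struc.AtomArray(2)
        for i, x in enumerate((7.0, 5.0)):
            b.coord[i] = (x, 0, 0)
            b.chain_id[i] = "B"
            b.res_id[i] = 1
            b.res_name[i] = "GLY"
            b.atom_name[i] = ("CA", "CB")[i]
            b.element[i] = "C"
            b.hetero[i] = False
        path = _write_pdb(arr + b, tmp_path / "min.pdb")
        c1, c2 = parse_dimer(path, "A", "B")
        assert extract_contacts(c1, c2).n_contacts == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_symmetry_monotonicity_and_brute_force(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = 12, 10
        coords1 = rng.uniform(0, 25, size=(n1, 3))
        coords2 = rng.uniform(0, 25, size=(n2, 3))
        c1, c2 = _two_point_chains(tmp_path, coords1, coords2)
        got6 = extract_contacts(c1, c2, cutoff=6.0)
        got5 = extract_contacts(c1, c2, cutoff=5.0)
        # symmetry: transposed extraction
        rev = extract_contacts(c2, c1, cutoff=6.0)
        assert rev.transpose().contacts == got6.contacts
        # monotonicity in the cutoff
        assert set(got5.contacts) <= set(got6.contacts)
        # brute-force all-pairs oracle
        expected = sorted(
            (c1.res_keys[i], c2.res_keys[j])
            for i in range(n1)
            for j in range(n2)
            if min(
                np.linalg.norm(a - b)
                for a in c1.residue_coords(i)
                for b in c2.residue_coords(j)
            )
            < 6.0
        )
        assert got6.contacts == expected


class TestStructureToMsaMapping:
    def _stub_chain(self, seq: str) -> ChainStructure:
        return ChainStructure(
            chain_id="A",
            atoms=None,
            res_keys=[(i + 1, "") for i in range(len(seq))],
            sequence=seq,
            res_starts=np.arange(len(seq) + 1),
        )

    def test_identical_sequence_identity_mapping(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        mapping = map_structure_to_msa(self._stub_chain(seq), seq)
        assert mapping == {(i + 1, ""): i for i in range(len(seq))}

    def test_disordered_gap_skips_exact_positions(self):
        query = "ACDEFGHIKLMNPQRSTVWY"
        # residues at query positions 4..9 (0-based) missing from the model
        chain_seq = query[:4] + query[10:]
        mapping = map_structure_to_msa(self._stub_chain(chain_seq), query)
        assert set(mapping.values()) == set(range(4)) | set(range(10, 20))

    def test_point_mutations_still_mapped(self):
        query = "ACDEFGHIKLMNPQRSTVWY"
        mutated = "AWDEFGHIKLMNPQRSTVWF"  # positions 1 and 19 mutated
        mapping = map_structure_to_msa(self._stub_chain(mutated), query)
        # hand-checked alignment: ungapped, all positions map identically
        assert mapping == {(i + 1, ""): i for i in range(20)}

    def test_low_identity_raises(self):
        chain = self._stub_chain("AAAAAAAAAAAAAAAAAAAA")
        with pytest.raises(SequenceStructureMismatchError):
            map_structure_to_msa(chain, "WYWYWYWYWYWYWYWYWYWY")


def test_toy_dimer_realises_designated_contacts(tmp_path):
    spec = FixtureSpec(seed=2, contacts=((0, 0), (4, 6), (9, 9)))
    path = write_toy_dimer(spec, tmp_path / "d.pdb")
    c1, c2 = parse_dimer(path, "A", "B")
    contacts = extract_contacts(c1, c2, cutoff=6.0)
    expected = sorted(((i + 1, ""), (j + 1, "")) for i, j in spec.contacts)
    assert contacts.contacts == expected
    # contacts placed at 5.0 A: a 4.0 A cutoff finds nothing
    assert extract_contacts(c1, c2, cutoff=4.0).is_empty


def test_toy_dimer_deterministic_text():
    spec = FixtureSpec(seed=4)
    assert make_toy_dimer(spec) == make_toy_dimer(FixtureSpec(seed=4))
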