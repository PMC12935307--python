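"""Structure parsing and interface labeling against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import parascope as ps
from parascope.errors import AssignmentError, StructureParseError
from parascope.structure import AtomRecord

from conftest import brute_force_contact_labels

MINIMAL_TWO_ATOM_PDB = """\
ATOM      1  CA  GLY H   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   1       0.000   0.000   4.400  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AGLY H   1       0.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BGLY H   1       5.000   0.000   0.000  0.40  0.00           C
END
"""

INSERTION_PDB = """\
ATOM      1  CA  GLY H 100       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA H 100A      8.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  LYS H 101      16.000   0.000   0.000  1.00  0.00           C
ATOM      4  CA  MSE H 102      24.000   0.000   0.000  1.00  0.00           C
END
"""


def _pdb(tmp_path, text, name="x.pdb"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestParseStructure:
    def test_minimal_readback(self, tmp_path):
        cx = ps.parse_structure(_pdb(tmp_path, MINIMAL_TWO_ATOM_PDB), dialect="pdb")
        assert cx.n_atoms == 2
        assert sorted(cx.chain_ids) == ["A", "H"]

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        cx = ps.parse_structure(_pdb(tmp_path, ALTLOC_PDB), dialect="pdb")
        residues = cx.residues("H")
        assert len(residues) == 1 and len(residues[0].atoms) == 1
        kept = residues[0].atoms[0]
        assert kept.occupancy == pytest.approx(0.6)
        assert kept.position[0] == pytest.approx(0.0)

    def test_generated_toy_atom_count(self, toy_complex, toy_structure):
        # the generator emits one CA per antibody residue and one antigen
        # atom per lattice site
        n = toy_complex.spec.n_antibody_residues
        assert toy_structure.n_atoms == 2 * n

    def test_unreadable_file_raises(self, tmp_path):
        with pytest.raises(StructureParseError):
            ps.parse_structure(tmp_path / "missing.pdb")

    def test_waters_excluded(self, tmp_path):
        text = MINIMAL_TWO_ATOM_PDB.replace(
            "END",
            "HETATM    3  O   HOH W   1       1.000   1.000   1.000  1.00  0.00           O\nEND",
        )
        cx = ps.parse_structure(_pdb(tmp_path, text), dialect="pdb")
        assert "W" not in cx.chain_ids


class TestLabeling:
    def _one_pair(self, tmp_path, dz):
        text = MINIMAL_TWO_ATOM_PDB.replace("4.400", f"{dz:.3f}")
        cx = ps.parse_structure(_pdb(tmp_path, text), dialect="pdb")
        assignment = ps.ChainAssignment("H", None, ("A",))
        return ps.label_paratope(cx, assignment)["H"].labels

    def test_below_cutoff_labels_one(self, tmp_path):
        assert self._one_pair(tmp_path, 4.4).tolist() == [1]

    def test_boundary_inclusive(self, tmp_path):
        assert self._one_pair(tmp_path, 4.5).tolist() == [1]

    def test_above_cutoff_labels_zero(self, tmp_path):
        assert self._one_pair(tmp_path, 4.6).tolist() == [0]

    def test_antigen_hydrogen_ignored(self, tmp_path):
        text = (
            "ATOM      1  CA  GLY H   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  H   ALA A   1       0.000   0.000   1.000  1.00  0.00           H\n"
            "ATOM      3  CA  ALA A   2       0.000   0.000  50.000  1.00  0.00           C\n"
            "END\n"
        )
        cx = ps.parse_structure(_pdb(tmp_path, text), dialect="pdb")
        labels = ps.label_paratope(cx, ps.ChainAssignment("H", None, ("A",)))["H"].labels
        assert labels.tolist() == [0]

    def test_missing_chain_raises(self, toy_structure):
        with pytest.raises(AssignmentError):
            ps.label_paratope(toy_structure, ps.ChainAssignment("Z", None, ("A",)))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 40))
        contacts = frozenset(
            int(i) for i in rng.choice(n, size=rng.integers(1, n // 2), replace=False)
        )
        toy = ps.generate_toy_complex(
            ps.ToyComplexSpec(
                n_antibody_residues=n,
                contact_positions=contacts,
                contact_distance=float(rng.uniform(2.0, 4.4)),
                decoy_distance=float(rng.uniform(4.6, 9.0)),
                seed=seed,
            )
        )
        path = _pdb(tmp_path, toy.pdb_text)
        cx = ps.parse_structure(path, dialect="pdb")
        assignment = ps.ChainAssignment("H", None, ("A",))
        got = ps.label_paratope(cx, assignment)["H"].labels
        oracle = brute_force_contact_labels(cx, ["H"], ["A"])["H"]
        assert np.array_equal(got, oracle)
        assert np.array_equal(got, toy.paratope_labels)

    def test_monotone_in_cutoff(self, toy_structure):
        assignment = ps.ChainAssignment("H", None, ("A",))
        previous = None
        for cutoff in (1.0, 3.0, 4.5, 6.0, 10.0):
            labels = ps.label_paratope(
                toy_structure, assignment, ps.LabelingConfig(cutoff_angstrom=cutoff)
            )["H"].labels
            if previous is not None:
                assert np.all(previous <= labels)
            previous = labels

    def test_hydrogen_atoms_never_change_labels(self, tmp_path, toy_complex):
        base = toy_complex.pdb_text
        cx0 = ps.parse_structure(_pdb(tmp_path, base, "a.pdb"), dialect="pdb")
        with_h = ps.generate_toy_complex(
            ps.ToyComplexSpec(
                n_antibody_residues=20,
                contact_positions=frozenset({3, 7}),
                hydrogen_decoy_positions=frozenset({1, 5, 12}),
                seed=1,
            )
        )
        cx1 = ps.parse_structure(_pdb(tmp_path, with_h.pdb_text, "b.pdb"), dialect="pdb")
        assignment = ps.ChainAssignment("H", None, ("A",))
        l0 = ps.label_paratope(cx0, assignment)["H"].labels
        l1 = ps.label_paratope(cx1, assignment)["H"].labels
        assert np.array_equal(l0, l1)


class TestEpitope:
    def test_epitope_counts_contacts(self, toy_structure, toy_complex):
        assignment = ps.ChainAssignment("H", None, ("A",))
        track = ps.label_epitope(toy_structure, assignment)["A"]
        oracle = brute_force_contact_labels(toy_structure, ["A"], ["H"])["A"]
        assert np.array_equal(track.labels, oracle)
        assert track.labels.sum() == toy_complex.epitope_labels.sum()

    def test_no_contact_gives_all_zero(self, tmp_path):
        toy = ps.generate_toy_complex(
            ps.ToyComplexSpec(
                n_antibody_residues=10,
                contact_positions=frozenset(),
                contact_distance=4.4,
                decoy_distance=20.0,
            )
        )
        cx = ps.parse_structure(_pdb(tmp_path, toy.pdb_text), dialect="pdb")
        assignment = ps.ChainAssignment("H", None, ("A",))
        assert ps.label_epitope(cx, assignment)["A"].labels.sum() == 0

    def test_role_symmetry(self, toy_structure):
        """Epitope labeling equals paratope labeling with roles swapped."""
        fwd = ps.label_epitope(
            toy_structure, ps.ChainAssignment("H", None, ("A",))
        )["A"].labels
        swapped = ps.label_paratope(
            toy_structure, ps.ChainAssignment("A", None, ("H",))
        )["A"].labels
        assert np.array_equal(fwd, swapped)


class TestSequenceExtraction:
    def test_three_letter_mapping_and_order(self, tmp_path):
        cx = ps.parse_structure(_pdb(tmp_path, INSERTION_PDB), dialect="pdb")
        seq, keys = ps.extract_fv_sequence(cx, "H")
        assert seq == "GAKX"  # MSE maps to X
        numbers = [(k.residue_number, k.insertion_code) for k in keys]
        assert numbers == [(100, ""), (100, "A"), (101, ""), (102, "")]

    def test_track_alignment_invariant(self, toy_structure):
        tracks = ps.label_paratope(
            toy_structure, ps.ChainAssignment("H", None, ("A",))
        )
        for track in tracks.values():
            assert len(track.labels) == len(track.sequence) == len(track.keys)

    def test_csv_round_trip(self, toy_structure, tmp_path):
        tracks = ps.label_paratope(
            toy_structure, ps.ChainAssignment("H", None, ("A",))
        )
        path = tmp_path / "labels.csv"
        ps.tracks_to_csv(tracks, path)
        back = ps.tracks_from_csv(path)
        assert back["H"].sequence == tracks["H"].sequence
        assert np.array_equal(back["H"].labels, tracks["H"].labels)


@settings(max_examples=25, deadline=None)
@given(
    cutoff_lo=st.floats(1.5, 4.0),
    extra=st.floats(0.5, 5.0),
    seed=st.integers(0, 10_000),
)
def test_paratope_set_grows_with_cutoff(cutoff_lo, extra, seed, tmp_path_factory):
    """Property: the paratope at cutoff c is a subset of the paratope at any
    larger cutoff, for random toy geometries."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 25))
    contacts = frozenset(int(i) for i in rng.choice(n, size=max(1, n // 4), replace=False))
    toy = ps.generate_toy_complex(
        ps.ToyComplexSpec(
            n_antibody_residues=n,
            contact_positions=contacts,
            contact_distance=float(rng.uniform(1.0, 4.0)),
            decoy_distance=float(rng.uniform(4.6, 12.0)),
            seed=seed,
        )
    )
    path = tmp_path_factory.mktemp("mono") / "toy.pdb"
    path.write_text(toy.pdb_text)
    cx = ps.parse_structure(path, dialect="pdb")
    assignment = ps.ChainAssignment("H", None, ("A",))
    lo = ps.label_paratope(cx, assignment, ps.LabelingConfig(cutoff_angstrom=cutoff_lo))
    hi = ps.label_paratope(
        cx, assignment, ps.LabelingConfig(cutoff_angstrom=cutoff_lo + extra)
    )
    assert np.all(lo["H"].labels <= hi["H"].labels)


def test_atom_record_hydrogen_detection():
    def atom(element, name):
        return AtomRecord("H", 1, "", "GLY", name, element, 1.0, "", (0, 0, 0))

    assert atom("H", "H") .is_hydrogen
    assert atom("D", "D1").is_hydrogen
    assert atom("", "1HB").is_hydrogen  # legacy PDB name convention
    assert not atom("C", "CA").is_hydrogen
    assert not atom("", "CA").is_hydrogen
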