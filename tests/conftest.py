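import numpy as np
import pytest

import parascope as ps


@pytest.fixture(scope="session")
def toy_complex():
    return ps.generate_toy_complex(
        ps.ToyComplexSpec(
            n_antibody_residues=20, contact_positions=frozenset({3, 7}), seed=1
        )
    )


@pytest.fixture()
def toy_structure(toy_complex, tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(toy_complex.pdb_text)
    return ps.parse_structure(path, dialect="pdb")


@pytest.fixture(scope="session")
def small_backends():
    return [
        ps.SyntheticBackend("alpha", 8, seed=11),
        ps.SyntheticBackend("beta", 16, seed=11),
    ]


def brute_force_contact_labels(complex, labeled_chains, opposite_chains, cutoff=4.5):
    """Exhaustive all-pairs distance oracle for interface labeling, kept
    independent of the spatial-index implementation."""
    target = []
    for cid in opposite_chains:
        for res in complex.residues(cid):
            for atom in res.atoms:
                if not atom.is_hydrogen:
                    target.append(atom.position)
    target = np.asarray(target, dtype=float).reshape(-1, 3)
    out = {}
    for cid in labeled_chains:
        labels = []
        for res in complex.residues(cid):
            contact = 0
            for atom in res.atoms:
                if atom.is_hydrogen:
                    continue
                pos = np.asarray(atom.position)
                if target.size and np.any(
                    np.linalg.norm(target - pos, axis=1) <= cutoff
                ):
                    contact = 1
                    break
            labels.append(contact)
        out[cid] = np.array(labels, dtype=int)
    return out
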