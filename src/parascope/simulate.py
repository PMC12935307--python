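"""Deterministic generators for toy complexes and synthetic training sets.

These generators make every analysis in the package testable without any
external download: minimal antibody-antigen structures whose ground-truth
contact labels are known by construction, two-arm complexes with a planted
paratope asymmetry, and labeled synthetic training sets whose features carry
a planted linear paratope signal of controlled effect size.  Toy structures
place one C-alpha atom per antibody residue on a spaced lattice and a
single-atom antigen "residue" at a controlled distance from each contact
position, so the brute-force distance oracle is trivially auditable.  They
emulate the geometry of interface labeling, not antibody chemistry.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .embeddings import FeatureMatrix, SyntheticBackend, build_features, AMINO_ACIDS
from .errors import SpecError
from .model import SequenceExample

_LATTICE_SPACING = 8.0  # Angstrom between residue sites; > any default cutoff


@dataclass(frozen=True)
class ToyComplexSpec:
    n_antibody_residues: int = 20
    contact_positions: frozenset[int] = frozenset({3, 7})
    contact_distance: float = 4.4
    decoy_distance: float = 4.6
    hydrogen_decoy_positions: frozenset[int] = frozenset()
    seed: int = 0

    def __post_init__(self):
        if self.contact_distance >= self.decoy_distance:
            raise SpecError("contact_distance must be below decoy_distance")
        out_of_range = [
            p
            for p in self.contact_positions | self.hydrogen_decoy_positions
            if not 0 <= p < self.n_antibody_residues
        ]
        if out_of_range:
            raise SpecError(f"positions out of range: {out_of_range}")


@dataclass
class ToyComplex:
    pdb_text: str
    antibody_chain_id: str
    antigen_chain_id: str
    antibody_sequence: str
    paratope_labels: np.ndarray
    epitope_labels: np.ndarray
    spec: ToyComplexSpec


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def _write_pdb(atoms: list[dict]) -> str:
    """Serialize atom dicts to PDB text via biotite."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    arr = struc.AtomArray(len(atoms))
    arr.coord = np.array([a["coord"] for a in atoms], dtype=np.float32)
    arr.chain_id = np.array([a["chain"] for a in atoms])
    arr.res_id = np.array([a["res_id"] for a in atoms])
    arr.res_name = np.array([a["res_name"] for a in atoms])
    arr.atom_name = np.array([a["atom"] for a in atoms])
    arr.element = np.array([a["element"] for a in atoms])
    arr.hetero = np.zeros(len(atoms), dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


def _complex_atoms(
    spec: ToyComplexSpec,
    sequence: str,
    antibody_chain: str,
    antigen_chain: str,
    contacts: frozenset[int],
    z_offset: float = 0.0,
) -> tuple[list[dict], np.ndarray, np.ndarray]:
    """Atoms for one arm: antibody CA lattice plus a one-atom antigen residue
    per position (contact distance at contacts, decoy distance elsewhere)."""
    n = spec.n_antibody_residues
    atoms = []
    for i in range(n):
        atoms.append(
            dict(
                chain=antibody_chain,
                res_id=i + 1,
                res_name=_ONE_TO_THREE[sequence[i]],
                atom="CA",
                element="C",
                coord=(i * _LATTICE_SPACING, 0.0, z_offset),
            )
        )
    ag_res = 0
    epitope = []
    for i in range(n):
        if i in spec.hydrogen_decoy_positions and i not in contacts:
            ag_res += 1
            atoms.append(
                dict(
                    chain=antigen_chain,
                    res_id=ag_res,
                    res_name="GLY",
                    atom="H",
                    element="H",
                    coord=(i * _LATTICE_SPACING, 1.0, z_offset),
                )
            )
            epitope.append(0)
            continue
        dist = spec.contact_distance if i in contacts else spec.decoy_distance
        ag_res += 1
        atoms.append(
            dict(
                chain=antigen_chain,
                res_id=ag_res,
                res_name="GLY",
                atom="CA",
                element="C",
                coord=(i * _LATTICE_SPACING, dist, z_offset),
            )
        )
        epitope.append(1 if i in contacts else 0)
    labels = np.array([1 if i in contacts else 0 for i in range(n)], dtype=int)
    return atoms, labels, np.array(epitope, dtype=int)


def generate_toy_complex(spec: ToyComplexSpec) -> ToyComplex:
    """Emit a standards-conformant PDB text and its intended label tracks."""
    rng = np.random.default_rng(spec.seed)
    sequence = _random_sequence(rng, spec.n_antibody_residues)
    atoms, labels, epitope = _complex_atoms(
        spec, sequence, "H", "A", spec.contact_positions
    )
    return ToyComplex(
        pdb_text=_write_pdb(atoms),
        antibody_chain_id="H",
        antigen_chain_id="A",
        antibody_sequence=sequence,
        paratope_labels=labels,
        epitope_labels=epitope,
        spec=spec,
    )


@dataclass
class TwoArmComplex:
    pdb_text: str
    arm_chain_ids: list[tuple[str, str]]  # (antibody, antigen) per arm
    sequence: str
    arm_labels: list[np.ndarray]
    arm_paratope_sets: list[frozenset]
    planted_asymmetry: int
    spec: ToyComplexSpec


def generate_two_arm_complex(
    spec: ToyComplexSpec, planted_asymmetry: int
) -> TwoArmComplex:
    """Duplicate the toy antibody/antigen into two arms, perturbing the
    second arm's antigen placement so that exactly ``planted_asymmetry``
    positions flip paratope membership."""
    k = planted_asymmetry
    n = spec.n_antibody_residues
    contacts1 = sorted(spec.contact_positions)
    non_contacts = sorted(set(range(n)) - spec.contact_positions)

    # plant by adding contacts to arm 2 where possible (keeps the union at
    # |P1| + k), dropping arm-1 contacts only when lattice positions run out
    k_add = min(k, len(non_contacts))
    k_drop = k - k_add
    if k_drop > len(contacts1):
        raise SpecError(
            f"asymmetry {k} infeasible with {len(contacts1)} contacts over "
            f"{n} residues"
        )
    contacts2 = frozenset(contacts1[k_drop:]) | frozenset(non_contacts[:k_add])

    rng = np.random.default_rng(spec.seed)
    sequence = _random_sequence(rng, n)
    atoms1, labels1, _ = _complex_atoms(
        spec, sequence, "H", "A", spec.contact_positions, z_offset=0.0
    )
    atoms2, labels2, _ = _complex_atoms(
        spec, sequence, "M", "B", contacts2, z_offset=100.0
    )
    sets = [
        frozenset((sequence[i], i) for i in np.flatnonzero(lab))
        for lab in (labels1, labels2)
    ]
    return TwoArmComplex(
        pdb_text=_write_pdb(atoms1 + atoms2),
        arm_chain_ids=[("H", "A"), ("M", "B")],
        sequence=sequence,
        arm_labels=[labels1, labels2],
        arm_paratope_sets=sets,
        planted_asymmetry=k,
        spec=spec,
    )


@dataclass(frozen=True)
class PlantedSignalSpec:
    """Label-correlated feature shift emulating the paratope signal that
    language-model embeddings carry.

    ``signal_dimensions`` index the assembled feature matrix; at positive
    positions those dimensions are shifted by ``effect_size``.  Labels are
    drawn at ``label_prevalence`` (about 1:10 positives over the variable
    region in real data), clustered into three CDR-like windows per chain
    when ``window_clustering`` is set.
    """

    signal_dimensions: frozenset[int] = frozenset({0, 1, 2, 3})
    effect_size: float = 4.0
    label_prevalence: float = 0.12
    window_clustering: bool = True

    def __post_init__(self):
        if not 0 < self.label_prevalence < 1:
            raise ValueError("label_prevalence must be in (0, 1)")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")


@dataclass
class TrainingSetSplit:
    train: list[SequenceExample]
    val: list[SequenceExample]
    test: list[SequenceExample]
    block_index: dict[str, tuple[int, int]] = field(default_factory=dict)
    window_positions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def all_examples(self) -> list[SequenceExample]:
        return [*self.train, *self.val, *self.test]


def _draw_labels(
    rng: np.random.Generator, length: int, spec: PlantedSignalSpec
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    if not spec.window_clustering:
        return (rng.random(length) < spec.label_prevalence).astype(int), []
    # three CDR-like windows covering ~30% of the chain
    w = max(2, int(round(0.1 * length)))
    starts = sorted(rng.choice(max(1, length - w), size=3, replace=False)) if length > w + 3 else [0]
    windows = [(int(s), int(min(length, s + w))) for s in starts]
    coverage = np.zeros(length, dtype=bool)
    for s, e in windows:
        coverage[s:e] = True
    q = min(1.0, spec.label_prevalence * length / max(1, coverage.sum()))
    labels = np.zeros(length, dtype=int)
    labels[coverage] = (rng.random(int(coverage.sum())) < q).astype(int)
    return labels, windows


def generate_training_set(
    n_sequences: int,
    length_range: tuple[int, int] = (100, 130),
    signal: PlantedSignalSpec | None = None,
    backends=None,
    seed: int = 0,
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
) -> TrainingSetSplit:
    """Labeled synthetic sequences with planted-signal features, split into
    disjoint train/validation/test sets (seeded).

    Each sequence is a paired heavy+light pseudo-antibody; features come
    from the supplied backends (default: one 24-dimensional synthetic
    backend) and the signal shift is added to ``signal.signal_dimensions``
    of the assembled feature matrix at positive positions.
    """
    if n_sequences < 1:
        raise SpecError("n_sequences must be at least 1")
    signal = signal or PlantedSignalSpec()
    rng = np.random.default_rng(seed)
    if backends is None:
        backends = [SyntheticBackend("synth", 24, seed=seed)]

    dims = sorted(signal.signal_dimensions)
    examples = []
    window_positions: dict[str, list[tuple[int, int]]] = {}
    for idx in range(n_sequences):
        lh = int(rng.integers(length_range[0] // 2, length_range[1] // 2 + 1))
        ll = int(rng.integers(length_range[0] // 2, length_range[1] // 2 + 1))
        heavy = _random_sequence(rng, lh)
        light = _random_sequence(rng, ll)
        lab_h, win_h = _draw_labels(rng, lh, signal)
        lab_l, win_l = _draw_labels(rng, ll, signal)
        labels = np.concatenate([lab_h, lab_l])
        fm = build_features(heavy, light, backends, mode="paired")
        values = fm.values.copy()
        if signal.effect_size != 0 and dims:
            values[np.ix_(labels.astype(bool), dims)] += signal.effect_size
        sid = f"seq_{idx:04d}"
        window_positions[sid] = win_h + [(lh + s, lh + e) for s, e in win_l]
        examples.append(SequenceExample(id=sid, features=values, labels=labels))
        block_index = fm.block_index

    order = rng.permutation(n_sequences)
    n_train = int(round(split_fractions[0] * n_sequences))
    n_val = int(round(split_fractions[1] * n_sequences))
    train = [examples[i] for i in order[:n_train]]
    val = [examples[i] for i in order[n_train : n_train + n_val]]
    test = [examples[i] for i in order[n_train + n_val :]]
    return TrainingSetSplit(
        train=train,
        val=val,
        test=test,
        block_index=block_index,
        window_positions=window_positions,
    )
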