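"""Ground-truth paratope/epitope labeling from antibody-antigen complexes.

An antibody residue belongs to the paratope when at least one of its
non-hydrogen atoms lies within a distance cutoff (default 4.5 Angstrom,
inclusive) of any non-hydrogen atom of the bound antigen; the epitope is
defined symmetrically on the antigen side.  Labels are produced per chain as
binary tracks aligned 1:1 with the extracted one-letter sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import (
    AlignmentError,
    AssignmentError,
    EmptyStructureError,
    EmptyTrackError,
    StructureParseError,
)

logger = logging.getLogger(__name__)

#: standard 3-letter -> 1-letter amino-acid code map; everything else maps to X
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_HYDROGEN_ELEMENTS = {"H", "D"}


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Unique residue identity within one structure, totally ordered."""

    chain_id: str
    residue_number: int
    insertion_code: str = ""


@dataclass(frozen=True)
class AtomRecord:
    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    occupancy: float
    altloc: str
    position: tuple[float, float, float]

    @property
    def is_hydrogen(self) -> bool:
        """Hydrogen or deuterium, by element symbol with an atom-name
        fallback for legacy PDB records lacking element columns."""
        el = self.element.strip().upper()
        if el:
            return el in _HYDROGEN_ELEMENTS
        name = self.atom_name.strip().lstrip("0123456789").upper()
        return name[:1] in _HYDROGEN_ELEMENTS


@dataclass
class Residue:
    key: ResidueKey
    name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def heavy_coords(self) -> np.ndarray:
        pts = [a.position for a in self.atoms if not a.is_hydrogen]
        return np.asarray(pts, dtype=float).reshape(-1, 3)


@dataclass
class StructureComplex:
    """Polymer atoms of one antibody-antigen complex, grouped by chain."""

    name: str
    chains: dict[str, list[Residue]]

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for ress in self.chains.values() for r in ress)

    def residues(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chains:
            raise AssignmentError(
                f"chain {chain_id!r} not in structure {self.name!r} "
                f"(has {sorted(self.chains)})"
            )
        return self.chains[chain_id]


@dataclass(frozen=True)
class ChainAssignment:
    """Which chains form one antibody arm and its bound antigen."""

    heavy_chain_id: str
    light_chain_id: str | None
    antigen_chain_ids: tuple[str, ...]
    arm_index: int = 0

    def __post_init__(self):
        ab = {self.heavy_chain_id}
        if self.light_chain_id is not None:
            if self.light_chain_id == self.heavy_chain_id:
                raise AssignmentError("heavy and light chain ids must differ")
            ab.add(self.light_chain_id)
        if ab & set(self.antigen_chain_ids):
            raise AssignmentError("antigen chains overlap antibody chains")

    @property
    def antibody_chain_ids(self) -> tuple[str, ...]:
        if self.light_chain_id is None:
            return (self.heavy_chain_id,)
        return (self.heavy_chain_id, self.light_chain_id)


@dataclass(frozen=True)
class LabelingConfig:
    """Distance criterion for interface labeling.

    ``cutoff_angstrom``: contact cutoff; a residue is labeled 1 when any of
    its non-hydrogen atoms is within this distance of a non-hydrogen atom on
    the other side.  ``boundary_inclusive`` reads "within" as <= (default).
    """

    cutoff_angstrom: float = 4.5
    exclude_hydrogen: bool = True
    boundary_inclusive: bool = True

    def __post_init__(self):
        if self.cutoff_angstrom <= 0:
            raise ValueError("cutoff_angstrom must be positive")


@dataclass
class ResidueLabelTrack:
    """Ordered residues of one chain with binary interface labels."""

    keys: list[ResidueKey]
    sequence: str
    labels: np.ndarray
    chain_id: str = ""
    flagged_positions: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.keys) == len(self.sequence) == len(self.labels)):
            raise AlignmentError(
                "keys, sequence and labels must have equal length"
            )
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain_id": [k.chain_id for k in self.keys],
                "residue_number": [k.residue_number for k in self.keys],
                "insertion_code": [k.insertion_code for k in self.keys],
                "aa": list(self.sequence),
                "label": self.labels,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ResidueLabelTrack":
        ins = df["insertion_code"].fillna("").astype(str)
        keys = [
            ResidueKey(str(c), int(n), i.strip())
            for c, n, i in zip(df["chain_id"], df["residue_number"], ins)
        ]
        chain = keys[0].chain_id if keys else ""
        return cls(
            keys=keys,
            sequence="".join(df["aa"].astype(str)),
            labels=df["label"].to_numpy(dtype=int),
            chain_id=chain,
        )


def _is_amino_acid(res_name: str, het_flag: str) -> bool:
    import gemmi

    info = gemmi.find_tabulated_residue(res_name)
    if info is not None and info.is_amino_acid():
        return True
    # unknown residue names recorded as ATOM are kept (mapped to X later)
    return het_flag == "A"


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, ties broken by
    altloc identifier order."""
    by_name: dict[str, list[AtomRecord]] = {}
    for a in atoms:
        by_name.setdefault(a.atom_name, []).append(a)
    kept = []
    for variants in by_name.values():
        variants.sort(key=lambda a: (-a.occupancy, a.altloc))
        kept.append(variants[0])
    return kept


def parse_structure(path: str | Path, dialect: str = "auto") -> StructureComplex:
    """Parse a PDB or mmCIF file into a :class:`StructureComplex`.

    Waters and non-amino-acid heteroatoms are excluded; altloc duplicates
    are resolved to the highest-occupancy conformer.  Only the first model
    is used.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }.get(dialect)
    if fmt is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"failed to parse {path}: {exc}") from exc

    chains: dict[str, list[Residue]] = {}
    if len(st) == 0:
        raise EmptyStructureError(f"{path} contains no models")
    model = st[0]
    for chain in model:
        for res in chain:
            if res.is_water():
                continue
            if not _is_amino_acid(res.name, res.het_flag):
                continue
            icode = res.seqid.icode.strip()
            key = ResidueKey(chain.name, res.seqid.num, icode)
            atoms = [
                AtomRecord(
                    chain_id=chain.name,
                    residue_number=res.seqid.num,
                    insertion_code=icode,
                    residue_name=res.name,
                    atom_name=atom.name,
                    element=atom.element.name,
                    occupancy=float(atom.occ),
                    altloc=atom.altloc or "",
                    position=(atom.pos.x, atom.pos.y, atom.pos.z),
                )
                for atom in res
            ]
            atoms = _resolve_altlocs(atoms)
            residues = chains.setdefault(chain.name, [])
            existing = next((r for r in residues if r.key == key), None)
            if existing is None:
                residues.append(Residue(key=key, name=res.name, atoms=atoms))
            else:
                existing.atoms.extend(atoms)

    # author numbering order with insertion-code lexicographic tie-break
    for cid in chains:
        chains[cid].sort(key=lambda r: (r.key.residue_number, r.key.insertion_code))

    if not any(chains.values()):
        raise EmptyStructureError(f"{path} contains no polymer amino-acid atoms")
    return StructureComplex(name=path.stem, chains=chains)


def extract_fv_sequence(
    complex: StructureComplex, chain_id: str
) -> tuple[str, list[ResidueKey]]:
    """One-letter sequence of a chain in residue-key order.

    Nonstandard residues map to ``X`` with a logged warning so that
    structural tracks stay aligned with sequence-model tracks.
    """
    residues = complex.residues(chain_id)
    letters = []
    keys = []
    for res in residues:
        one = THREE_TO_ONE.get(res.name)
        if one is None:
            logger.warning(
                "nonstandard residue %s at %s:%s%s mapped to X",
                res.name, chain_id, res.key.residue_number, res.key.insertion_code,
            )
            one = "X"
        letters.append(one)
        keys.append(res.key)
    return "".join(letters), keys


def _collect_heavy_atoms(
    complex: StructureComplex, chain_ids: Iterable[str]
) -> np.ndarray:
    coords = []
    for cid in chain_ids:
        for res in complex.residues(cid):
            pts = res.heavy_coords()
            if pts.size:
                coords.append(pts)
    if not coords:
        return np.empty((0, 3))
    return np.vstack(coords)


def _contact_tracks(
    complex: StructureComplex,
    labeled_chain_ids: Sequence[str],
    opposite_chain_ids: Sequence[str],
    config: LabelingConfig,
) -> dict[str, ResidueLabelTrack]:
    """Label residues of ``labeled_chain_ids`` that contact any non-hydrogen
    atom of ``opposite_chain_ids`` within the cutoff."""
    target = _collect_heavy_atoms(complex, opposite_chain_ids)
    tree = cKDTree(target) if len(target) else None
    cutoff = config.cutoff_angstrom

    tracks = {}
    for cid in labeled_chain_ids:
        residues = complex.residues(cid)
        if not residues:
            raise EmptyTrackError(f"chain {cid!r} has zero residues")
        sequence, keys = extract_fv_sequence(complex, cid)
        labels = np.zeros(len(residues), dtype=int)
        flagged = []
        for i, res in enumerate(residues):
            pts = res.heavy_coords()
            if pts.shape[0] == 0:
                flagged.append(i)  # no resolved heavy atom: labeled 0, flagged
                continue
            if tree is None:
                continue
            dmin = float(np.min(tree.query(pts)[0]))
            if config.boundary_inclusive:
                labels[i] = int(dmin <= cutoff)
            else:
                labels[i] = int(dmin < cutoff)
        tracks[cid] = ResidueLabelTrack(
            keys=keys,
            sequence=sequence,
            labels=labels,
            chain_id=cid,
            flagged_positions=flagged,
        )
    return tracks


def label_paratope(
    complex: StructureComplex,
    assignment: ChainAssignment,
    config: LabelingConfig | None = None,
) -> dict[str, ResidueLabelTrack]:
    """Binary paratope track per antibody chain: a residue is 1 iff any of
    its non-hydrogen atoms lies within the cutoff of any non-hydrogen atom
    of an assigned antigen chain."""
    config = config or LabelingConfig()
    for cid in assignment.antibody_chain_ids + tuple(assignment.antigen_chain_ids):
        if cid not in complex.chains:
            raise AssignmentError(f"assigned chain {cid!r} missing from structure")
    return _contact_tracks(
        complex,
        assignment.antibody_chain_ids,
        assignment.antigen_chain_ids,
        config,
    )


def label_epitope(
    complex: StructureComplex,
    assignment: ChainAssignment,
    config: LabelingConfig | None = None,
) -> dict[str, ResidueLabelTrack]:
    """Binary epitope track per antigen chain (roles of antibody and
    antigen swapped relative to :func:`label_paratope`)."""
    config = config or LabelingConfig()
    for cid in assignment.antibody_chain_ids + tuple(assignment.antigen_chain_ids):
        if cid not in complex.chains:
            raise AssignmentError(f"assigned chain {cid!r} missing from structure")
    return _contact_tracks(
        complex,
        tuple(assignment.antigen_chain_ids),
        assignment.antibody_chain_ids,
        config,
    )


def tracks_to_csv(tracks: dict[str, ResidueLabelTrack], path: str | Path) -> None:
    pd.concat([t.to_frame() for t in tracks.values()]).to_csv(path, index=False)


def tracks_from_csv(path: str | Path) -> dict[str, ResidueLabelTrack]:
    df = pd.read_csv(path, keep_default_na=False)
    return {
        str(cid): ResidueLabelTrack.from_frame(sub)
        for cid, sub in df.groupby("chain_id", sort=False)
    }
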