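"""Two-arm paratope/epitope asymmetry statistics and the prediction
upper bound.

An IgG binds its antigen through two identical Fab arms, so comparing the
two arms' structurally derived paratopes measures intrinsic binding-site
variability.  Asymmetry is the cardinality of the symmetric difference of
the two paratope sets; its normalized form (divided by the union size)
equals the Jaccard distance.  Treating one arm's labels as ground truth and
the other's as predictions yields an empirical upper bound on any
sequence-based predictor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, SchemaError, UndefinedInputError
from .metrics import confusion, f1, mcc
from .structure import ResidueLabelTrack

#: a paratope is a set of (amino-acid, position) pairs, e.g. ("L", 63)
ParatopeSet = frozenset


def track_to_paratope_set(
    sequence: str, labels: np.ndarray, by_position_only: bool = False
) -> frozenset:
    """Positive positions of a label track as a paratope set.

    Members are (amino acid, position) pairs by default; with
    ``by_position_only`` bare positions are used (the two coincide when the
    compared arms have identical sequences, as curation guarantees).
    """
    labels = np.asarray(labels, dtype=int)
    if len(sequence) != len(labels):
        raise AlignmentError("sequence and labels must have equal length")
    if by_position_only:
        return frozenset(int(i) for i in np.flatnonzero(labels))
    return frozenset((sequence[i], int(i)) for i in np.flatnonzero(labels))


def paratope_asymmetry(p1: Iterable, p2: Iterable) -> int:
    """Count of members in exactly one of the two sets: |(P1 u P2) \\ (P1 n P2)|."""
    return len(set(p1) ^ set(p2))


def normalized_asymmetry(p1: Iterable, p2: Iterable) -> float:
    """Symmetric difference over union: the Jaccard distance d_J = 1 - J."""
    s1, s2 = set(p1), set(p2)
    union = s1 | s2
    if not union:
        raise UndefinedInputError(
            "normalized asymmetry is undefined when both sets are empty"
        )
    return len(s1 ^ s2) / len(union)


@dataclass(frozen=True)
class AsymmetryRecord:
    paratope_asymmetry: int
    normalized_paratope_asymmetry: float
    epitope_asymmetry: int
    normalized_epitope_asymmetry: float
    paratope_union_size: int
    epitope_union_size: int


def asymmetry_record(p1, p2, e1, e2) -> AsymmetryRecord:
    """Full asymmetry summary for one complex from its two arms' paratope
    sets (p1, p2) and epitope sets (e1, e2)."""
    return AsymmetryRecord(
        paratope_asymmetry=paratope_asymmetry(p1, p2),
        normalized_paratope_asymmetry=normalized_asymmetry(p1, p2),
        epitope_asymmetry=paratope_asymmetry(e1, e2),
        normalized_epitope_asymmetry=normalized_asymmetry(e1, e2),
        paratope_union_size=len(set(p1) | set(p2)),
        epitope_union_size=len(set(e1) | set(e2)),
    )


@dataclass
class CurationFilterReport:
    """Per-stage complex counts for the four-filter curation cascade."""

    n_input: int
    stage_counts: list[int]  # retained after each of the four filters
    stage_names: list[str]
    retained: list[str]  # pdb ids surviving all filters
    removed: dict[str, list[str]]  # stage name -> pdb ids removed there

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "stage_counts": self.stage_counts,
            "stage_names": self.stage_names,
            "retained": self.retained,
            "removed": self.removed,
        }


_REQUIRED_COLUMNS = ("pdb_id", "antigen_type", "heavy_seq", "light_seq", "antigen_seq")
_PROTEIN_TYPES = {"protein", "peptide", "protein | protein", "peptide | protein"}


def _levenshtein(a: str, b: str) -> int:
    import edlib

    return edlib.align(a, b, task="distance")["editDistance"]


def _arms_match(rows: pd.DataFrame, max_difference: int) -> bool:
    (h1, l1, g1), (h2, l2, g2) = rows[["heavy_seq", "light_seq", "antigen_seq"]].values
    if max_difference == 0:
        return h1 == h2 and l1 == l2 and g1 == g2
    return (
        _levenshtein(h1, h2) <= max_difference
        and _levenshtein(l1, l2) <= max_difference
        and _levenshtein(g1, g2) <= max_difference
    )


def curate_two_arm_dataset(
    metadata: pd.DataFrame, max_arm_difference: int = 0
) -> CurationFilterReport:
    """Apply the four curation filters, counting complexes at each stage.

    One metadata row describes one antibody-antigen interaction (one arm);
    a complex is one pdb_id.  Filters, in order: (1) the antigen is a
    protein or peptide; (2) both heavy and light chains are present
    (excludes nanobodies); (3) the complex has exactly two arms; (4) the two
    arms are identical in heavy, light, and bound antigen sequence
    (``max_arm_difference`` relaxes identity to a Levenshtein threshold for
    sensitivity analyses).
    """
    missing = [c for c in _REQUIRED_COLUMNS if c not in metadata.columns]
    if missing:
        raise SchemaError(f"metadata missing required columns: {missing}")

    df = metadata.copy()
    df["pdb_id"] = df["pdb_id"].astype(str)
    complexes = list(dict.fromkeys(df["pdb_id"]))  # order-stable unique ids
    groups = {pid: df[df["pdb_id"] == pid] for pid in complexes}

    def is_protein_antigen(rows: pd.DataFrame) -> bool:
        types = rows["antigen_type"].astype(str).str.strip().str.lower()
        return bool(types.isin(_PROTEIN_TYPES).all())

    def has_both_chains(rows: pd.DataFrame) -> bool:
        h = rows["heavy_seq"].fillna("").astype(str).str.len() > 0
        l = rows["light_seq"].fillna("").astype(str).str.len() > 0
        return bool((h & l).all())

    filters = [
        ("protein_or_peptide_antigen", is_protein_antigen),
        ("heavy_and_light_present", has_both_chains),
        ("exactly_two_arms", lambda rows: len(rows) == 2),
        ("identical_arms", lambda rows: _arms_match(rows, max_arm_difference)),
    ]

    surviving = sorted(complexes)
    stage_counts, stage_names, removed = [], [], {}
    for name, predicate in filters:
        kept, dropped = [], []
        for pid in surviving:
            (kept if predicate(groups[pid]) else dropped).append(pid)
        surviving = kept
        stage_counts.append(len(kept))
        stage_names.append(name)
        removed[name] = dropped

    return CurationFilterReport(
        n_input=len(complexes),
        stage_counts=stage_counts,
        stage_names=stage_names,
        retained=surviving,
        removed=removed,
    )


def _as_labels(track) -> np.ndarray:
    if isinstance(track, ResidueLabelTrack):
        return np.asarray(track.labels, dtype=int)
    return np.asarray(track, dtype=int)


def arm_upper_bound(track_arm1, track_arm2) -> tuple[float, float]:
    """F1 and MCC of arm 2's labels scored against arm 1's labels.

    With one arm treated as ground truth and the other as a perfect-oracle
    prediction, this is the best score any predictor that cannot distinguish
    the arms could achieve.
    """
    y1, y2 = _as_labels(track_arm1), _as_labels(track_arm2)
    if y1.shape != y2.shape:
        raise AlignmentError("arm tracks must be position-aligned")
    counts = confusion(y1, y2)
    return f1(counts), mcc(counts)


def asymmetry_correlation(
    records: Sequence[AsymmetryRecord],
) -> tuple[float, float]:
    """Pearson r (and two-sided p by the t approximation) between normalized
    paratope and normalized epitope asymmetry across complexes."""
    if len(records) < 3:
        raise UndefinedInputError("need at least 3 records for a correlation")
    x = np.array([r.normalized_paratope_asymmetry for r in records], dtype=float)
    y = np.array([r.normalized_epitope_asymmetry for r in records], dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise UndefinedInputError("records contain non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedInputError("correlation undefined: zero variance margin")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def records_to_frame(records: Sequence[AsymmetryRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
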