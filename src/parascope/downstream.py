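"""Paratope-derived downstream operators.

Three operators consume per-residue paratope probabilities: a summed-
probability paratope-size proxy, paratope-weighted pooling of residue
embeddings into a fixed-length sequence vector, and a region combiner that
substitutes a region-restricted predictor's probabilities (e.g. CDR+/-2)
into a full-sequence track.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .embeddings import FeatureMatrix
from .errors import AlignmentError, CoverageError, NormalizationError


def paratope_size(probabilities: np.ndarray) -> float:
    """Paratope-size proxy: the sum of per-residue paratope probabilities
    over all amino acids supplied (heavy plus light when paired; a
    single-chain sum is not comparable to a paired-chain sum)."""
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0:
        warnings.warn("empty probability track; paratope size is 0")
        return 0.0
    return float(p.sum())


def binarized_paratope_size(probabilities: np.ndarray, threshold: float) -> int:
    """Count of residues with probability >= threshold (an alternative size
    proxy; monotone non-increasing in the threshold)."""
    p = np.asarray(probabilities, dtype=float)
    return int((p >= threshold).sum())


@dataclass
class PooledEmbedding:
    vector: np.ndarray
    pooling: str  # "unweighted" | "paratope-weighted"


def pooled_embedding(
    embeddings: np.ndarray | FeatureMatrix,
    probabilities: np.ndarray | None = None,
) -> PooledEmbedding:
    """Pool residue embeddings into one sequence vector.

    Without probabilities: the unweighted mean e_avg = (1/N) sum_i e_i.
    With probabilities: the paratope-weighted mean e_para = sum_i w_i e_i
    with w_i = p_i / sum_j p_j, so the result lies in the convex hull of the
    residue vectors and is invariant to uniform rescaling of p.
    """
    E = embeddings.values if isinstance(embeddings, FeatureMatrix) else embeddings
    E = np.asarray(E, dtype=float)
    if probabilities is None:
        return PooledEmbedding(vector=E.mean(axis=0), pooling="unweighted")
    p = np.asarray(probabilities, dtype=float)
    if p.shape[0] != E.shape[0]:
        raise AlignmentError("probability track must align with embedding rows")
    total = p.sum()
    if total <= 0:
        raise NormalizationError("probabilities sum to zero; weights undefined")
    w = p / total
    return PooledEmbedding(vector=w @ E, pooling="paratope-weighted")


def combine_tracks(
    region_track: np.ndarray,
    full_track: np.ndarray,
    mask: np.ndarray,
) -> np.ndarray:
    """Substitute a region predictor's probabilities into a full-sequence
    track: the output takes ``region_track`` on masked positions and
    ``full_track`` elsewhere, yielding one contiguous probability track.

    ``region_track`` may be compact (one value per masked position, in
    position order) or full-length (values read at masked positions only).
    Raw values are substituted with no boundary rescaling.
    """
    full = np.asarray(full_track, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    region = np.asarray(region_track, dtype=float)
    if mask.shape[0] != full.shape[0]:
        raise AlignmentError("mask must align with the full track")
    n_masked = int(mask.sum())
    out = full.copy()
    if region.shape[0] == n_masked:
        out[mask] = region
    elif region.shape[0] == full.shape[0]:
        out[mask] = region[mask]
    else:
        raise CoverageError(
            f"region track has {region.shape[0]} values; expected {n_masked} "
            f"(masked positions) or {full.shape[0]} (full length)"
        )
    return out
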