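"""Shapley-value attribution over input dimensions and per-backend
importance profiles.

For one residue, each scalar embedding dimension is a player and the value
function is the classifier's paratope probability with absent dimensions
replaced by baseline values.  Exact attribution enumerates all coalitions
(feasible up to ~12 dimensions); the sampling estimator averages marginal
contributions over random feature orderings and converges to the exact
values.  Dimension attributions aggregate into per-backend importance: raw
scores sum a backend's dimensions, mean scores divide by the block width,
and either variant is normalized to sum to 1 across backends.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import NormalizationError


@dataclass
class ShapleyAttribution:
    """Per-dimension Shapley values for one prediction."""

    values: np.ndarray
    baseline_value: float  # f with every feature at its baseline
    full_value: float  # f with every feature present

    @property
    def efficiency_gap(self) -> float:
        """Sum of values minus (full - baseline); ~0 for a valid attribution."""
        return float(self.values.sum() - (self.full_value - self.baseline_value))


def exact_shapley(
    value_function: Callable[[np.ndarray], float],
    x: np.ndarray,
    baseline: np.ndarray,
    max_features: int = 12,
) -> ShapleyAttribution:
    """Exact Shapley values by full coalition enumeration.

    phi_i = sum over S not containing i of
            |S|! (n - |S| - 1)! / n! * [f(S u {i}) - f(S)],
    where f(S) evaluates ``value_function`` on a vector holding ``x`` on the
    dimensions in S and ``baseline`` elsewhere.
    """
    x = np.asarray(x, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    n = x.shape[0]
    if n > max_features:
        raise ValueError(
            f"{n} features would require 2^{n} evaluations; "
            "use approx_shapley for larger inputs"
        )

    # evaluate f on every coalition, indexed by bitmask
    f = np.empty(1 << n)
    for s in range(1 << n):
        member = np.array([(s >> i) & 1 for i in range(n)], dtype=bool)
        f[s] = value_function(np.where(member, x, baseline))

    fact = [factorial(k) for k in range(n + 1)]
    phi = np.zeros(n)
    for i in range(n):
        bit = 1 << i
        for s in range(1 << n):
            if s & bit:
                continue
            size = bin(s).count("1")
            weight = fact[size] * fact[n - size - 1] / fact[n]
            phi[i] += weight * (f[s | bit] - f[s])
    return ShapleyAttribution(
        values=phi, baseline_value=float(f[0]), full_value=float(f[(1 << n) - 1])
    )


def approx_shapley(
    predict_fn: Callable[[np.ndarray], np.ndarray | float],
    x: np.ndarray,
    background: np.ndarray,
    n_samples: int = 200,
    seed: int = 0,
) -> ShapleyAttribution:
    """Permutation-sampling Shapley estimate.

    Absent features take the mean of the background sample.  For each
    sampled feature ordering, features are switched on one by one and the
    marginal prediction changes are accumulated; the estimator satisfies the
    efficiency axiom exactly and converges to :func:`exact_shapley`.
    """
    x = np.asarray(x, dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] == 0:
        raise ValueError("background sample must be non-empty")
    baseline = background.mean(axis=0)
    n = x.shape[0]
    rng = np.random.default_rng(seed)

    def f(vec: np.ndarray) -> float:
        out = predict_fn(vec.reshape(1, -1))
        return float(np.asarray(out).ravel()[0])

    base_value = f(baseline)
    full_value = f(x)
    phi = np.zeros(n)
    for _ in range(n_samples):
        order = rng.permutation(n)
        current = baseline.copy()
        prev = base_value
        for i in order:
            current[i] = x[i]
            value = f(current)
            phi[i] += value - prev
            prev = value
    phi /= n_samples
    return ShapleyAttribution(
        values=phi, baseline_value=base_value, full_value=full_value
    )


@dataclass
class ImportanceProfile:
    """Per-backend Shapley importance, normalized to sum to 1."""

    backends: list[str]
    scores: dict[str, float]  # raw or mean scores before normalization
    normalized: dict[str, float]
    mode: str  # "raw" | "mean"


def backend_importance(
    attribution: ShapleyAttribution | np.ndarray,
    block_index: Mapping[str, tuple[int, int]],
    mode: str = "raw",
    signed: bool = False,
) -> ImportanceProfile:
    """Aggregate dimension attributions into per-backend importance.

    Raw mode sums a backend's dimension scores; mean mode divides the sum by
    the block width to control for embedding dimensionality.  Scores use
    absolute Shapley values by default so normalization I~_k = I_k / sum_j I_j
    is well defined; ``signed`` sums signed values instead.
    """
    if mode not in ("raw", "mean"):
        raise ValueError(f"unknown mode {mode!r}")
    values = (
        attribution.values
        if isinstance(attribution, ShapleyAttribution)
        else np.asarray(attribution, dtype=float)
    )
    contribution = values if signed else np.abs(values)

    names = sorted(block_index, key=lambda k: block_index[k][0])
    spans = [block_index[k] for k in names]
    if spans[0][0] != 0 or any(
        a[1] != b[0] for a, b in zip(spans[:-1], spans[1:])
    ) or spans[-1][1] != values.shape[0]:
        raise ValueError("block ranges must partition all dimensions")

    scores = {}
    for name in names:
        start, stop = block_index[name]
        s = float(contribution[start:stop].sum())
        if mode == "mean":
            s /= stop - start
        scores[name] = s
    total = sum(scores.values())
    if total == 0:
        raise NormalizationError("all backend scores are zero; cannot normalize")
    normalized = {k: v / total for k, v in scores.items()}
    return ImportanceProfile(
        backends=names, scores=scores, normalized=normalized, mode=mode
    )


def aggregate_importance(
    profiles: Sequence[ImportanceProfile],
) -> ImportanceProfile:
    """Mean of normalized backend scores over residues or sequences,
    renormalized to sum to 1."""
    if not profiles:
        raise ValueError("need at least one profile")
    names = profiles[0].backends
    if any(p.backends != names for p in profiles):
        raise ValueError("profiles cover different backend sets")
    mode = profiles[0].mode
    mean_scores = {
        k: float(np.mean([p.normalized[k] for p in profiles])) for k in names
    }
    total = sum(mean_scores.values())
    if total == 0:
        raise NormalizationError("aggregated scores are all zero")
    return ImportanceProfile(
        backends=list(names),
        scores=mean_scores,
        normalized={k: v / total for k, v in mean_scores.items()},
        mode=mode,
    )


def aggregate_importance_by_position(
    per_sequence: Sequence[Mapping[int, ImportanceProfile]],
) -> dict[int, ImportanceProfile]:
    """Position-keyed aggregation: each position's profile is averaged over
    only the sequences in which that position is present."""
    positions: dict[int, list[ImportanceProfile]] = {}
    for mapping in per_sequence:
        for pos, profile in mapping.items():
            positions.setdefault(pos, []).append(profile)
    return {pos: aggregate_importance(profs) for pos, profs in sorted(positions.items())}
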