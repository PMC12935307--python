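"""Per-residue embedding backends and feature-matrix assembly.

Residue embeddings come from pluggable backends (real protein-language-model
adapters are optional); the built-in :class:`SyntheticBackend` is a fully
deterministic stand-in that hashes each residue's local sequence context to
standard-normal-like vectors and can plant a linear paratope signal for
controlled experiments.  Features from several backends are concatenated
per residue, heavy-chain rows first, in a fixed alphabetical backend order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

from .errors import AlphabetError, ContractViolationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = set(AMINO_ACIDS) | {"X"}

#: (tag, sequence) pairs; tags keep chains distinguishable to chain-aware backends
Chains = Sequence[tuple[str, str]]


class EmbeddingBackend(Protocol):
    name: str
    dimension: int
    pairing_mode: str  # "single-sequence" | "paired-aware"

    def embed(self, chains: Chains, marked: np.ndarray | None = None) -> np.ndarray:
        """Return one ``dimension``-vector per residue over all chains, in
        chain order. Must be deterministic."""
        ...


def _validate_sequence(seq: str) -> None:
    bad = set(seq) - ALPHABET
    if bad:
        raise AlphabetError(f"sequence contains invalid symbols: {sorted(bad)}")


@dataclass(frozen=True)
class PlantedSignal:
    """Linear paratope signal planted into designated embedding dimensions.

    At positions flagged as paratope-like, each dimension in
    ``signal_dimensions`` is shifted by ``effect_size``.
    """

    signal_dimensions: frozenset[int]
    effect_size: float

    def __post_init__(self):
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")


class SyntheticBackend:
    """Deterministic hash-based residue embedder.

    Each residue's vector is a function of (amino acid, +/-``window`` sequence
    context, chain tag, backend name, seed), drawn as standard-normal values
    from a hash-seeded generator.  Windows never cross a chain boundary and
    the chain tag enters the hash, so paired-mode rows for one chain are
    identical to single-mode rows for that chain.  The symbol X embeds as the
    mean of the 20 standard-residue vectors for the same context.
    """

    def __init__(
        self,
        name: str,
        dimension: int,
        seed: int = 0,
        signal: PlantedSignal | None = None,
        window: int = 2,
        pairing_mode: str = "paired-aware",
    ):
        if dimension < 1:
            raise ValueError("dimension must be >= 1")
        self.name = name
        self.dimension = dimension
        self.seed = seed
        self.signal = signal
        self.window = window
        self.pairing_mode = pairing_mode

    def _context_vector(self, tag: str, context: str) -> np.ndarray:
        key = f"{self.name}|{self.seed}|{tag}|{context}".encode()
        digest = hashlib.blake2b(key, digest_size=8).digest()
        rng = np.random.Generator(np.random.PCG64(int.from_bytes(digest, "little")))
        return rng.standard_normal(self.dimension)

    def _residue_vector(self, tag: str, seq: str, i: int) -> np.ndarray:
        lo, hi = max(0, i - self.window), min(len(seq), i + self.window + 1)
        left, center, right = seq[lo:i], seq[i], seq[i:hi][1:]
        if center == "X":
            vecs = [
                self._context_vector(tag, f"{left}[{aa}]{right}")
                for aa in AMINO_ACIDS
            ]
            return np.mean(vecs, axis=0)
        return self._context_vector(tag, f"{left}[{center}]{right}")

    def embed(self, chains: Chains, marked: np.ndarray | None = None) -> np.ndarray:
        rows = []
        for tag, seq in chains:
            _validate_sequence(seq)
            for i in range(len(seq)):
                rows.append(self._residue_vector(tag, seq, i))
        out = np.asarray(rows, dtype=float).reshape(-1, self.dimension)
        if self.signal is not None and marked is not None:
            marked = np.asarray(marked, dtype=bool)
            if marked.shape[0] != out.shape[0]:
                raise ContractViolationError(
                    "marked-position mask length does not match residue count"
                )
            dims = sorted(self.signal.signal_dimensions)
            out[np.ix_(marked, dims)] += self.signal.effect_size
        return out


def synthetic_backend(
    name: str,
    dimension: int,
    seed: int = 0,
    signal: PlantedSignal | None = None,
    **kwargs,
) -> SyntheticBackend:
    """Convenience constructor mirroring the backend registry style."""
    return SyntheticBackend(name, dimension, seed=seed, signal=signal, **kwargs)


@dataclass
class FeatureMatrix:
    """Concatenated per-residue features with named backend blocks."""

    values: np.ndarray  # (n_residues, total_dimension)
    block_index: dict[str, tuple[int, int]]
    mode: str = "paired"
    chain_tags: list[str] = field(default_factory=list)
    n_heavy: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        d = self.values.shape[1] if self.values.ndim == 2 else 0
        covered = sorted(self.block_index.values())
        pos = 0
        for start, stop in covered:
            if start != pos:
                raise ContractViolationError("block ranges must partition [0, d)")
            pos = stop
        if pos != d:
            raise ContractViolationError("block ranges must partition [0, d)")

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]

    @property
    def total_dimension(self) -> int:
        return self.values.shape[1]

    def block(self, name: str) -> np.ndarray:
        start, stop = self.block_index[name]
        return self.values[:, start:stop]


def build_features(
    heavy: str,
    light: str | None,
    backends: Sequence[EmbeddingBackend],
    mode: str = "paired",
    marked: np.ndarray | None = None,
) -> FeatureMatrix:
    """Embed a chain (or paired chains) with every backend and concatenate.

    In paired mode, single-sequence backends receive the heavy+light
    concatenation as one pseudo-chain while paired-aware backends receive
    each chain separately.  Backends are applied in alphabetical name order,
    which is also the block order in the output.
    """
    if mode not in ("paired", "single"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "paired" and light is None:
        raise ValueError("paired mode requires both heavy and light chains")
    _validate_sequence(heavy)
    if light is not None:
        _validate_sequence(light)
    if not backends:
        raise ValueError("at least one backend required")

    ordered = sorted(backends, key=lambda b: b.name)
    if len({b.name for b in ordered}) != len(ordered):
        raise ValueError("backend names must be unique")

    if mode == "paired":
        n_total = len(heavy) + len(light)
        tags = ["H"] * len(heavy) + ["L"] * len(light)
        n_heavy = len(heavy)
    else:
        n_total = len(heavy)
        tags = ["H"] * len(heavy)
        n_heavy = len(heavy)

    blocks = []
    block_index: dict[str, tuple[int, int]] = {}
    offset = 0
    for backend in ordered:
        if mode == "paired":
            if backend.pairing_mode == "single-sequence":
                chains = [("H+L", heavy + light)]
            else:
                chains = [("H", heavy), ("L", light)]
        else:
            chains = [("H", heavy)]
        out = np.asarray(backend.embed(chains, marked=marked), dtype=float)
        if out.shape != (n_total, backend.dimension):
            raise ContractViolationError(
                f"backend {backend.name!r} returned shape {out.shape}, "
                f"expected {(n_total, backend.dimension)}"
            )
        if not np.isfinite(out).all():
            raise ContractViolationError(
                f"backend {backend.name!r} returned non-finite values"
            )
        blocks.append(out)
        block_index[backend.name] = (offset, offset + backend.dimension)
        offset += backend.dimension

    return FeatureMatrix(
        values=np.hstack(blocks),
        block_index=block_index,
        mode=mode,
        chain_tags=tags,
        n_heavy=n_heavy,
    )


@dataclass
class ContractReport:
    backend_name: str
    passed: bool
    failures: list[str]


def adapter_contract_check(
    backend: EmbeddingBackend,
    test_sequence: str = "QVQLVQSGAEVKKPGA",
) -> ContractReport:
    """Verify a backend honours the embedding contract: correct row count,
    declared dimension, determinism on repeat, and finite values."""
    failures = []
    chains = [("H", test_sequence)]
    try:
        out1 = np.asarray(backend.embed(chains))
        out2 = np.asarray(backend.embed(chains))
    except Exception as exc:  # noqa: BLE001 - report, don't crash
        return ContractReport(backend.name, False, [f"embed raised: {exc!r}"])
    if out1.ndim != 2 or out1.shape[0] != len(test_sequence):
        failures.append(
            f"row-count: expected {len(test_sequence)} rows, got shape {out1.shape}"
        )
    if out1.ndim == 2 and out1.shape[1] != backend.dimension:
        failures.append(
            f"dimension: declared {backend.dimension}, got {out1.shape[1]}"
        )
    if not np.isfinite(out1).all():
        failures.append("finiteness: output contains NaN or inf")
    if out1.shape == out2.shape and not np.array_equal(out1, out2):
        failures.append("determinism: repeated calls differ")
    return ContractReport(backend.name, not failures, failures)


def parse_backend_spec(spec: str, seed: int = 0) -> list[SyntheticBackend]:
    """Parse ``"name:dim,name:dim"`` CLI syntax into synthetic backends."""
    backends = []
    for part in spec.split(","):
        name, _, dim = part.strip().partition(":")
        if not name or not dim.isdigit():
            raise ValueError(f"bad backend spec {part!r}; expected name:dim")
        backends.append(SyntheticBackend(name, int(dim), seed=seed))
    return backends
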