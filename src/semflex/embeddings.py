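"""Word-embedding spaces and per-token weight tables.

The scoring pipeline represents every free-text response as a weighted
average of word vectors drawn from a fixed semantic space.  This module
loads such spaces from the plain-text GloVe format (``token v1 ... vd``,
one record per line), synthesizes small planted-cluster spaces for
testing and simulation, and handles the optional term-weight table that
down-weights frequent words before averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingModel",
    "WeightTable",
    "ToyEmbeddingConfig",
    "MalformedEmbeddingError",
    "load_embeddings",
    "save_embeddings",
    "make_toy_embeddings",
    "load_term_weights",
    "save_term_weights",
]


class MalformedEmbeddingError(ValueError):
    """Raised when an embedding file violates the one-token-plus-d-floats format."""


@dataclass
class EmbeddingModel:
    """A token -> vector map with a fixed dimension.

    Vectors are read-only downstream: scoring never mutates the space.
    Lookup lower-cases the query first and falls back to the raw form,
    since distributed GloVe vocabularies are predominantly lower-case
    while divergent-thinking responses are free text.
    """

    vectors: dict[str, np.ndarray]
    dimension: int
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.vectors:
            raise ValueError("embedding model must contain at least one token")
        for tok, vec in self.vectors.items():
            if vec.shape != (self.dimension,):
                raise ValueError(
                    f"token {tok!r} has {vec.shape[0]} components, expected {self.dimension}"
                )
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"token {tok!r} has non-finite components")
            if not np.any(vec):
                raise ValueError(f"token {tok!r} maps to the all-zero vector")

    @property
    def vocabulary(self) -> set[str]:
        return set(self.vectors)

    def __len__(self) -> int:
        return len(self.vectors)

    def __contains__(self, token: str) -> bool:
        return self.lookup(token) is not None

    def lookup(self, token: str) -> np.ndarray | None:
        """Return the vector for ``token`` (lower-cased first, raw as fallback)."""
        vec = self.vectors.get(token.lower())
        if vec is None:
            vec = self.vectors.get(token)
        return vec


@dataclass
class WeightTable:
    """Non-negative multiplicative term weights applied before averaging.

    Tokens absent from the table receive ``default_weight``.  A uniform
    table (the default) makes weighting a no-op, since the response
    vector is a *normalized* weighted mean.
    """

    weights: dict[str, float] = field(default_factory=dict)
    default_weight: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.default_weight) and self.default_weight > 0):
            raise ValueError("default_weight must be finite and > 0")
        for tok, w in self.weights.items():
            if not (np.isfinite(w) and w >= 0):
                raise ValueError(f"weight for {tok!r} must be finite and >= 0, got {w}")

    def lookup(self, token: str) -> float:
        return self.weights.get(token, self.default_weight)


@dataclass(frozen=True)
class ToyEmbeddingConfig:
    """Geometry of a synthetic planted-cluster embedding space.

    ``within_cluster_spread`` (in the open interval (0, 1)) scales the
    isotropic noise added to each cluster centroid before re-normalizing
    to unit length; small values give tight clusters whose within-cluster
    cosine similarity clearly exceeds the between-cluster similarity.
    """

    n_clusters: int = 2
    tokens_per_cluster: int = 5
    dimension: int = 8
    within_cluster_spread: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.tokens_per_cluster < 1:
            raise ValueError("tokens_per_cluster must be >= 1")
        if self.dimension < 2:
            raise ValueError("dimension must be >= 2")
        if not (0 < self.within_cluster_spread < 1):
            raise ValueError("within_cluster_spread must lie in (0, 1)")


def _parse_line(line: str, lineno: int) -> tuple[str, np.ndarray]:
    parts = line.split()
    token = parts[0]
    try:
        vec = np.asarray([float(x) for x in parts[1:]], dtype=float)
    except ValueError as exc:
        raise MalformedEmbeddingError(f"line {lineno}: non-numeric vector component") from exc
    return token, vec


def load_embeddings(path: str | Path, expected_dimension: int | None = None) -> EmbeddingModel:
    """Load a whitespace-delimited GloVe-format embedding file.

    A leading header line of exactly two integer fields (token count and
    dimension, as written by some tools) is detected and skipped.
    Duplicate tokens keep the first occurrence; all-zero vectors are
    dropped; both are logged.
    """
    path = Path(path)
    vectors: dict[str, np.ndarray] = {}
    dimension: int | None = None
    n_dupe = n_zero = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split()
            if lineno == 1 and len(parts) == 2:
                try:
                    int(parts[0]), int(parts[1])
                    continue  # header line
                except ValueError:
                    pass
            token, vec = _parse_line(line, lineno)
            if dimension is None:
                dimension = vec.shape[0]
                if dimension == 0:
                    raise MalformedEmbeddingError(f"line {lineno}: token with no vector components")
            elif vec.shape[0] != dimension:
                raise MalformedEmbeddingError(
                    f"line {lineno}: expected {dimension} components, found {vec.shape[0]}"
                )
            if not np.all(np.isfinite(vec)):
                raise MalformedEmbeddingError(f"line {lineno}: non-finite vector component")
            if token in vectors:
                n_dupe += 1
                continue
            if not np.any(vec):
                n_zero += 1
                continue
            vectors[token] = vec
    if dimension is None or not vectors:
        raise MalformedEmbeddingError(f"{path}: empty embedding file")
    if expected_dimension is not None and dimension != expected_dimension:
        raise MalformedEmbeddingError(
            f"{path}: dimension {dimension} does not match expected {expected_dimension}"
        )
    if n_dupe:
        logger.warning("%s: kept first occurrence of %d duplicated token(s)", path, n_dupe)
    if n_zero:
        logger.warning("%s: dropped %d all-zero vector(s)", path, n_zero)
    return EmbeddingModel(vectors=vectors, dimension=dimension, source_tag=str(path))


def save_embeddings(model: EmbeddingModel, path: str | Path) -> None:
    """Write a model back out in the same single-space-separated text format."""
    with open(path, "w", encoding="utf-8") as fh:
        for token, vec in model.vectors.items():
            fh.write(token + " " + " ".join(repr(float(x)) for x in vec) + "\n")


def make_toy_embeddings(config: ToyEmbeddingConfig) -> EmbeddingModel:
    """Generate a deterministic planted-cluster space.

    Tokens are named ``c{cluster}_t{index}``.  Cluster centroids are
    orthonormal when the dimension allows (guaranteeing separation);
    token vectors are unit-norm perturbations of their centroid.
    """
    rng = np.random.default_rng(config.seed)
    k, d = config.n_clusters, config.dimension
    if k <= d:
        basis, _ = np.linalg.qr(rng.standard_normal((d, k)))
        centroids = basis.T
    else:
        centroids = rng.standard_normal((k, d))
        centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    vectors: dict[str, np.ndarray] = {}
    for c in range(k):
        for t in range(config.tokens_per_cluster):
            v = centroids[c] + config.within_cluster_spread * rng.standard_normal(d)
            norm = np.linalg.norm(v)
            if norm == 0:  # pragma: no cover - measure-zero event
                v = centroids[c]
                norm = 1.0
            vectors[f"c{c}_t{t}"] = v / norm
    return EmbeddingModel(
        vectors=vectors, dimension=d, source_tag=f"toy(seed={config.seed}, k={k}, d={d})"
    )


def cluster_of(token: str) -> int:
    """Cluster index encoded in a toy-space token name ``c{cluster}_t{index}``."""
    return int(token.split("_")[0][1:])


def load_term_weights(path: str | Path | None = None, default_weight: float = 1.0) -> WeightTable:
    """Parse a ``token,weight`` CSV into a :class:`WeightTable`.

    With no path, returns the uniform table (every token weight 1), under
    which weighting is a documented no-op.
    """
    if path is None:
        return WeightTable(default_weight=default_weight)
    weights: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != 2:
                raise ValueError(f"{path}, row {lineno}: expected 'token,weight', got {line!r}")
            token, text = fields[0].strip(), fields[1].strip()
            try:
                w = float(text)
            except ValueError as exc:
                raise ValueError(f"{path}, row {lineno}: non-numeric weight {text!r}") from exc
            if not (np.isfinite(w) and w >= 0):
                raise ValueError(f"{path}, row {lineno}: weight must be finite and >= 0")
            weights[token] = w
    return WeightTable(weights=weights, default_weight=default_weight)


def save_term_weights(table: WeightTable | Mapping[str, float], path: str | Path) -> None:
    weights = table.weights if isinstance(table, WeightTable) else dict(table)
    with open(path, "w", encoding="utf-8") as fh:
        for token, w in weights.items():
            fh.write(f"{token},{w!r}\n")
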