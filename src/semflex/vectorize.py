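"""Turning one free-text response into a single semantic vector.

A response ("musical instrument", "hold flowers in it") is tokenized,
stoplisted, and mapped into the embedding space as the weighted
arithmetic mean of its surviving in-vocabulary word vectors.  Responses
whose every token is stoplisted or out-of-vocabulary yield an explicit
*undefined* vector — never a zero vector, which would fabricate extreme
cosine distances downstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .embeddings import EmbeddingModel, WeightTable

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseRecord",
    "ResponseVector",
    "DEFAULT_STOPLIST",
    "tokenize",
    "load_stoplist",
    "vectorize_response",
]

# Small English function-word list; overridable via a stoplist file.
DEFAULT_STOPLIST: frozenset[str] = frozenset(
    """
    a about above after again all also am an and any are as at be because been
    before being below between both but by can could did do does doing down
    during each few for from further had has have having he her here hers him
    his how i if in into is it its itself just me more most my myself no nor
    not now of off on once only or other our ours out over own same she should
    so some such than that the their theirs them then there these they this
    those through to too under until up very was we were what when where which
    while who whom why will with would you your yours
    """.split()
)

# Underscore is word-internal (identifier-style tokens survive intact);
# hyphens, apostrophes and all other punctuation separate.
_TOKEN_RE = re.compile(r"[a-z0-9_]+")


@dataclass(frozen=True)
class ResponseRecord:
    """One ordered free-text answer by one participant to one prompt."""

    participant_id: str
    item_id: str
    order_index: int
    text: str


@dataclass
class ResponseVector:
    """A response's position in semantic space, or an explicit undefined state.

    ``vector`` is ``None`` iff no token survived stoplisting and
    vocabulary lookup (or the surviving weights summed to zero); the drop
    counters make the failure auditable.
    """

    vector: np.ndarray | None
    tokens_used: int = 0
    tokens_dropped_stoplist: int = 0
    tokens_dropped_oov: int = 0

    @property
    def defined(self) -> bool:
        return self.vector is not None


def tokenize(text: str) -> list[str]:
    """Lower-case and split on runs of non-alphanumeric characters.

    Hyphens and apostrophes act as separators; digit runs are kept as
    tokens.  Total function: any input yields a (possibly empty) list.
    """
    return _TOKEN_RE.findall(text.lower())


def load_stoplist(path: str | Path | None = None) -> frozenset[str]:
    """Read a one-token-per-line stoplist file (``#`` comments allowed).

    Without a path, returns the bundled English function-word list.
    """
    if path is None:
        return DEFAULT_STOPLIST
    tokens: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                tokens.add(line.lower())
    return frozenset(tokens)


def vectorize_response(
    text: str,
    model: EmbeddingModel,
    weights: WeightTable | None = None,
    stoplist: Iterable[str] | None = None,
) -> ResponseVector:
    """Weighted mean of in-vocabulary token vectors after stoplisting.

    The result equals ``sum(w(t) * v(t)) / sum(w(t))`` over surviving
    tokens, so it is invariant to token order and to rescaling all
    weights by a constant.  With a single surviving token and uniform
    weights it is that token's embedding exactly.
    """
    if weights is None:
        weights = WeightTable()
    stopset = DEFAULT_STOPLIST if stoplist is None else frozenset(t.lower() for t in stoplist)

    n_stop = n_oov = 0
    acc = np.zeros(model.dimension)
    total_weight = 0.0
    n_used = 0
    for token in tokenize(text):
        if token in stopset:
            n_stop += 1
            continue
        vec = model.lookup(token)
        if vec is None:
            n_oov += 1
            continue
        w = weights.lookup(token)
        acc += w * vec
        total_weight += w
        n_used += 1

    if n_used == 0:
        return ResponseVector(None, 0, n_stop, n_oov)
    if total_weight == 0:
        logger.warning("response %r: surviving token weights sum to zero; vector undefined", text)
        return ResponseVector(None, 0, n_stop, n_oov)
    mean = acc / total_weight
    if not np.any(mean):
        # opposed vectors can cancel exactly; a zero vector has no direction
        logger.warning("response %r: token vectors cancel to zero; vector undefined", text)
        return ResponseVector(None, 0, n_stop, n_oov)
    return ResponseVector(mean, n_used, n_stop, n_oov)
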