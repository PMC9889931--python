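"""Seeded fixture generators with known ground truth.

Two generators cover the two halves of the package.
``simulate_responses`` emulates the structure of verbal
divergent-thinking data: each participant produces an ordered sequence
of responses per prompt, drawn as a random walk over the planted
clusters of a toy embedding space — the next response stays in the
current semantic cluster with probability ``1 - switch_probability``,
else jumps to a uniformly chosen other cluster.  Higher switch
probability therefore yields higher flexibility by construction.
``simulate_factor_data`` draws indicator data from a known factor model
(Lambda Phi Lambda' + Theta), the ground truth for the CFA and
reliability recovery tests.

All randomness flows from one seed through named sub-streams (fluency
draws, cluster walk, token choice, noise), so adding a stream never
shifts the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .embeddings import EmbeddingModel, ToyEmbeddingConfig, cluster_of, make_toy_embeddings

__all__ = [
    "IdeationSimConfig",
    "FactorSimConfig",
    "simulate_responses",
    "simulate_factor_data",
]

_STREAMS = ("fluency", "walk", "token", "noise")


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


@dataclass(frozen=True)
class IdeationSimConfig:
    """Conditions for a simulated divergent-thinking study.

    Defaults mirror a ten-prompt battery with per-item response counts
    in the single-digit range typical of timed verbal tasks, and a
    moderate cluster-switching rate.
    """

    embedding: ToyEmbeddingConfig = field(
        default_factory=lambda: ToyEmbeddingConfig(
            n_clusters=5, tokens_per_cluster=20, dimension=50, within_cluster_spread=0.2, seed=0
        )
    )
    n_participants: int = 200
    items: tuple[str, ...] = ()  # default: first token of each cluster
    fluency_min: int = 3
    fluency_max: int = 12
    switch_probability: float = 0.5
    tokens_per_response: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not (1 <= self.fluency_min <= self.fluency_max):
            raise ValueError("need 1 <= fluency_min <= fluency_max")
        if not (0.0 <= self.switch_probability <= 1.0):
            raise ValueError("switch_probability must lie in [0, 1]")
        if self.tokens_per_response not in (1, 2):
            raise ValueError("tokens_per_response must be 1 or 2")


def simulate_responses(
    config: IdeationSimConfig, model: EmbeddingModel | None = None
) -> pd.DataFrame:
    """Generate a response table (participant_id,item_id,order_index,response).

    ``model`` is the toy space generated from ``config.embedding`` (built
    here when omitted; pass it in to avoid rebuilding).  Items default
    to the first token of each of up to ten clusters and must belong to
    the toy vocabulary.  Responses are toy-vocabulary tokens, so their
    cluster membership is exactly known; with ``tokens_per_response=2``
    each response is two tokens from the same cluster, exercising
    multiword averaging.
    """
    if model is None:
        model = make_toy_embeddings(config.embedding)
    vocab = model.vocabulary
    k = config.embedding.n_clusters
    items = config.items or tuple(
        f"c{c}_t0" for c in range(min(k, 10))
    )
    unknown = [it for it in items if it not in vocab]
    if unknown:
        raise ValueError(f"item prompt(s) outside the toy vocabulary: {unknown}")

    rngs = _substreams(config.seed)
    tpc = config.embedding.tokens_per_cluster
    rows: list[tuple[str, str, int, str]] = []
    for p in range(config.n_participants):
        pid = f"p{p:04d}"
        for item in items:
            fluency = int(
                rngs["fluency"].integers(config.fluency_min, config.fluency_max + 1)
            )
            cluster = int(rngs["walk"].integers(k))
            for order in range(1, fluency + 1):
                if order > 1 and k > 1 and rngs["walk"].random() < config.switch_probability:
                    step = int(rngs["walk"].integers(1, k))
                    cluster = (cluster + step) % k
                toks = [
                    f"c{cluster}_t{int(rngs['token'].integers(tpc))}"
                    for _ in range(config.tokens_per_response)
                ]
                rows.append((pid, item, order, " ".join(toks)))
    return pd.DataFrame(rows, columns=["participant_id", "item_id", "order_index", "response"])


def realized_switch_rate(responses: pd.DataFrame) -> float:
    """Fraction of consecutive response pairs that changed cluster.

    Only meaningful for single-token toy responses; multi-token
    responses use their first token's cluster.
    """
    n_switch = n_pairs = 0
    for _, group in responses.groupby(["participant_id", "item_id"], sort=False):
        clusters = [
            cluster_of(text.split()[0]) for text in group.sort_values("order_index")["response"]
        ]
        for a, b in zip(clusters, clusters[1:]):
            n_pairs += 1
            n_switch += a != b
    if n_pairs == 0:
        raise ValueError("no consecutive pairs in the response table")
    return n_switch / n_pairs


@dataclass(frozen=True)
class FactorSimConfig:
    """Ground-truth factor model for multivariate indicator data.

    ``loadings`` maps each variable to its (factor, loading) — one
    factor per variable.  Residual variances default to 1 - loading^2 so
    indicators have unit variance; ``residual_pairs`` plants residual
    covariances between named variable pairs.
    """

    loadings: dict[str, tuple[str, float]]
    factor_correlations: dict[tuple[str, str], float] = field(default_factory=dict)
    residual_pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    n: int = 1000
    seed: int = 0

    def factor_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for fac, _ in self.loadings.values():
            seen.setdefault(fac)
        return list(seen)

    def implied_covariance(self) -> pd.DataFrame:
        variables = list(self.loadings)
        factors = self.factor_names()
        fix = {f: i for i, f in enumerate(factors)}
        vix = {v: i for i, v in enumerate(variables)}
        lam = np.zeros((len(variables), len(factors)))
        for v, (fac, val) in self.loadings.items():
            lam[vix[v], fix[fac]] = val
        phi = np.eye(len(factors))
        for (a, b), r in self.factor_correlations.items():
            phi[fix[a], fix[b]] = phi[fix[b], fix[a]] = r
        communality = np.sum(lam * (lam @ phi), axis=1)  # diag of Lambda Phi Lambda'
        theta = np.diag(1.0 - communality)
        for (a, b), val in self.residual_pairs.items():
            theta[vix[a], vix[b]] = theta[vix[b], vix[a]] = val
        sigma = lam @ phi @ lam.T + theta
        return pd.DataFrame(sigma, index=variables, columns=variables)


def simulate_factor_data(config: FactorSimConfig) -> pd.DataFrame:
    """Draw ``n`` multivariate-normal rows from the implied covariance."""
    sigma = config.implied_covariance()
    vals = np.linalg.eigvalsh(sigma.to_numpy())
    if vals.min() <= 1e-10:
        raise ValueError(
            f"implied covariance is not positive definite (min eigenvalue {vals.min():.3g})"
        )
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    chol = np.linalg.cholesky(sigma.to_numpy())
    data = rng.standard_normal((config.n, len(sigma))) @ chol.T
    return pd.DataFrame(data, columns=list(sigma.columns))
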