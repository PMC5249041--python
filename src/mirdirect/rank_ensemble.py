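"""Inverse-rank-product aggregation of association networks.

Different estimators (and different bootstrap replicates) produce weights on
incomparable scales, so networks are combined on ranks rather than raw
values: each network's bipartite miRNA×mRNA weights are ranked (rank 1 =
strongest, ties get the average of their covered positions) and the
aggregate weight of a pair across a set of networks G is

    r'_ij = 1 / log( Π_{m in G} (r_ij^m + 1) )

with the natural log.  Higher weight = stronger consensus association.
Since every rank is ≥ 1, the product is ≥ 2^|G| and the weight lies in
(0, 1/log 2].
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .estimators import ScoreMatrix, _jsonable

logger = logging.getLogger(__name__)


@dataclass
class RankMatrix:
    """Ranks of bipartite miRNA×mRNA association weights (1 = strongest)."""

    ranks: np.ndarray
    mirna_ids: list[str]
    mrna_ids: list[str]

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=float)
        if self.ranks.shape != (len(self.mirna_ids), len(self.mrna_ids)):
            raise ValueError("rank matrix shape does not match id lists")
        k = self.ranks.size
        if k and (self.ranks.min() < 1.0
                  or abs(self.ranks.sum() - k * (k + 1) / 2.0) > 1e-6):
            raise ValueError("ranks must be an average-tie ranking of 1..K")


@dataclass
class AggregatedScores:
    """Inverse-rank-product weights over the bipartite miRNA×mRNA pairs."""

    weights: np.ndarray
    mirna_ids: list[str]
    mrna_ids: list[str]
    source_count: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.mirna_ids), len(self.mrna_ids)):
            raise ValueError("weight matrix shape does not match id lists")
        if self.weights.size and not (np.isfinite(self.weights).all()
                                      and (self.weights > 0).all()):
            raise ValueError("aggregated weights must be positive and finite")

    def save(self, path) -> None:
        """Write a TSV weight matrix plus a JSON metadata sidecar."""
        pd.DataFrame(
            self.weights, index=self.mirna_ids, columns=self.mrna_ids
        ).to_csv(path, sep="\t")
        sidecar = {"source_count": self.source_count,
                   "metadata": _jsonable(self.metadata)}
        Path(f"{path}.meta.json").write_text(json.dumps(sidecar, indent=2))


def load_aggregated(path) -> AggregatedScores:
    df = pd.read_csv(path, sep="\t", index_col=0)
    sidecar = json.loads(Path(f"{path}.meta.json").read_text())
    return AggregatedScores(
        weights=df.to_numpy(),
        mirna_ids=[str(i) for i in df.index],
        mrna_ids=[str(c) for c in df.columns],
        source_count=sidecar["source_count"],
        metadata=sidecar.get("metadata", {}),
    )


def _rank_block(block: np.ndarray, signed: bool = False) -> np.ndarray:
    """Rank a weight block, 1 = strongest, average ties.

    By default strength is |weight| (miRNA repression makes strong
    associations negative); ``signed=True`` ranks most-negative first.
    """
    key = block.ravel() if signed else -np.abs(block.ravel())
    return rankdata(key, method="average").reshape(block.shape)


def to_ranks(
    s: ScoreMatrix,
    mirna_ids: list[str] | None = None,
    mrna_ids: list[str] | None = None,
    signed: bool = False,
) -> RankMatrix:
    """Extract the bipartite miRNA×mRNA block of a score matrix and rank it.

    Exact zeros (SPACE drop-outs) all share the worst average rank.
    """
    mirna_ids = list(mirna_ids) if mirna_ids is not None else s.mirna_ids
    mrna_ids = list(mrna_ids) if mrna_ids is not None else s.mrna_ids
    if not mirna_ids or not mrna_ids:
        raise ValueError("both miRNA and mRNA id sets must be non-empty")
    pos = {f: i for i, f in enumerate(s.feature_ids)}
    missing = [f for f in mirna_ids + mrna_ids if f not in pos]
    if missing:
        raise ValueError(f"ids absent from score matrix: {missing[:5]}")
    block = s.values[np.ix_([pos[m] for m in mirna_ids],
                            [pos[g] for g in mrna_ids])]
    return RankMatrix(_rank_block(block, signed=signed), mirna_ids, mrna_ids)


def inverse_rank_product(networks: list[RankMatrix]) -> AggregatedScores:
    """Aggregate rank matrices: weight = 1 / Σ_m log(r_m + 1)."""
    if not networks:
        raise ValueError("need at least one network to aggregate")
    first = networks[0]
    for nw in networks[1:]:
        if nw.mirna_ids != first.mirna_ids or nw.mrna_ids != first.mrna_ids:
            diff = (set(nw.mirna_ids) ^ set(first.mirna_ids)) | (
                set(nw.mrna_ids) ^ set(first.mrna_ids))
            raise ValueError(
                "rank matrices cover different pairs; symmetric difference: "
                f"{sorted(diff)[:10]}" if diff else
                "rank matrices have differently ordered ids"
            )
    log_prod = np.zeros_like(first.ranks)
    for nw in networks:
        log_prod += np.log(nw.ranks + 1.0)
    return AggregatedScores(
        weights=1.0 / log_prod,
        mirna_ids=first.mirna_ids,
        mrna_ids=first.mrna_ids,
        source_count=len(networks),
    )


def ensemble(
    methods: list[AggregatedScores | ScoreMatrix], signed: bool = False
) -> AggregatedScores:
    """Combine ≥2 networks (estimator outputs or bootstrap aggregates).

    Each input is re-ranked on its bipartite block — aggregated weights by
    descending weight, score matrices by the :func:`to_ranks` rule — and the
    rankings fused by the inverse rank product.  Supports any method subset
    (pairwise combinations or all three estimators).
    """
    if len(methods) < 2:
        raise ValueError("ensemble needs at least two input networks")
    rank_matrices = []
    labels = []
    for m in methods:
        if isinstance(m, AggregatedScores):
            rank_matrices.append(
                RankMatrix(_rank_block(m.weights, signed=False),
                           m.mirna_ids, m.mrna_ids))
            labels.append(m.metadata.get("estimator", "aggregate"))
        elif isinstance(m, ScoreMatrix):
            rank_matrices.append(to_ranks(m, signed=signed))
            labels.append(m.metadata.get("estimator", "scores"))
        elif isinstance(m, RankMatrix):
            rank_matrices.append(m)
            labels.append("ranks")
        else:
            raise TypeError(f"cannot ensemble object of type {type(m).__name__}")
    out = inverse_rank_product(rank_matrices)
    out.metadata["sources"] = labels
    logger.info("ensemble of %d networks: %s", len(labels), "&".join(labels))
    return out
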