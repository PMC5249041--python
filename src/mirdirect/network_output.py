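"""Edge extraction and Cytoscape-compatible export.

Aggregated bipartite weights are turned into (a) a global top-N edge list
for network reconstruction and (b) per-miRNA top-k target lists for the
overlap-precision evaluation.  Ties are broken lexicographically by
(miRNA id, mRNA id) so output is reproducible across runs and platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import pandas as pd

from .rank_ensemble import AggregatedScores

logger = logging.getLogger(__name__)


class Edge(NamedTuple):
    mirna: str
    mrna: str
    weight: float
    rank: int


@dataclass
class EdgeList:
    """Ranked miRNA–mRNA pairs, strongest first, global ranks from 1."""

    edges: list[Edge]

    def __post_init__(self) -> None:
        for pos, e in enumerate(self.edges, start=1):
            if e.rank != pos:
                raise ValueError("edge ranks must be consecutive from 1")
            if pos > 1 and e.weight > self.edges[pos - 2].weight:
                raise ValueError("edges must be sorted by descending weight")
        if len({(e.mirna, e.mrna) for e in self.edges}) != len(self.edges):
            raise ValueError("duplicate pairs in edge list")

    def __len__(self) -> int:
        return len(self.edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["mirna", "mrna", "weight", "rank"])


def _sorted_pairs(a: AggregatedScores) -> list[tuple[str, str, float]]:
    pairs = [
        (mi, mr, float(a.weights[i, j]))
        for i, mi in enumerate(a.mirna_ids)
        for j, mr in enumerate(a.mrna_ids)
    ]
    pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
    return pairs


def top_n_edges(a: AggregatedScores, n: int) -> EdgeList:
    """The n highest-weight bipartite pairs with global ranks 1..n."""
    total = a.weights.size
    if not 1 <= n <= total:
        raise ValueError(f"n must lie in [1, {total}] (total pair count)")
    pairs = _sorted_pairs(a)
    if n < total and pairs[n - 1][2] == pairs[n][2]:
        logger.warning(
            "top_n_edges: weight tie at the n=%d boundary; lexicographically "
            "smaller pairs retained", n,
        )
    return EdgeList([Edge(mi, mr, w, r)
                     for r, (mi, mr, w) in enumerate(pairs[:n], start=1)])


def top_k_per_mirna(a: AggregatedScores, k: int) -> dict[str, list[str]]:
    """For each miRNA, its k best mRNAs by weight (tie rule as above)."""
    n_mrna = len(a.mrna_ids)
    if not 1 <= k <= n_mrna:
        raise ValueError(f"k must lie in [1, {n_mrna}] (mRNA count)")
    out: dict[str, list[str]] = {}
    for i, mi in enumerate(a.mirna_ids):
        row = sorted(
            zip(a.mrna_ids, a.weights[i]), key=lambda t: (-t[1], t[0])
        )
        out[mi] = [mr for mr, _ in row[:k]]
    return out


def export_edges(e: EdgeList, path, format: str = "tsv") -> None:
    """Write the edge list as TSV or Cytoscape SIF (``associates`` edges)."""
    if format not in ("tsv", "sif"):
        raise ValueError("format must be 'tsv' or 'sif'")
    if not e.edges:
        logger.warning("exporting an empty edge list to %s", path)
    with open(path, "w", encoding="utf-8") as fh:
        if format == "tsv":
            fh.write("mirna\tmrna\tweight\trank\n")
            for edge in e.edges:
                fh.write(f"{edge.mirna}\t{edge.mrna}\t{edge.weight:.12g}\t{edge.rank}\n")
        else:
            for edge in e.edges:
                fh.write(f"{edge.mirna} associates {edge.mrna}\n")


def read_edges(path, format: str = "tsv") -> EdgeList:
    """Parse an exported edge list back (SIF loses weights/ranks)."""
    edges: list[Edge] = []
    with open(path, encoding="utf-8") as fh:
        if format == "tsv":
            header = fh.readline()
            if not header.startswith("mirna\t"):
                raise ValueError(f"{path}: not an edge-list TSV")
            for line in fh:
                mi, mr, w, r = line.rstrip("\n").split("\t")
                edges.append(Edge(mi, mr, float(w), int(r)))
        elif format == "sif":
            for rank, line in enumerate(fh, start=1):
                parts = line.split()
                if len(parts) != 3 or parts[1] != "associates":
                    raise ValueError(f"{path}: malformed SIF line {rank}")
                edges.append(Edge(parts[0], parts[2], 0.0, rank))
        else:
            raise ValueError("format must be 'tsv' or 'sif'")
    if format == "sif":
        return EdgeList(edges=[Edge(e.mirna, e.mrna, float(-e.rank), e.rank)
                               for e in edges])
    return EdgeList(edges)


def write_top_k(predictions: dict[str, list[str]], path) -> None:
    """Serialize per-miRNA ordered target lists (mirna, local rank, mrna)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mirna\trank\tmrna\n")
        for mi, targets in predictions.items():
            for r, mr in enumerate(targets, start=1):
                fh.write(f"{mi}\t{r}\t{mr}\n")


def read_top_k(path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("mirna\t"):
            raise ValueError(f"{path}: not a top-k prediction TSV")
        for line in fh:
            mi, _r, mr = line.rstrip("\n").split("\t")
            out.setdefault(mi, []).append(mr)
    return out
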