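"""Synthetic matched miRNA/mRNA data from a known Gaussian graphical model.

The generator draws samples from a multivariate normal whose precision
matrix encodes a sparse *bipartite* direct-association graph: a chosen
number of miRNA–mRNA pairs receive nonzero partial correlations, all other
conditional dependencies are exactly zero.  Inverting the precision matrix
couples every connected pair marginally, so the sampled data contain the
transitive (indirect) correlations that direct-association estimators must
suppress — which is exactly what makes the dataset a useful benchmark: the
set of direct edges is known, and so is the set of purely transitive pairs.

The GGM is the model class under which "direct association" is
well-defined (a nonzero precision entry), which is why data are generated
this way rather than from a mechanistic miRNA kinetics model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import (
    MIRNA,
    MRNA,
    ExpressionMatrix,
    GroundTruth,
    write_expression,
    write_ground_truth,
)

logger = logging.getLogger(__name__)

# keep the loaded precision matrix comfortably positive definite
_MIN_EIGENVALUE = 0.05


@dataclass
class SyntheticSpec:
    """Parameters of the generating graphical model.

    ``edge_weight_range`` gives the magnitude interval of the direct-edge
    partial correlations; signs are random unless ``repressive`` forces
    them negative (miRNAs repress their targets).  ``noise_sd`` adds
    independent observation noise on top of the GGM draw.
    """

    n_mirna: int
    n_mrna: int
    n_direct_edges: int
    n_samples: int
    edge_weight_range: tuple[float, float] = (0.25, 0.4)
    noise_sd: float = 0.0
    repressive: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirna < 1 or self.n_mrna < 1:
            raise ValueError("need at least one miRNA and one mRNA")
        if not 0 <= self.n_direct_edges <= self.n_mirna * self.n_mrna:
            raise ValueError("n_direct_edges must fit the bipartite grid")
        if self.n_samples < 2:
            raise ValueError("need at least two samples")
        lo, hi = self.edge_weight_range
        if not 0 < lo <= hi < 1:
            raise ValueError("edge weights must satisfy 0 < lo <= hi < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix
    direct_edges: set[tuple[str, str]]
    truth: GroundTruth
    precision_matrix: np.ndarray = field(repr=False, default=None)


def _mirna_id(i: int) -> str:
    return f"miR-{i + 1:03d}"


def _gene_id(j: int) -> str:
    return f"gene-{j + 1:04d}"


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Sample a dataset from the bipartite GGM described by ``spec``.

    The precision matrix starts as the identity; each chosen bipartite
    edge (i, j) with target partial correlation v gets Ω_ij = −v.  If the
    smallest eigenvalue falls below a safety floor the matrix is diagonally
    loaded and renormalized to unit diagonal, which shrinks all realized
    partial correlations by a common factor (recorded in the log).  Samples
    are drawn from N(0, Ω⁻¹), plus optional white observation noise.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.n_mirna + spec.n_mrna
    flat = rng.choice(spec.n_mirna * spec.n_mrna, size=spec.n_direct_edges,
                      replace=False)
    lo, hi = spec.edge_weight_range
    mags = rng.uniform(lo, hi, size=spec.n_direct_edges)
    signs = (np.full(spec.n_direct_edges, -1.0) if spec.repressive
             else rng.choice([-1.0, 1.0], size=spec.n_direct_edges))
    omega = np.eye(p)
    edges: set[tuple[str, str]] = set()
    for f, mag, sign in zip(flat, mags, signs):
        i = int(f) // spec.n_mrna                 # miRNA index
        j = int(f) % spec.n_mrna                  # mRNA index
        v = sign * mag                            # target partial correlation
        omega[i, spec.n_mirna + j] = -v
        omega[spec.n_mirna + j, i] = -v
        edges.add((_mirna_id(i), _gene_id(j)))
    min_eig = float(np.linalg.eigvalsh(omega).min())
    if min_eig < _MIN_EIGENVALUE:
        c = _MIN_EIGENVALUE - min_eig
        if c > 1.0:
            raise ValueError(
                "cannot make the precision matrix positive definite without "
                "halving the requested edge weights; use smaller weights or "
                "fewer edges"
            )
        omega = (omega + c * np.eye(p)) / (1.0 + c)
        logger.info(
            "diagonal loading c=%.3f applied; realized partial correlations "
            "scaled by %.3f", c, 1.0 / (1.0 + c),
        )
    cov = np.linalg.inv(omega)
    chol = np.linalg.cholesky(cov)
    values = chol @ rng.standard_normal((p, spec.n_samples))
    if spec.noise_sd > 0:
        values = values + spec.noise_sd * rng.standard_normal(values.shape)
    x = ExpressionMatrix(
        values=values,
        feature_ids=[_mirna_id(i) for i in range(spec.n_mirna)]
        + [_gene_id(j) for j in range(spec.n_mrna)],
        feature_kind=[MIRNA] * spec.n_mirna + [MRNA] * spec.n_mrna,
        sample_ids=[f"S{k + 1:04d}" for k in range(spec.n_samples)],
    )
    truth = GroundTruth({})
    for mi, g in sorted(edges):
        truth.pairs.setdefault(mi, set()).add(g)
    return SyntheticDataset(expression=x, direct_edges=edges, truth=truth,
                            precision_matrix=omega)


def indirect_pairs(d: SyntheticDataset) -> set[tuple[str, str]]:
    """Bipartite pairs correlated only through transitive flow.

    A miRNA and an mRNA in a bipartite graph can never share a neighbor,
    so the shortest purely transitive route between a non-adjacent
    miRNA–mRNA pair has length 3 (miR–gene–miR–gene).  Returned are all
    non-edge bipartite pairs connected within at most two intermediate
    features, found by powering the adjacency matrix.
    """
    x = d.expression
    mirna_ids, mrna_ids = x.mirna_ids, x.mrna_ids
    n_mi = len(mirna_ids)
    p = n_mi + len(mrna_ids)
    a = np.zeros((p, p), dtype=bool)
    pos = {f: i for i, f in enumerate(mirna_ids + mrna_ids)}
    for mi, g in d.direct_edges:
        a[pos[mi], pos[g]] = True
        a[pos[g], pos[mi]] = True
    a2 = a @ a
    a3 = a2 @ a
    reachable = a | a2 | a3
    out: set[tuple[str, str]] = set()
    for mi in mirna_ids:
        for g in mrna_ids:
            i, j = pos[mi], pos[g]
            if reachable[i, j] and not a[i, j]:
                out.add((mi, g))
    return out


def save_dataset(d: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Write miRNA/mRNA expression TSVs and the ground-truth TSV.

    The files use the standard loader layouts, so the full pipeline runs on
    synthetic data unchanged.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    x = d.expression
    kinds = np.array(x.feature_kind)
    mi_rows = np.where(kinds == MIRNA)[0]
    mr_rows = np.where(kinds == MRNA)[0]
    paths = {
        "mirna": out / "mirna_expression.tsv",
        "mrna": out / "mrna_expression.tsv",
        "truth": out / "ground_truth.tsv",
    }
    write_expression(
        ExpressionMatrix(x.values[mi_rows], [x.feature_ids[i] for i in mi_rows],
                         [MIRNA] * len(mi_rows), x.sample_ids),
        paths["mirna"],
    )
    write_expression(
        ExpressionMatrix(x.values[mr_rows], [x.feature_ids[i] for i in mr_rows],
                         [MRNA] * len(mr_rows), x.sample_ids),
        paths["mrna"],
    )
    write_ground_truth(d.truth, paths["truth"])
    return paths
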