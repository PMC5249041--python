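"""Containers and I/O for matched miRNA/mRNA expression profiles.

Expression data arrive as two tab-separated matrices (features in rows,
samples in columns) measured on the same biological samples, typically with
many more features than samples.  Downstream estimators operate on a single
row-standardized matrix in which every feature is tagged with its kind
(miRNA or mRNA), so the loaders here are strict: duplicate identifiers,
missing values and constant features are rejected up front rather than
silently propagated into the correlation machinery.

Ground truth — the set of validated miRNA→target-gene pairs used for
precision evaluation — is a plain two-column TSV mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIRNA = "MIRNA"
MRNA = "MRNA"
_VALID_KINDS = frozenset({MIRNA, MRNA})

# strings treated as an explicitly missing cell (as opposed to a typo)
_NA_STRINGS = frozenset({"", "na", "nan", "n/a", "null", "none"})


class ValidationError(ValueError):
    """Raised when an input matrix or pair list violates its contract."""


@dataclass
class ExpressionMatrix:
    """A features × samples expression matrix with per-feature kind labels.

    ``values[i, j]`` is the expression of feature ``feature_ids[i]`` in
    sample ``sample_ids[j]``.  ``feature_kind[i]`` is ``MIRNA`` or ``MRNA``.
    """

    values: np.ndarray
    feature_ids: list[str]
    feature_kind: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = list(self.feature_ids)
        self.feature_kind = list(self.feature_kind)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        p, n = self.values.shape
        if len(self.feature_ids) != p or len(self.feature_kind) != p:
            raise ValidationError(
                f"feature metadata length mismatch: {p} rows, "
                f"{len(self.feature_ids)} ids, {len(self.feature_kind)} kinds"
            )
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"sample id count {len(self.sample_ids)} != column count {n}"
            )
        dup = _duplicates(self.feature_ids)
        if dup:
            raise ValidationError(f"duplicate feature ids: {sorted(dup)}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ValidationError(f"duplicate sample ids: {sorted(dup)}")
        bad = set(self.feature_kind) - _VALID_KINDS
        if bad:
            raise ValidationError(f"unknown feature kinds: {sorted(bad)}")
        if not np.isfinite(self.values).all():
            fi, si = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                "non-finite value at feature "
                f"'{self.feature_ids[fi]}', sample '{self.sample_ids[si]}'"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def mirna_ids(self) -> list[str]:
        return [f for f, k in zip(self.feature_ids, self.feature_kind) if k == MIRNA]

    @property
    def mrna_ids(self) -> list[str]:
        return [f for f, k in zip(self.feature_ids, self.feature_kind) if k == MRNA]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for it in items:
        if it in seen:
            dup.add(it)
        seen.add(it)
    return dup


def load_expression(path, kind: str, impute: bool = False) -> ExpressionMatrix:
    """Read a TSV expression matrix (features in rows, samples in columns).

    Every feature is tagged with ``kind`` (``MIRNA`` or ``MRNA``).  Cells that
    cannot be parsed as numbers raise a :class:`ValidationError` naming the
    offending feature and sample; explicitly missing cells ("NA", empty, ...)
    are rejected unless ``impute`` is set, in which case they are replaced by
    the feature's mean over the observed samples.
    """
    if kind not in _VALID_KINDS:
        raise ValidationError(f"kind must be one of {sorted(_VALID_KINDS)}")
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed expression file {path}: {exc}") from exc
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate feature ids in {path}: {dup}")

    values = np.empty(raw.shape, dtype=float)
    str_values = raw.to_numpy()
    for i, fid in enumerate(raw.index):
        for j, sid in enumerate(raw.columns):
            cell = str_values[i, j]
            cell_str = "" if cell is None else str(cell).strip()
            if cell_str.lower() in _NA_STRINGS:
                if not impute:
                    raise ValidationError(
                        f"missing value at feature '{fid}', sample '{sid}' "
                        "(enable imputation or fix the input)"
                    )
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell_str)
            except ValueError as exc:
                raise ValidationError(
                    f"non-numeric cell '{cell_str}' at feature '{fid}', "
                    f"sample '{sid}'"
                ) from exc
    if impute:
        for i in range(values.shape[0]):
            row = values[i]
            mask = np.isnan(row)
            if mask.all():
                raise ValidationError(
                    f"feature '{raw.index[i]}' has no observed values to impute from"
                )
            if mask.any():
                row[mask] = row[~mask].mean()
                logger.info(
                    "imputed %d missing values for feature %s",
                    int(mask.sum()),
                    raw.index[i],
                )
    return ExpressionMatrix(
        values=values,
        feature_ids=[str(i) for i in raw.index],
        feature_kind=[kind] * raw.shape[0],
        sample_ids=[str(c) for c in raw.columns],
    )


def write_expression(x: ExpressionMatrix, path) -> None:
    """Write the matrix in the same TSV layout the loader expects."""
    x.to_frame().to_csv(path, sep="\t")


def integrate(mirna: ExpressionMatrix, mrna: ExpressionMatrix) -> ExpressionMatrix:
    """Row-stack matched miRNA and mRNA profiles over their shared samples.

    Sample columns are aligned by id (order follows the miRNA matrix); miRNA
    rows come first.  Feature ids must not collide across the two inputs —
    a collision would make ground-truth matching ambiguous, so it aborts.
    """
    collisions = set(mirna.feature_ids) & set(mrna.feature_ids)
    if collisions:
        raise ValidationError(
            "feature ids present in both the miRNA and mRNA matrices: "
            f"{sorted(collisions)[:5]}... — prefix ids to disambiguate kinds"
        )
    mrna_set = set(mrna.sample_ids)
    shared = [s for s in mirna.sample_ids if s in mrna_set]
    if not shared:
        raise ValidationError("the two matrices share no sample ids")
    dropped = (len(mirna.sample_ids) - len(shared), len(mrna.sample_ids) - len(shared))
    if any(dropped):
        logger.info("integrate: dropped %d miRNA / %d mRNA unmatched samples", *dropped)
    mi_cols = [mirna.sample_ids.index(s) for s in shared]
    mr_cols = [mrna.sample_ids.index(s) for s in shared]
    return ExpressionMatrix(
        values=np.vstack([mirna.values[:, mi_cols], mrna.values[:, mr_cols]]),
        feature_ids=mirna.feature_ids + mrna.feature_ids,
        feature_kind=mirna.feature_kind + mrna.feature_kind,
        sample_ids=shared,
    )


def standardize(x: ExpressionMatrix, mode: str = "per_feature") -> ExpressionMatrix:
    """Z-score the matrix (mean 0, sd 1 with the n−1 denominator).

    ``mode="per_feature"`` (default) standardizes each feature over the
    samples; ``mode="per_sample"`` standardizes each sample column instead.
    Constant rows (or columns) carry no correlation information and are
    rejected with an error listing the offending ids.
    """
    v = x.values
    if mode == "per_feature":
        mu = v.mean(axis=1, keepdims=True)
        sd = v.std(axis=1, ddof=1, keepdims=True)
        flat = np.where(sd.ravel() <= 1e-12)[0]
        if flat.size:
            ids = [x.feature_ids[i] for i in flat]
            raise ValidationError(f"constant feature rows cannot be standardized: {ids}")
    elif mode == "per_sample":
        mu = v.mean(axis=0, keepdims=True)
        sd = v.std(axis=0, ddof=1, keepdims=True)
        flat = np.where(sd.ravel() <= 1e-12)[0]
        if flat.size:
            ids = [x.sample_ids[i] for i in flat]
            raise ValidationError(f"constant sample columns cannot be standardized: {ids}")
    else:
        raise ValueError(f"unknown standardization mode '{mode}'")
    return ExpressionMatrix(
        values=(v - mu) / sd,
        feature_ids=x.feature_ids,
        feature_kind=x.feature_kind,
        sample_ids=x.sample_ids,
    )


@dataclass
class GroundTruth:
    """Validated miRNA → target-gene pairs for precision evaluation."""

    pairs: dict[str, set[str]] = field(default_factory=dict)

    def targets(self, mirna: str) -> set[str]:
        """Target set for ``mirna``; unknown miRNAs yield the empty set."""
        return self.pairs.get(mirna, set())

    @property
    def n_mirnas(self) -> int:
        return len(self.pairs)

    @property
    def n_genes(self) -> int:
        return len(set().union(*self.pairs.values())) if self.pairs else 0

    @property
    def n_pairs(self) -> int:
        return sum(len(t) for t in self.pairs.values())


def load_ground_truth(path, has_header: bool = False) -> GroundTruth:
    """Read a two-column ``miRNA<TAB>gene`` pair list; duplicates collapse."""
    pairs: dict[str, set[str]] = {}
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 and has_header:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValidationError(
                    f"{path}: line {lineno} has {len(cols)} columns, expected 2"
                )
            mirna, gene = cols[0].strip(), cols[1].strip()
            if not mirna or not gene:
                raise ValidationError(f"{path}: line {lineno} has an empty field")
            pairs.setdefault(mirna, set()).add(gene)
            n_rows += 1
    gt = GroundTruth(pairs)
    if not pairs:
        logger.warning("ground-truth file %s is empty", path)
    else:
        logger.info(
            "ground truth: %d rows -> %d unique pairs, %d miRNAs, %d genes",
            n_rows,
            gt.n_pairs,
            gt.n_mirnas,
            gt.n_genes,
        )
    return gt


def write_ground_truth(gt: GroundTruth, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for mirna in sorted(gt.pairs):
            for gene in sorted(gt.pairs[mirna]):
                fh.write(f"{mirna}\t{gene}\n")
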