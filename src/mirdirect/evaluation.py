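"""Overlap-precision scoring against a ground-truth pair list.

Validated miRNA→target databases are far from complete, so evaluation
counts, for each miRNA, how many of its top-k predicted mRNAs appear in the
ground truth.  Since every method predicts the same number of pairs, a
higher overlap count means higher precision.  Identifier matching is
exact-string after case-folding; optional stripping of mature-arm suffixes
(-3p/-5p) is off by default because silent fuzzy matching inflates scores.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .data_model import GroundTruth

logger = logging.getLogger(__name__)

_ARM_SUFFIX = re.compile(r"-(3p|5p)$", re.IGNORECASE)


@dataclass
class PrecisionReport:
    """Per-miRNA and total counts of ground-truth hits in the top-k lists."""

    total_overlap: int
    per_mirna: dict[str, int]
    k: int
    evaluated_mirnas: int
    mirnas_not_in_truth: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.total_overlap != sum(self.per_mirna.values()):
            raise ValueError("total_overlap must equal the per-miRNA sum")
        if any(not 0 <= c <= self.k for c in self.per_mirna.values()):
            raise ValueError("per-miRNA overlap must lie in [0, k]")


def _norm(identifier: str, fold_case: bool, strip_arm: bool) -> str:
    out = identifier.lower() if fold_case else identifier
    if strip_arm:
        out = _ARM_SUFFIX.sub("", out)
    return out


def overlap_precision(
    predictions: dict[str, list[str]],
    truth: GroundTruth,
    k: int,
    fold_case: bool = True,
    strip_arm_suffix: bool = False,
) -> PrecisionReport:
    """Count predicted targets confirmed by the ground truth.

    ``predictions`` maps each miRNA to its ordered top-k mRNA list (length
    ≤ k).  miRNAs absent from the truth contribute 0 and are listed in the
    report so both evaluation conventions (count-as-zero vs. exclude) can
    be derived.
    """
    too_long = [m for m, t in predictions.items() if len(t) > k]
    if too_long:
        raise ValueError(f"prediction lists longer than k={k}: {too_long[:5]}")
    if truth.n_pairs == 0:
        logger.warning("ground truth is empty; every overlap count is zero")
    truth_norm = {
        _norm(mi, fold_case, strip_arm_suffix): {
            _norm(g, fold_case, strip_arm=False) for g in targets
        }
        for mi, targets in truth.pairs.items()
    }
    per_mirna: dict[str, int] = {}
    missing: list[str] = []
    for mi, targets in predictions.items():
        key = _norm(mi, fold_case, strip_arm_suffix)
        true_targets = truth_norm.get(key)
        if true_targets is None:
            missing.append(mi)
            per_mirna[mi] = 0
            continue
        per_mirna[mi] = sum(
            1 for g in targets if _norm(g, fold_case, False) in true_targets
        )
    return PrecisionReport(
        total_overlap=sum(per_mirna.values()),
        per_mirna=per_mirna,
        k=k,
        evaluated_mirnas=len(predictions),
        mirnas_not_in_truth=missing,
    )


def compare_methods(
    reports: dict[str, PrecisionReport],
    ensembles: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Tabulate total overlap per method and flag ensemble behavior.

    ``ensembles`` optionally maps an ensemble label to its constituent
    labels; for each such ensemble the table attrs record whether it beat
    its worst constituent ("relief of the worst model") and all of them.
    """
    if not reports:
        raise ValueError("no reports to compare")
    ks = {r.k for r in reports.values()}
    if len(ks) > 1:
        raise ValueError(f"reports computed at different k: {sorted(ks)}")
    df = pd.DataFrame(
        [
            {
                "method": label,
                "k": r.k,
                "total_overlap": r.total_overlap,
                "evaluated_mirnas": r.evaluated_mirnas,
                "mirnas_in_truth": r.evaluated_mirnas - len(r.mirnas_not_in_truth),
            }
            for label, r in reports.items()
        ]
    )
    best = df.loc[df["total_overlap"].idxmax(), "method"]
    df.attrs["best_method"] = str(best)
    relief: dict[str, dict[str, bool]] = {}
    for ens, parts in (ensembles or {}).items():
        known = [p for p in parts if p in reports]
        if ens not in reports or not known:
            continue
        totals = [reports[p].total_overlap for p in known]
        relief[ens] = {
            "beats_worst_constituent": reports[ens].total_overlap > min(totals),
            "beats_all_constituents": reports[ens].total_overlap > max(totals),
        }
    df.attrs["ensemble_relief"] = relief
    return df


def write_comparison(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_per_mirna_detail(report: PrecisionReport, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mirna\toverlap\tin_truth\n")
        missing = set(report.mirnas_not_in_truth)
        for mi, count in report.per_mirna.items():
            fh.write(f"{mi}\t{count}\t{int(mi not in missing)}\n")
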