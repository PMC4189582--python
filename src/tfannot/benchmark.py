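"""Benchmarking a predicted annotation against a reference.

*Coverage* is the overlap (by protein id) between prediction and
reference; *classification accuracy* is the fraction of recovered
proteins whose predicted family corresponds to their reference family.
When the two annotations use different family nomenclatures, a
correspondence map (reference family → acceptable predicted families,
possibly many-to-one) mediates the comparison; reference entries whose
family has no correspondence are excluded from the accuracy denominator
and reported separately.

Two accuracy denominators are reported: the overlap set (headline) and
the full reference set (``accuracy_vs_reference``, which is bounded by
the coverage fraction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CorrespondenceMap",
    "BenchmarkReport",
    "evaluate",
    "missed_report",
]

MISS_TAGS = ("FD_veto", "below_cutoff", "no_hit", "other")


class CorrespondenceMap(dict):
    """reference family → set of corresponding predicted families."""

    def __init__(self, mapping: Mapping[str, Iterable[str]]):
        super().__init__()
        for ref_family, targets in mapping.items():
            targets = frozenset(targets)
            if not targets:
                raise ValueError(f"empty correspondence for family {ref_family!r}")
            self[ref_family] = targets

    def corresponds(self, reference_family: str, predicted_family: str) -> bool:
        return predicted_family in self.get(reference_family, frozenset())


@dataclass
class BenchmarkReport:
    n_reference: int
    n_predicted: int
    n_overlap: int
    n_correct_family: int
    n_excluded_by_map: int
    coverage_fraction: float
    accuracy_fraction: float  # denominator: mappable overlap
    accuracy_vs_reference: float  # denominator: mappable reference
    confusion: pd.DataFrame  # reference_family, predicted_family, count


def evaluate(
    predicted: Mapping[str, str],
    reference: Mapping[str, str],
    corr: CorrespondenceMap | None = None,
) -> BenchmarkReport:
    """Score a predicted annotation against a reference annotation.

    Both arguments map protein (or gene) id → family over a shared id
    space.  With ``corr=None`` families are compared by identity.
    Disjoint id sets simply give zero coverage.
    """
    overlap_ids = sorted(set(predicted) & set(reference))
    if corr is None:
        mappable_ref = set(reference)
    else:
        mappable_ref = {i for i, fam in reference.items() if fam in corr}
    mappable_overlap = [i for i in overlap_ids if i in mappable_ref]

    n_correct = 0
    confusion: dict[tuple[str, str], int] = {}
    for i in mappable_overlap:
        ref_fam, pred_fam = reference[i], predicted[i]
        correct = (
            corr.corresponds(ref_fam, pred_fam) if corr else pred_fam == ref_fam
        )
        n_correct += correct
        confusion[(ref_fam, pred_fam)] = confusion.get((ref_fam, pred_fam), 0) + 1

    confusion_df = pd.DataFrame(
        [
            {"reference_family": rf, "predicted_family": pf, "count": n}
            for (rf, pf), n in sorted(confusion.items())
        ],
        columns=["reference_family", "predicted_family", "count"],
    )
    n_ref = len(reference)
    return BenchmarkReport(
        n_reference=n_ref,
        n_predicted=len(predicted),
        n_overlap=len(overlap_ids),
        n_correct_family=n_correct,
        n_excluded_by_map=len(reference) - len(mappable_ref),
        coverage_fraction=len(overlap_ids) / n_ref if n_ref else 0.0,
        accuracy_fraction=(
            n_correct / len(mappable_overlap) if mappable_overlap else 0.0
        ),
        accuracy_vs_reference=(
            n_correct / len(mappable_ref) if mappable_ref else 0.0
        ),
        confusion=confusion_df,
    )


def missed_report(
    predicted: Mapping[str, str],
    reference: Mapping[str, str],
    reasons: Mapping[str, str] | None = None,
    scanned_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Tabulate reference entries the prediction did not recover.

    Each missed id gets a reason tag: a user-supplied tag from
    ``reasons`` (e.g. ``FD_veto`` for proteins rejected by a forbidden
    domain, ``below_cutoff`` for a best DBD hit under threshold), else
    ``no_hit`` when the id was not among the scanned inputs, else
    ``other``.
    """
    reasons = dict(reasons or {})
    scanned = set(scanned_ids) if scanned_ids is not None else None
    rows = []
    for i in sorted(set(reference) - set(predicted)):
        if i in reasons:
            tag = reasons[i]
        elif scanned is not None and i not in scanned:
            tag = "no_hit"
        else:
            tag = "other"
        rows.append({"id": i, "reference_family": reference[i], "reason": tag})
    return pd.DataFrame(rows, columns=["id", "reference_family", "reason"])
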