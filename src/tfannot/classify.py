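"""Family-assignment rule engine.

A protein's accepted domain profile is mapped to a TF family, a TC
family, or no call:

1. TF rules are evaluated first.  A rule fires when all of its required
   and auxiliary domains are present and none of its forbidden domains
   is (a forbidden domain *vetoes* the rule — a protein whose every
   DBD-bearing rule is vetoed gets no TF call).
2. Among firing rules the most specific wins: rule R1 beats R2 when
   R1's matched set (required ∪ auxiliary) strictly contains R2's.  A
   homeobox protein that also carries START therefore resolves to
   HD-ZIP, not to the plain homeobox family.
3. TC rules are evaluated only when no TF rule fires — coregulators are
   by definition proteins without a (non-vetoed) DBD signature.

Proteins matching several maximal, incomparable rules (e.g. two
unrelated DBDs) are flagged ``multi_family`` and resolved to the
lexicographically first family so downstream counts stay deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .registry import FamilyRule, Registry
from .scan import DomainHit, ProteinDomainProfile

__all__ = [
    "ProteinCall",
    "GeneCall",
    "classify_protein",
    "classify_proteins",
    "aggregate_gene_calls",
    "protein_calls_to_table",
    "gene_calls_to_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProteinCall:
    protein_id: str
    category: str  # "TF" | "TC"
    family: str
    matched_rule: str
    evidence: tuple[DomainHit, ...]
    multi_family: bool = False
    alternatives: tuple[str, ...] = ()


@dataclass(frozen=True)
class GeneCall:
    gene_id: str
    category: str
    resolved_family: str
    families: frozenset[str]
    n_isoforms_called: int
    multi_family: bool = False


def _firing_rules(
    rules: Iterable[FamilyRule], present: frozenset[str]
) -> list[FamilyRule]:
    fired = []
    for rule in rules:
        if not rule.required_domains <= present:
            continue
        if not rule.auxiliary_required <= present:
            continue
        if rule.forbidden_domains & present:
            continue  # vetoed
        fired.append(rule)
    return fired


def _maximal_rules(fired: list[FamilyRule]) -> list[FamilyRule]:
    """Keep rules whose matched set is not strictly contained in another's."""
    return [
        r
        for r in fired
        if not any(o is not r and r.matched_set < o.matched_set for o in fired)
    ]


def classify_protein(
    profile: ProteinDomainProfile, registry: Registry
) -> ProteinCall | None:
    """Assign one protein to a TF or TC family, or return ``None``."""
    present = profile.present_domains
    for category in ("TF", "TC"):
        fired = _firing_rules(registry.rules_for_category(category), present)
        if not fired:
            continue
        maximal = sorted(_maximal_rules(fired), key=lambda r: r.family)
        winner = maximal[0]
        evidence = tuple(h for h in profile.hits if h.domain_id in winner.matched_set)
        if len(maximal) > 1:
            logger.warning(
                "protein %s matches %d incomparable families %s; resolving to %s",
                profile.protein_id,
                len(maximal),
                [r.family for r in maximal],
                winner.family,
            )
        return ProteinCall(
            protein_id=profile.protein_id,
            category=category,
            family=winner.family,
            matched_rule=winner.family,
            evidence=evidence,
            multi_family=len(maximal) > 1,
            alternatives=tuple(r.family for r in maximal[1:]),
        )
    return None


def classify_proteins(
    profiles: Mapping[str, ProteinDomainProfile] | Iterable[ProteinDomainProfile],
    registry: Registry,
) -> list[ProteinCall]:
    """Classify every protein profile; proteins with no call are omitted."""
    if isinstance(profiles, Mapping):
        profiles = profiles.values()
    calls = []
    for prof in sorted(profiles, key=lambda p: p.protein_id):
        call = classify_protein(prof, registry)
        if call is not None:
            calls.append(call)
    return calls


def aggregate_gene_calls(
    calls: Iterable[ProteinCall], isoform_map: Mapping[str, str]
) -> list[GeneCall]:
    """Collapse per-protein (isoform) calls to per-gene calls.

    The resolved family is the one supported by the most isoforms; ties
    break lexicographically (logged).  A gene with both TF- and
    TC-called isoforms resolves to TF (logged), with the family taken
    from its TF isoforms.
    """
    calls = list(calls)
    missing = sorted({c.protein_id for c in calls} - set(isoform_map))
    if missing:
        raise KeyError(
            f"{len(missing)} called protein(s) absent from isoform map: {missing}"
        )
    per_gene: dict[str, list[ProteinCall]] = {}
    for call in calls:
        per_gene.setdefault(isoform_map[call.protein_id], []).append(call)

    gene_calls: list[GeneCall] = []
    for gene_id in sorted(per_gene):
        gcalls = per_gene[gene_id]
        categories = {c.category for c in gcalls}
        category = "TF" if "TF" in categories else "TC"
        if len(categories) > 1:
            logger.warning(
                "gene %s has both TF- and TC-called isoforms; resolving to TF",
                gene_id,
            )
        winning = [c for c in gcalls if c.category == category]
        counts: dict[str, int] = {}
        for c in winning:
            counts[c.family] = counts.get(c.family, 0) + 1
        top = max(counts.values())
        leaders = sorted(f for f, n in counts.items() if n == top)
        if len(leaders) > 1:
            logger.warning(
                "gene %s: family tie %s; resolving to %s", gene_id, leaders, leaders[0]
            )
        gene_calls.append(
            GeneCall(
                gene_id=gene_id,
                category=category,
                resolved_family=leaders[0],
                families=frozenset(c.family for c in gcalls),
                n_isoforms_called=len(gcalls),
                multi_family=any(c.multi_family for c in gcalls)
                or len(counts) > 1
                or len(categories) > 1,
            )
        )
    return gene_calls


def protein_calls_to_table(calls: Iterable[ProteinCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": c.protein_id,
                "category": c.category,
                "family": c.family,
                "evidence_domains": ",".join(
                    sorted({h.domain_id for h in c.evidence})
                ),
                "multi_family": c.multi_family,
            }
            for c in calls
        ],
        columns=["protein_id", "category", "family", "evidence_domains", "multi_family"],
    )


def gene_calls_to_table(calls: Iterable[GeneCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "category": c.category,
                "family": c.resolved_family,
                "all_families": ",".join(sorted(c.families)),
                "n_isoforms_called": c.n_isoforms_called,
                "multi_family": c.multi_family,
            }
            for c in calls
        ],
        columns=[
            "gene_id",
            "category",
            "family",
            "all_families",
            "n_isoforms_called",
            "multi_family",
        ],
    )
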