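"""Domain and family-rule registry.

Transcription factor (TF) and transcription coregulator (TC) annotation
rests on a curated catalogue of signature protein domains and the rules
that combine them into families.  Four domain roles are distinguished:

``DBD``
    DNA-binding domain.  One or more DBDs are the defining feature of a TF.
``AD``
    Auxiliary domain.  Refines family membership: proteins sharing a DBD
    but carrying different ADs fall into different families (e.g. the
    START domain turns a plain homeobox protein into an HD-ZIP).
``FD``
    Forbidden domain.  Its presence vetoes a TF call even when a DBD is
    present (e.g. RNase_T alongside a C2H2 zinc finger).
``TC``
    Coregulator signature domain.  Defines TC families for proteins that
    lack any DBD.

Every domain carries two bit-score thresholds, a *sequence cutoff*
(applied to the full-sequence score of a profile-HMM hit) and a *domain
cutoff* (applied to the per-domain score); a hit must meet both.  The
registry is loaded from a single YAML file; a small demonstration
registry covering eight domains and eight families ships with the
package (see :func:`load_demo_registry`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import math

import pandas as pd
import yaml

__all__ = [
    "DomainModel",
    "FamilyRule",
    "Registry",
    "RegistryError",
    "load_registry",
    "save_registry",
    "registry_to_table",
    "derive_pfam_cutoffs",
    "calibrate_family_cutoff",
    "demo_registry_path",
    "load_demo_registry",
]

DOMAIN_TYPES = ("DBD", "AD", "FD", "TC")
CUTOFF_SOURCES = (
    "pfam_noise",
    "plantTFDB2_min",
    "family_calibrated",
    "plantTFDB2_suggested",
)
CATEGORIES = ("TF", "TC")


class RegistryError(ValueError):
    """Raised for malformed or inconsistent registry configuration."""


@dataclass(frozen=True)
class DomainModel:
    """One signature domain with its dual bit-score cutoffs.

    Parameters
    ----------
    domain_id : str
        Unique identifier (a Pfam accession/name or a self-built name).
    domain_type : str
        One of ``DBD``, ``AD``, ``FD``, ``TC``.
    sequence_cutoff : float
        Minimum full-sequence bit score for an acceptable hit.
    domain_cutoff : float
        Minimum per-domain bit score for an acceptable hit.
    source : str
        Provenance of the cutoffs: Pfam noise cutoff, the minimum of
        database-suggested and Pfam noise values, calibration on known
        family members, or a database-suggested threshold.
    profile_ref : str or None
        Path or identifier of the HMM profile / seed alignment.  May be
        absent for domains kept only for bookkeeping (some FDs).
    """

    domain_id: str
    domain_type: str
    sequence_cutoff: float
    domain_cutoff: float
    source: str = "pfam_noise"
    profile_ref: str | None = None

    def __post_init__(self) -> None:
        if self.domain_type not in DOMAIN_TYPES:
            raise RegistryError(
                f"domain {self.domain_id!r}: unknown type {self.domain_type!r}"
            )
        if self.source not in CUTOFF_SOURCES:
            raise RegistryError(
                f"domain {self.domain_id!r}: unknown cutoff source {self.source!r}"
            )
        for name in ("sequence_cutoff", "domain_cutoff"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise RegistryError(
                    f"domain {self.domain_id!r}: {name} must be a finite number, got {v!r}"
                )


@dataclass(frozen=True)
class FamilyRule:
    """Required / auxiliary / forbidden domain sets defining one family.

    ``required_domains`` must all be present (DBDs for TF families, TC
    domains for TC families).  ``auxiliary_required`` lists domains that
    must additionally be present; a rule with a nonempty auxiliary set is
    strictly more specific than the rule sharing its required set with an
    empty one.  Any domain in ``forbidden_domains`` vetoes the rule.
    """

    family: str
    category: str
    required_domains: frozenset[str]
    auxiliary_required: frozenset[str] = frozenset()
    forbidden_domains: frozenset[str] = frozenset()
    superfamily: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise RegistryError(
                f"family {self.family!r}: category must be TF or TC, got {self.category!r}"
            )
        if not self.required_domains:
            raise RegistryError(f"family {self.family!r}: required_domains is empty")
        overlap = self.required_domains & self.forbidden_domains
        if overlap:
            raise RegistryError(
                f"family {self.family!r}: domains {sorted(overlap)} are both "
                "required and forbidden"
            )

    @property
    def matched_set(self) -> frozenset[str]:
        """Domains a protein must carry for this rule: required ∪ auxiliary."""
        return self.required_domains | self.auxiliary_required


@dataclass
class Registry:
    """A versioned collection of domain models and family rules."""

    domains: dict[str, DomainModel]
    families: list[FamilyRule]
    version: str = "unversioned"
    base_path: Path | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rule in self.families:
            if rule.family in seen:
                raise RegistryError(f"duplicate family name {rule.family!r}")
            seen.add(rule.family)
            unknown = (rule.matched_set | rule.forbidden_domains) - set(self.domains)
            if unknown:
                raise RegistryError(
                    f"family {rule.family!r} references unknown domains "
                    f"{sorted(unknown)}"
                )

    def rules_for_category(self, category: str) -> list[FamilyRule]:
        return [r for r in self.families if r.category == category]

    def domain_type(self, domain_id: str) -> str:
        return self.domains[domain_id].domain_type

    def profile_path(self, domain_id: str) -> Path | None:
        """Resolve a domain's profile/alignment reference against the config dir."""
        ref = self.domains[domain_id].profile_ref
        if ref is None:
            return None
        p = Path(ref)
        if not p.is_absolute() and self.base_path is not None:
            p = self.base_path / p
        return p

    def __eq__(self, other: object) -> bool:  # base_path is location, not content
        if not isinstance(other, Registry):
            return NotImplemented
        return (
            self.domains == other.domains
            and sorted(self.families, key=lambda r: r.family)
            == sorted(other.families, key=lambda r: r.family)
            and self.version == other.version
        )


def _as_frozenset(value, *, what: str) -> frozenset[str]:
    if value is None:
        return frozenset()
    if isinstance(value, str):
        raise RegistryError(f"{what} must be a list, got a bare string {value!r}")
    return frozenset(str(v) for v in value)


def load_registry(config_path: str | Path) -> Registry:
    """Load a :class:`Registry` from a YAML config file.

    The file holds a ``version`` tag, a ``domains`` list (``id``,
    ``type``, ``sequence_cutoff``, ``domain_cutoff``, optional ``source``
    and ``profile``) and a ``families`` list (``name``, ``category``,
    ``required``, optional ``auxiliary``, ``forbidden``, ``superfamily``).
    Duplicate domain ids or family names, and rules referencing unknown
    domains, are fatal.  Loading is order-independent.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise RegistryError(f"{config_path}: registry config must be a mapping")

    domains: dict[str, DomainModel] = {}
    for entry in raw.get("domains", []):
        dom = DomainModel(
            domain_id=str(entry["id"]),
            domain_type=str(entry["type"]),
            sequence_cutoff=float(entry["sequence_cutoff"]),
            domain_cutoff=float(entry["domain_cutoff"]),
            source=str(entry.get("source", "pfam_noise")),
            profile_ref=entry.get("profile"),
        )
        if dom.domain_id in domains:
            raise RegistryError(f"duplicate domain id {dom.domain_id!r}")
        domains[dom.domain_id] = dom

    families = [
        FamilyRule(
            family=str(entry["name"]),
            category=str(entry["category"]),
            required_domains=_as_frozenset(entry.get("required"), what="required"),
            auxiliary_required=_as_frozenset(entry.get("auxiliary"), what="auxiliary"),
            forbidden_domains=_as_frozenset(entry.get("forbidden"), what="forbidden"),
            superfamily=entry.get("superfamily"),
        )
        for entry in raw.get("families", [])
    ]

    return Registry(
        domains=domains,
        families=families,
        version=str(raw.get("version", "unversioned")),
        base_path=config_path.parent,
    )


def save_registry(registry: Registry, config_path: str | Path) -> None:
    """Serialize a registry back to YAML (round-trips with :func:`load_registry`)."""
    payload = {
        "version": registry.version,
        "domains": [
            {
                "id": d.domain_id,
                "type": d.domain_type,
                "sequence_cutoff": float(d.sequence_cutoff),
                "domain_cutoff": float(d.domain_cutoff),
                "source": d.source,
                **({"profile": d.profile_ref} if d.profile_ref else {}),
            }
            for d in sorted(registry.domains.values(), key=lambda d: d.domain_id)
        ],
        "families": [
            {
                "name": r.family,
                "category": r.category,
                "required": sorted(r.required_domains),
                **(
                    {"auxiliary": sorted(r.auxiliary_required)}
                    if r.auxiliary_required
                    else {}
                ),
                **(
                    {"forbidden": sorted(r.forbidden_domains)}
                    if r.forbidden_domains
                    else {}
                ),
                **({"superfamily": r.superfamily} if r.superfamily else {}),
            }
            for r in sorted(registry.families, key=lambda r: r.family)
        ],
    }
    with open(config_path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def registry_to_table(registry: Registry) -> pd.DataFrame:
    """Export the domain catalogue as a table.

    Columns: domain, type, profile, sequence_cutoff, domain_cutoff, source.
    """
    rows = [
        {
            "domain": d.domain_id,
            "type": d.domain_type,
            "profile": d.profile_ref or "",
            "sequence_cutoff": d.sequence_cutoff,
            "domain_cutoff": d.domain_cutoff,
            "source": d.source,
        }
        for d in sorted(registry.domains.values(), key=lambda d: d.domain_id)
    ]
    return pd.DataFrame(rows)


def derive_pfam_cutoffs(
    candidates: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Combine candidate cutoff pairs from several sources.

    For a Pfam domain with thresholds suggested by more than one source
    (e.g. a TF database's cutoffs and the Pfam noise cutoff), the adopted
    thresholds are the component-wise minima, i.e. the most permissive
    value per component.

    Parameters
    ----------
    candidates : sequence of (sequence_cutoff, domain_cutoff)

    Returns
    -------
    (sequence_cutoff, domain_cutoff)
        Component-wise minimum over the candidates.
    """
    if not candidates:
        raise ValueError("derive_pfam_cutoffs: no candidate cutoff pairs given")
    seqs, doms = zip(*candidates)
    return (min(seqs), min(doms))


def calibrate_family_cutoff(
    member_scores: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Calibrate cutoffs from known family members' bit scores.

    For families whose profiles were built in-house, thresholds are set
    from the hit scores of already-annotated members: the lowest domain
    score and the lowest sequence score observed among members become the
    domain and sequence cutoffs.  The minima are taken component-wise, so
    the result never exceeds any single member's scores and never excludes
    a known member.

    Parameters
    ----------
    member_scores : sequence of (domain_score, sequence_score)
        One pair per known family member.

    Returns
    -------
    (sequence_cutoff, domain_cutoff)
    """
    if not member_scores:
        raise ValueError("calibrate_family_cutoff: no member scores given")
    doms, seqs = zip(*member_scores)
    return (min(seqs), min(doms))


def demo_registry_path() -> Path:
    """Path of the demonstration registry shipped with the package."""
    return Path(resources.files("tfannot").joinpath("data", "demo_registry.yaml"))


def load_demo_registry() -> Registry:
    """Load the shipped demonstration registry (8 domains, 8 families)."""
    return load_registry(demo_registry_path())
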