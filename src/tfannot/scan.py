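"""Profile-HMM domain scanning and the dual bit-score filter.

Domain presence is established with HMMER-style profile HMM searches
(via :mod:`pyhmmer`): profiles are built from seed alignments
(``hmmbuild``) and searched against the proteome (``hmmsearch``).  Each
hit carries two bit scores — the full-sequence score and the per-domain
score — and is accepted only if both meet the domain's registered
cutoffs.  Precomputed searches can be supplied as HMMER3 ``--domtblout``
tables instead of running the engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pyhmmer
from pyhmmer.easel import Alphabet, MSAFile, SequenceFile
from pyhmmer.plan7 import HMM, Background, Builder

from .registry import Registry

__all__ = [
    "DomainHit",
    "ProteinDomainProfile",
    "build_profiles",
    "scan_proteome",
    "parse_domtblout",
    "filter_hits",
    "build_protein_profiles",
    "hits_to_table",
    "write_hits",
]


@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM match of a domain on a protein.

    Coordinates are the 1-based inclusive envelope bounds reported by the
    search engine.  ``sequence_score`` is the full-sequence bit score of
    the protein against the profile; ``domain_score`` the per-domain bit
    score of this match.
    """

    protein_id: str
    domain_id: str
    env_start: int
    env_end: int
    domain_score: float
    sequence_score: float
    domain_evalue: float = float("nan")

    def __post_init__(self) -> None:
        if not (1 <= self.env_start <= self.env_end):
            raise ValueError(
                f"invalid envelope [{self.env_start}, {self.env_end}] for "
                f"{self.domain_id} on {self.protein_id}"
            )


@dataclass
class ProteinDomainProfile:
    """Accepted hits of one protein, grouped by domain role."""

    protein_id: str
    hits: list[DomainHit] = field(default_factory=list)
    by_type: dict[str, list[DomainHit]] = field(default_factory=dict)

    @property
    def present_domains(self) -> frozenset[str]:
        return frozenset(h.domain_id for h in self.hits)

    def domains_of_type(self, domain_type: str) -> frozenset[str]:
        return frozenset(h.domain_id for h in self.by_type.get(domain_type, []))


_ALPHABET = Alphabet.amino()


def _name(value: str | bytes) -> str:
    return value.decode() if isinstance(value, bytes) else value


def build_profiles(alignment_paths: Iterable[str | Path]) -> dict[str, HMM]:
    """Build one profile HMM per seed alignment (``hmmbuild`` equivalent).

    Each alignment must contain at least two sequences of consistent
    alignment length; the profile is named after the file stem.  Building
    is deterministic for identical inputs (fixed builder seed).
    """
    builder = Builder(_ALPHABET)
    background = Background(_ALPHABET)
    profiles: dict[str, HMM] = {}
    for path in alignment_paths:
        path = Path(path)
        name = path.stem
        try:
            with MSAFile(str(path), digital=True, alphabet=_ALPHABET) as fh:
                msa = fh.read()
        except Exception as exc:
            raise ValueError(f"cannot read alignment {path}: {exc}") from exc
        if msa is None or len(msa.sequences) < 2:
            raise ValueError(f"alignment {path} needs at least 2 sequences")
        msa.name = name
        hmm, _, _ = builder.build_msa(msa, background)
        profiles[name] = hmm
    return profiles


def scan_proteome(
    fasta: str | Path, profiles: dict[str, HMM] | Sequence[HMM]
) -> list[DomainHit]:
    """Search every profile against a proteome FASTA (``hmmsearch`` equivalent).

    Returns raw (unfiltered) hits at the engine's default reporting
    thresholds; apply :func:`filter_hits` to enforce the registry's dual
    bit-score cutoffs.  An empty proteome yields an empty list.
    """
    hmms = list(profiles.values()) if isinstance(profiles, dict) else list(profiles)
    if not hmms:
        raise ValueError("scan_proteome: no profiles given")
    fasta = Path(fasta)
    if not fasta.exists():
        raise FileNotFoundError(fasta)
    if fasta.stat().st_size == 0:  # format sniffing fails on empty files
        return []
    with SequenceFile(str(fasta), digital=True, alphabet=_ALPHABET) as fh:
        sequences = fh.read_block()
    if len(sequences) == 0:
        return []
    hits: list[DomainHit] = []
    for tophits in pyhmmer.hmmsearch(hmms, sequences):
        domain_id = _name(tophits.query.name)
        for hit in tophits:
            for dom in hit.domains:
                if not dom.reported:
                    continue
                hits.append(
                    DomainHit(
                        protein_id=_name(hit.name),
                        domain_id=domain_id,
                        env_start=dom.env_from,
                        env_end=dom.env_to,
                        domain_score=dom.score,
                        sequence_score=hit.score,
                        domain_evalue=dom.i_evalue,
                    )
                )
    return hits


# --domtblout column indices (whitespace-separated; description trails)
_DOMTBL_MIN_FIELDS = 23


def parse_domtblout(path: str | Path) -> list[DomainHit]:
    """Parse a HMMER3 per-domain table (``--domtblout``) into hits.

    One :class:`DomainHit` per data row; ``#`` comment lines are skipped.
    Coordinates are taken from the envelope columns, the sequence score
    from the full-sequence column and the per-domain E-value from the
    independent E-value column.  Malformed rows raise with the 1-based
    line number.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < _DOMTBL_MIN_FIELDS:
                raise ValueError(
                    f"{path}: line {lineno}: expected ≥{_DOMTBL_MIN_FIELDS} "
                    f"columns, found {len(fields)}"
                )
            try:
                hits.append(
                    DomainHit(
                        protein_id=fields[0],
                        domain_id=fields[3],
                        sequence_score=float(fields[7]),
                        domain_evalue=float(fields[12]),
                        domain_score=float(fields[13]),
                        env_start=int(fields[19]),
                        env_end=int(fields[20]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def filter_hits(
    raw: Iterable[DomainHit],
    registry: Registry,
    *,
    unknown: str = "drop",
) -> list[DomainHit]:
    """Apply the dual bit-score filter.

    A hit is retained iff ``domain_score >= domain_cutoff`` **and**
    ``sequence_score >= sequence_cutoff`` for its domain (both
    comparisons inclusive).  Input order is preserved and the filter is
    idempotent.

    ``unknown`` controls hits whose domain is absent from the registry:
    ``"drop"`` (default, with a warning), ``"error"``, or ``"keep"``.
    """
    if unknown not in ("drop", "error", "keep"):
        raise ValueError(f"unknown= must be drop/error/keep, got {unknown!r}")
    accepted: list[DomainHit] = []
    unseen: set[str] = set()
    for hit in raw:
        model = registry.domains.get(hit.domain_id)
        if model is None:
            if unknown == "error":
                raise KeyError(f"hit references unknown domain {hit.domain_id!r}")
            if unknown == "keep":
                accepted.append(hit)
            else:
                unseen.add(hit.domain_id)
            continue
        if (
            hit.domain_score >= model.domain_cutoff
            and hit.sequence_score >= model.sequence_cutoff
        ):
            accepted.append(hit)
    if unseen:
        warnings.warn(
            f"dropped hits for domains absent from registry: {sorted(unseen)}",
            stacklevel=2,
        )
    return accepted


def build_protein_profiles(
    accepted: Iterable[DomainHit], registry: Registry
) -> dict[str, ProteinDomainProfile]:
    """Group accepted hits per protein, indexed by domain role."""
    profiles: dict[str, ProteinDomainProfile] = {}
    for hit in accepted:
        prof = profiles.setdefault(hit.protein_id, ProteinDomainProfile(hit.protein_id))
        prof.hits.append(hit)
        dtype = registry.domain_type(hit.domain_id)
        prof.by_type.setdefault(dtype, []).append(hit)
    return profiles


def hits_to_table(hits: Iterable[DomainHit], registry: Registry | None = None) -> pd.DataFrame:
    """Tabulate hits (protein, domain, type, envelope, scores)."""
    rows = []
    for h in hits:
        rows.append(
            {
                "protein_id": h.protein_id,
                "domain_id": h.domain_id,
                "type": registry.domain_type(h.domain_id) if registry else "",
                "env_start": h.env_start,
                "env_end": h.env_end,
                "domain_score": h.domain_score,
                "sequence_score": h.sequence_score,
                "domain_evalue": h.domain_evalue,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "domain_id",
            "type",
            "env_start",
            "env_end",
            "domain_score",
            "sequence_score",
            "domain_evalue",
        ],
    )


def write_hits(
    hits: Iterable[DomainHit], path: str | Path, registry: Registry | None = None
) -> None:
    hits_to_table(hits, registry).to_csv(path, sep="\t", index=False)
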