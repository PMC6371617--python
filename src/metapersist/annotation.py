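"""Functional and taxonomic annotation of protein groups.

A group inherits the KO term, phylum and genus of its seed sequence, and is
categorised as human, microbial (phylum present) or unassigned.  Because
members of a 90%-identity group almost always agree with their seed, the
seed's annotation is applied unconditionally; `ambiguity_report` quantifies
how often members positively disagree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .grouping import ProteinGroup
from .io import AnnotationRow

logger = logging.getLogger(__name__)

CATEGORY_HUMAN = "human"
CATEGORY_MICROBIAL = "microbial"
CATEGORY_UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class AnnotatedGroup:
    group_id: str
    ko_term: str | None = None
    phylum: str | None = None
    genus: str | None = None
    category: str = CATEGORY_UNASSIGNED

    def __post_init__(self) -> None:
        if self.category == CATEGORY_HUMAN and self.phylum is not None:
            raise ValueError(f"{self.group_id}: human groups carry no phylum")


@dataclass(frozen=True)
class AmbiguityReport:
    """Fraction of groups whose members positively disagree with the seed."""

    fraction: float
    discordant_groups: tuple[str, ...]


def annotate_groups(
    groups: Sequence[ProteinGroup],
    annotation_rows: Iterable[AnnotationRow],
) -> list[AnnotatedGroup]:
    """Attach the seed sequence's annotation to every group.

    Seeds missing from the annotation table yield unassigned groups (with a
    warning); nothing is fatal here.
    """
    by_accession = {row.accession: row for row in annotation_rows}
    annotated: list[AnnotatedGroup] = []
    missing = 0
    for group in groups:
        row = by_accession.get(group.seed_accession)
        if row is None:
            missing += 1
            annotated.append(AnnotatedGroup(group_id=group.group_id))
            continue
        if row.organism_label == "human":
            annotated.append(
                AnnotatedGroup(
                    group_id=group.group_id,
                    ko_term=row.ko_term,
                    genus=None,
                    category=CATEGORY_HUMAN,
                )
            )
        elif row.phylum is not None:
            annotated.append(
                AnnotatedGroup(
                    group_id=group.group_id,
                    ko_term=row.ko_term,
                    phylum=row.phylum,
                    genus=row.genus,
                    category=CATEGORY_MICROBIAL,
                )
            )
        else:
            annotated.append(
                AnnotatedGroup(group_id=group.group_id, ko_term=row.ko_term)
            )
    if missing:
        logger.warning(
            "%d group seed(s) missing from the annotation table; left unassigned",
            missing,
        )
    return annotated


def ambiguity_report(
    groups: Sequence[ProteinGroup],
    annotation_rows: Iterable[AnnotationRow],
) -> AmbiguityReport:
    """How often do group members disagree with the seed on KO or phylum?

    Only positive disagreement counts: a member with no KO (or no phylum)
    never makes a group ambiguous, but a member whose stated value differs
    from the seed's (including when the seed has none) does.
    """
    by_accession = {row.accession: row for row in annotation_rows}
    discordant: list[str] = []
    for group in groups:
        seed = by_accession.get(group.seed_accession)
        seed_ko = seed.ko_term if seed else None
        seed_phylum = seed.phylum if seed else None
        for accession in group.member_accessions:
            if accession == group.seed_accession:
                continue
            member = by_accession.get(accession)
            if member is None:
                continue
            ko_conflict = member.ko_term is not None and member.ko_term != seed_ko
            phylum_conflict = (
                member.phylum is not None and member.phylum != seed_phylum
            )
            if ko_conflict or phylum_conflict:
                discordant.append(group.group_id)
                break
    fraction = len(discordant) / len(groups) if groups else 0.0
    return AmbiguityReport(fraction=fraction, discordant_groups=tuple(discordant))
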