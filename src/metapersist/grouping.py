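"""Protein-group construction and per-sample identification.

Metaproteome databases carry heavy sequence redundancy: the same gene is
predicted from several assemblies, often as overlapping fragments.  To make
spectral counts comparable, sequences are collapsed into *protein groups* of
>= 90% pairwise identity to a seed (centroid) sequence, peptides are mapped
to groups by exact substring containment, and a group counts as *identified*
in a sample only if its observed peptides include at least two distinct
sequences, at least one of which is unique to the group.

Clustering is a deterministic greedy centroid pass: sequences are processed
in order of decreasing length (ties broken by accession), each sequence
joins the first existing seed it matches at or above the identity threshold,
and otherwise founds a new group.  Identity is computed from a global affine
alignment (match +1, mismatch -1, gap open -5, gap extend -1, terminal gaps
free) as identical residue pairs divided by the alignment columns spanned by
the shorter sequence -- internal gaps count against identity, terminal
overhangs of the longer sequence do not, so a perfect fragment of a longer
ORF has identity 1.0 and collapses into its full-length group, while a
chance end-overlap between unrelated sequences is still normalised by the
whole shorter sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align

from .io import ProteinRecord, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_THRESHOLD = 0.90
# floating-point guard for ratio-of-small-integers comparisons like 9/10 >= 0.9
_EPS = 1e-12


class ConfigError(ValueError):
    """An out-of-range analysis parameter."""


@dataclass(frozen=True)
class ProteinGroup:
    """A cluster of near-identical protein sequences.

    The seed is the founding (longest) member and donates downstream
    annotations; members all have pairwise identity >= threshold to it.
    """

    group_id: str
    seed_accession: str
    member_accessions: tuple[str, ...]
    individual_id: str = ""

    def __post_init__(self) -> None:
        if self.seed_accession not in self.member_accessions:
            raise ValidationError(
                f"{self.group_id}: seed {self.seed_accession} not among members"
            )


@dataclass(frozen=True)
class PeptideMap:
    """peptide -> set of protein groups containing it as an exact substring."""

    mapping: Mapping[str, frozenset[str]]
    unmapped: tuple[str, ...] = ()

    def groups_for(self, peptide: str) -> frozenset[str]:
        return self.mapping.get(peptide, frozenset())

    def is_unique(self, peptide: str) -> bool:
        """True when the peptide maps to exactly one group."""
        return len(self.mapping.get(peptide, ())) == 1

    def is_shared(self, peptide: str) -> bool:
        return len(self.mapping.get(peptide, ())) > 1


def make_aligner() -> Align.PairwiseAligner:
    """The global affine aligner used for identity calculations."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    # terminal overhangs are free so fragments align flush against full
    # length ORFs instead of being forced into internal gaps
    aligner.open_end_gap_score = 0.0
    aligner.extend_end_gap_score = 0.0
    return aligner


def _canon(sequence: str, ile_leu_equivalent: bool) -> str:
    return sequence.replace("L", "I") if ile_leu_equivalent else sequence


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    ile_leu_equivalent: bool = False,
    _aligner: Align.PairwiseAligner | None = None,
) -> float:
    """Fraction of identical residue pairs in the global alignment of two
    sequences, over the alignment columns spanned by the shorter sequence
    (from its first to its last residue; internal gap columns included,
    terminal overhangs of the longer sequence excluded).  Symmetric.
    """
    if not seq_a or not seq_b:
        raise ValidationError("pairwise_identity requires non-empty sequences")
    a = _canon(seq_a, ile_leu_equivalent)
    b = _canon(seq_b, ile_leu_equivalent)
    if a == b:
        return 1.0
    # the identity is defined on the unordered pair; fixing the argument
    # order makes tie-breaking among equally optimal alignments symmetric
    if (len(a), a) > (len(b), b):
        a, b = b, a
    aligner = _aligner if _aligner is not None else make_aligner()
    alignment = aligner.align(a, b)[0]
    ga, gb = alignment[0], alignment[1]
    return _alignment_identity(ga, gb)


def _alignment_identity(ga: str, gb: str) -> float:
    """Identity of one gapped alignment under the shorter-sequence-span
    denominator.  For equal-length sequences the larger of the two spans is
    used, which keeps the measure symmetric."""
    len_a = sum(1 for c in ga if c != "-")
    len_b = sum(1 for c in gb if c != "-")

    def span(g: str) -> tuple[int, int]:
        first = next(i for i, c in enumerate(g) if c != "-")
        last = next(i for i in range(len(g) - 1, -1, -1) if g[i] != "-")
        return first, last

    if len_a < len_b:
        spans = [span(ga)]
    elif len_b < len_a:
        spans = [span(gb)]
    else:
        spans = [max(span(ga), span(gb), key=lambda s: s[1] - s[0])]
    start, end = spans[0]
    columns = end - start + 1
    matches = sum(
        1 for i in range(start, end + 1) if ga[i] == gb[i] and ga[i] != "-"
    )
    return matches / columns


def cluster_proteins(
    records: Sequence[ProteinRecord],
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    ile_leu_equivalent: bool = False,
) -> list[ProteinGroup]:
    """Greedy centroid clustering of a protein database into groups.

    Deterministic: records are processed by decreasing sequence length with
    lexicographic accession tie-break; each record joins the first existing
    seed (in founding order) with identity >= ``threshold``, else founds a
    new group.  The groups partition the input.
    """
    if not 0.0 < threshold <= 1.0:
        raise ConfigError(f"identity threshold {threshold} outside (0, 1]")
    if not records:
        raise ValidationError("cluster_proteins requires a non-empty database")
    accessions = [r.accession for r in records]
    if len(set(accessions)) != len(accessions):
        raise ValidationError("duplicate accessions in clustering input")

    aligner = make_aligner()
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.accession))
    seeds: list[ProteinRecord] = []
    members: list[list[str]] = []
    for record in ordered:
        for gi, seed in enumerate(seeds):
            identity = pairwise_identity(
                record.sequence, seed.sequence, ile_leu_equivalent, _aligner=aligner
            )
            if identity >= threshold - _EPS:
                members[gi].append(record.accession)
                break
        else:
            seeds.append(record)
            members.append([record.accession])

    width = max(5, len(str(len(seeds))))
    return [
        ProteinGroup(
            group_id=f"PG{gi:0{width}d}",
            seed_accession=seed.accession,
            member_accessions=tuple(accs),
            individual_id=seed.individual_id,
        )
        for gi, (seed, accs) in enumerate(zip(seeds, members), start=1)
    ]


def map_peptides(
    peptides: Iterable[str],
    groups: Sequence[ProteinGroup],
    records: Sequence[ProteinRecord] | Mapping[str, str],
    ile_leu_equivalent: bool = False,
) -> PeptideMap:
    """Map peptides onto protein groups by exact substring containment.

    A peptide maps to a group when it occurs in any member sequence.
    Peptides found in no sequence are listed as unmapped (a warning, not an
    error) and are excluded downstream.
    """
    if isinstance(records, Mapping):
        seq_of = dict(records)
    else:
        seq_of = {r.accession: r.sequence for r in records}
    group_sequences = [
        (g.group_id, [_canon(seq_of[a], ile_leu_equivalent) for a in g.member_accessions])
        for g in groups
    ]
    mapping: dict[str, frozenset[str]] = {}
    unmapped: list[str] = []
    for peptide in sorted(set(peptides)):
        probe = _canon(peptide, ile_leu_equivalent)
        hits = frozenset(
            gid
            for gid, seqs in group_sequences
            if any(probe in s for s in seqs)
        )
        if hits:
            mapping[peptide] = hits
        else:
            unmapped.append(peptide)
    if unmapped:
        logger.warning(
            "%d peptide(s) map to no protein group and will be excluded",
            len(unmapped),
        )
    return PeptideMap(mapping=mapping, unmapped=tuple(unmapped))


def classify_identified(
    group_id: str,
    peptide_map: PeptideMap,
    observed_peptides: Iterable[str],
    min_distinct_peptides: int = 2,
    min_unique_peptides: int = 1,
) -> bool:
    """Identification rule for one group in one sample.

    True iff the observed peptides mapping to the group comprise at least
    ``min_distinct_peptides`` distinct sequences of which at least
    ``min_unique_peptides`` are unique to the group.
    """
    distinct = 0
    unique = 0
    for peptide in set(observed_peptides):
        hits = peptide_map.groups_for(peptide)
        if group_id in hits:
            distinct += 1
            if len(hits) == 1:
                unique += 1
    return distinct >= min_distinct_peptides and unique >= min_unique_peptides


def identification_matrix(
    groups: Sequence[ProteinGroup],
    peptide_map: PeptideMap,
    psm_frame: pd.DataFrame,
    min_distinct_peptides: int = 2,
    min_unique_peptides: int = 1,
) -> pd.DataFrame:
    """Boolean group x sample matrix of the identification rule."""
    samples = sorted(psm_frame["sample_id"].unique())
    observed = {
        sample: set(psm_frame.loc[psm_frame["sample_id"] == sample, "peptide"])
        for sample in samples
    }
    data = {
        sample: [
            classify_identified(
                g.group_id,
                peptide_map,
                observed[sample],
                min_distinct_peptides,
                min_unique_peptides,
            )
            for g in groups
        ]
        for sample in samples
    }
    return pd.DataFrame(data, index=[g.group_id for g in groups], dtype=bool)


def groups_to_frame(groups: Sequence[ProteinGroup]) -> pd.DataFrame:
    """Groups as a TSV-ready frame (members semicolon-joined)."""
    return pd.DataFrame(
        {
            "group_id": [g.group_id for g in groups],
            "seed_accession": [g.seed_accession for g in groups],
            "member_accessions": [";".join(g.member_accessions) for g in groups],
            "individual_id": [g.individual_id for g in groups],
        }
    )


def groups_from_frame(frame: pd.DataFrame) -> list[ProteinGroup]:
    return [
        ProteinGroup(
            group_id=r.group_id,
            seed_accession=r.seed_accession,
            member_accessions=tuple(r.member_accessions.split(";")),
            individual_id=getattr(r, "individual_id", "") or "",
        )
        for r in frame.itertuples()
    ]
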