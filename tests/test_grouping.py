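"""Pairwise identity, greedy centroid clustering, peptide mapping and the
per-sample identification rule.

The identity oracle enumerates every global alignment of two short
sequences, scores each with the affine scheme (match +1, mismatch -1, gap
open -5, gap extend -1, terminal gap runs free) and recomputes identity
under the shorter-sequence-span denominator -- fully independent of the
aligner-based implementation it checks.
"""

from __future__ import annotations

import random

import pytest

from metapersist import (
    ProteinRecord,
    ValidationError,
    classify_identified,
    cluster_proteins,
    map_peptides,
    pairwise_identity,
)
from metapersist.grouping import ConfigError

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# brute-force alignment oracle
# ---------------------------------------------------------------------------


def _all_alignments(a: str, b: str):
    """Every global alignment of a and b as gapped string pairs."""
    out = []

    def rec(i, j, ga, gb):
        if i == len(a) and j == len(b):
            out.append((ga, gb))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, ga + a[i], gb + b[j])
        if i < len(a):
            rec(i + 1, j, ga + a[i], gb + "-")
        if j < len(b):
            rec(i, j + 1, ga + "-", gb + b[j])

    rec(0, 0, "", "")
    return out


def _score(ga: str, gb: str) -> float:
    """Affine score with free terminal gap runs (first gap residue -5, each
    further -1)."""
    first_a = min(i for i, c in enumerate(ga) if c != "-")
    last_a = max(i for i, c in enumerate(ga) if c != "-")
    first_b = min(i for i, c in enumerate(gb) if c != "-")
    last_b = max(i for i, c in enumerate(gb) if c != "-")
    score = 0.0
    gap_a = gap_b = False
    for i, (ca, cb) in enumerate(zip(ga, gb)):
        if ca != "-" and cb != "-":
            score += 1.0 if ca == cb else -1.0
            gap_a = gap_b = False
        elif ca == "-":
            if first_a <= i <= last_a:  # internal gap in sequence a
                score += -1.0 if gap_a else -5.0
            gap_a, gap_b = True, False
        else:
            if first_b <= i <= last_b:
                score += -1.0 if gap_b else -5.0
            gap_b, gap_a = True, False
    return score


def _oracle_identity(ga: str, gb: str) -> float:
    """Matches over the columns spanned by the shorter sequence."""
    len_a = sum(c != "-" for c in ga)
    len_b = sum(c != "-" for c in gb)

    def span(g):
        idx = [i for i, c in enumerate(g) if c != "-"]
        return idx[0], idx[-1]

    if len_a < len_b:
        start, end = span(ga)
    elif len_b < len_a:
        start, end = span(gb)
    else:
        sa, sb = span(ga), span(gb)
        start, end = max((sa, sb), key=lambda s: s[1] - s[0])
    matches = sum(
        1 for i in range(start, end + 1) if ga[i] == gb[i] and ga[i] != "-"
    )
    return matches / (end - start + 1)


def _oracle_identities(a: str, b: str) -> set[float]:
    """Identities of every optimal-scoring global alignment."""
    alignments = _all_alignments(a, b)
    best = max(_score(ga, gb) for ga, gb in alignments)
    return {
        round(_oracle_identity(ga, gb), 9)
        for ga, gb in alignments
        if _score(ga, gb) == best
    }


# ---------------------------------------------------------------------------
# pairwise identity
# ---------------------------------------------------------------------------


def test_identity_of_identical_sequences_is_one():
    assert pairwise_identity("ACDEFGHIKL", "ACDEFGHIKL") == 1.0


def test_identity_single_substitution_over_ten_columns():
    # no gap can pay off at these scores, so the ungapped alignment is optimal
    assert pairwise_identity("ACDEFGHIKL", "ACDEFGHIKW") == pytest.approx(0.9)


def test_identity_perfect_fragment_collapses():
    """A prefix fragment spans only its own residues, so identity is 1.0 and
    fragment-vs-full-length redundancy collapses at the 90% threshold."""
    assert pairwise_identity("ACDEFGHIKL", "ACDEFGHIK") == 1.0
    assert pairwise_identity("MKACDEFGHIKLWWYR", "ACDEFGHIKL") == 1.0


def test_identity_is_symmetric():
    rng = random.Random(0)
    for _ in range(10):
        a = "".join(rng.choice(AA) for _ in range(rng.randint(5, 30)))
        b = "".join(rng.choice(AA) for _ in range(rng.randint(5, 30)))
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))


def test_identity_empty_sequence_is_error():
    with pytest.raises(ValidationError):
        pairwise_identity("", "ACDE")


def test_identity_matches_enumeration_oracle():
    """Against brute-force enumeration of every global alignment of short
    sequences (the aligner may pick any optimal alignment, so membership in
    the optimal set is the contract)."""
    rng = random.Random(42)
    pairs = [("ACDEFG", "ACDEFG"), ("ACDEFG", "ACDEF"), ("ACDEF", "AWDEF")]
    for _ in range(8):
        a = "".join(rng.choice(AA) for _ in range(rng.randint(3, 6)))
        b = "".join(rng.choice(AA) for _ in range(rng.randint(3, 6)))
        pairs.append((a, b))
    for a, b in pairs:
        got = round(pairwise_identity(a, b), 9)
        assert got in _oracle_identities(a, b), (a, b, got)


def test_ile_leu_policy_is_a_switch():
    a, b = "AAAIIIKKKR", "AAALLLKKKR"
    assert pairwise_identity(a, b) == pytest.approx(0.7)
    assert pairwise_identity(a, b, ile_leu_equivalent=True) == 1.0


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def _rec(acc, seq):
    return ProteinRecord(acc, seq)


def test_single_sequence_forms_singleton_group():
    (group,) = cluster_proteins([_rec("p1", "ACDEFGHIKL")])
    assert group.seed_accession == "p1"
    assert group.member_accessions == ("p1",)


def test_identical_sequences_share_group_with_lexicographic_seed():
    groups = cluster_proteins([_rec("b", "ACDEFGHIKL"), _rec("a", "ACDEFGHIKL")])
    assert len(groups) == 1
    assert groups[0].seed_accession == "a"
    assert set(groups[0].member_accessions) == {"a", "b"}


def test_three_way_clustering_structure():
    a = "ACDEFGHIKL"
    b = "ACDEFGHIKW"  # 0.9 to a
    c = "WYWYWYWYWY"  # unrelated
    assert pairwise_identity(a, b) == pytest.approx(0.9)
    assert pairwise_identity(a, c) < 0.9
    assert pairwise_identity(b, c) < 0.9
    groups = cluster_proteins([_rec("a", a), _rec("b", b), _rec("c", c)])
    members = sorted(tuple(sorted(g.member_accessions)) for g in groups)
    assert members == [("a", "b"), ("c",)]


def test_clustering_partitions_the_database():
    rng = random.Random(3)
    records = []
    for fam in range(6):
        base = "".join(rng.choice(AA) for _ in range(40))
        for v in range(3):
            seq = "".join(
                c if rng.random() > 0.03 else rng.choice(AA.replace(c, ""))
                for c in base
            )
            records.append(_rec(f"f{fam}v{v}", seq))
    groups = cluster_proteins(records)
    seen = [a for g in groups for a in g.member_accessions]
    assert sorted(seen) == sorted(r.accession for r in records)
    for g in groups:
        assert g.seed_accession in g.member_accessions


def test_lower_threshold_does_not_increase_group_count_on_family_data():
    rng = random.Random(5)
    records = []
    for fam in range(5):
        base = "".join(rng.choice(AA) for _ in range(50))
        for v in range(4):
            seq = "".join(
                c if rng.random() > 0.05 else rng.choice(AA.replace(c, ""))
                for c in base
            )
            records.append(_rec(f"f{fam}v{v}", seq))
    counts = [
        len(cluster_proteins(records, threshold=t)) for t in (0.95, 0.9, 0.8, 0.5)
    ]
    assert counts == sorted(counts, reverse=True)


def test_threshold_out_of_range_is_config_error():
    with pytest.raises(ConfigError):
        cluster_proteins([_rec("p1", "ACDEFGHIKL")], threshold=1.5)


# ---------------------------------------------------------------------------
# peptide mapping and identification
# ---------------------------------------------------------------------------


@pytest.fixture
def two_group_world():
    records = [
        _rec("g1a", "AAAAAAKCCCCCCKDDDDDDK"),
        _rec("g2a", "EEEEEEKCCCCCCKFFFFFFK"),
    ]
    groups = cluster_proteins(records)
    assert len(groups) == 2
    return records, groups


def test_map_peptides_unique_shared_unmapped(two_group_world, caplog):
    records, groups = two_group_world
    with caplog.at_level("WARNING"):
        pmap = map_peptides(
            ["AAAAAAK", "CCCCCCK", "WWWWWWK"], groups, records
        )
    assert pmap.is_unique("AAAAAAK")
    assert pmap.is_shared("CCCCCCK")
    assert len(pmap.groups_for("CCCCCCK")) == 2
    assert pmap.unmapped == ("WWWWWWK",)


def test_identification_rule(two_group_world):
    records, groups = two_group_world
    pmap = map_peptides(["AAAAAAK", "CCCCCCK", "DDDDDDK"], groups, records)
    g1 = next(g.group_id for g in groups if "g1a" in g.member_accessions)
    g2 = next(g.group_id for g in groups if "g2a" in g.member_accessions)
    # one unique + one shared: two distinct, one unique -> identified
    assert classify_identified(g1, pmap, {"AAAAAAK", "CCCCCCK"})
    # a single unique peptide is not enough distinct evidence
    assert not classify_identified(g1, pmap, {"AAAAAAK"})
    # shared-only evidence never identifies
    assert not classify_identified(g2, pmap, {"CCCCCCK"})


def test_identification_monotone_in_observed_peptides(two_group_world):
    records, groups = two_group_world
    peptides = ["AAAAAAK", "CCCCCCK", "DDDDDDK"]
    pmap = map_peptides(peptides, groups, records)
    g1 = next(g.group_id for g in groups if "g1a" in g.member_accessions)
    observed: set[str] = set()
    was_identified = False
    for peptide in peptides:
        observed.add(peptide)
        now = classify_identified(g1, pmap, observed)
        assert now or not was_identified
        was_identified = now
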