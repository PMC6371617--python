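"""Balanced spectral counting.

Each sample's peptide-level spectral counts are distributed over the protein
groups identified in that sample.  Unique peptides (mapping to exactly one
group) donate their counts wholly to that group; shared peptides are then
split across their identified carrier groups in proportion to the carriers'
unique-count totals, or equally when no carrier has unique evidence.  The
allocation is a single pass, independent of processing order, and conserves
the total count of every retained peptide.

Peptides whose carrier groups are all unidentified in the sample are dropped
from that sample's conserved total (with a warning); peptides matching no
group at all were already excluded by the peptide map.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .grouping import PeptideMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AbundanceTable:
    """Balanced counts (group x sample) plus per-sample retained totals.

    ``counts`` column sums equal ``total_spectra`` (the mapped spectra of the
    sample's identified groups) to float tolerance; ``dropped_spectra`` are
    spectra of peptides with no identified carrier in that sample.
    """

    counts: pd.DataFrame
    total_spectra: pd.Series
    dropped_spectra: pd.Series


def balance_sample(
    peptide_counts: Mapping[str, int],
    peptide_map: PeptideMap,
    identified_groups: Iterable[str],
) -> tuple[dict[str, float], int]:
    """Allocate one sample's peptide counts over its identified groups.

    Returns ``(balanced_counts, dropped)`` where ``dropped`` is the summed
    count of observed peptides whose mapped groups include no identified
    group (unmapped peptides are ignored entirely).
    """
    identified = set(identified_groups)
    unique_totals: dict[str, float] = defaultdict(float)
    shared: list[tuple[int, frozenset[str]]] = []
    dropped = 0
    for peptide, count in peptide_counts.items():
        hits = peptide_map.groups_for(peptide)
        if not hits:
            continue
        carriers = hits & identified
        if not carriers:
            dropped += count
            continue
        if len(hits) == 1:
            (group,) = hits
            unique_totals[group] += count
        else:
            shared.append((count, frozenset(carriers)))

    balanced: dict[str, float] = dict(unique_totals)
    for count, carriers in shared:
        evidence = sum(unique_totals.get(g, 0.0) for g in carriers)
        if evidence > 0.0:
            for g in carriers:
                share = count * unique_totals.get(g, 0.0) / evidence
                if share:
                    balanced[g] = balanced.get(g, 0.0) + share
        else:
            share = count / len(carriers)
            for g in carriers:
                balanced[g] = balanced.get(g, 0.0) + share
    if dropped:
        logger.debug("dropped %d spectra with no identified carrier group", dropped)
    return balanced, dropped


def abundance_table(
    psm_frame: pd.DataFrame,
    peptide_map: PeptideMap,
    identification: pd.DataFrame,
) -> AbundanceTable:
    """Balanced spectral counts for every sample in a PSM frame.

    ``identification`` is the boolean group x sample matrix; its index fixes
    the row order of the result.
    """
    samples = list(identification.columns)
    counts = pd.DataFrame(
        0.0, index=identification.index, columns=samples, dtype=float
    )
    totals = pd.Series(0.0, index=samples, dtype=float)
    dropped = pd.Series(0, index=samples, dtype=int)
    for sample in samples:
        sub = psm_frame.loc[psm_frame["sample_id"] == sample]
        peptide_counts = dict(zip(sub["peptide"], sub["spectral_count"]))
        identified = set(identification.index[identification[sample]])
        balanced, n_dropped = balance_sample(peptide_counts, peptide_map, identified)
        for group, value in balanced.items():
            counts.at[group, sample] = value
        totals[sample] = sum(balanced.values())
        dropped[sample] = n_dropped
    return AbundanceTable(counts=counts, total_spectra=totals, dropped_spectra=dropped)
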