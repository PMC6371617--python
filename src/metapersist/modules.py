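"""Phylum-stratified metabolic-module inference and quantification.

A metabolic module (an ordered list of enzymatic steps, each a set of
OR-alternative KO terms, optionally with AND-components) is *inferred* for a
(sample, phylum) stratum when at least one third of its steps are covered by
KO terms with identified protein evidence in that phylum -- coverage is
never pooled across phyla.  The threshold is the exact rational 1/3 with a
>= comparison, so a 3-step module with one covered step is inferred and
float edge cases cannot arise.

Module abundance is reported two ways: the mean balanced spectral count of
the phylum's groups mapping to the module in the sample, and their summed
balanced counts as a fraction of the sample's total spectra.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import CATEGORY_MICROBIAL, AnnotatedGroup
from .grouping import ConfigError
from .io import ModuleDefinition

DEFAULT_COVERAGE_THRESHOLD = Fraction(1, 3)

#: The four phyla dominating gut metaproteomes; used for redundancy classes.
MAJOR_PHYLA = frozenset(
    {"Firmicutes", "Bacteroidetes", "Actinobacteria", "Proteobacteria"}
)

CLASS_SINGLE = "single-phylum"
CLASS_MULTI = "multi-phylum"
CLASS_ALL_MAJOR = "all-four-major-phyla"


@dataclass(frozen=True)
class ModuleCall:
    """Coverage/inference/abundance of one module in one (sample, phylum)."""

    sample_id: str
    phylum: str
    module_id: str
    coverage: Fraction
    inferred: bool
    abundance_mean: float = 0.0
    abundance_fraction: float = 0.0


def detected_ko_sets(
    annotated_groups: Sequence[AnnotatedGroup],
    identification: pd.DataFrame,
) -> dict[tuple[str, str], set[str]]:
    """KO terms with identified microbial protein evidence per (sample, phylum).

    Human and unassigned groups, and groups without a KO term, contribute
    nothing.
    """
    by_group = {g.group_id: g for g in annotated_groups}
    detected: dict[tuple[str, str], set[str]] = defaultdict(set)
    for sample in identification.columns:
        for group_id in identification.index[identification[sample]]:
            g = by_group.get(group_id)
            if (
                g is not None
                and g.category == CATEGORY_MICROBIAL
                and g.ko_term is not None
                and g.phylum is not None
            ):
                detected[(sample, g.phylum)].add(g.ko_term)
    return dict(detected)


def compute_coverage(module: ModuleDefinition, ko_set: Iterable[str]) -> Fraction:
    """Fraction of the module's steps covered by the KO set.

    A step is covered iff every AND-component has at least one OR-alternative
    present in ``ko_set``.
    """
    kos = set(ko_set)
    covered = sum(
        1
        for step in module.steps
        if all(not component.isdisjoint(kos) for component in step)
    )
    return Fraction(covered, len(module.steps))


def infer_modules(
    modules: Sequence[ModuleDefinition],
    detected_sets: Mapping[tuple[str, str], set[str]],
    threshold: Fraction = DEFAULT_COVERAGE_THRESHOLD,
) -> list[ModuleCall]:
    """Evaluate every module against every (sample, phylum) KO set.

    Coverage is computed within each phylum separately; evidence is never
    pooled across phyla.  ``inferred`` is ``coverage >= threshold`` in exact
    rational arithmetic.
    """
    threshold = Fraction(threshold)
    if not 0 < threshold <= 1:
        raise ConfigError(f"coverage threshold {threshold} outside (0, 1]")
    calls = []
    for (sample, phylum), kos in sorted(detected_sets.items()):
        for module in modules:
            coverage = compute_coverage(module, kos)
            calls.append(
                ModuleCall(
                    sample_id=sample,
                    phylum=phylum,
                    module_id=module.module_id,
                    coverage=coverage,
                    inferred=coverage >= threshold,
                )
            )
    return calls


def quantify_modules(
    calls: Sequence[ModuleCall],
    modules: Sequence[ModuleDefinition],
    annotated_groups: Sequence[AnnotatedGroup],
    counts: pd.DataFrame,
    identification: pd.DataFrame,
    total_spectra: pd.Series,
) -> list[ModuleCall]:
    """Fill the abundance fields of module calls from balanced counts.

    A group maps to a module iff its KO appears as any alternative in any
    step; only groups identified in the sample and matching the call's
    phylum contribute.  ``abundance_mean`` is the arithmetic mean of their
    balanced counts, ``abundance_fraction`` their sum over the sample total;
    both are 0 when no group maps.
    """
    module_kos = {m.module_id: m.ko_terms for m in modules}
    microbial = [
        g
        for g in annotated_groups
        if g.category == CATEGORY_MICROBIAL and g.ko_term and g.phylum
    ]
    # (phylum, module) -> candidate group ids
    candidates: dict[tuple[str, str], list[str]] = defaultdict(list)
    for g in microbial:
        for module_id, kos in module_kos.items():
            if g.ko_term in kos:
                candidates[(g.phylum, module_id)].append(g.group_id)

    out = []
    for call in calls:
        groups = [
            gid
            for gid in candidates.get((call.phylum, call.module_id), ())
            if bool(identification.at[gid, call.sample_id])
        ]
        if not groups:
            out.append(replace(call, abundance_mean=0.0, abundance_fraction=0.0))
            continue
        values = [float(counts.at[gid, call.sample_id]) for gid in groups]
        total = float(total_spectra[call.sample_id])
        out.append(
            replace(
                call,
                abundance_mean=sum(values) / len(values),
                abundance_fraction=(sum(values) / total) if total > 0 else 0.0,
            )
        )
    return out


@dataclass(frozen=True)
class RedundancyClass:
    module_id: str
    phyla: tuple[str, ...]
    redundancy_class: str


def redundancy_classes(calls: Sequence[ModuleCall]) -> list[RedundancyClass]:
    """Classify each inferred module by the phyla that ever provided inference.

    A module inferred in one phylum only is single-phylum; in two or more,
    multi-phylum; a module covering all four major gut phyla gets the most
    specific class.
    """
    phyla_of: dict[str, set[str]] = defaultdict(set)
    for call in calls:
        if call.inferred:
            phyla_of[call.module_id].add(call.phylum)
    out = []
    for module_id in sorted(phyla_of):
        phyla = phyla_of[module_id]
        if MAJOR_PHYLA <= phyla:
            cls = CLASS_ALL_MAJOR
        elif len(phyla) >= 2:
            cls = CLASS_MULTI
        else:
            cls = CLASS_SINGLE
        out.append(RedundancyClass(module_id, tuple(sorted(phyla)), cls))
    return out


def calls_to_frame(calls: Sequence[ModuleCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "phylum": [c.phylum for c in calls],
            "module_id": [c.module_id for c in calls],
            "coverage": [float(c.coverage) for c in calls],
            "inferred": [c.inferred for c in calls],
            "abundance_mean": [c.abundance_mean for c in calls],
            "abundance_fraction": [c.abundance_fraction for c in calls],
        }
    )
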