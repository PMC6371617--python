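"""Module coverage, the 1/3 inference rule, abundance, and redundancy
classes.

The coverage oracle expands each step's AND-of-OR structure into its
disjunctive normal form (every way of choosing one alternative per
component) and checks whether any choice is a subset of the detected KO
set -- an evaluation route independent of the implementation's
per-component check.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from metapersist import compute_coverage, detected_ko_sets, infer_modules
from metapersist.annotation import AnnotatedGroup
from metapersist.grouping import ConfigError
from metapersist.io import ModuleDefinition
from metapersist.modules import (
    CLASS_ALL_MAJOR,
    CLASS_MULTI,
    CLASS_SINGLE,
    ModuleCall,
    quantify_modules,
    redundancy_classes,
)


def _module(module_id, steps):
    return ModuleDefinition(
        module_id,
        "toy",
        tuple(tuple(frozenset(c) for c in step) for step in steps),
    )


def _coverage_oracle(module: ModuleDefinition, ko_set: set[str]) -> Fraction:
    covered = 0
    for step in module.steps:
        choices = itertools.product(*(sorted(c) for c in step))
        if any(set(choice) <= ko_set for choice in choices):
            covered += 1
    return Fraction(covered, len(module.steps))


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------


def test_three_step_module_one_covered_step_is_exactly_one_third():
    m = _module("MF0001", [[["K00001"]], [["K00002"]], [["K00003"]]])
    assert compute_coverage(m, {"K00001"}) == Fraction(1, 3)


def test_empty_ko_set_gives_zero_coverage():
    m = _module("MF0001", [[["K00001"]], [["K00002"]]])
    assert compute_coverage(m, set()) == 0


def test_or_alternative_satisfies_a_step():
    m = _module("MF0001", [[["K00001", "K00002"]], [["K00003"]]])
    assert compute_coverage(m, {"K00002"}) == Fraction(1, 2)


def test_and_components_all_required():
    m = _module("MF0001", [[["K00001"], ["K00002"]]])
    assert compute_coverage(m, {"K00001"}) == 0
    assert compute_coverage(m, {"K00001", "K00002"}) == 1


def test_coverage_matches_dnf_oracle_on_random_modules():
    """All modules with <= 4 steps and <= 3 alternatives, against DNF
    truth-table evaluation, over random KO subsets."""
    rng = np.random.default_rng(11)
    kos = [f"K{i:05d}" for i in range(1, 13)]
    for _ in range(60):
        steps = []
        for _ in range(int(rng.integers(1, 5))):
            components = []
            for _ in range(int(rng.integers(1, 3))):
                alts = rng.choice(len(kos), size=int(rng.integers(1, 4)), replace=False)
                components.append([kos[int(a)] for a in alts])
            steps.append(components)
        module = _module("MF0001", steps)
        for _ in range(5):
            ko_set = {k for k in kos if rng.random() < 0.4}
            assert compute_coverage(module, ko_set) == _coverage_oracle(module, ko_set)


def test_coverage_is_monotone_in_the_ko_set():
    rng = np.random.default_rng(23)
    kos = [f"K{i:05d}" for i in range(1, 10)]
    module = _module(
        "MF0001", [[["K00001", "K00002"]], [["K00003"], ["K00004"]], [["K00005"]]]
    )
    for _ in range(30):
        small = {k for k in kos if rng.random() < 0.3}
        large = small | {k for k in kos if rng.random() < 0.3}
        assert compute_coverage(module, small) <= compute_coverage(module, large)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def test_one_third_coverage_is_inferred_but_one_quarter_is_not():
    three = _module("MF0001", [[["K00001"]], [["K00002"]], [["K00003"]]])
    four = _module(
        "MF0002", [[["K00001"]], [["K00004"]], [["K00005"]], [["K00006"]]]
    )
    detected = {("S1", "Firmicutes"): {"K00001"}}
    calls = {c.module_id: c for c in infer_modules([three, four], detected)}
    assert calls["MF0001"].inferred  # 1/3 >= 1/3
    assert not calls["MF0002"].inferred  # 1/4 < 1/3


def test_coverage_is_never_pooled_across_phyla():
    m = _module(
        "MF0001", [[["K00001"]], [["K00002"]], [["K00003"]], [["K00004"]]]
    )
    detected = {
        ("S1", "Firmicutes"): {"K00001"},
        ("S1", "Bacteroidetes"): {"K00002"},
    }
    calls = infer_modules([m], detected)
    assert all(not c.inferred for c in calls)
    assert all(c.coverage == Fraction(1, 4) for c in calls)


def test_inference_threshold_out_of_range_is_config_error():
    with pytest.raises(ConfigError):
        infer_modules([], {}, threshold=Fraction(3, 2))


# ---------------------------------------------------------------------------
# detected KO sets
# ---------------------------------------------------------------------------


def _ident(index, columns, true_cells):
    frame = pd.DataFrame(False, index=index, columns=columns)
    for gid, sample in true_cells:
        frame.at[gid, sample] = True
    return frame


def test_detected_ko_sets_from_identified_microbial_groups():
    annotated = [
        AnnotatedGroup("PG1", "K00925", "Firmicutes", None, "microbial"),
        AnnotatedGroup("PG2", "K00925", "Bacteroidetes", None, "microbial"),
        AnnotatedGroup("PG3", None, None, None, "human"),
    ]
    ident = _ident(
        ["PG1", "PG2", "PG3"],
        ["S1"],
        [("PG1", "S1"), ("PG2", "S1"), ("PG3", "S1")],
    )
    detected = detected_ko_sets(annotated, ident)
    # the same KO identified in two phyla appears in both phylum sets;
    # human groups contribute nothing
    assert detected == {
        ("S1", "Firmicutes"): {"K00925"},
        ("S1", "Bacteroidetes"): {"K00925"},
    }


# ---------------------------------------------------------------------------
# abundance
# ---------------------------------------------------------------------------


def test_module_abundance_mean_and_fraction():
    module = _module("MF0001", [[["K00001"]], [["K00002"]], [["K00003"]]])
    annotated = [
        AnnotatedGroup("PG1", "K00001", "Firmicutes", None, "microbial"),
        AnnotatedGroup("PG2", "K00002", "Firmicutes", None, "microbial"),
        AnnotatedGroup("PG3", "K00009", "Firmicutes", None, "microbial"),
    ]
    counts = pd.DataFrame({"S1": [4.0, 6.0, 90.0]}, index=["PG1", "PG2", "PG3"])
    ident = _ident(
        ["PG1", "PG2", "PG3"], ["S1"], [("PG1", "S1"), ("PG2", "S1"), ("PG3", "S1")]
    )
    call = ModuleCall("S1", "Firmicutes", "MF0001", Fraction(2, 3), True)
    (out,) = quantify_modules(
        [call], [module], annotated, counts, ident, counts.sum(axis=0)
    )
    assert out.abundance_mean == pytest.approx(5.0)  # mean of 4 and 6
    assert out.abundance_fraction == pytest.approx(0.1)  # 10 / 100


def test_module_abundance_zero_without_mapping_groups():
    module = _module("MF0001", [[["K00001"]]])
    call = ModuleCall("S1", "Firmicutes", "MF0001", Fraction(0, 1), False)
    counts = pd.DataFrame({"S1": [5.0]}, index=["PG1"])
    ident = _ident(["PG1"], ["S1"], [("PG1", "S1")])
    (out,) = quantify_modules(
        [call],
        [module],
        [AnnotatedGroup("PG1", "K00099", "Firmicutes", None, "microbial")],
        counts,
        ident,
        counts.sum(axis=0),
    )
    assert out.abundance_mean == 0.0
    assert out.abundance_fraction == 0.0


# ---------------------------------------------------------------------------
# redundancy classes
# ---------------------------------------------------------------------------


def test_redundancy_classes():
    def call(sample, phylum, module_id, inferred=True):
        return ModuleCall(sample, phylum, module_id, Fraction(1, 2), inferred)

    calls = [
        call("S1", "Firmicutes", "MF0001"),
        call("S2", "Firmicutes", "MF0001"),
        call("S1", "Firmicutes", "MF0002"),
        call("S1", "Bacteroidetes", "MF0002"),
        call("S1", "Firmicutes", "MF0003"),
        call("S1", "Bacteroidetes", "MF0003"),
        call("S2", "Actinobacteria", "MF0003"),
        call("S2", "Proteobacteria", "MF0003"),
        call("S2", "Verrucomicrobia", "MF0004", inferred=False),
    ]
    classes = {r.module_id: r.redundancy_class for r in redundancy_classes(calls)}
    assert classes == {
        "MF0001": CLASS_SINGLE,
        "MF0002": CLASS_MULTI,
        "MF0003": CLASS_ALL_MAJOR,
    }
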