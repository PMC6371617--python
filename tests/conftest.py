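"""Shared fixtures.

The default synthetic cohort (5 individuals x 5 time points, 20k spectra
per sample) and its full pipeline run are expensive enough to share at
session scope; smaller configurations are built inline where a test needs
different study conditions.
"""

from __future__ import annotations

import pathlib

import pytest

from metapersist import PipelineConfig, SimulationConfig, run_all, simulate_study


@pytest.fixture(scope="session")
def default_study(tmp_path_factory):
    """The default study conditions, written to disk once per session."""
    outdir = tmp_path_factory.mktemp("study")
    study = simulate_study(SimulationConfig(rng_seed=1), outdir=outdir)
    return study, outdir


@pytest.fixture(scope="session")
def pipeline_result(default_study, tmp_path_factory):
    """Full pipeline run over the default synthetic cohort."""
    study, outdir = default_study
    run_dir = tmp_path_factory.mktemp("run")
    config = PipelineConfig(
        fasta_paths=tuple(sorted(outdir.glob("*.fasta"))),
        psm_path=outdir / "psms.tsv",
        annotation_path=outdir / "annotations.tsv",
        module_path=outdir / "modules.txt",
        outdir=run_dir,
    )
    return run_all(config)


def small_config(**overrides) -> SimulationConfig:
    """A reduced cohort for tests that only need structure, not scale."""
    base = dict(
        n_individuals=3,
        timepoints_per_individual=3,
        proteins_per_individual_db=40,
        n_ko_terms=12,
        depth=2000,
        expressed_per_sample=20,
        n_modules=6,
        max_seq_len=300,
        rng_seed=7,
    )
    base.update(overrides)
    return SimulationConfig(**base)
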