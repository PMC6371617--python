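"""End-to-end orchestration: group -> identify -> balance -> annotate ->
infer modules -> persistence/similarity, with deterministic TSV outputs and
a run manifest.

The stage outputs are pure functions of the inputs and the configuration;
rerunning with the same inputs reproduces every output byte for byte, which
the manifest's checksums make easy to verify.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from . import io as mio
from .annotation import (
    CATEGORY_HUMAN,
    CATEGORY_MICROBIAL,
    AmbiguityReport,
    AnnotatedGroup,
    ambiguity_report,
    annotate_groups,
)
from .balancing import AbundanceTable, abundance_table
from .grouping import (
    PeptideMap,
    ProteinGroup,
    cluster_proteins,
    groups_to_frame,
    identification_matrix,
    map_peptides,
)
from .modules import (
    ModuleCall,
    RedundancyClass,
    calls_to_frame,
    detected_ko_sets,
    infer_modules,
    quantify_modules,
    redundancy_classes,
)
from .persistence import (
    CoherenceResult,
    PresenceMatrix,
    SampleClustering,
    cluster_samples,
    functional_influence,
    individual_coherence,
    persistence_across_individuals,
    persistence_by_individual,
    spearman_matrix,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass(frozen=True)
class PipelineConfig:
    """All paths and analysis constants for a run.

    FASTA files are one per individual; the file stem is the individual id.
    """

    fasta_paths: tuple[Path, ...]
    psm_path: Path
    annotation_path: Path
    module_path: Path
    outdir: Path
    identity_threshold: float = 0.90
    coverage_threshold: Fraction = Fraction(1, 3)
    min_distinct_peptides: int = 2
    min_unique_peptides: int = 1
    min_peptide_length: int = mio.DEFAULT_MIN_PEPTIDE_LENGTH
    linkage: str = "average"
    distance_mode: str = "rho_rows"
    ile_leu_equivalent: bool = False
    rng_seed: int = 0

    def input_paths(self) -> list[Path]:
        return [*self.fasta_paths, self.psm_path, self.annotation_path, self.module_path]


@dataclass
class PipelineResult:
    """Everything a run computed, in memory."""

    config: PipelineConfig
    groups: list[ProteinGroup]
    peptide_map: PeptideMap
    identification: pd.DataFrame
    abundance: AbundanceTable
    annotated: list[AnnotatedGroup]
    ambiguity: AmbiguityReport
    module_calls: list[ModuleCall]
    redundancy: list[RedundancyClass]
    presence: dict[str, PresenceMatrix]
    persistence_individual: pd.DataFrame
    persistence_across: pd.DataFrame
    influence: pd.DataFrame
    rho: pd.DataFrame
    clustering: SampleClustering
    coherence: CoherenceResult
    manifest: dict


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _stage(name: str):
    """Wrap stage bodies so failures abort with the stage name and cause."""

    class _StageContext:
        def __enter__(self):
            logger.info("stage: %s", name)

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _StageContext()


def build_presence_matrices(
    annotated: Sequence[AnnotatedGroup],
    identification: pd.DataFrame,
    module_calls: Sequence[ModuleCall],
    sample_meta: pd.DataFrame,
) -> dict[str, PresenceMatrix]:
    """Binary presence at the three entity levels, microbial entities only.

    Protein-group presence is the identification matrix; a KO term is
    present when any identified microbial group carries it; a module is
    present when it is inferred in any phylum of the sample.
    """
    samples = list(identification.columns)
    by_group = {g.group_id: g for g in annotated}
    microbial_ids = [
        gid for gid in identification.index
        if by_group[gid].category == CATEGORY_MICROBIAL
    ]
    group_presence = identification.loc[microbial_ids]

    ko_terms = sorted(
        {by_group[g].ko_term for g in microbial_ids if by_group[g].ko_term}
    )
    ko_presence = pd.DataFrame(False, index=ko_terms, columns=samples)
    for gid in microbial_ids:
        ko = by_group[gid].ko_term
        if ko:
            ko_presence.loc[ko] = ko_presence.loc[ko] | identification.loc[gid]

    module_ids = sorted({c.module_id for c in module_calls})
    module_presence = pd.DataFrame(False, index=module_ids, columns=samples)
    for call in module_calls:
        if call.inferred:
            module_presence.at[call.module_id, call.sample_id] = True

    return {
        "protein_group": PresenceMatrix("protein_group", group_presence, sample_meta),
        "ko_term": PresenceMatrix("ko_term", ko_presence, sample_meta),
        "module": PresenceMatrix("module", module_presence, sample_meta),
    }


def run_all(config: PipelineConfig) -> PipelineResult:
    """Run every stage in order and write all outputs plus the manifest."""
    for path in config.input_paths():
        if not Path(path).exists():
            raise PipelineError(f"missing input file: {path}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with _stage("load-inputs"):
        records_by_individual = {
            Path(p).stem: mio.read_fasta(p, individual_id=Path(p).stem)
            for p in sorted(config.fasta_paths)
        }
        # study-wide de-replicated union; a shared accession must carry the
        # same sequence everywhere
        union: dict[str, mio.ProteinRecord] = {}
        for individual, records in records_by_individual.items():
            for record in records:
                known = union.get(record.accession)
                if known is None:
                    union[record.accession] = record
                elif known.sequence != record.sequence:
                    raise mio.ValidationError(
                        f"accession {record.accession!r} has conflicting sequences "
                        f"between individual databases"
                    )
        records = [union[a] for a in sorted(union)]
        psm_rows = mio.read_psm_table(
            config.psm_path, min_peptide_length=config.min_peptide_length
        )
        psm_frame = mio.psms_to_frame(psm_rows)
        annotations = mio.read_annotation_table(config.annotation_path)
        modules = mio.read_module_definitions(config.module_path)
        sample_meta = (
            psm_frame[["sample_id", "individual_id", "day"]]
            .drop_duplicates()
            .set_index("sample_id")
            .sort_index()
        )

    with _stage("group"):
        groups = cluster_proteins(
            records,
            threshold=config.identity_threshold,
            ile_leu_equivalent=config.ile_leu_equivalent,
        )
        groups_frame = groups_to_frame(groups)
        groups_frame.to_csv(
            outdir / "groups.tsv", sep="\t", index=False, lineterminator="\n"
        )

    with _stage("identify"):
        peptide_map = map_peptides(
            psm_frame["peptide"], groups, records, config.ile_leu_equivalent
        )
        identification = identification_matrix(
            groups,
            peptide_map,
            psm_frame,
            config.min_distinct_peptides,
            config.min_unique_peptides,
        )
        mio.write_matrix(
            identification.astype(int), outdir / "identification.tsv", "group_id"
        )
        pmap_frame = pd.DataFrame(
            {
                "peptide": list(peptide_map.mapping),
                "group_ids": [
                    ";".join(sorted(gs)) for gs in peptide_map.mapping.values()
                ],
            }
        ).sort_values("peptide", kind="mergesort")
        pmap_frame.to_csv(
            outdir / "peptide_map.tsv", sep="\t", index=False, lineterminator="\n"
        )

    with _stage("balance"):
        abundance = abundance_table(psm_frame, peptide_map, identification)
        mio.write_matrix(abundance.counts, outdir / "abundance.tsv", "group_id")
        totals = pd.DataFrame(
            {
                "total_spectra": abundance.total_spectra,
                "dropped_spectra": abundance.dropped_spectra,
            }
        )
        totals.index.name = "sample_id"
        totals.to_csv(outdir / "sample_totals.tsv", sep="\t", lineterminator="\n")

    with _stage("annotate"):
        annotated = annotate_groups(groups, annotations)
        ambiguity = ambiguity_report(groups, annotations)
        pd.DataFrame(
            {
                "group_id": [g.group_id for g in annotated],
                "ko_term": [g.ko_term or "" for g in annotated],
                "phylum": [g.phylum or "" for g in annotated],
                "genus": [g.genus or "" for g in annotated],
                "category": [g.category for g in annotated],
            }
        ).to_csv(
            outdir / "annotated_groups.tsv", sep="\t", index=False, lineterminator="\n"
        )

    with _stage("infer-modules"):
        detected = detected_ko_sets(annotated, identification)
        calls = infer_modules(modules, detected, config.coverage_threshold)
        calls = quantify_modules(
            calls, modules, annotated, abundance.counts, identification,
            abundance.total_spectra,
        )
        calls_to_frame(calls).to_csv(
            outdir / "module_calls.tsv", sep="\t", index=False, lineterminator="\n"
        )
        redundancy = redundancy_classes(calls)
        pd.DataFrame(
            {
                "module_id": [r.module_id for r in redundancy],
                "phyla": [";".join(r.phyla) for r in redundancy],
                "redundancy_class": [r.redundancy_class for r in redundancy],
            }
        ).to_csv(
            outdir / "module_redundancy.tsv", sep="\t", index=False, lineterminator="\n"
        )

    with _stage("stats"):
        presence = build_presence_matrices(annotated, identification, calls, sample_meta)
        rows = []
        for level, matrix in presence.items():
            for individual in matrix.individuals():
                counts = persistence_by_individual(matrix, individual)
                fr = counts.fractions()
                rows.append(
                    (level, individual, counts.all_observed, counts.multiple_not_all,
                     counts.single, fr[0], fr[1], fr[2])
                )
        persistence_individual = pd.DataFrame(
            rows,
            columns=["entity_level", "individual_id", "all_timepoints",
                     "multiple_not_all", "single", "frac_all", "frac_multiple",
                     "frac_single"],
        )
        persistence_individual.to_csv(
            outdir / "persistence_by_individual.tsv", sep="\t", index=False,
            lineterminator="\n",
        )

        rows = []
        for level, matrix in presence.items():
            counts = persistence_across_individuals(matrix)
            fr = counts.fractions()
            rows.append(
                (level, counts.all_observed, counts.multiple_not_all, counts.single,
                 fr[0], fr[1], fr[2])
            )
        persistence_across = pd.DataFrame(
            rows,
            columns=["entity_level", "all_individuals", "multiple_not_all", "single",
                     "frac_all", "frac_multiple", "frac_single"],
        )
        persistence_across.to_csv(
            outdir / "persistence_across_individuals.tsv", sep="\t", index=False,
            lineterminator="\n",
        )

        annotation_by_accession = {a.accession: a for a in annotations}
        universes = {
            individual: {
                annotation_by_accession[r.accession].ko_term
                for r in recs
                if r.accession in annotation_by_accession
                and annotation_by_accession[r.accession].ko_term
            }
            for individual, recs in records_by_individual.items()
        }
        rows = []
        for sample in identification.columns:
            individual = sample_meta.at[sample, "individual_id"]
            fractions = functional_influence(detected, universes[individual], sample)
            for phylum in sorted(fractions):
                rows.append((sample, phylum, fractions[phylum]))
        influence = pd.DataFrame(
            rows, columns=["sample_id", "phylum", "functional_influence"]
        )
        influence.to_csv(
            outdir / "functional_influence.tsv", sep="\t", index=False,
            lineterminator="\n",
        )

        rho = spearman_matrix(abundance.counts)
        mio.write_matrix(rho, outdir / "spearman_rho.tsv", "sample_id")
        clustering = cluster_samples(rho, config.linkage, config.distance_mode)
        (outdir / "sample_dendrogram.nwk").write_text(
            clustering.newick + "\n", encoding="utf-8"
        )
        coherence = individual_coherence(
            rho, clustering, sample_meta["individual_id"].to_dict()
        )
        pd.DataFrame(
            {
                "nearest_neighbor_same_individual_fraction": [
                    coherence.nearest_neighbor_fraction
                ],
                "adjusted_rand_at_k": [coherence.adjusted_rand],
            }
        ).to_csv(
            outdir / "coherence.tsv", sep="\t", index=False, lineterminator="\n"
        )

    with _stage("manifest"):
        manifest = {
            "version": __version__,
            "config": {
                k: (
                    [str(p) for p in v]
                    if isinstance(v, tuple)
                    else str(v)
                )
                for k, v in dataclasses.asdict(config).items()
            },
            "inputs": {str(p): _sha256(Path(p)) for p in config.input_paths()},
            "outputs": {
                p.name: _sha256(p)
                for p in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.nwk"))
            },
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )

    return PipelineResult(
        config=config,
        groups=groups,
        peptide_map=peptide_map,
        identification=identification,
        abundance=abundance,
        annotated=annotated,
        ambiguity=ambiguity,
        module_calls=calls,
        redundancy=redundancy,
        presence=presence,
        persistence_individual=persistence_individual,
        persistence_across=persistence_across,
        influence=influence,
        rho=rho,
        clustering=clustering,
        coherence=coherence,
        manifest=manifest,
    )
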