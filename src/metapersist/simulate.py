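"""Synthetic longitudinal metaproteome cohorts.

The generator emulates the statistical structure of a multi-individual,
multi-time-point gut metaproteome study so every downstream stage can be
exercised without any real data:

* a global protein pool organised as within-KO sequence families -- one
  ancestor per KO term, phylum-level founders diverged ~20% from it (below
  the 90% grouping threshold, but sharing enough exact tryptic peptides to
  exercise shared-peptide balancing), and ~95%-identity variants within each
  family (above the threshold, so grouping is exercised too);
* a configurable fraction of KO terms encoded redundantly in two or more
  phyla, individual-specific databases sampled from the pool, and a human
  protein fraction that is always expressed and comparatively abundant;
* longitudinal expression with high protein-level turnover but KO-term
  preservation: at each time point a ``turnover`` fraction of expressed
  proteins is replaced, and with probability ``ko_preservation`` the
  replacement is drawn from unexpressed database proteins carrying the same
  KO term -- in any phylum.  This single mechanism produces protein-level
  volatility, KO-level stability, and phylum switching of module evidence;
* in-silico tryptic digestion (cleave after K/R except before P, no missed
  cleavages, peptides of 6-40 residues) and multinomial sampling of a fixed
  number of spectra per sample, proportional to protein abundance.

Everything is a pure function of ``rng_seed``: repeated runs emit
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import parser as _pyteomics_parser

from . import io as mio
from .grouping import ConfigError
from .io import AnnotationRow, ModuleDefinition, ProteinRecord, PsmRow

logger = logging.getLogger(__name__)

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: cleave C-terminal to K/R unless the next residue is proline
TRYPSIN_RULE = r"[KR](?!P)"

DEFAULT_PHYLA = (
    "Firmicutes",
    "Bacteroidetes",
    "Actinobacteria",
    "Proteobacteria",
    "Verrucomicrobia",
)
DEFAULT_PHYLUM_WEIGHTS = (0.34, 0.30, 0.16, 0.14, 0.06)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    The default cohort is five individuals sampled at five time points over
    roughly a year, with half of the expressed proteome replaced between
    consecutive time points, nine out of ten replacements preserving the
    departing protein's KO term, and most KO terms encoded in at least two
    phyla.  See docs/methods.md for the rationale behind each default.
    """

    n_individuals: int = 5
    timepoints_per_individual: int = 5
    proteins_per_individual_db: int = 150
    n_ko_terms: int = 40
    phyla: tuple[str, ...] = DEFAULT_PHYLA
    phylum_weights: tuple[float, ...] = DEFAULT_PHYLUM_WEIGHTS
    ko_phylum_redundancy: float = 0.8
    turnover: float = 0.5
    ko_preservation: float = 0.9
    individual_effect: float = 0.9
    human_fraction: float = 0.05
    depth: int = 20000
    rng_seed: int = 1
    # structural knobs (pool geometry and noise)
    family_size: int = 3
    family_mutation_rate: float = 0.025
    phylum_divergence: float = 0.20
    no_ko_fraction: float = 0.15
    expressed_per_sample: int = 60
    n_modules: int = 16
    abundance_sigma: float = 1.5
    sample_noise_sigma: float = 0.3
    min_seq_len: int = 80
    max_seq_len: int = 600
    day_spacing: int = 90

    def __post_init__(self) -> None:
        for name in (
            "ko_phylum_redundancy",
            "turnover",
            "ko_preservation",
            "individual_effect",
            "human_fraction",
            "no_ko_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name}={value} outside [0, 1]")
        if self.n_individuals < 2:
            raise ConfigError("n_individuals must be >= 2")
        if self.timepoints_per_individual < 2:
            raise ConfigError("timepoints_per_individual must be >= 2")
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")
        if self.ko_phylum_redundancy > 0 and len(self.phyla) < 2:
            raise ConfigError(
                "ko_phylum_redundancy > 0 needs at least two phyla to draw from"
            )
        if len(self.phyla) != len(self.phylum_weights):
            raise ConfigError("phyla and phylum_weights lengths differ")

    def individuals(self) -> tuple[str, ...]:
        return tuple(f"P{i + 1:02d}" for i in range(self.n_individuals))

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if isinstance(value, tuple):
                value = ",".join(str(v) for v in value)
            lines.append(f"{f.name} = {value}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        kwargs: dict = {}
        types = {f.name: f for f in dataclasses.fields(cls)}
        for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise mio.FormatError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in types:
                raise mio.FormatError(f"{path}:{lineno}: unknown key {key!r}")
            default = getattr(cls, key, None)
            if key == "phyla":
                kwargs[key] = tuple(value.split(","))
            elif key == "phylum_weights":
                kwargs[key] = tuple(float(v) for v in value.split(","))
            elif isinstance(default, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(value)
            elif isinstance(default, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class Cohort:
    """The generated protein universe and per-individual databases."""

    individuals: tuple[str, ...]
    records: dict[str, ProteinRecord]
    annotations: list[AnnotationRow]
    modules: list[ModuleDefinition]
    databases: dict[str, list[str]]
    human_accessions: tuple[str, ...]

    @property
    def ko_of(self) -> dict[str, str | None]:
        return {a.accession: a.ko_term for a in self.annotations}

    @property
    def phylum_of(self) -> dict[str, str | None]:
        return {a.accession: a.phylum for a in self.annotations}


@dataclass(frozen=True)
class SampleTruth:
    """Ground-truth expression for one sample."""

    sample_id: str
    individual_id: str
    day: int
    abundances: dict[str, float]


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    cohort: Cohort
    samples: list[SampleTruth]
    psms: list[PsmRow]


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(AA[rng.integers(0, len(AA), size=length)])


def _mutate(rng: np.random.Generator, sequence: str, rate: float) -> str:
    """Substitute each residue independently with probability ``rate``
    (always to a different residue, so lengths never change)."""
    arr = np.array(list(sequence))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        replacements = AA[rng.integers(0, len(AA) - 1, size=int(hit.sum()))]
        current = arr[hit]
        # shift any accidental self-substitution to the next residue
        same = replacements == current
        if same.any():
            idx = np.searchsorted(AA, current[same])
            replacements[same] = AA[(idx + 1) % len(AA)]
        arr[hit] = replacements
    return "".join(arr)


def tryptic_peptides(
    sequence: str, min_length: int = 6, max_length: int = 40
) -> list[str]:
    """In-silico tryptic digest: cleave after K/R except before P, zero
    missed cleavages, retain peptides of ``min_length``-``max_length``
    residues.  Returns the distinct peptides in sorted order.
    """
    peptides = _pyteomics_parser.cleave(
        sequence, TRYPSIN_RULE, missed_cleavages=0, min_length=min_length
    )
    return sorted(p for p in peptides if len(p) <= max_length)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(
    config: SimulationConfig, seed: np.random.SeedSequence | None = None
) -> Cohort:
    """Build the protein pool, annotations, module set and per-individual
    databases.  Fully determined by ``config.rng_seed``."""
    if seed is None:
        seed = np.random.SeedSequence([config.rng_seed, 0])
    rng = np.random.default_rng(seed)
    weights = np.asarray(config.phylum_weights, dtype=float)
    weights = weights / weights.sum()
    kos = [f"K{i + 1:05d}" for i in range(config.n_ko_terms)]

    records: dict[str, ProteinRecord] = {}
    annotations: list[AnnotationRow] = []
    counter = 0

    def new_accession(prefix: str = "orf") -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}{counter:05d}"

    for ko in kos:
        if rng.random() < config.ko_phylum_redundancy:
            n_phyla = 3 if (len(config.phyla) >= 3 and rng.random() < 0.3) else 2
        else:
            n_phyla = 1
        chosen = rng.choice(
            len(config.phyla), size=n_phyla, replace=False, p=weights
        )
        length = int(rng.integers(config.min_seq_len, config.max_seq_len + 1))
        ancestor = _random_sequence(rng, length)
        for pi in chosen:
            phylum = config.phyla[int(pi)]
            founder = _mutate(rng, ancestor, config.phylum_divergence)
            genus = f"{phylum}_genus{int(rng.integers(1, 4))}"
            family = [founder] + [
                _mutate(rng, founder, config.family_mutation_rate)
                for _ in range(config.family_size - 1)
            ]
            for seq in family:
                accession = new_accession()
                records[accession] = ProteinRecord(accession, seq)
                annotations.append(
                    AnnotationRow(accession, ko, phylum, genus, phylum)
                )

    # proteins Ghost-KOALA-style annotation would miss: taxonomy without a KO
    # term, or nothing at all
    n_no_ko = round(config.no_ko_fraction * len(records))
    for i in range(n_no_ko):
        length = int(rng.integers(config.min_seq_len, config.max_seq_len + 1))
        accession = new_accession()
        records[accession] = ProteinRecord(accession, _random_sequence(rng, length))
        if rng.random() < 0.7:
            phylum = config.phyla[int(rng.choice(len(config.phyla), p=weights))]
            annotations.append(
                AnnotationRow(accession, None, phylum, f"{phylum}_genus1", phylum)
            )
        else:
            annotations.append(AnnotationRow(accession, None, None, None, "unassigned"))

    microbial_accessions = sorted(records)
    n_human = max(1, round(config.human_fraction * len(microbial_accessions)))
    human_accessions = []
    for i in range(n_human):
        length = int(rng.integers(config.min_seq_len, config.max_seq_len + 1))
        accession = f"human{i + 1:04d}"
        records[accession] = ProteinRecord(accession, _random_sequence(rng, length))
        annotations.append(AnnotationRow(accession, None, None, None, "human"))
        human_accessions.append(accession)

    if config.proteins_per_individual_db > len(microbial_accessions):
        raise ConfigError(
            f"proteins_per_individual_db={config.proteins_per_individual_db} "
            f"exceeds the microbial pool ({len(microbial_accessions)})"
        )
    databases: dict[str, list[str]] = {}
    for individual in config.individuals():
        chosen = rng.choice(
            len(microbial_accessions),
            size=config.proteins_per_individual_db,
            replace=False,
        )
        db = sorted(microbial_accessions[int(i)] for i in chosen)
        databases[individual] = db + sorted(human_accessions)

    modules: list[ModuleDefinition] = []
    for m in range(config.n_modules):
        n_steps = int(rng.integers(2, 5))
        steps = []
        for _ in range(n_steps):
            n_components = 2 if rng.random() < 0.1 else 1
            components = []
            for _ in range(n_components):
                n_alternatives = int(rng.integers(1, 4))
                alts = rng.choice(len(kos), size=n_alternatives, replace=False)
                components.append(frozenset(kos[int(a)] for a in alts))
            steps.append(tuple(components))
        modules.append(
            ModuleDefinition(
                f"MF{m + 1:04d}", f"synthetic module {m + 1}", tuple(steps)
            )
        )

    return Cohort(
        individuals=config.individuals(),
        records=records,
        annotations=annotations,
        modules=modules,
        databases=databases,
        human_accessions=tuple(sorted(human_accessions)),
    )


# ---------------------------------------------------------------------------
# longitudinal expression
# ---------------------------------------------------------------------------


def simulate_timepoints(
    config: SimulationConfig,
    cohort: Cohort,
    seed: np.random.SeedSequence | None = None,
) -> list[SampleTruth]:
    """Expressed protein sets and abundances for every (individual, day).

    Each individual has a stable log-normal baseline over its database whose
    individual-specific share is set by ``individual_effect``; between
    consecutive time points a ``turnover`` fraction of the expressed
    microbial proteins is replaced, KO-preservingly with probability
    ``ko_preservation``.  Human proteins are always expressed.
    """
    if seed is None:
        seed = np.random.SeedSequence([config.rng_seed, 1])
    common_seed, *individual_seeds = seed.spawn(1 + len(cohort.individuals))
    rng_common = np.random.default_rng(common_seed)
    microbial_pool = sorted(
        a for a in cohort.records if a not in set(cohort.human_accessions)
    )
    z_common = dict(zip(microbial_pool, rng_common.standard_normal(len(microbial_pool))))
    z_common_human = dict(
        zip(
            cohort.human_accessions,
            rng_common.standard_normal(len(cohort.human_accessions)),
        )
    )
    ko_of = cohort.ko_of

    samples: list[SampleTruth] = []
    for individual, ind_seed in zip(cohort.individuals, individual_seeds):
        rng = np.random.default_rng(ind_seed)
        db = cohort.databases[individual]
        human_db = [a for a in db if a in set(cohort.human_accessions)]
        microbial_db = [a for a in db if a not in set(cohort.human_accessions)]
        if config.expressed_per_sample > len(microbial_db):
            raise ConfigError(
                "expressed_per_sample exceeds the individual database size"
            )
        ie = config.individual_effect
        z_ind = rng.standard_normal(len(microbial_db))
        log_base = config.abundance_sigma * (
            math.sqrt(ie) * z_ind
            + math.sqrt(1.0 - ie) * np.array([z_common[a] for a in microbial_db])
        )
        base = dict(zip(microbial_db, np.exp(log_base)))
        # host proteins: abundant (log-mean shifted up), with the same
        # individual-specific/shared mixture as the microbial baseline
        for acc in human_db:
            z = math.sqrt(ie) * float(rng.standard_normal()) + math.sqrt(
                1.0 - ie
            ) * z_common_human[acc]
            base[acc] = float(np.exp(1.5 + 0.5 * z))

        p = np.array([base[a] for a in microbial_db])
        chosen = rng.choice(
            len(microbial_db),
            size=config.expressed_per_sample,
            replace=False,
            p=p / p.sum(),
        )
        expressed = {microbial_db[int(i)] for i in chosen}

        for t in range(config.timepoints_per_individual):
            if t > 0:
                n_replace = round(config.turnover * len(expressed))
                current = sorted(expressed)
                departures = [
                    current[int(i)]
                    for i in rng.choice(len(current), size=n_replace, replace=False)
                ]
                banned = set(departures)
                expressed -= banned
                for departing in departures:
                    ko = ko_of.get(departing)
                    same_ko = [
                        a
                        for a in microbial_db
                        if a not in expressed
                        and a not in banned
                        and ko is not None
                        and ko_of.get(a) == ko
                    ]
                    if same_ko and rng.random() < config.ko_preservation:
                        replacement = same_ko[int(rng.integers(len(same_ko)))]
                    else:
                        open_pool = [
                            a
                            for a in microbial_db
                            if a not in expressed and a not in banned
                        ]
                        if not open_pool:
                            logger.warning(
                                "%s: database exhausted during turnover", individual
                            )
                            continue
                        replacement = open_pool[int(rng.integers(len(open_pool)))]
                    expressed.add(replacement)
            day = t * config.day_spacing
            abundances = {}
            for acc in sorted(expressed) + human_db:
                noise = float(rng.standard_normal())
                abundances[acc] = base[acc] * math.exp(
                    config.sample_noise_sigma * noise
                )
            samples.append(
                SampleTruth(
                    sample_id=f"{individual}-d{day:03d}",
                    individual_id=individual,
                    day=day,
                    abundances=abundances,
                )
            )
    return samples


# ---------------------------------------------------------------------------
# spectral sampling
# ---------------------------------------------------------------------------


def sample_psms(
    abundances: Mapping[str, float],
    sequences: Mapping[str, str],
    depth: int,
    rng_seed: int | np.random.SeedSequence | np.random.Generator,
) -> dict[str, int]:
    """Draw ``depth`` spectra multinomially over (protein, peptide) pairs
    weighted by protein abundance; returns per-peptide aggregated counts.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    pair_peptides: list[str] = []
    pair_weights: list[float] = []
    for accession in sorted(abundances):
        peptides = tryptic_peptides(sequences[accession])
        if not peptides:
            raise mio.ValidationError(
                f"{accession}: no tryptic peptides in the retained length range"
            )
        pair_peptides.extend(peptides)
        pair_weights.extend([abundances[accession]] * len(peptides))
    weights = np.asarray(pair_weights, dtype=float)
    counts = rng.multinomial(depth, weights / weights.sum())
    aggregated: dict[str, int] = defaultdict(int)
    for peptide, count in zip(pair_peptides, counts):
        if count:
            aggregated[peptide] += int(count)
    return dict(aggregated)


# ---------------------------------------------------------------------------
# whole-study convenience
# ---------------------------------------------------------------------------


def simulate_study(
    config: SimulationConfig, outdir: str | Path | None = None
) -> SimulatedStudy:
    """Generate a complete study and optionally write every input format.

    With ``outdir`` set, emits per-individual FASTA databases
    (``<individual>.fasta``), ``annotations.tsv``, ``modules.txt``,
    ``psms.tsv``, the ground truth under ``ground_truth/`` and the config
    echo ``sim_config.txt`` -- byte-identical for a fixed seed.
    """
    root = np.random.SeedSequence([config.rng_seed, 2])
    cohort_seed, timepoint_seed, psm_seed = root.spawn(3)
    cohort = generate_cohort(config, seed=cohort_seed)
    samples = simulate_timepoints(config, cohort, seed=timepoint_seed)
    sequences = {a: r.sequence for a, r in cohort.records.items()}
    psms: list[PsmRow] = []
    for sample, child in zip(samples, psm_seed.spawn(len(samples))):
        counts = sample_psms(sample.abundances, sequences, config.depth, child)
        for peptide in sorted(counts):
            psms.append(
                PsmRow(
                    sample_id=sample.sample_id,
                    individual_id=sample.individual_id,
                    day=sample.day,
                    peptide=peptide,
                    spectral_count=counts[peptide],
                )
            )
    study = SimulatedStudy(config=config, cohort=cohort, samples=samples, psms=psms)
    if outdir is not None:
        write_study(study, outdir)
    return study


def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for individual in study.cohort.individuals:
        records = [
            ProteinRecord(a, study.cohort.records[a].sequence, individual)
            for a in study.cohort.databases[individual]
        ]
        mio.write_fasta(records, outdir / f"{individual}.fasta")
    mio.write_annotation_table(study.cohort.annotations, outdir / "annotations.tsv")
    mio.write_module_definitions(study.cohort.modules, outdir / "modules.txt")
    mio.write_psm_table(study.psms, outdir / "psms.tsv")
    study.config.to_file(outdir / "sim_config.txt")

    truth_dir = outdir / "ground_truth"
    truth_dir.mkdir(exist_ok=True)
    ko_of = study.cohort.ko_of
    phylum_of = study.cohort.phylum_of
    rows = []
    for sample in study.samples:
        for accession in sorted(sample.abundances):
            rows.append(
                (
                    sample.sample_id,
                    accession,
                    f"{sample.abundances[accession]:.6g}",
                    ko_of.get(accession) or "",
                    phylum_of.get(accession) or "",
                )
            )
    pd.DataFrame(
        rows, columns=["sample_id", "accession", "abundance", "ko_term", "phylum"]
    ).to_csv(truth_dir / "expressed_abundance.tsv", sep="\t", index=False,
             lineterminator="\n")
    coverage = expected_module_coverage(study)
    coverage.to_csv(truth_dir / "expected_coverage.tsv", sep="\t", index=False,
                    lineterminator="\n")


def expected_module_coverage(study: SimulatedStudy) -> pd.DataFrame:
    """Ground-truth module coverage per (sample, phylum) from the true
    expressed protein sets (i.e. before any identification losses)."""
    from .modules import compute_coverage

    ko_of = study.cohort.ko_of
    phylum_of = study.cohort.phylum_of
    rows = []
    for sample in study.samples:
        by_phylum: dict[str, set[str]] = defaultdict(set)
        for accession in sample.abundances:
            ko, phylum = ko_of.get(accession), phylum_of.get(accession)
            if ko and phylum:
                by_phylum[phylum].add(ko)
        for phylum in sorted(by_phylum):
            for module in study.cohort.modules:
                cov = compute_coverage(module, by_phylum[phylum])
                rows.append(
                    (sample.sample_id, phylum, module.module_id, float(cov))
                )
    return pd.DataFrame(
        rows, columns=["sample_id", "phylum", "module_id", "expected_coverage"]
    )
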