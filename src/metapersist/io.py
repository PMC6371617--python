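"""Plain-text formats used throughout the pipeline.

Every external table is UTF-8, tab-delimited, newline-terminated, with a
fixed column order, so that writing and re-reading any object is lossless.
The formats are:

* protein FASTA (one database per individual; the header token before the
  first whitespace is the accession),
* a five-column PSM table (``sample_id  individual_id  day  peptide
  spectral_count``) holding already FDR-filtered, per-peptide spectral
  counts,
* an annotation table mapping accessions to KEGG Orthology (KO) terms and
  phylum/genus taxonomy (``accession  ko_term  phylum  genus
  organism_label``),
* a metabolic-module definition dialect: a ``MF####<TAB>name`` header line,
  one line per enzymatic step where tabs separate required (AND) components
  and commas separate alternative (OR) KO terms, and ``///`` terminates each
  record.  This mirrors the public gut-metabolic-module distribution format
  so the published module set can be dropped in unchanged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
KO_RE = re.compile(r"^K\d{5}$")
MODULE_ID_RE = re.compile(r"^MF\d{4}$")

PSM_COLUMNS = ["sample_id", "individual_id", "day", "peptide", "spectral_count"]
ANNOTATION_COLUMNS = ["accession", "ko_term", "phylum", "genus", "organism_label"]

DEFAULT_MIN_PEPTIDE_LENGTH = 6


class FormatError(ValueError):
    """A file does not conform to its declared syntax."""


class ValidationError(ValueError):
    """A syntactically valid file violates a content invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """One predicted protein sequence from an individual's database."""

    accession: str
    sequence: str
    individual_id: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("protein record with empty accession")
        if not self.sequence:
            raise ValidationError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValidationError(
                f"{self.accession}: illegal residue(s) {sorted(bad)} "
                "(expected the 20 canonical amino acids, upper case)"
            )


@dataclass(frozen=True)
class PsmRow:
    """Aggregated spectral count for one peptide in one sample."""

    sample_id: str
    individual_id: str
    day: int
    peptide: str
    spectral_count: int

    def __post_init__(self) -> None:
        if self.spectral_count < 1:
            raise ValidationError(
                f"{self.sample_id}/{self.peptide}: spectral_count must be >= 1"
            )


@dataclass(frozen=True)
class AnnotationRow:
    """Seed-level annotation of one accession.

    ``organism_label`` is ``"human"``, a phylum name, or ``"unassigned"``.
    Human records never carry a phylum.
    """

    accession: str
    ko_term: str | None = None
    phylum: str | None = None
    genus: str | None = None
    organism_label: str = "unassigned"

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("annotation row with empty accession")
        if self.ko_term is not None and not KO_RE.match(self.ko_term):
            raise ValidationError(
                f"{self.accession}: bad KO term {self.ko_term!r} (expected K#####)"
            )
        if self.organism_label == "human" and self.phylum is not None:
            raise ValidationError(
                f"{self.accession}: human records must not carry a phylum"
            )


@dataclass(frozen=True)
class ModuleDefinition:
    """A metabolic module as an ordered list of enzymatic steps.

    ``steps[i]`` is a tuple of AND-components; each component is a frozenset
    of OR-alternative KO terms.  A step is covered when every component has
    at least one alternative with enzyme evidence.
    """

    module_id: str
    name: str
    steps: tuple[tuple[frozenset[str], ...], ...]

    def __post_init__(self) -> None:
        if not MODULE_ID_RE.match(self.module_id):
            raise ValidationError(f"bad module id {self.module_id!r} (expected MF####)")
        if not self.steps:
            raise ValidationError(f"{self.module_id}: module must have >= 1 step")
        for step in self.steps:
            if not step:
                raise ValidationError(f"{self.module_id}: empty step")
            for component in step:
                if not component:
                    raise ValidationError(f"{self.module_id}: empty AND-component")
                for ko in component:
                    if not KO_RE.match(ko):
                        raise ValidationError(
                            f"{self.module_id}: bad KO term {ko!r}"
                        )

    @property
    def ko_terms(self) -> frozenset[str]:
        """All KO terms appearing anywhere in the module."""
        return frozenset(
            ko for step in self.steps for component in step for ko in component
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, individual_id: str = "") -> list[ProteinRecord]:
    """Read a protein FASTA into validated records.

    The accession is the header token before the first whitespace.
    Duplicate accessions within one file are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if not entry.id:
            raise FormatError(f"{path}: FASTA entry with empty header")
        if entry.id in seen:
            raise ValidationError(f"{path}: duplicate accession {entry.id!r}")
        seen.add(entry.id)
        records.append(
            ProteinRecord(entry.id, str(entry.seq).upper(), individual_id)
        )
    if not records:
        logger.warning("%s: empty FASTA file", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    recs = [SeqRecord(Seq(r.sequence), id=r.accession, description="") for r in records]
    with open(path, "w", encoding="utf-8") as handle:
        SeqIO.write(recs, handle, "fasta-2line")


# ---------------------------------------------------------------------------
# PSM table
# ---------------------------------------------------------------------------


def read_psm_table(
    path: str | Path, min_peptide_length: int = DEFAULT_MIN_PEPTIDE_LENGTH
) -> list[PsmRow]:
    """Read and aggregate a PSM table.

    Rows with identical ``(sample_id, peptide)`` are summed; zero counts are
    dropped with a warning; negative counts and sub-floor peptides are
    errors.  Reading an already-aggregated table is a no-op.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty PSM table") from None
    missing = [c for c in PSM_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    frame = frame[PSM_COLUMNS].copy()
    try:
        frame["day"] = frame["day"].astype(int)
        frame["spectral_count"] = frame["spectral_count"].astype(int)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer day or spectral_count: {exc}") from None
    if (frame["spectral_count"] < 0).any():
        bad = frame.loc[frame["spectral_count"] < 0].iloc[0]
        raise ValidationError(
            f"{path}: negative spectral_count for {bad['sample_id']}/{bad['peptide']}"
        )
    n_zero = int((frame["spectral_count"] == 0).sum())
    if n_zero:
        logger.warning("%s: dropped %d zero-count row(s)", path, n_zero)
        frame = frame[frame["spectral_count"] > 0]
    short = frame["peptide"].str.len() < min_peptide_length
    if short.any():
        raise ValidationError(
            f"{path}: {int(short.sum())} peptide(s) shorter than the "
            f"{min_peptide_length}-residue floor, e.g. "
            f"{frame.loc[short, 'peptide'].iloc[0]!r}"
        )
    meta = frame[["sample_id", "individual_id", "day"]].drop_duplicates()
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(
            f"{path}: sample {dup!r} has inconsistent individual_id/day"
        )
    agg = (
        frame.groupby(["sample_id", "peptide"], as_index=False)["spectral_count"]
        .sum()
        .merge(meta, on="sample_id")
        .sort_values(["sample_id", "peptide"], kind="mergesort")
    )
    return [
        PsmRow(r.sample_id, r.individual_id, int(r.day), r.peptide, int(r.spectral_count))
        for r in agg.itertuples()
    ]


def write_psm_table(rows: Iterable[PsmRow], path: str | Path) -> None:
    frame = psms_to_frame(rows)
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def psms_to_frame(rows: Iterable[PsmRow]) -> pd.DataFrame:
    """PSM rows as a DataFrame in canonical column and sort order."""
    frame = pd.DataFrame(
        [(r.sample_id, r.individual_id, r.day, r.peptide, r.spectral_count) for r in rows],
        columns=PSM_COLUMNS,
    )
    return frame.sort_values(["sample_id", "peptide"], kind="mergesort").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# annotation table
# ---------------------------------------------------------------------------


def read_annotation_table(path: str | Path) -> list[AnnotationRow]:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty annotation table") from None
    missing = [c for c in ANNOTATION_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    rows = []
    for r in frame.itertuples():
        rows.append(
            AnnotationRow(
                accession=r.accession,
                ko_term=r.ko_term or None,
                phylum=r.phylum or None,
                genus=r.genus or None,
                organism_label=r.organism_label or "unassigned",
            )
        )
    if frame["accession"].duplicated().any():
        dup = frame.loc[frame["accession"].duplicated(), "accession"].iloc[0]
        raise ValidationError(f"{path}: duplicate annotation for accession {dup!r}")
    return rows


def write_annotation_table(rows: Iterable[AnnotationRow], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            (r.accession, r.ko_term or "", r.phylum or "", r.genus or "", r.organism_label)
            for r in rows
        ],
        columns=ANNOTATION_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# module definitions
# ---------------------------------------------------------------------------


def read_module_definitions(path: str | Path) -> list[ModuleDefinition]:
    """Parse the module-definition dialect (tab = AND, comma = OR, /// = end)."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    modules: list[ModuleDefinition] = []
    seen: set[str] = set()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        header = lines[i].split("\t")
        if len(header) != 2 or not MODULE_ID_RE.match(header[0]):
            raise FormatError(
                f"{path}:{i + 1}: expected 'MF####<TAB>name' header, got {lines[i]!r}"
            )
        module_id, name = header
        if module_id in seen:
            raise ValidationError(f"{path}:{i + 1}: duplicate module id {module_id}")
        seen.add(module_id)
        i += 1
        steps: list[tuple[frozenset[str], ...]] = []
        terminated = False
        while i < len(lines):
            line = lines[i]
            if line.strip() == "///":
                terminated = True
                i += 1
                break
            components = []
            for component in line.split("\t"):
                alternatives = frozenset(a.strip() for a in component.split(","))
                for ko in alternatives:
                    if not KO_RE.match(ko):
                        raise FormatError(
                            f"{path}:{i + 1}: malformed KO term {ko!r}"
                        )
                components.append(alternatives)
            steps.append(tuple(components))
            i += 1
        if not terminated:
            raise FormatError(f"{path}: module {module_id} missing '///' terminator")
        try:
            modules.append(ModuleDefinition(module_id, name, tuple(steps)))
        except ValidationError as exc:
            raise FormatError(f"{path}: {exc}") from None
    return modules


def write_module_definitions(
    modules: Iterable[ModuleDefinition], path: str | Path
) -> None:
    out: list[str] = []
    for m in modules:
        out.append(f"{m.module_id}\t{m.name}")
        for step in m.steps:
            out.append("\t".join(",".join(sorted(c)) for c in step))
        out.append("///")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# generic matrix helpers (group x sample tables written by the pipeline)
# ---------------------------------------------------------------------------


def write_matrix(frame: pd.DataFrame, path: str | Path, index_name: str) -> None:
    frame = frame.copy()
    frame.index.name = index_name
    frame.to_csv(path, sep="\t", lineterminator="\n")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
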