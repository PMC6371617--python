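# metapersist

Longitudinal metaproteome analysis for gut-microbiome studies: from
peptide-spectrum-match (PSM) tables and per-individual protein sequence
databases to protein groups, balanced spectral counts, KEGG-Orthology and
phylum annotations, phylum-stratified metabolic-module inference, and
persistence / redundancy / similarity statistics.

## The problem

Shotgun metaproteomics of stool samples identifies thousands of microbial
protein groups per individual, but the protein inventory is volatile: most
protein groups appear at only one or a few time points, and very few are
shared between individuals. The question this package is built around is
whether *function* is more stable than the proteins that carry it. It
answers that by rolling the same presence/abundance data up three levels —
protein groups, KO terms (KEGG Orthology identifiers, `K#####`), and gut
metabolic modules (`MF####`, ordered lists of enzymatic steps) — and
computing the same persistence statistics at each level, stratified by
phylum so that functional redundancy *across* phyla is visible.

## Core methods

* **Protein grouping.** Sequences are collapsed at >= 90% pairwise identity
  by deterministic greedy centroid clustering (longest sequence first,
  lexicographic tie-break; each sequence joins the first seed it matches,
  else founds a group). Identity comes from a global affine alignment
  (match +1, mismatch −1, gap open −5, gap extend −1, terminal gaps free)
  as matches over the alignment columns spanned by the shorter sequence, so
  a perfect fragment of a full-length ORF has identity 1 and collapses into
  its group.
* **Identification rule.** A group counts as identified in a sample iff its
  observed peptides include >= 2 distinct sequences, >= 1 of them unique to
  the group (peptides are mapped to groups by exact substring containment).
* **Balanced spectral counts.** Unique peptides donate their spectral
  counts wholly to their group; shared peptides are split across their
  identified carriers in proportion to the carriers' unique-count totals
  (equally if none has unique evidence). Per-sample totals are conserved.
* **Annotation.** Each group inherits the KO term / phylum / genus of its
  seed sequence and is categorised human / microbial / unassigned; an
  ambiguity report quantifies member-vs-seed disagreement.
* **Module inference.** A module is inferred for a (sample, phylum) stratum
  iff coverage >= 1/3 (exact rational), where a step is covered when every
  AND-component has >= 1 OR-alternative KO with identified evidence in that
  phylum — evidence is never pooled across phyla. Module abundance is the
  mean balanced count of the phylum's mapping groups, and their summed
  counts over the sample total.
* **Persistence & similarity.** Entities are categorised as seen in all /
  more than one but not all / exactly one time point (or individual);
  sample similarity is Spearman's rho on balanced counts, hierarchically
  clustered (average linkage on Euclidean distances between correlation
  profiles) with nearest-neighbour and adjusted-Rand summaries of how well
  the clustering recovers individuals; functional influence is the fraction
  of a database's predicted KO universe with protein evidence per phylum.
* **Synthetic cohorts.** A generator emulates the statistical structure the
  analysis assumes — individual-specific repertoires, high protein turnover
  with KO-term preservation, KO terms encoded redundantly in >= 2 phyla, a
  human protein fraction, tryptic digestion and multinomial spectral
  sampling — fully deterministic in its seed, so the whole pipeline is
  testable without any external data.

## Worked example

```python
from pathlib import Path
from metapersist import SimulationConfig, simulate_study, PipelineConfig, run_all

study = simulate_study(SimulationConfig(rng_seed=1), outdir=Path("demo/study"))
result = run_all(PipelineConfig(
    fasta_paths=tuple(sorted(Path("demo/study").glob("*.fasta"))),
    psm_path=Path("demo/study/psms.tsv"),
    annotation_path=Path("demo/study/annotations.tsv"),
    module_path=Path("demo/study/modules.txt"),
    outdir=Path("demo/run"),
))
print(f"protein groups: {len(result.groups)}")
print(f"nearest-neighbour same-individual fraction: "
      f"{result.coherence.nearest_neighbor_fraction:.2f}")
print(f"adjusted Rand at k=5: {result.coherence.adjusted_rand:.2f}")
table = result.persistence_individual.pivot(
    index="individual_id", columns="entity_level", values="frac_all")
print(table.round(2).to_string())
```

prints

```
protein groups: 134
nearest-neighbour same-individual fraction: 1.00
adjusted Rand at k=5: 1.00
entity_level   ko_term  module  protein_group
individual_id
P01               0.76    1.00           0.26
P02               0.75    0.94           0.27
P03               0.57    0.94           0.24
P04               0.85    1.00           0.36
P05               0.61    0.88           0.25
```

Read: the 25 synthetic samples cluster perfectly by individual
(personalised metaproteomes), and for every individual the fraction of
entities present at *all five* time points rises from ~0.2–0.4 at the
protein-group level through ~0.6–0.9 at the KO level to ~0.9–1.0 at the
module level — protein turnover with functional stability. All stage
outputs (groups, identification matrix, balanced abundance, annotations,
module calls and redundancy classes, persistence tables, correlation
matrix, dendrogram in Newick, run manifest with checksums) are written as
tab-separated text under `demo/run/`.

The same pipeline runs from the shell:

```bash
metapersist simulate --out demo/study --seed 1
metapersist run-all --fasta-dir demo/study --psms demo/study/psms.tsv \
    --annotations demo/study/annotations.tsv --modules demo/study/modules.txt \
    --outdir demo/run
```

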