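# Methods

This note documents the models, rules and numerical choices implemented in
`metapersist`, the assumptions behind them, and what the synthetic cohort
does and does not emulate.

## Pipeline model

The pipeline consumes four plain-text inputs: per-individual protein FASTA
databases (stand-ins for concatenated, de-replicated predicted ORF sets),
an aggregated, already FDR-filtered PSM table
(`sample_id individual_id day peptide spectral_count`), a seed-level
annotation table (`accession ko_term phylum genus organism_label`), and a
module-definition file in the public gut-metabolic-module dialect (header
`MF####<TAB>name`; one line per enzymatic step; tab separates required
AND-components, comma separates alternative OR KO terms; `///` terminates a
record). Stages run strictly in order: group → identify → balance →
annotate → infer modules → persistence/similarity. Every stage output is a
pure function of the inputs and configuration; the run manifest records
SHA-256 checksums of inputs and outputs so byte-identical reruns are
checkable.

### Sequence identity and grouping

Pairwise identity is computed from a global affine alignment with match +1,
mismatch −1, gap open −5 (charged on the first gap position), gap extend
−1, and free terminal gaps (`Bio.Align.PairwiseAligner`). Identity is the
number of identical aligned residue pairs divided by the number of
alignment columns spanned by the *shorter* sequence — from its first to its
last residue, internal gap columns included. Two consequences are
intentional:

* a fragment contained in a longer ORF scores identity 1.0, so
  fragment-vs-full-length redundancy collapses at the 90% threshold, which
  is what the threshold exists for;
* a chance end-overlap between unrelated sequences is still normalised by
  the whole shorter sequence, so it cannot reach the threshold. (Trimming
  the denominator to the aligned span alone makes unrelated proteins merge
  through high-scoring micro-overlaps; this failure mode was observed and
  is covered by tests.)

For equal-length sequences the larger of the two spans is used, and the
argument pair is put in a canonical order before aligning, which makes the
measure exactly symmetric even when several alignments tie for the optimal
score. Isoleucine and leucine are distinct residues by default
(`ile_leu_equivalent` merges them in both alignment and peptide matching).

Clustering is greedy centroid assignment: sequences sorted by decreasing
length (lexicographic accession tie-break); each sequence joins the first
existing seed with identity >= threshold, else founds a new group. This is
deterministic, exact at desk scale (no k-mer prefiltering), and verified
against exhaustive re-checking on small databases. One caveat is
documented rather than "fixed": strict monotonicity of the group count in
the threshold is not a theorem for greedy centroid clustering — a
borderline merge at a lower threshold can eliminate a seed that would have
absorbed several later sequences — so monotonicity is tested statistically
on family-structured data, where it holds.

Grouping is applied to the *union* of the individual databases (de-
replicated by accession; one accession must carry one sequence study-wide),
because cross-individual statistics (groups shared by all individuals,
sample clustering across individuals) require study-wide group identities.

### Identification and balanced spectral counts

Peptides map to groups by exact substring containment against any member
sequence; peptides contained in no database sequence are excluded with a
warning. Uniqueness is defined at the group level. A group is identified
in a sample iff >= 2 distinct observed peptides map to it and >= 1 of them
is unique — identification strictly precedes balancing, so only identified
groups receive spectra.

Balancing is a single pass: unique peptide counts accumulate per group;
each shared peptide's count is then split across its *identified* carriers
proportionally to those unique totals, or equally when all carriers lack
unique evidence. A shared peptide with exactly one identified carrier goes
wholly to it; a peptide none of whose carriers is identified is dropped
from the sample's conserved total (logged). The allocation is independent
of processing order and conserves the retained total exactly up to float
rounding (tested at 1e-9 relative over random instances). Balanced counts
stay real-valued; downstream rank statistics are unaffected by the lack of
rounding. An iterative re-balancing variant is deliberately out of scope.

### Annotation

A group inherits its seed's KO term, phylum and genus. `organism_label ==
"human"` forces the human category (no phylum); a phylum implies microbial;
otherwise unassigned. Members lacking annotations never create ambiguity;
only positive member-vs-seed disagreement on KO or phylum does. Seed-wins
is applied unconditionally; genus is carried for reporting but unused in
downstream inference.

### Module inference

A step is covered iff every AND-component has at least one OR-alternative
KO detected; coverage is covered steps over total steps, kept as an exact
`Fraction`. A module is inferred for a (sample, phylum) iff coverage >=
1/3 — the rational comparison makes the 3-step/1-covered boundary case
infer and removes float edge cases. Coverage is evaluated within each
phylum separately; the union across phyla is never used, so a module
needing four steps covered by four different phyla is inferred nowhere.
Abundance per call uses the *group-mean* of the phylum's mapping identified
groups (a step-mean is a possible variant, not implemented), and the
summed mapping counts divided by the sample's total retained spectra. A
group with no KO never maps to a module; a KO in several modules counts in
each independently. Redundancy classes per module (phyla ever providing
inference): single-phylum, >= 2 phyla, all four major gut phyla
(Firmicutes, Bacteroidetes, Actinobacteria, Proteobacteria).

### Persistence, influence and similarity

Presence at the KO and module levels is derived from *identified* groups
(not raw peptide hits), for consistency with the identification rule; the
protein-group level is the identification matrix itself, restricted to
microbial groups. Entities never observed are dropped. The three
categories (all time points / more than one but not all / exactly one)
partition the observed entities; the same categories apply across
individuals (observed in all / several / one individual).

Functional influence per (sample, phylum) is the number of KO terms with
identified evidence in that phylum divided by the number of distinct KO
terms predicted in the sample individual's database; detected KO terms
must be a subset of that universe.

Sample similarity is Spearman's rho over balanced counts with zero entries
participating as rank ties (the union entity set is correlated, not
pairwise-complete subsets). Samples are clustered agglomeratively on the
Euclidean distance between rows of the correlation matrix; average linkage
is the default (robust for correlation-derived distances; the linkage and
a direct `1 − rho` distance are configurable). Sample ids are sorted
before clustering, fixing tie-breaks. The dendrogram is exported as
Newick with branch lengths equal to merge-height differences. Coherence is
summarised by the fraction of samples whose highest-rho partner shares
their individual, and the adjusted Rand index between individual labels
and the k-cluster cut (k = number of individuals).

## The synthetic cohort

### What it emulates

The generator reproduces the structure the statistics are sensitive to:

* **Within-KO sequence families.** Each KO term gets an ancestor sequence;
  each phylum encoding that KO gets a founder diverged 20% from the
  ancestor (identity ~0.64, well below the 0.9 grouping threshold, but
  sharing ~25% of exact tryptic peptides — exercising shared-peptide
  balancing across groups); each family holds 3 variants at ~2.5% mutation
  (identity ~0.95, above the threshold — exercising grouping). Sequences
  are uniform-random over the 20 residues, length 80–600; peptide
  uniqueness/sharing structure, not biochemistry, is what downstream stages
  consume.
* **KO-phylum redundancy.** Each KO is encoded in >= 2 phyla with
  probability `ko_phylum_redundancy` (default 0.8 — at the study scale
  being emulated, nearly all functions observed in every individual were
  multi-phylum). Phyla are drawn by weight from the four dominant gut
  phyla plus one minor.
* **Individual-specific repertoires.** Each individual's database is a
  random `proteins_per_individual_db` subset of the microbial pool; human
  proteins are in every database and always expressed, with an elevated
  baseline (few human groups, large spectra share).
* **Turnover with functional preservation.** Each individual has a stable
  log-normal expression baseline; `individual_effect` in [0, 1] sets the
  share of individual-specific versus cohort-shared variance in the
  log-baseline (for host proteins too). Between consecutive time points a
  `turnover` fraction of expressed microbial proteins departs; each
  replacement is drawn from unexpressed same-KO database proteins (any
  phylum) with probability `ko_preservation`, else at random. This single
  mechanism yields protein-level volatility, KO-level stability, and
  phylum switching of module evidence.
* **Spectra.** Proteins are digested in silico (cleave after K/R except
  before P, zero missed cleavages, peptides of 6–40 residues; the rule is
  passed explicitly to the digestion engine, so no extended exception
  rules apply) and `depth` spectra are drawn multinomially over
  (protein, peptide) pairs weighted by protein abundance, then aggregated
  per peptide.

All randomness flows from `rng_seed` through named `SeedSequence` children
(cohort / time points / one per sample), so repeated runs are
byte-identical and no order-dependent accumulation exists.

### Default study conditions

5 individuals × 5 time points (days 0–360 at 90-day spacing), turnover
0.5, KO preservation 0.9, individual effect 0.9, depth 20,000 spectra per
sample. Sizes were fixed once at desk scale so the full pipeline runs in
well under a minute: 40 KO terms, a pool of ~300 proteins, 150-protein
individual databases, 60 expressed microbial proteins per sample, 16
modules of 2–4 steps (components of 1–3 OR-alternatives; 10% of steps have
two AND-components), 15% of microbial proteins without a KO term, 5% human
records. These proportions keep the quantities that drive the statistics —
proteins per KO, KOs per module step, spectra per expressed protein — in
realistic ranges while the absolute counts are scaled down by roughly two
orders of magnitude from a real study.

### What passing tests do and do not show

Because sequences are uniform-random and digestion is noiseless (no missed
cleavages, no modifications, no FDR, no intensity model), passing tests
demonstrate the correctness and stability of the *inference machinery* —
grouping, balancing, the coverage rule, the persistence hierarchy — under
the assumed generative structure. They do not validate biochemical
realism, search-engine behaviour, or robustness to annotation error, all
of which are upstream of this package's contract.

Two idealisations deserve explicit mention. First, at full turnover with
`ko_preservation = 1` the expressed KO set is *nearly* but not exactly
fixed: when a KO's entire database membership is expressed and departs in
one step, no same-KO replacement exists and the fallback is random (tests
bound the KO-set Jaccard from below rather than asserting equality).
Second, the individual-effect contrast is confounded at default settings
by repertoire differences and temporal autocorrelation; the test isolating
it gives every individual the full pool and full turnover, under which
adjusted Rand falls to ~0 as `individual_effect → 0`.

## Numerical and degenerate-input choices

* Identity comparisons use a 1e-12 tolerance so ratios of small integers
  (9/10) meet a 0.9 threshold exactly.
* Coverage thresholds are exact rationals; no floats cross the inference
  decision.
* Zero-count PSM rows are dropped with a warning; negative counts,
  sub-floor peptides (default floor 6, configurable), inconsistent sample
  metadata, duplicate accessions, and human annotations carrying a phylum
  are errors.
* Zero-variance abundance columns make Spearman undefined and raise,
  naming the sample.
* Single-time-point individuals are rejected by the per-individual
  persistence statistics.
* Empty FASTA files parse to empty lists with a warning; an empty
  clustering input is an error.

## Known limitations

* Greedy centroid clustering is quadratic in database size; it is exact
  and reproducible at desk scale but not a substitute for heuristic
  clustering tools on hundreds of thousands of ORFs.
* Peptide-to-group mapping is exact substring containment; modified
  peptides and isobaric ambiguity (beyond the optional I/L switch) are out
  of scope.
* The spectral-balancing contract is the standard single-pass
  unique-evidence-proportional scheme; iterative re-balancing is not
  implemented.
* Module topologies richer than ordered steps of AND-components with
  OR-alternatives are flattened by the input dialect and not represented.
* No statistical testing of cluster significance, ordination, or
  intensity-based quantification.
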