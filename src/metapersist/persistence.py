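"""Persistence, redundancy, functional-influence and similarity statistics.

All statistics operate on an entity x sample view of the study, where the
entity level is protein groups, KO terms or metabolic modules.  The central
observation these statistics are built to expose is a hierarchy of temporal
stability: individual protein groups turn over quickly, the KO terms they
encode persist longer, and module-level function is the most stable layer.

Sample similarity uses Spearman rank correlation of balanced counts (robust
to the heavy-tailed, zero-inflated abundance distributions of spectral
counting), hierarchically clustered on the Euclidean distance between the
samples' correlation profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from .io import ValidationError

logger = logging.getLogger(__name__)

ENTITY_LEVELS = ("protein_group", "ko_term", "module")


@dataclass
class PresenceMatrix:
    """Binary entity x sample matrix with per-sample individual/day metadata.

    ``samples`` is indexed by sample id with columns ``individual_id`` and
    ``day``; every column of ``data`` must appear there.  All-zero entity
    rows are dropped on construction.
    """

    entity_level: str
    data: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.entity_level not in ENTITY_LEVELS:
            raise ValidationError(f"unknown entity level {self.entity_level!r}")
        missing = set(self.data.columns) - set(self.samples.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")
        self.data = self.data.astype(bool)
        empty = ~self.data.any(axis=1)
        if empty.any():
            logger.warning(
                "%s: dropped %d never-observed entit(ies)",
                self.entity_level,
                int(empty.sum()),
            )
            self.data = self.data.loc[~empty]

    def individuals(self) -> list[str]:
        return sorted(self.samples["individual_id"].unique())

    def samples_of(self, individual: str) -> list[str]:
        sub = self.samples[self.samples["individual_id"] == individual]
        return list(sub.sort_values("day").index)


@dataclass(frozen=True)
class PersistenceCounts:
    """Entities seen in all, in more than one but not all, or in exactly one
    of an individual's time points (or of the study's individuals).  The
    three categories partition the observed entities.
    """

    all_observed: int
    multiple_not_all: int
    single: int

    @property
    def total(self) -> int:
        return self.all_observed + self.multiple_not_all + self.single

    def fractions(self) -> tuple[float, float, float]:
        t = self.total
        if t == 0:
            return (0.0, 0.0, 0.0)
        return (self.all_observed / t, self.multiple_not_all / t, self.single / t)


def _categorise(observed_in: int, out_of: int) -> str:
    if observed_in == out_of:
        return "all"
    if observed_in == 1:
        return "single"
    return "multiple"


def persistence_by_individual(
    presence: PresenceMatrix, individual: str
) -> PersistenceCounts:
    """Time-point persistence categories for one individual's entities."""
    cols = presence.samples_of(individual)
    if len(cols) < 2:
        raise ValidationError(
            f"individual {individual!r} has {len(cols)} time point(s); need >= 2"
        )
    sub = presence.data[cols]
    seen = sub.sum(axis=1)
    seen = seen[seen > 0]
    counts = {"all": 0, "multiple": 0, "single": 0}
    for n in seen:
        counts[_categorise(int(n), len(cols))] += 1
    return PersistenceCounts(counts["all"], counts["multiple"], counts["single"])


def persistence_across_individuals(presence: PresenceMatrix) -> PersistenceCounts:
    """Individual-level persistence: in how many individuals was each entity
    ever observed?"""
    individuals = presence.individuals()
    if len(individuals) < 2:
        raise ValidationError("persistence across individuals needs >= 2 individuals")
    counts = {"all": 0, "multiple": 0, "single": 0}
    per_individual = {
        ind: presence.data[presence.samples_of(ind)].any(axis=1)
        for ind in individuals
    }
    observed = pd.DataFrame(per_individual)
    n_seen = observed.sum(axis=1)
    for n in n_seen[n_seen > 0]:
        counts[_categorise(int(n), len(individuals))] += 1
    return PersistenceCounts(counts["all"], counts["multiple"], counts["single"])


def functional_influence(
    detected_sets: Mapping[tuple[str, str], set[str]],
    db_ko_universe: set[str],
    sample: str,
) -> dict[str, float]:
    """Per-phylum share of a sample's database KO universe with protein
    evidence: |KOs detected in the phylum| / |KOs predicted in the database|.
    """
    if not db_ko_universe:
        raise ValidationError(f"{sample}: empty database KO universe")
    out: dict[str, float] = {}
    for (s, phylum), kos in detected_sets.items():
        if s != sample:
            continue
        extra = kos - db_ko_universe
        if extra:
            raise ValidationError(
                f"{sample}/{phylum}: detected KO(s) outside the database "
                f"universe: {sorted(extra)[:5]}"
            )
        out[phylum] = len(kos) / len(db_ko_universe)
    return out


def spearman_matrix(abundance: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation between samples (columns) of an abundance
    table; zero entries participate as rank ties.  Average ranks resolve
    ties; the diagonal is exactly 1.
    """
    samples = list(abundance.columns)
    if len(samples) < 2:
        raise ValidationError("spearman_matrix needs >= 2 samples")
    values = abundance.to_numpy(dtype=float)
    for j, sample in enumerate(samples):
        if np.all(values[:, j] == values[0, j]):
            raise ValidationError(
                f"sample {sample!r} has zero abundance variance; rho undefined"
            )
    rho = spearmanr(values, axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the two-sample case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=samples, columns=samples)


@dataclass(frozen=True)
class SampleClustering:
    linkage: np.ndarray
    leaf_order: tuple[str, ...]
    newick: str


def _to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string; branch lengths are
    differences between merge heights."""
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    if tree.is_leaf():  # single sample
        return f"{labels[tree.id]}:0;"
    left = render(tree.left, tree.dist)
    right = render(tree.right, tree.dist)
    return f"({left},{right});"


def cluster_samples(
    rho: pd.DataFrame,
    linkage_method: str = "average",
    distance_mode: str = "rho_rows",
) -> SampleClustering:
    """Agglomerative clustering of samples from their correlation structure.

    ``distance_mode`` selects the sample-to-sample distance: Euclidean
    distance between rows of the correlation matrix (``rho_rows``, default)
    or ``1 - rho`` directly (``one_minus_rho``).  Samples are processed in
    sorted id order, which fixes tie-breaking.
    """
    samples = sorted(rho.index)
    rho = rho.loc[samples, samples]
    if distance_mode == "rho_rows":
        condensed = pdist(rho.to_numpy(dtype=float), metric="euclidean")
    elif distance_mode == "one_minus_rho":
        condensed = squareform(1.0 - rho.to_numpy(dtype=float), checks=False)
    else:
        raise ValidationError(f"unknown distance mode {distance_mode!r}")
    Z = hierarchy.linkage(condensed, method=linkage_method)
    leaves = hierarchy.leaves_list(Z)
    return SampleClustering(
        linkage=Z,
        leaf_order=tuple(samples[i] for i in leaves),
        newick=_to_newick(Z, samples),
    )


@dataclass(frozen=True)
class CoherenceResult:
    """How well does sample similarity recover the individuals?

    ``nearest_neighbor_fraction``: share of samples whose highest-correlation
    partner belongs to the same individual.  ``adjusted_rand``: agreement
    between the individual labels and the k-cluster cut of the dendrogram
    (k = number of individuals); ~0 for random labels, 1 for perfect
    recovery.
    """

    nearest_neighbor_fraction: float
    adjusted_rand: float


def individual_coherence(
    rho: pd.DataFrame,
    clustering: SampleClustering,
    individual_of: Mapping[str, str],
) -> CoherenceResult:
    samples = sorted(rho.index)
    labels = [individual_of[s] for s in samples]
    individuals = sorted(set(labels))
    if len(individuals) < 2 or min(labels.count(i) for i in individuals) < 2:
        raise ValidationError(
            "individual_coherence needs >= 2 individuals with >= 2 samples each"
        )
    rho = rho.loc[samples, samples]
    matched = 0
    values = rho.to_numpy(dtype=float).copy()
    np.fill_diagonal(values, -np.inf)
    for i, sample in enumerate(samples):
        partner = int(np.argmax(values[i]))
        if labels[partner] == labels[i]:
            matched += 1
    cut = hierarchy.fcluster(clustering.linkage, t=len(individuals), criterion="maxclust")
    ari = float(adjusted_rand_score(labels, cut))
    return CoherenceResult(
        nearest_neighbor_fraction=matched / len(samples),
        adjusted_rand=ari,
    )


def plot_similarity_heatmap(rho: pd.DataFrame, clustering: SampleClustering, path):
    """Optional clustered-heatmap rendering of the correlation matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = list(clustering.leaf_order)
    fig, ax = plt.subplots(figsize=(0.35 * len(order) + 2, 0.35 * len(order) + 2))
    im = ax.imshow(rho.loc[order, order].to_numpy(), vmin=-1, vmax=1, cmap="vlag"
                   if "vlag" in plt.colormaps() else "coolwarm")
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=7)
    ax.set_yticks(range(len(order)), order, fontsize=7)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
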