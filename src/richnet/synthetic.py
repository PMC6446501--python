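"""Synthetic gene-set libraries with planted overlap-community structure.

The generator emulates the two inputs of the workflow — a curated gene-set
library and a per-gene ranking statistic — with known ground truth, so that
every downstream stage (enrichment, thresholded overlap graph, community
detection, labeling) can be exercised and scored without external data.

Design: the gene universe is a large shared *background pool* plus one
disjoint *cluster pool* per planted cluster and one small private pool per
singleton set. Each set draws a fraction ``within_draw`` of its members
from its own pool and the remainder from the background. Two sets of the
same cluster therefore share on the order of ``within_draw**2 * set_size``
genes — with the defaults (set_size 30, within_draw 0.8) an expected
Jaccard index of roughly ``0.64 * 30 / (60 - 0.64 * 30)`` ≈ 0.47, well above
the 0.2 edge threshold — while sets from different clusters (or singleton
sets) overlap only through sparse background draws and stay far below it.

Gene statistics are Normal(0, noise_sd) noise; genes in the pools of
*active* clusters (and active singleton sets) are shifted by ±``effect``,
which makes those sets coherently Up or Down under a competitive test.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geneset_io import GeneSetLibrary

__all__ = ["PlantedDesign", "generate_library", "generate_gene_stats", "write_truth"]

# topic vocabulary: gives set names realistic repeated tokens so that the
# automatic cluster labeling has something to recover
_CLUSTER_TOPICS = (
    "MUSCLE_CONTRACTION",
    "INTERFERON_IMMUNE_DEFENSE",
    "LIPID_METABOLISM",
    "AXON_GUIDANCE",
    "DNA_REPAIR",
    "OXIDATIVE_PHOSPHORYLATION",
    "CHROMATIN_REMODELING",
    "GLUCOSE_TRANSPORT",
)
_SINGLETON_TOPICS = (
    "APOPTOSIS", "GLYCOLYSIS", "AUTOPHAGY", "SPLICEOSOME", "PROTEOLYSIS",
    "TRANSLATION", "ADHESION", "SECRETION", "FIBROSIS", "ANGIOGENESIS",
    "HYPOXIA", "INFLAMMATION",
)


@dataclass(frozen=True)
class PlantedDesign:
    """Parameters of the planted-structure benchmark.

    Defaults describe the standard benchmark condition: five clusters of six
    sets each (30 genes per set drawn 80% from a 60-gene cluster pool), ten
    singleton sets on private pools, a 1000-gene shared background, all
    clusters and singletons active with a ±3 standard-deviation shift.
    """

    n_clusters: int = 5
    sets_per_cluster: int = 6
    pool_size: int = 60
    set_size: int = 30
    within_draw: float = 0.8
    n_singleton_sets: int = 10
    background_pool: int = 1000
    active_clusters: tuple[int, ...] | None = None  # None = all clusters active
    down_clusters: tuple[int, ...] = (1, 3)  # 0-based ids shifted by -effect
    shift_singletons: bool = True
    effect: float = 3.0
    noise_sd: float = 1.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.set_size > self.pool_size:
            raise ValueError("infeasible design: set_size exceeds pool_size")
        if not 0.0 <= self.within_draw <= 1.0:
            raise ValueError("within_draw must lie in [0, 1]")
        if min(
            self.n_clusters, self.sets_per_cluster, self.n_singleton_sets,
            self.background_pool, self.set_size, self.pool_size,
        ) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def active(self) -> tuple[int, ...]:
        if self.active_clusters is None:
            return tuple(range(self.n_clusters))
        return self.active_clusters


def _gene_ids(start: int, n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(start, start + n)]


def _pools(d: PlantedDesign) -> tuple[list[str], list[list[str]], list[list[str]]]:
    """Disjoint background, cluster and singleton-private gene pools."""
    background = _gene_ids(0, d.background_pool)
    nxt = d.background_pool
    cluster_pools = []
    for _ in range(d.n_clusters):
        cluster_pools.append(_gene_ids(nxt, d.pool_size))
        nxt += d.pool_size
    singleton_pools = []
    for _ in range(d.n_singleton_sets):
        singleton_pools.append(_gene_ids(nxt, d.set_size))
        nxt += d.set_size
    return background, cluster_pools, singleton_pools


def _draw_set(
    rng: np.random.Generator, pool: list[str], background: list[str], d: PlantedDesign
) -> list[str]:
    # The within-cluster part is drawn from a core region of set_size genes
    # at the front of the pool, so that two sets of the same cluster share
    # within_draw**2 * set_size genes in expectation and their Jaccard index
    # is ~ w^2*s / (2s - w^2*s) (~0.47 at the defaults, comfortably above
    # the 0.2 edge threshold). Pool genes beyond the core pad the measured
    # universe and still carry the cluster's planted shift.
    core = pool[: d.set_size]
    n_within = round(d.within_draw * d.set_size)
    n_within = min(n_within, len(core))
    members = list(rng.choice(core, size=n_within, replace=False))
    n_bg = d.set_size - n_within
    if n_bg > 0:
        if n_bg > len(background):
            raise ValueError("infeasible design: background pool too small")
        members += list(rng.choice(background, size=n_bg, replace=False))
    return members


def generate_library(
    d: PlantedDesign, rng: np.random.Generator | None = None
) -> tuple[GeneSetLibrary, dict[str, str]]:
    """Planted library plus ground truth (set name -> cluster/singleton label).

    Truth labels are ``"C1".."Cn"`` for cluster members and a unique
    ``"S<i>"`` per singleton set. Reproducible for a fixed design seed.
    """
    if rng is None:
        rng = np.random.default_rng(d.seed)
    background, cluster_pools, singleton_pools = _pools(d)

    sets: dict[str, list[str]] = {}
    truth: dict[str, str] = {}
    for k in range(d.n_clusters):
        topic = _CLUSTER_TOPICS[k % len(_CLUSTER_TOPICS)]
        for j in range(d.sets_per_cluster):
            name = f"CL{k + 1}_SET{j + 1}_{topic}"
            sets[name] = _draw_set(rng, cluster_pools[k], background, d)
            truth[name] = f"C{k + 1}"
    for i in range(d.n_singleton_sets):
        topic = _SINGLETON_TOPICS[i % len(_SINGLETON_TOPICS)]
        name = f"SINGLETON{i + 1}_{topic}"
        sets[name] = _draw_set(rng, singleton_pools[i], background, d)
        truth[name] = f"S{i + 1}"
    return GeneSetLibrary(sets), truth


def generate_gene_stats(
    lib: GeneSetLibrary,
    truth: dict[str, str],
    d: PlantedDesign,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-gene statistics with planted set-level shifts.

    The measured universe is every pool gene (background, cluster and
    singleton pools), so all set members are covered. Statistics are
    Normal(0, noise_sd); genes unique to an active cluster's pool are
    shifted by +effect (or -effect for designated down clusters); private
    genes of active singleton sets alternate +effect / -effect.
    """
    if rng is None:
        rng = np.random.default_rng(d.seed + 1)
    background, cluster_pools, singleton_pools = _pools(d)
    genes = background + [g for p in cluster_pools for g in p]
    genes += [g for p in singleton_pools for g in p]

    stat = rng.normal(0.0, d.noise_sd, size=len(genes))
    shift = pd.Series(0.0, index=genes)
    active = set(d.active)
    down = set(d.down_clusters)
    for k, pool in enumerate(cluster_pools):
        if k in active and d.effect != 0:
            shift[pool] = -d.effect if k in down else d.effect
    if d.shift_singletons and d.effect != 0:
        for i, pool in enumerate(singleton_pools):
            shift[pool] = d.effect if i % 2 == 0 else -d.effect
    stat = stat + shift.to_numpy()
    return pd.DataFrame({"gene_id": genes, "stat": stat})


def write_truth(truth: dict[str, str], path: str | os.PathLike[str]) -> None:
    """Write the ground-truth assignment as TSV (name, truth_label)."""
    pd.DataFrame(
        {"name": list(truth), "truth_label": list(truth.values())}
    ).to_csv(path, sep="\t", index=False)
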