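"""Synthetic fixtures with the statistical structure the method assumes.

Three generators:

* planted sparse-weight multi-label datasets — sparse non-negative integer
  "GO term frequency" features with correlated column blocks, labels from
  the sign of a noisy linear latent score, so selection-stage support
  recovery can be measured against a known ground truth;
* toy GO DAGs (per-taxonomy rooted trees plus extra cross edges) with a
  leaf-biased annotation database;
* label compositions mimicking the 14-location human benchmark (3106
  actual / 3681 locative proteins; 2580/480/43/3 proteins with 1/2/3/4
  locations).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .go_features import AnnotationDB, Dataset, GoTerm
from .hib import GoDag, build_dag

#: published composition of the 14-location human benchmark: number of
#: actual proteins with exactly 1, 2, 3 and 4 subcellular locations
HUMAN_COLOCATION_COUNTS = (2580, 480, 43, 3)
HUMAN_ACTUAL_TOTAL = 3106
HUMAN_M = 14

#: per-location locative-protein counts of the human benchmark
HUMAN_LOCATIVE_COUNTS = {
    "Centrosome": 77,
    "Cytoplasm": 817,
    "Cytoskeleton": 79,
    "Endoplasmic reticulum": 229,
    "Endosome": 24,
    "Extracellular": 385,
    "Golgi apparatus": 161,
    "Lysosome": 77,
    "Microsome": 24,
    "Mitochondrion": 364,
    "Nucleus": 1021,
    "Peroxisome": 47,
    "Plasma membrane": 354,
    "Synapse": 22,
}


@dataclass
class PlantedTruth:
    """Ground truth of a planted dataset: weights, intercepts, noise, blocks."""

    beta: np.ndarray          # M x T row-sparse true weight matrix
    intercepts: np.ndarray    # length M latent-score offsets
    supports: list[np.ndarray]
    sigma: float
    corr_blocks: list[np.ndarray]
    seed: int


def make_planted_dataset(
    N: int = 500,
    T: int = 200,
    M: int = 4,
    k: int = 10,
    magnitude_range: tuple[float, float] = (0.5, 1.5),
    sigma: float = 0.5,
    corr_block_size: int = 4,
    n_corr_blocks: int = 5,
    zero_inflation: float = 0.7,
    poisson_rate: float = 1.5,
    flip_rate: float = 0.0,
    seed: int = 0,
) -> tuple[Dataset, PlantedTruth]:
    """Planted sparse multi-label dataset with known per-class supports.

    Features are zero-inflated Poisson counts (zero with probability
    ``zero_inflation``, else Poisson(``poisson_rate``)), mimicking sparse GO
    term frequencies.  ``n_corr_blocks`` blocks of ``corr_block_size``
    columns are made strongly correlated (copies of a block leader with a
    20% entrywise redraw) to exercise the elastic net's grouping; blocks
    are placed on columns outside every planted support so that support
    recovery stays well defined.  Each class m has exactly k nonzero true
    weights with magnitudes drawn from ``magnitude_range`` and random
    signs; the transformed label is the sign of the latent score
    ``beta_m.x + b_m + eps`` with eps ~ N(0, sigma^2) and b_m centering
    the score at the population mean of x.  Rows with no positive label
    get their best-scoring class forced positive, so every label set is
    non-empty.  ``flip_rate`` optionally adds independent label noise.
    """
    if k > T:
        raise ValueError("k must be <= T")
    if N < 1 or M < 1:
        raise ValueError("N and M must be >= 1")
    if not 0 <= zero_inflation < 1:
        raise ValueError("zero_inflation must be in [0, 1)")
    need = n_corr_blocks * corr_block_size
    if M * k + need > T:
        raise ValueError("not enough columns for disjoint supports-free blocks")
    rng = np.random.default_rng(seed)

    # sparse non-negative integer counts
    X = rng.poisson(poisson_rate, size=(N, T)).astype(np.float64)
    X *= rng.random(size=(N, T)) >= zero_inflation

    # per-class supports (may overlap between classes, never with blocks)
    lo, hi = magnitude_range
    beta = np.zeros((M, T))
    supports = []
    support_pool = np.arange(T)
    for m in range(M):
        sup = np.sort(rng.choice(support_pool[: T - need], size=k, replace=False))
        mags = rng.uniform(lo, hi, size=k)
        signs = rng.choice([-1.0, 1.0], size=k)
        beta[m, sup] = mags * signs
        supports.append(sup)

    # correlated blocks on the trailing (support-free) columns
    corr_blocks = []
    block_cols = np.arange(T - need, T)
    for b in range(n_corr_blocks):
        cols = block_cols[b * corr_block_size: (b + 1) * corr_block_size]
        leader = X[:, cols[0]].copy()
        for c in cols[1:]:
            redraw = rng.random(N) < 0.2
            X[:, c] = np.where(
                redraw,
                rng.poisson(poisson_rate, N) * (rng.random(N) >= zero_inflation),
                leader,
            )
        corr_blocks.append(cols)

    # every protein keeps >= 1 term, mirroring the guarantee of
    # homolog-transferred GO annotation
    for i in np.flatnonzero(~X.any(axis=1)):
        X[i, rng.integers(T)] = 1.0

    # latent scores centered at the population feature mean
    mu = (1 - zero_inflation) * poisson_rate
    intercepts = -beta.sum(axis=1) * mu
    Z = X @ beta.T + intercepts + rng.normal(0.0, sigma, size=(N, M))
    Y = np.where(Z > 0, 1.0, -1.0)
    if flip_rate > 0:
        flips = rng.random(size=(N, M)) < flip_rate
        Y[flips] *= -1
    # guarantee a non-empty label set per protein
    empty = ~(Y > 0).any(axis=1)
    Y[empty, np.argmax(Z[empty], axis=1)] = 1.0

    label_sets = [set((np.flatnonzero(Y[i] > 0) + 1).tolist()) for i in range(N)]
    ids = [f"SYN{i:05d}" for i in range(N)]
    dataset = Dataset(ids=ids, label_sets=label_sets, M=M, X=X)
    truth = PlantedTruth(
        beta=beta,
        intercepts=intercepts,
        supports=supports,
        sigma=sigma,
        corr_blocks=corr_blocks,
        seed=seed,
    )
    return dataset, truth


def make_toy_dag(
    depth: int = 3,
    branching: int = 2,
    extra_edge_frac: float = 0.1,
    n_proteins: int = 20,
    terms_per_protein: int = 4,
    seed: int = 0,
) -> tuple[GoDag, AnnotationDB]:
    """Toy GO DAG: one rooted tree per taxonomy plus extra DAG edges.

    Each taxonomy (CC, MF, BP) gets a complete ``branching``-ary tree of
    the given depth with is_a child->parent edges; a fraction
    ``extra_edge_frac`` of non-root nodes gains an extra part_of edge to a
    random strictly-shallower node of the same taxonomy (keeping the graph
    acyclic).  The annotation database assigns each synthetic accession a
    leaf-biased multiset of terms.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    nodes: list[tuple[str, str]] = []
    edges: list[tuple[str, str, str]] = []
    next_id = 1
    per_category_nodes: dict[str, list[tuple[str, int]]] = {}

    for category in ("CC", "MF", "BP"):
        levels: list[list[str]] = []
        all_nodes: list[tuple[str, int]] = []  # (id, level)
        root = f"GO:{next_id:07d}"
        next_id += 1
        nodes.append((root, category))
        levels.append([root])
        all_nodes.append((root, 0))
        for level in range(1, depth + 1):
            current: list[str] = []
            for parent in levels[level - 1]:
                for _ in range(branching):
                    child = f"GO:{next_id:07d}"
                    next_id += 1
                    nodes.append((child, category))
                    edges.append((child, parent, "is_a"))
                    current.append(child)
                    all_nodes.append((child, level))
            levels.append(current)
        # extra DAG edges to strictly shallower nodes keep acyclicity
        non_root = [(n, lv) for n, lv in all_nodes if lv > 0]
        n_extra = int(round(extra_edge_frac * len(non_root)))
        for n, lv in (non_root[i] for i in rng.permutation(len(non_root))[:n_extra]):
            shallower = [m for m, mlv in all_nodes if mlv < lv and m != n]
            target = shallower[int(rng.integers(len(shallower)))]
            if (n, target, "is_a") not in edges:
                edges.append((n, target, "part_of"))
        per_category_nodes[category] = all_nodes

    dag = build_dag(nodes, edges)

    entries: dict[str, Counter] = {}
    cat_of = dict(nodes)
    ids = list(cat_of)
    weights = np.asarray([1.0 + 2.0 * _node_level(t, per_category_nodes, cat_of) for t in ids])
    weights /= weights.sum()
    for p in range(n_proteins):
        accession = f"ACC{p:04d}"
        picks = rng.choice(len(ids), size=terms_per_protein, replace=True, p=weights)
        multiset: Counter = Counter()
        for idx in picks:
            multiset[GoTerm(ids[idx], cat_of[ids[idx]])] += 1
        entries[accession] = multiset
    return dag, AnnotationDB(entries)


def _node_level(term_id, per_category_nodes, cat_of) -> int:
    for node, level in per_category_nodes[cat_of[term_id]]:
        if node == term_id:
            return level
    return 0


def make_benchmark_like_composition(
    scale: float = 1.0, seed: int = 0
) -> Dataset:
    """Label-set skeleton with the human benchmark's co-location profile.

    Draws label-set sizes matching the published 1/2/3/4-location
    histogram at the requested scale over M = 14 locations, with the
    locations of each protein sampled (without replacement) proportionally
    to the published per-location locative counts.  At scale 1 the
    histogram is exactly (2580, 480, 43, 3).
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    rng = np.random.default_rng(seed)
    histogram = [max(int(round(scale * n)), 1 if n else 0) for n in HUMAN_COLOCATION_COUNTS]
    weights = np.asarray(list(HUMAN_LOCATIVE_COUNTS.values()), dtype=np.float64)
    weights /= weights.sum()
    ids: list[str] = []
    label_sets: list[set[int]] = []
    i = 0
    for n_locations, count in enumerate(histogram, start=1):
        for _ in range(count):
            locs = rng.choice(HUMAN_M, size=n_locations, replace=False, p=weights)
            ids.append(f"BM{i:05d}")
            label_sets.append({int(m) + 1 for m in locs})
            i += 1
    return Dataset(ids=ids, label_sets=label_sets, M=HUMAN_M)
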