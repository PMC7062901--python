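"""Diversity, distance and topography statistics for mapped subclones.

Implements the study-level summary statistics: Gini-Simpson subclone
diversity (the probability that two spots drawn without replacement
belong to different subclones), normalized phylogenetic distance
between adjacent subclones, the Manhattan (Hamming) distance between
dichotomized VAF vectors, spatial-vs-genetic correlation within slides,
the spatial-contiguity fraction of multi-spot subclones, and the
uniformity test of adjacency distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import hypot
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .datamodel import CloneTree, SpotRecord
from .genotyping import Subclone

__all__ = [
    "SubcloneCensus",
    "DiversityResult",
    "gini_simpson",
    "normalized_adjacency_distance",
    "dichotomized_L1",
    "spatial_genetic_correlation",
    "contiguity_fraction",
    "ks_uniform",
    "within_between_slide_distances",
    "WithinBetweenResult",
]


@dataclass(frozen=True)
class SubcloneCensus:
    """Spot counts per subclone in a region of interest."""

    region: str
    n_per_subclone: tuple[int, ...]

    @property
    def n_spots(self) -> int:
        return sum(self.n_per_subclone)

    @property
    def n_subclones(self) -> int:
        return len(self.n_per_subclone)

    @classmethod
    def from_spots(
        cls, region: str, spot_to_subclone: Mapping[str, str],
        spots: Sequence[SpotRecord] | None = None,
    ) -> "SubcloneCensus":
        counts: dict[str, int] = {}
        for sid, sub in spot_to_subclone.items():
            counts[sub] = counts.get(sub, 0) + 1
        return cls(region, tuple(sorted(counts.values(), reverse=True)))


@dataclass(frozen=True)
class DiversityResult:
    region: str
    gs: float


def gini_simpson(census: SubcloneCensus) -> DiversityResult:
    """Gini-Simpson index GS = 1 - sum n_i (n_i - 1) / (N (N - 1)).

    The probability that two spots sampled without replacement from the
    region belong to different subclones.  Undefined for N < 2.
    """
    n = census.n_spots
    if n < 2:
        raise ValueError(f"Gini-Simpson undefined for N={n} spots")
    same = sum(ni * (ni - 1) for ni in census.n_per_subclone)
    return DiversityResult(census.region, 1.0 - same / (n * (n - 1)))


def normalized_adjacency_distance(tree: CloneTree, clone_a: str, clone_b: str) -> float:
    """Normalized count of internal nodes separating two tips.

    Sister tips (one shared internal node) score 0; the most separated
    tip pair on the tree scores 1.  Both the numerator and the
    tree-wide maximum are shifted by -1 so the normalization is tight.
    """
    if clone_a == clone_b:
        raise ValueError("identical subclones have no adjacency distance")
    tips = tree.tips()
    if len(tips) < 3:
        raise ValueError("need at least 3 tips for a nonzero denominator")
    num = tree.internal_nodes_between(clone_a, clone_b) - 1
    den = max(
        tree.internal_nodes_between(a, b) for a, b in combinations(tips, 2)
    ) - 1
    if den <= 0:
        return 0.0
    return num / den


def dichotomized_L1(genotype_a: Sequence[int], genotype_b: Sequence[int]) -> int:
    """Manhattan distance between binary call vectors (= Hamming distance)."""
    if len(genotype_a) != len(genotype_b):
        raise ValueError(
            f"genotype length mismatch: {len(genotype_a)} vs {len(genotype_b)}"
        )
    return int(sum(abs(int(a) - int(b)) for a, b in zip(genotype_a, genotype_b)))


def spatial_genetic_correlation(
    spots: Sequence[SpotRecord],
    genotypes: Mapping[str, Sequence[int]],
) -> float:
    """Pearson correlation of spatial vs genetic distances within a slide.

    All spots must lie on one slide; pairwise Euclidean distances in mm
    are correlated against pairwise Hamming distances between the spot
    genotypes.  Returns NaN with a warning if either distance has zero
    variance.
    """
    if len(spots) < 3:
        raise ValueError("need at least 3 spots on the slide")
    slides = {s.slide_id for s in spots}
    if len(slides) != 1:
        raise ValueError(f"spots span multiple slides: {sorted(slides)}")
    spatial, genetic = [], []
    for a, b in combinations(spots, 2):
        spatial.append(hypot(a.x_mm - b.x_mm, a.y_mm - b.y_mm))
        genetic.append(dichotomized_L1(genotypes[a.spot_id], genotypes[b.spot_id]))
    if np.std(spatial) == 0 or np.std(genetic) == 0:
        warnings.warn("zero variance in a distance sample; correlation undefined",
                      stacklevel=2)
        return float("nan")
    r, _ = stats.pearsonr(spatial, genetic)
    return float(r)


def contiguity_fraction(
    spots: Sequence[SpotRecord],
    spot_to_subclone: Mapping[str, str],
    adjacency: nx.Graph | None = None,
    radius_mm: float = 4.0,
) -> tuple[float, int, int]:
    """Fraction of multi-spot (subclone, slide) instances that are contiguous.

    Two same-slide spots are adjacent iff within ``radius_mm`` of each
    other, unless an explicit adjacency graph is supplied.  Instances
    with more than 2 spots count; an instance is contiguous when its
    member spots induce a connected subgraph.  Returns
    (fraction, n_contiguous, n_eligible).
    """
    primary = [s for s in spots if s.is_primary and s.spot_id in spot_to_subclone]
    if adjacency is not None:
        missing = {s.spot_id for s in primary} - set(adjacency.nodes)
        if missing:
            raise ValueError(f"adjacency graph does not cover spots: {sorted(missing)}")
        graph = adjacency
    else:
        graph = nx.Graph()
        graph.add_nodes_from(s.spot_id for s in primary)
        by_slide: dict[str, list[SpotRecord]] = {}
        for s in primary:
            by_slide.setdefault(s.slide_id, []).append(s)
        for members in by_slide.values():
            for a, b in combinations(members, 2):
                if hypot(a.x_mm - b.x_mm, a.y_mm - b.y_mm) <= radius_mm:
                    graph.add_edge(a.spot_id, b.spot_id)

    instances: dict[tuple[str, str], list[str]] = {}
    for s in primary:
        instances.setdefault((spot_to_subclone[s.spot_id], s.slide_id), []).append(s.spot_id)
    eligible = {k: v for k, v in instances.items() if len(v) > 2}
    n_contig = sum(
        1 for members in eligible.values()
        if nx.is_connected(graph.subgraph(members))
    )
    n_elig = len(eligible)
    frac = n_contig / n_elig if n_elig else float("nan")
    return frac, n_contig, n_elig


def ks_uniform(values: Sequence[float]) -> tuple[float, float]:
    """Two-sided one-sample Kolmogorov-Smirnov test against Uniform(0, 1)."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 values")
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("values outside [0, 1]")
    res = stats.kstest(vals, "uniform")
    return float(res.statistic), float(res.pvalue)


@dataclass
class WithinBetweenResult:
    within: list[float]
    between: list[float]
    statistic: float | None
    pvalue: float | None


def within_between_slide_distances(
    tree: CloneTree,
    subclone_slides: Mapping[str, set],
) -> WithinBetweenResult | None:
    """Tree distances for within-slide vs between-slide subclone pairs.

    ``subclone_slides`` maps each subclone to the slides where it has
    spots.  A pair sharing at least one slide contributes a within-slide
    distance; a pair on disjoint slide sets contributes a between-slide
    distance.  Distances are normalized adjacency distances on the clone
    tree; the comparison is a two-sided Wilcoxon rank-sum.  Returns None
    for single-slide tumors.
    """
    all_slides = set().union(*subclone_slides.values()) if subclone_slides else set()
    if len(all_slides) < 2:
        return None
    within, between = [], []
    for a, b in combinations(sorted(subclone_slides), 2):
        if a not in tree.tips() or b not in tree.tips():
            continue
        d = normalized_adjacency_distance(tree, a, b)
        if subclone_slides[a] & subclone_slides[b]:
            within.append(d)
        else:
            between.append(d)
    if not within or not between:
        return WithinBetweenResult(within, between, None, None)
    res = stats.ranksums(within, between)
    return WithinBetweenResult(within, between, float(res.statistic), float(res.pvalue))
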