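"""Shared fixtures and generators for the test suite."""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pytest

from phylogeo import PipelineConfig, analyze_tumor, make_worked_fixture
from phylogeo.datamodel import GERMLINE, CloneTree, Locus, SpotRecord, VAFMatrix
from phylogeo.genotyping import Subclone


def make_spot(spot_id, phenotype="S", tumor="T1", slide="X", x=0.0, y=0.0,
              site="primary"):
    return SpotRecord(spot_id=spot_id, tumor_id=tumor, slide_id=slide,
                      x_mm=x, y_mm=y, phenotype=phenotype, site=site)


def make_subclones(genotypes: dict[str, tuple[int, ...]],
                   phenotypes: dict[str, list[str]] | None = None) -> list[Subclone]:
    """Subclones from a name -> binary-genotype mapping; optional member
    phenotype lists (one spot per listed phenotype, M implies lymph_node)."""
    out = []
    for k, (name, geno) in enumerate(genotypes.items()):
        phenos = (phenotypes or {}).get(name, ["S"])
        members = tuple(
            make_spot(f"{name.lower()}{i}", phenotype=p,
                      site="primary" if p != "M" else "lymph_node")
            for i, p in enumerate(phenos)
        )
        out.append(Subclone(name, tuple(geno), members, 0))
    return out


def random_genealogy(rng: np.random.Generator, n_tips: int, n_loci: int = 40,
                     n_public: int = 3, k_range: tuple[int, int] = (1, 3)):
    """Random homoplasy-free genotypes plus the true clone tree.

    Grows a genealogy by repeatedly descending from a random existing
    genotype with ``k_range`` fresh mutations (infinite sites on the
    panel).  Returns (subclones, truth CloneTree).
    """
    pool = list(range(n_public, n_loci))
    rng.shuffle(pool)
    genotypes: list[set[int]] = [set(range(n_public))]
    parents: list[int] = [-1]
    while len(genotypes) < n_tips:
        k = int(rng.integers(k_range[0], k_range[1] + 1))
        if k > len(pool):
            raise RuntimeError("locus pool exhausted; enlarge n_loci")
        parent = int(rng.integers(0, len(genotypes)))
        child = set(genotypes[parent])
        for _ in range(k):
            child.add(pool.pop())
        genotypes.append(child)
        parents.append(parent)

    names = [f"SC{i + 1}" for i in range(n_tips)]
    subclones = [
        Subclone(names[i],
                 tuple(1 if j in genotypes[i] else 0 for j in range(n_loci)),
                 (make_spot(f"s{i}"),), 0)
        for i in range(n_tips)
    ]

    graph = nx.DiGraph()
    graph.add_node(GERMLINE)
    locus_names = [f"L{j}" for j in range(n_loci)]
    for i in range(n_tips):
        pnode = GERMLINE if parents[i] == -1 else f"g{parents[i]}"
        new = genotypes[i] - (set() if parents[i] == -1 else genotypes[parents[i]])
        graph.add_edge(pnode, f"g{i}", mutations=frozenset(locus_names[j] for j in new))
        graph.add_edge(f"g{i}", names[i], mutations=frozenset())
    truth = CloneTree(graph)
    return subclones, truth


def random_labeled_tree(rng: np.random.Generator, n_tips: int):
    """A random rooted tree plus random S / I / S-I tip labels."""
    subclones, truth = random_genealogy(rng, n_tips, n_loci=6 * n_tips + 6)
    labels = {}
    for sc in subclones:
        labels[sc.subclone_id] = ("S", "I", "S-I")[int(rng.integers(0, 3))]
    return truth, labels


def vafmatrix_from_binary(binary, phenotypes=None, depth=9000):
    """A noise-free VAFMatrix whose calls reproduce a binary matrix."""
    binary = np.asarray(binary)
    n_s, n_l = binary.shape
    phenotypes = phenotypes or ["S"] * n_s
    spots = [make_spot(f"s{i + 1}", phenotype=phenotypes[i]) for i in range(n_s)]
    loci = [Locus(f"L{j + 1}") for j in range(n_l)]
    vaf = np.where(binary > 0, 0.5, 0.0)
    dep = np.full((n_s, n_l), depth, dtype=np.int64)
    return VAFMatrix(spots, loci, vaf, dep)


@pytest.fixture(scope="session")
def worked():
    return make_worked_fixture()


@pytest.fixture(scope="session")
def worked_report(worked):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze_tumor(worked.vafs, PipelineConfig(rng_seed=1, bootstrap_n=500))
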