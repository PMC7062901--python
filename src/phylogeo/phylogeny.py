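"""Rooted subclone trees by exact maximum parsimony.

After homoplasy avoidance the binary genotype matrix is compatible
(every locus pair passes the four-gamete test), so the perfect
phylogeny — built directly from the laminar family of mutation-sharing
subclone sets — is the unique maximum-parsimony tree and no heuristic
search is needed.  An exhaustive Fitch-scored search over topologies is
provided as a fallback for matrices where homoplasy is tolerated, and
character (column) bootstrap quantifies edge support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .datamodel import GERMLINE, CloneTree, PipelineConfig
from .genotyping import CallMatrix, Subclone, violating_pairs

__all__ = [
    "four_gamete_test",
    "build_perfect_phylogeny",
    "fitch_parsimony_length",
    "exhaustive_parsimony_search",
    "bootstrap_support",
    "BootstrapSupport",
    "ParsimonyResult",
]


# ---------------------------------------------------------------------------
# Four-gamete test
# ---------------------------------------------------------------------------

def four_gamete_test(calls) -> list[tuple[str, str]]:
    """All locus pairs failing the four-gamete condition.

    Accepts a CallMatrix (uses its effective binary matrix over included
    spots) or a plain binary array.  The germline all-absent genotype is
    implicitly one of the rows, so a pair is incompatible iff patterns
    01, 10 and 11 all occur.  An empty result is equivalent to the
    existence of a perfect phylogeny.
    """
    if isinstance(calls, CallMatrix):
        binary, _ = calls.effective_binary()
        names = calls.locus_ids
    else:
        binary = np.asarray(calls)
        names = [f"L{j}" for j in range(binary.shape[1])]
    return [(names[p], names[q]) for p, q in violating_pairs(binary)]


# ---------------------------------------------------------------------------
# Perfect phylogeny
# ---------------------------------------------------------------------------

def _genotype_matrix(subclones: Sequence[Subclone]) -> np.ndarray:
    return np.array([sc.genotype for sc in subclones], dtype=np.int8)


def build_perfect_phylogeny(
    subclones: Sequence[Subclone], locus_ids: Sequence[str] | None = None
) -> CloneTree:
    """Build the unique perfect phylogeny for compatible subclone genotypes.

    Mutations with identical carrier sets share one edge.  The carrier
    sets of a compatible matrix form a laminar family, which directly
    yields the tree: each set's parent is the smallest strictly
    containing set (the germline root holds all subclones).  A subclone
    whose genotype equals an inferred internal node is attached there as
    a zero-length tip.
    """
    mat = _genotype_matrix(subclones)
    n_sub, n_loci = mat.shape
    if locus_ids is None:
        locus_ids = [f"L{j}" for j in range(n_loci)]
    bad = violating_pairs(mat)
    if bad:
        pairs = [(locus_ids[p], locus_ids[q]) for p, q in bad]
        raise ValueError(
            f"matrix is not tree-compatible (four-gamete violations: {pairs}); "
            "resolve homoplasy first"
        )
    keys = [sc.subclone_id for sc in subclones]
    if len(set(keys)) != n_sub:
        raise ValueError("subclone ids not unique")
    if len({sc.genotype for sc in subclones}) != n_sub:
        raise ValueError("subclone genotypes not pairwise distinct")

    # carrier set -> mutations on that edge
    clusters: dict[frozenset, set] = {}
    for j in range(n_loci):
        carriers = frozenset(i for i in range(n_sub) if mat[i, j])
        if not carriers:
            continue
        clusters.setdefault(carriers, set()).add(locus_ids[j])

    graph = nx.DiGraph()
    graph.add_node(GERMLINE)
    order = sorted(clusters, key=lambda s: (-len(s), sorted(s)))
    node_of: dict[frozenset, str] = {}
    parent_of: dict[frozenset, frozenset | None] = {}
    for support in order:
        parent = None
        for cand in order:
            if cand is support:
                continue
            if len(cand) > len(support) and support < cand:
                if parent is None or len(cand) < len(parent):
                    parent = cand
        parent_of[support] = parent

    counter = 0
    for support in order:
        if support == frozenset({next(iter(support))}) and len(support) == 1:
            name = subclones[next(iter(support))].subclone_id
        else:
            counter += 1
            name = f"n{counter}"
        node_of[support] = name
    for support in order:
        parent = parent_of[support]
        pname = GERMLINE if parent is None else node_of[parent]
        graph.add_edge(pname, node_of[support], mutations=frozenset(clusters[support]))

    # attach tips
    for i, sc in enumerate(subclones):
        own = frozenset({i})
        if own in node_of:
            continue  # the singleton cluster node is the tip itself
        best = None
        for support in order:
            if i in support and (best is None or len(support) < len(best)):
                best = support
        attach = GERMLINE if best is None else node_of[best]
        graph.add_edge(attach, sc.subclone_id, mutations=frozenset())

    tree = CloneTree(graph, root=GERMLINE)
    return tree


# ---------------------------------------------------------------------------
# Fitch small parsimony
# ---------------------------------------------------------------------------

def fitch_parsimony_length(tree: CloneTree, genotypes: Mapping[str, Sequence[int]]) -> int:
    """Total Fitch parsimony length of a rooted tree on binary characters.

    ``genotypes`` maps tip names to 0/1 vectors.  The germline root is
    constrained to the all-absent state (one extra change is charged per
    locus whose root state set excludes 0).
    """
    tips = tree.tips()
    for t in tips:
        if t not in genotypes:
            raise KeyError(f"tip {t} missing from genotype matrix")
    n_loci = len(next(iter(genotypes.values()))) if genotypes else 0
    order = list(nx.dfs_postorder_nodes(tree.graph, tree.root))
    big = 10 ** 9
    total = 0
    # Sankoff DP with unit costs (exact also on polytomies)
    for j in range(n_loci):
        cost: dict[str, tuple[int, int]] = {}
        for node in order:
            kids = tree.children(node)
            if not kids:
                s = int(genotypes[node][j])
                cost[node] = (0 if s == 0 else big, 0 if s == 1 else big)
                continue
            c0 = c1 = 0
            for k in kids:
                k0, k1 = cost[k]
                c0 += min(k0, k1 + 1)
                c1 += min(k1, k0 + 1)
            cost[node] = (c0, c1)
        total += cost[tree.root][0]  # germline root fixed to the absent state
    return total


def _binary_fitch_length(tree_struct, genotypes: dict, n_loci: int) -> int:
    """Fitch length on a nested-tuple binary tree rooted at the germline."""
    total = 0
    for j in range(n_loci):
        def fitch(node) -> tuple[frozenset, int]:
            if isinstance(node, str):
                return frozenset({int(genotypes[node][j])}), 0
            (ls, lc), (rs, rc) = fitch(node[0]), fitch(node[1])
            inter = ls & rs
            if inter:
                return inter, lc + rc
            return ls | rs, lc + rc + 1
        root_set, changes = fitch(tree_struct)
        if 0 not in root_set:
            changes += 1
        total += changes
    return total


# ---------------------------------------------------------------------------
# Exhaustive search (fallback when homoplasy is tolerated)
# ---------------------------------------------------------------------------

@dataclass
class ParsimonyResult:
    tree: CloneTree
    length: int
    n_optimal: int  # number of tied topologies at the minimum


def _all_rooted_trees(tips: list[str]):
    """All rooted binary topologies over the given tips ((2n-3)!! of them,
    equivalently all attachments of the germline leaf to the unrooted tree)."""
    if len(tips) == 1:
        yield tips[0]
        return

    def insert(tree, tip):
        yield (tip, tree)
        if isinstance(tree, tuple):
            left, right = tree
            for nl in insert(left, tip):
                yield (nl, right)
            for nr in insert(right, tip):
                yield (left, nr)

    for sub in _all_rooted_trees(tips[1:]):
        yield from insert(sub, tips[0])


def _struct_newick(node) -> str:
    if isinstance(node, str):
        return node
    return "(" + ",".join(sorted(_struct_newick(c) for c in node)) + ")"


def _struct_to_clonetree(struct, genotypes: dict, n_loci: int) -> CloneTree:
    """Convert a scored topology to a CloneTree with Fitch-assigned edges.

    With homoplasy present a mutation may label several edges; branch
    lengths remain the per-edge change counts.
    """
    graph = nx.DiGraph()
    counter = 0

    def build(node) -> tuple[str, dict[int, frozenset]]:
        nonlocal counter
        if isinstance(node, str):
            graph.add_node(node)
            return node, {j: frozenset({int(genotypes[node][j])}) for j in range(n_loci)}
        counter += 1
        name = f"n{counter}"
        graph.add_node(name)
        child_infos = [build(c) for c in node]
        sets = {}
        for j in range(n_loci):
            inter = child_infos[0][1][j] & child_infos[1][1][j]
            sets[j] = inter if inter else child_infos[0][1][j] | child_infos[1][1][j]
        for cname, csets in child_infos:
            graph.add_edge(name, cname, mutations=frozenset())
        graph.nodes[name]["fitch"] = sets
        return name, sets

    top_name, top_sets = build(struct)
    graph.add_edge(GERMLINE, top_name, mutations=frozenset())

    # second pass: resolve states top-down (root forced all-absent) and
    # label edges with the loci that change on them
    state: dict[str, dict[int, int]] = {GERMLINE: {j: 0 for j in range(n_loci)}}
    for parent, child in nx.bfs_edges(graph, GERMLINE):
        if graph.out_degree(child) == 0:
            cstate = {j: int(genotypes[child][j]) for j in range(n_loci)}
        else:
            csets = graph.nodes[child]["fitch"]
            cstate = {
                j: (state[parent][j] if state[parent][j] in csets[j] else min(csets[j]))
                for j in range(n_loci)
            }
        state[child] = cstate
        changed = frozenset(
            f"L{j}" for j in range(n_loci) if cstate[j] != state[parent][j]
        )
        graph.edges[parent, child]["mutations"] = changed
    for n in list(graph.nodes):
        graph.nodes[n].pop("fitch", None)
    return CloneTree(graph, root=GERMLINE)


def exhaustive_parsimony_search(
    subclones: Sequence[Subclone], max_tips: int = 9
) -> ParsimonyResult:
    """Globally minimal Fitch-length tree by topology enumeration.

    Ties are counted and broken by lexicographic order of the shape's
    Newick string.  Intended for desk-scale matrices; refuses more than
    ``max_tips`` subclones.
    """
    names = [sc.subclone_id for sc in subclones]
    if len(names) > max_tips:
        raise ValueError(
            f"{len(names)} subclones exceeds max_tips={max_tips}; "
            "resolve homoplasy and use build_perfect_phylogeny instead"
        )
    genotypes = {sc.subclone_id: sc.genotype for sc in subclones}
    n_loci = len(subclones[0].genotype)
    best: tuple[int, str] | None = None
    best_struct = None
    n_opt = 0
    for struct in _all_rooted_trees(sorted(names)):
        length = _binary_fitch_length(struct, genotypes, n_loci)
        key = (length, _struct_newick(struct))
        if best is None or length < best[0]:
            best, best_struct, n_opt = key, struct, 1
        elif length == best[0]:
            n_opt += 1
            if key < best:
                best, best_struct = key, struct
    assert best_struct is not None
    if isinstance(best_struct, str):  # single subclone
        graph = nx.DiGraph()
        muts = frozenset(f"L{j}" for j, g in enumerate(genotypes[best_struct]) if g)
        graph.add_edge(GERMLINE, best_struct, mutations=muts)
        return ParsimonyResult(CloneTree(graph), best[0], 1)
    tree = _struct_to_clonetree(best_struct, genotypes, n_loci)
    return ParsimonyResult(tree, best[0], n_opt)


# ---------------------------------------------------------------------------
# Character bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapSupport:
    """Per-internal-edge support fractions from column resampling."""

    support: dict[tuple[str, str], float]
    n_replicates: int


def bootstrap_support(
    subclones: Sequence[Subclone],
    cfg: PipelineConfig | None = None,
    tree: CloneTree | None = None,
    locus_ids: Sequence[str] | None = None,
) -> BootstrapSupport:
    """Column-bootstrap support for the internal edges of the clone tree.

    Loci are resampled with replacement ``bootstrap_n`` times and the
    tree rebuilt (column subsets of a compatible matrix stay compatible,
    so the perfect phylogeny always applies).  An edge's support is the
    fraction of replicates whose tree contains the same tip clade; the
    root edge is excluded.
    """
    cfg = cfg or PipelineConfig()
    if tree is None:
        tree = build_perfect_phylogeny(subclones, locus_ids)
    mat = _genotype_matrix(subclones)
    n_sub, n_loci = mat.shape
    tips = set(tree.tips())
    targets = {
        edge: clade for edge, clade in tree.tip_bipartitions().items()
        if edge[0] != tree.root and 1 < len(clade) < len(tips)
    }
    if not targets or n_loci == 0:
        return BootstrapSupport({}, cfg.bootstrap_n)

    rng = np.random.default_rng(cfg.rng_seed)
    hits = {edge: 0 for edge in targets}
    for _ in range(cfg.bootstrap_n):
        cols = rng.integers(0, n_loci, size=n_loci)
        sub = mat[:, cols]
        # rebuild clades directly from carrier sets (laminar family)
        clades = set()
        for j in range(n_loci):
            carriers = frozenset(i for i in range(n_sub) if sub[i, j])
            if 1 < len(carriers) < n_sub:
                clades.add(frozenset(subclones[i].subclone_id for i in carriers))
        for edge, clade in targets.items():
            if clade in clades:
                hits[edge] += 1
    return BootstrapSupport(
        {edge: hits[edge] / cfg.bootstrap_n for edge in targets}, cfg.bootstrap_n
    )
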