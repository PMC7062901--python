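"""Perfect phylogeny, Fitch scoring, exhaustive search and bootstrap."""

import shutil
import subprocess
import textwrap

import numpy as np
import pytest

from phylogeo.datamodel import PipelineConfig
from phylogeo.genotyping import Subclone, violating_pairs
from phylogeo.phylogeny import (
    bootstrap_support,
    build_perfect_phylogeny,
    exhaustive_parsimony_search,
    fitch_parsimony_length,
    four_gamete_test,
)

from conftest import make_spot, make_subclones, random_genealogy


class TestFourGameteTest:
    def test_violating_pair_detected(self):
        # rows 11, 10, 01 (germline 00 implicit) -> all four gametes
        assert four_gamete_test(np.array([[1, 1], [1, 0], [0, 1]])) == [("L0", "L1")]

    def test_nested_rows_compatible(self):
        assert four_gamete_test(np.array([[1, 0], [1, 1]])) == []

    def test_single_locus_always_compatible(self):
        assert four_gamete_test(np.array([[1], [0], [1]])) == []


class TestPerfectPhylogeny:
    def test_single_subclone_public_edge(self):
        subclones = make_subclones({"SC1": tuple([1] * 24)})
        tree = build_perfect_phylogeny(subclones)
        assert tree.tips() == ["SC1"]
        assert tree.branch_length("germline", "SC1") == 24

    def test_caterpillar_construction(self):
        # genotypes 1100, 1110, 1101 with germline 0000: the root edge
        # carries m1, m2; the tip carrying only them sits at the fork
        subclones = make_subclones({
            "X": (1, 1, 0, 0),
            "Y": (1, 1, 1, 0),
            "Z": (1, 1, 0, 1),
        })
        tree = build_perfect_phylogeny(subclones, ["m1", "m2", "m3", "m4"])
        fork = tree.parent("Y")
        assert tree.genotype_of(fork) == {"m1", "m2"}
        assert tree.parent("Z") == fork and tree.parent("X") == fork
        assert tree.edge_mutations(fork, "Y") == {"m3"}
        assert tree.edge_mutations(fork, "Z") == {"m4"}
        assert tree.branch_length(fork, "X") == 0  # observed internal genotype

    def test_incompatible_matrix_rejected(self):
        subclones = make_subclones({"A": (1, 1), "B": (1, 0), "C": (0, 1)})
        with pytest.raises(ValueError, match="resolve homoplasy"):
            build_perfect_phylogeny(subclones)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_genealogy_recovered(self, seed):
        rng = np.random.default_rng(seed)
        n_tips = int(rng.integers(3, 9))
        subclones, truth = random_genealogy(rng, n_tips)
        mat = np.array([sc.genotype for sc in subclones])
        assert violating_pairs(mat) == []
        tree = build_perfect_phylogeny(subclones)
        assert tree.isomorphic_to(truth)
        # root-to-tip mutation unions equal the genotypes
        for sc in subclones:
            muts = {int(m[1:]) for m in tree.genotype_of(sc.subclone_id)}
            assert muts == set(sc.mutations)

    def test_invariant_to_spot_and_locus_order(self):
        rng = np.random.default_rng(42)
        subclones, _ = random_genealogy(rng, 6)
        tree = build_perfect_phylogeny(subclones)
        perm = rng.permutation(len(subclones[0].genotype))
        shuffled = [
            Subclone(sc.subclone_id, tuple(sc.genotype[j] for j in perm),
                     sc.member_spots, 0)
            for sc in reversed(subclones)
        ]
        tree2 = build_perfect_phylogeny(shuffled)
        assert {frozenset(b) for b in tree.tip_bipartitions().values()} == \
               {frozenset(b) for b in tree2.tip_bipartitions().values()}


class TestFitchLength:
    def test_perfect_tree_length_equals_variant_count(self):
        rng = np.random.default_rng(1)
        subclones, _ = random_genealogy(rng, 6)
        tree = build_perfect_phylogeny(subclones)
        genotypes = {sc.subclone_id: sc.genotype for sc in subclones}
        n_variants = int((np.array(list(genotypes.values())).sum(axis=0) > 0).sum())
        assert fitch_parsimony_length(tree, genotypes) == n_variants

    def test_wrong_topology_is_longer(self):
        # a character shared by exactly two tips (m2 in A, B) forces a
        # second change on any topology that separates them
        subclones = make_subclones({
            "A": (1, 1, 0),
            "B": (1, 1, 1),
            "C": (1, 0, 0),
        })
        genotypes = {sc.subclone_id: sc.genotype for sc in subclones}
        assert exhaustive_parsimony_search(subclones).length == 3

        import networkx as nx

        from phylogeo.datamodel import GERMLINE, CloneTree

        def cherry(a, b, c):
            g = nx.DiGraph()
            g.add_edge(GERMLINE, "n1")
            g.add_edge("n1", c)
            g.add_edge("n1", "n2")
            g.add_edge("n2", a)
            g.add_edge("n2", b)
            return CloneTree(g)

        lengths = {
            pair: fitch_parsimony_length(cherry(*pair), genotypes)
            for pair in (("A", "B", "C"), ("A", "C", "B"), ("B", "C", "A"))
        }
        assert lengths[("A", "B", "C")] == 3
        assert lengths[("A", "C", "B")] == 4
        assert lengths[("B", "C", "A")] == 4

    def test_ancestral_genotype_ties_all_topologies(self):
        # when one observed genotype is ancestral to the other two, every
        # topology attains the same minimum (enumeration confirms)
        subclones = make_subclones({
            "X": (1, 1, 0, 0),
            "Y": (1, 1, 1, 0),
            "Z": (1, 1, 0, 1),
        })
        res = exhaustive_parsimony_search(subclones)
        assert res.length == 4
        assert res.n_optimal == 3

    def test_single_tip(self):
        subclones = make_subclones({"SC1": (1, 0, 1, 1)})
        tree = build_perfect_phylogeny(subclones)
        assert fitch_parsimony_length(tree, {"SC1": (1, 0, 1, 1)}) == 3

    def test_missing_tip_rejected(self):
        subclones = make_subclones({"SC1": (1, 0)})
        tree = build_perfect_phylogeny(subclones)
        with pytest.raises(KeyError):
            fitch_parsimony_length(tree, {"OTHER": (1, 0)})


class TestExhaustiveSearch:
    def test_matches_perfect_phylogeny_on_compatible_matrix(self):
        rng = np.random.default_rng(5)
        subclones, _ = random_genealogy(rng, 5)
        pp = build_perfect_phylogeny(subclones)
        genotypes = {sc.subclone_id: sc.genotype for sc in subclones}
        res = exhaustive_parsimony_search(subclones)
        assert res.length == fitch_parsimony_length(pp, genotypes)

    def test_injected_homoplasy_costs_one_extra(self):
        rng = np.random.default_rng(6)
        subclones, _ = random_genealogy(rng, 5, k_range=(2, 3))
        mat = np.array([sc.genotype for sc in subclones], dtype=np.int8)
        n_variants = int((mat.sum(axis=0) > 0).sum())
        for _ in range(200):
            r, c = rng.integers(0, mat.shape[0]), rng.integers(0, mat.shape[1])
            trial = mat.copy()
            trial[r, c] ^= 1
            if violating_pairs(trial):
                break
        else:
            pytest.fail("no violating flip found")
        n_variants_after = int((trial.sum(axis=0) > 0).sum())
        perturbed = [
            Subclone(sc.subclone_id, tuple(int(x) for x in trial[i]),
                     sc.member_spots, 0)
            for i, sc in enumerate(subclones)
        ]
        res = exhaustive_parsimony_search(perturbed)
        assert res.length == n_variants_after + 1

    def test_two_subclones_unique_topology(self):
        subclones = make_subclones({"A": (1, 1, 0), "B": (1, 0, 1)})
        res = exhaustive_parsimony_search(subclones)
        assert res.n_optimal == 1
        assert set(res.tree.tips()) == {"A", "B"}

    def test_too_many_tips_rejected(self):
        rng = np.random.default_rng(9)
        subclones, _ = random_genealogy(rng, 6)
        with pytest.raises(ValueError, match="max_tips"):
            exhaustive_parsimony_search(subclones, max_tips=5)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
class TestPhangornOracle:
    def test_parsimony_score_agrees_with_phangorn(self, tmp_path):
        """Independent maximum-parsimony oracle on a small matrix."""
        rng = np.random.default_rng(12)
        subclones, _ = random_genealogy(rng, 5, n_loci=20)
        mat = np.array([sc.genotype for sc in subclones], dtype=int)
        keep = mat.sum(axis=0) > 0
        mat = mat[:, keep]
        names = [sc.subclone_id for sc in subclones]
        phy = tmp_path / "m.csv"
        rows = ["germline," + ",".join("0" * 1 for _ in range(mat.shape[1]))]
        rows = [f"germline,{','.join('0' for _ in range(mat.shape[1]))}"]
        for i, n in enumerate(names):
            rows.append(n + "," + ",".join(str(x) for x in mat[i]))
        phy.write_text("\n".join(rows) + "\n")
        script = textwrap.dedent(f"""
            suppressMessages(library(phangorn))
            m <- as.matrix(read.csv("{phy}", header=FALSE, row.names=1))
            pd <- phyDat(m, type="USER", levels=c(0, 1))
            tr <- pratchet(pd, trace=0, minit=50)
            cat(parsimony(tr, pd))
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        phangorn_score = int(float(out.stdout.strip().split()[-1]))
        ours = exhaustive_parsimony_search(subclones).length
        assert ours == phangorn_score


class TestBootstrap:
    def test_heavily_supported_clade(self):
        # clade {A,B} defined by 30 of ~50 mutations: a replicate missing
        # all 30 columns is essentially impossible
        publics = 5
        clade = 30
        n = publics + clade + 10
        genoA = tuple(1 if j < publics + clade or j == n - 2 else 0 for j in range(n))
        genoB = tuple(1 if j < publics + clade or j == n - 1 else 0 for j in range(n))
        genoC = tuple(1 if j < publics else 0 for j in range(n))
        subclones = make_subclones({"A": genoA, "B": genoB, "C": genoC})
        cfg = PipelineConfig(bootstrap_n=1000, rng_seed=0)
        boot = bootstrap_support(subclones, cfg)
        assert boot.n_replicates == 1000
        (edge, support), = boot.support.items()
        assert support >= 0.99

    def test_polytomy_has_no_support_entry(self):
        subclones = make_subclones({
            "A": (1, 1, 0, 0), "B": (1, 0, 1, 0), "C": (1, 0, 0, 1),
        })
        boot = bootstrap_support(subclones, PipelineConfig(bootstrap_n=50, rng_seed=0))
        assert boot.support == {}
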