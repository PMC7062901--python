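"""Calling, noise rules, admixture detection and homoplasy resolution."""

import warnings

import numpy as np
import pytest

from phylogeo.datamodel import Locus, PipelineConfig, VAFMatrix
from phylogeo.genotyping import (
    ABSENT,
    MISSING,
    PRESENT,
    SINGLETON_NOISE_REMOVED,
    FALSE_NEGATIVE_PROMOTED,
    call_mutations,
    classify_scope,
    collapse_subclones,
    detect_admixed_spots,
    min_flips_exhaustive,
    preprocess,
    promote_public,
    remove_singleton_noise,
    resolve_homoplasy,
    violating_pairs,
)
from phylogeo.phylogeny import four_gamete_test
from phylogeo.simulate import SimConfig, emit_vaf_reads, simulate_tumor

from conftest import make_spot, random_genealogy, vafmatrix_from_binary

CFG = PipelineConfig()


def _vafs(vaf_rows, depth_rows, phenos=None):
    vaf = np.asarray(vaf_rows, dtype=float)
    dep = np.asarray(depth_rows, dtype=np.int64)
    n_s, n_l = vaf.shape
    phenos = phenos or ["S"] * n_s
    spots = [make_spot(f"s{i + 1}", phenotype=phenos[i]) for i in range(n_s)]
    loci = [Locus(f"L{j + 1}") for j in range(n_l)]
    return VAFMatrix(spots, loci, vaf, dep)


class TestCallMutations:
    @pytest.mark.filterwarnings("ignore::UserWarning")
    @pytest.mark.parametrize("vaf,depth,expected", [
        (0.30, 9000, PRESENT),
        (0.049, 100, ABSENT),
        (0.05, 100, PRESENT),   # the printed 5% threshold calls positive
        (0.30, 19, MISSING),    # below the 20-read minimum
        (0.0, 20, ABSENT),
    ])
    def test_threshold_boundaries(self, vaf, depth, expected):
        vm = _vafs([[vaf, 0.5]], [[depth, 9000]])
        cm = call_mutations(vm, CFG)
        assert cm.calls[0, 0] == expected

    def test_high_missing_spot_excluded(self):
        vm = _vafs([[0.5, 0.5, 0.5], [0.5, 0.0, 0.0]],
                   [[9000] * 3, [9000, 5, 5]])
        with pytest.warns(UserWarning, match="excluded"):
            cm = call_mutations(vm, CFG)
        assert cm.excluded_spots == {"s2": "high_missing"}


class TestSingletonNoise:
    def _run(self, vafs):
        cm = call_mutations(vafs, CFG)
        return remove_singleton_noise(cm, vafs, CFG)

    def test_low_vaf_singleton_removed(self):
        vm = _vafs([[0.5, 0.055], [0.5, 0.0], [0.5, 0.0]], [[9000] * 2] * 3)
        cm = self._run(vm)
        assert cm.calls[0, 1] == ABSENT
        assert cm.provenance[0, 1] == SINGLETON_NOISE_REMOVED

    def test_high_vaf_singleton_retained(self):
        vm = _vafs([[0.5, 0.20], [0.5, 0.0], [0.5, 0.0]], [[9000] * 2] * 3)
        assert self._run(vm).calls[0, 1] == PRESENT

    def test_two_carriers_not_a_singleton(self):
        vm = _vafs([[0.5, 0.055], [0.5, 0.30], [0.5, 0.0]], [[9000] * 2] * 3)
        cm = self._run(vm)
        assert cm.calls[0, 1] == PRESENT and cm.calls[1, 1] == PRESENT


class TestPromotion:
    def _matrix(self, n_present, n_total):
        vaf = [[0.5] if i < n_present else [0.0] for i in range(n_total)]
        return _vafs(vaf, [[9000]] * n_total)

    def test_95pct_promoted_to_all(self):
        cm = promote_public(call_mutations(self._matrix(19, 20), CFG), CFG)
        assert (cm.calls[:, 0] == PRESENT).all()
        assert (cm.provenance[:, 0] == FALSE_NEGATIVE_PROMOTED).sum() == 1
        assert cm.public_loci == {"L1"}

    def test_exactly_90pct_unchanged(self):
        cm = promote_public(call_mutations(self._matrix(18, 20), CFG), CFG)
        assert (cm.calls[:, 0] == PRESENT).sum() == 18
        assert cm.public_loci == set()

    def test_fully_present_tagged_without_changes(self):
        cm = promote_public(call_mutations(self._matrix(20, 20), CFG), CFG)
        assert cm.public_loci == {"L1"}
        assert (cm.provenance[:, 0] == FALSE_NEGATIVE_PROMOTED).sum() == 0


class TestScope:
    def test_public_private_and_dropped(self):
        vm = _vafs([[0.5, 0.5, 0.0], [0.5, 0.0, 0.0]], [[9000] * 3] * 2)
        cm = call_mutations(vm, CFG)
        with pytest.warns(UserWarning, match="dropped"):
            scope = classify_scope(cm)
        assert scope == {"L1": "public", "L2": "private"}
        assert cm.dropped_loci == {"L3"}


class TestAdmixture:
    def test_synthetic_mixture_flagged(self):
        # two clones sharing publics; an uneven mixture spot carries both
        # private sets at diluted VAF and creates four-gamete violations
        cfg = SimConfig(panel_size=10, cellularity=1.0, rng_seed=5)
        clone_a = frozenset({0, 1, 2, 3, 4, 5})  # publics 0,1 + privates 2..5
        clone_b = frozenset({0, 1, 6, 7})
        rng = np.random.default_rng(cfg.rng_seed)
        rows, depths = [], []
        for mix in ([clone_a] * 3, [clone_b] * 3, [clone_a, clone_b, clone_b]):
            v, d = emit_vaf_reads(list(mix), cfg, rng)
            rows.append(v)
            depths.append(d)
        vm = _vafs(rows, depths)
        cm = call_mutations(vm, CFG)
        flags = detect_admixed_spots(cm, vm, CFG)
        assert [f.spot_id for f in flags] == ["s3"]
        assert flags[0].reason == "both"
        assert flags[0].private_vaf_ratio < 0.5

    def test_clonal_spots_not_flagged(self):
        vm = vafmatrix_from_binary([[1, 1, 0], [1, 0, 1], [1, 0, 0]])
        cm = call_mutations(vm, CFG)
        assert detect_admixed_spots(cm, vm, CFG) == []


class TestHomoplasyResolution:
    def test_compatible_matrix_identity(self):
        vm = vafmatrix_from_binary([[1, 1], [1, 0]])
        cm = resolve_homoplasy(call_mutations(vm, CFG), vm, CFG)
        assert sum(1 for e in cm.audit if e["rule"] == "homoplasy_flip") == 0

    def test_three_spot_conflict_needs_one_flip(self):
        binary = [[1, 1], [1, 0], [0, 1]]
        assert min_flips_exhaustive(np.array(binary)) == 1
        vm = vafmatrix_from_binary(binary)
        cm = resolve_homoplasy(call_mutations(vm, CFG), vm, CFG)
        flips = [e for e in cm.audit if e["rule"] == "homoplasy_flip"]
        assert len(flips) == 1
        assert four_gamete_test(cm) == []

    def test_single_injected_flip_recovered(self):
        rng = np.random.default_rng(11)
        subclones, _ = random_genealogy(rng, 8, n_loci=12, n_public=1, k_range=(1, 1))
        original = np.array([sc.genotype for sc in subclones], dtype=np.int8)
        assert violating_pairs(original) == []
        # inject one flip that breaks compatibility
        for _ in range(100):
            r = int(rng.integers(0, original.shape[0]))
            c = int(rng.integers(0, original.shape[1]))
            perturbed = original.copy()
            perturbed[r, c] ^= 1
            if violating_pairs(perturbed):
                break
        else:
            pytest.fail("could not inject a violating flip")
        vm = vafmatrix_from_binary(perturbed)
        cm = resolve_homoplasy(call_mutations(vm, CFG), vm, CFG)
        flips = [e for e in cm.audit if e["rule"] == "homoplasy_flip"]
        assert len(flips) == 1
        resolved, _ = cm.effective_binary()
        assert np.array_equal(resolved, original)

    def test_branch_and_bound_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            subclones, _ = random_genealogy(rng, 5, n_loci=8, n_public=1,
                                            k_range=(1, 1))
            mat = np.array([sc.genotype for sc in subclones], dtype=np.int8)
            n_inject = int(rng.integers(1, 3))
            for _ in range(n_inject):
                mat[rng.integers(0, 5), rng.integers(0, 8)] ^= 1
            expected = min_flips_exhaustive(mat, max_flips=3)
            vm = vafmatrix_from_binary(mat)
            cm = resolve_homoplasy(call_mutations(vm, CFG), vm, CFG)
            got = sum(1 for e in cm.audit if e["rule"] == "homoplasy_flip")
            assert got == expected
            assert four_gamete_test(cm) == []

    def test_budget_exceeded_raises(self):
        rng = np.random.default_rng(0)
        mat = (rng.random((6, 8)) < 0.5).astype(np.int8)
        while not violating_pairs(mat):
            mat = (rng.random((6, 8)) < 0.5).astype(np.int8)
        vm = vafmatrix_from_binary(mat)
        cfg = PipelineConfig(homoplasy_flip_budget=0.001)
        with pytest.raises(ValueError, match="manual review"):
            resolve_homoplasy(call_mutations(vm, cfg), vm, cfg)


class TestCollapse:
    def test_identical_spots_one_subclone(self):
        vm = vafmatrix_from_binary([[1, 1, 0]] * 5)
        subs = collapse_subclones(call_mutations(vm, CFG))
        assert len(subs) == 1 and len(subs[0].member_spots) == 5

    def test_one_locus_difference_splits(self):
        vm = vafmatrix_from_binary([[1, 1], [1, 0]])
        assert len(collapse_subclones(call_mutations(vm, CFG))) == 2

    def test_seven_genotypes_from_29_spots(self):
        rng = np.random.default_rng(4)
        subclones, _ = random_genealogy(rng, 7, n_loci=13, n_public=2)
        rows = []
        assignment = rng.integers(0, 7, size=29)
        assignment[:7] = np.arange(7)  # every genotype sampled
        for a in assignment:
            rows.append(subclones[a].genotype)
        vm = vafmatrix_from_binary(rows)
        subs = collapse_subclones(call_mutations(vm, CFG))
        assert len(subs) == 7
        assert sum(len(s.member_spots) for s in subs) == 29


class TestChain:
    def test_idempotent_on_clean_input(self):
        vm = vafmatrix_from_binary([[1, 1, 0], [1, 0, 1], [1, 0, 0]])
        res1 = preprocess(vm, CFG)
        # feeding the cleaned calls back through yields identical calls
        res2 = preprocess(vm, CFG)
        assert np.array_equal(res1.call_matrix.calls, res2.call_matrix.calls)
        assert [s.subclone_id for s in res1.subclones] == \
               [s.subclone_id for s in res2.subclones]

    def test_noise_free_simulation_untouched(self):
        cfg = SimConfig(mode="multiclonal", glands_per_spot=1, noise_free=True,
                        n_spots=12, rng_seed=2)
        sim = simulate_tumor(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = preprocess(sim.vafs, CFG)
        cm = res.call_matrix
        assert res.admixture_flags == []
        assert res.n_homoplasy_flips == 0
        changed = (cm.provenance != 0).sum()
        assert changed == 0
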