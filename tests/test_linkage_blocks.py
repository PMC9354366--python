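"""Block partitioning: perfect-linkage cores, singleton assignment, composition."""

from fractions import Fraction

import numpy as np
import pytest

from ncohap.archaic_snps import ArchaicSNP, HaplotypeMatrix
from ncohap.linkage_blocks import (assign_singletons, block_summary,
                                   build_core_haplotypes,
                                   haplotype_composition,
                                   pairwise_linkage_window, partition_blocks,
                                   summarize_counts)


def make_matrix(columns, positions, chrom="chr1"):
    """HaplotypeMatrix from a list of 0/1 columns and 1-based positions."""
    mat = np.stack([np.asarray(c, dtype=np.int8) for c in columns], axis=1)
    n = mat.shape[0]
    snps = [ArchaicSNP(chrom, int(p), "A", "G",
                       Fraction(int(mat[:, j].sum()), n))
            for j, p in enumerate(positions)]
    return HaplotypeMatrix(snps=snps, matrix=mat)


C1 = [1, 1, 0, 0, 0, 0]
C2 = [1, 1, 1, 0, 0, 0]


class TestPairwiseWindow:
    def test_window_boundary_inclusive(self):
        m = make_matrix([C1, C1], [1, 200_001])
        assert len(pairwise_linkage_window(m, 200_000)) == 1

    def test_beyond_window_excluded(self):
        m = make_matrix([C1, C1], [1, 200_002])
        assert len(pairwise_linkage_window(m, 200_000)) == 0

    def test_complete_graph_in_1kb(self):
        m = make_matrix([C1] * 5, [100, 300, 500, 700, 900])
        assert len(pairwise_linkage_window(m)) == 10


class TestBuildCores:
    def test_identical_columns_form_core_leftover_stays(self):
        m = make_matrix([C1, C1, C1, C2], [100, 200, 300, 400])
        cores, leftover = build_core_haplotypes(m)
        assert len(cores) == 1 and cores[0].n_members == 3
        assert leftover == [3]
        assert cores[0].f_hap == Fraction(2, 6)

    def test_complementary_columns_never_merge(self):
        """r = −1 (complementary) columns are separate cores, not one."""
        comp = [1 - x for x in C1]
        m = make_matrix([C1, comp], [100, 200])
        cores, _ = build_core_haplotypes(m, min_core_size=1)
        assert len(cores) == 2
        assert all(c.n_members == 1 for c in cores)

    def test_large_block_topology(self):
        """28 identical columns plus 10 partially linked ones: one 28-SNP core
        and 10 singleton candidates."""
        rng = np.random.default_rng(5)
        base = (rng.random(40) < 0.5).astype(np.int8)
        cols = [base] * 28
        for _ in range(10):
            noisy = base.copy()
            flips = rng.choice(40, size=3, replace=False)
            noisy[flips] = 1 - noisy[flips]
            cols.append(noisy)
        m = make_matrix(cols, list(range(1000, 1000 + 38 * 250, 250)))
        cores, leftover = build_core_haplotypes(m)
        assert len(cores) >= 1
        assert cores[0].n_members == 28
        assert len(leftover) == 10

    def test_window_splits_identical_columns(self):
        m = make_matrix([C1, C1, C1, C1], [1, 100, 300_000, 300_100])
        cores, _ = build_core_haplotypes(m, window_bp=200_000)
        assert len(cores) == 2
        assert [c.n_members for c in cores] == [2, 2]

    def test_pair_stats_route_agrees(self):
        m = make_matrix([C1, C1, C2, [0, 1, 0, 1, 0, 0]],
                        [100, 200, 300, 400])
        stats = pairwise_linkage_window(m)
        cores_a, left_a = build_core_haplotypes(m, pair_stats=stats)
        cores_b, left_b = build_core_haplotypes(m)
        assert [c.member_indices for c in cores_a] == \
            [c.member_indices for c in cores_b]
        assert left_a == left_b

    def test_monomorphic_excluded(self):
        m = make_matrix([C1, C1, [1] * 6], [100, 200, 300])
        cores, leftover = build_core_haplotypes(m)
        assert len(cores) == 1 and leftover == []


class TestAssignSingletons:
    def test_argmax_r2(self):
        core_a = [1, 1, 1, 1, 0, 0, 0, 0]
        core_b = [1, 1, 0, 0, 1, 1, 0, 0]
        single = [1, 1, 1, 0, 0, 0, 0, 0]  # closer to A
        m = make_matrix([core_a, core_a, core_b, core_b, single],
                        [100, 200, 300, 400, 500])
        cores, leftover = build_core_haplotypes(m)
        assignments, omitted = assign_singletons(m, cores, leftover)
        (a,) = assignments
        assert omitted == []
        ra = cores[a.block_id]
        assert ra.member_indices == [0, 1]
        assert a.ld.r2 < 1

    def test_no_core_within_window_omitted(self):
        m = make_matrix([C1, C1, C2], [100, 200, 500_000])
        cores, leftover = build_core_haplotypes(m)
        _, omitted = assign_singletons(m, cores, leftover)
        assert omitted == [2]

    def test_tie_breaks_by_distance_then_block_id(self):
        core_a = [1, 1, 1, 1, 0, 0, 0, 0]
        # same column for both cores → equal r² against any singleton
        m = make_matrix([core_a, core_a, core_a, core_a,
                         [1, 1, 1, 0, 0, 0, 0, 0]],
                        [100, 200, 300_500, 300_600, 150_000])
        cores, leftover = build_core_haplotypes(m)
        assert len(cores) == 2
        assignments, _ = assign_singletons(m, cores, leftover)
        (a,) = assignments
        # distances: to span (100,200) = 149800; to span (300500,300600) = 150500
        assert a.block_id == cores[0].block_id
        assert a.distance_bp == 149_800


class TestSummary:
    def test_means_from_two_blocks(self):
        cols = [[1, 1, 0, 0]] * 3 + [[1, 0, 1, 0]] + [[0, 1, 1, 0]] * 5 \
            + [[0, 1, 0, 0], [0, 0, 1, 0], [1, 1, 1, 0]]
        pos = [100, 200, 300, 400] + [10_000, 10_100, 10_200, 10_300, 10_400,
                                      10_500, 10_600, 10_700]
        m = make_matrix(cols, pos)
        blocks, omitted = partition_blocks(m)
        s = block_summary(blocks, len(omitted))
        assert s["n_blocks"] == 2
        assert s["mean_block_snps_per_block"] == 4.0
        assert s["mean_singletons_per_block"] == 2.0
        assert s["mean_total_snps_per_block"] == 6.0

    def test_summarize_counts_arithmetic(self):
        s = summarize_counts(2, 8, 4)
        assert s["mean_block_snps_per_block"] == 4.0
        assert s["mean_singletons_per_block"] == 2.0
        assert s["singleton_percent"] == pytest.approx(100 * 4 / 12)


class TestComposition:
    def test_counts_and_binning(self):
        cols = [
            [1, 1, 0, 0, 0, 1],
            [1, 1, 0, 0, 0, 0],
            [1, 1, 0, 0, 0, 0],
        ]
        m = make_matrix(cols, [100, 200, 300])
        blocks, _ = partition_blocks(m)
        comp = haplotype_composition(m, blocks[0])
        assert comp.n_intact_derived == 2
        assert comp.n_intact_ancestral == 3
        assert sum(comp.mixed_bins) == 1
        assert comp.mixed_bins[3] == 1  # fraction 1/3 → bin (0.3, 0.4]
        assert comp.total == 6

    def test_exact_tenth_falls_in_lower_bin(self):
        # 10 SNPs, one haplotype with exactly 1 derived → fraction 0.1 → bin 0
        cols = []
        base = [1, 1, 0, 0]
        for _ in range(10):
            cols.append(base)
        mat = np.asarray(cols, dtype=np.int8).T.copy()
        mat[2, :] = 0
        mat[2, 0] = 1  # haplotype 2 carries 1 of 10 derived alleles
        m = make_matrix(list(mat.T), list(range(100, 1100, 100)))
        blocks, _ = partition_blocks(m)
        comp = haplotype_composition(m, blocks[0])
        assert comp.mixed_bins[0] == 1
        assert comp.total == 4

    def test_conservation_on_simulation(self, small_sim):
        from ncohap.model import ArchaicNCOModel
        res = ArchaicNCOModel.from_simulation(small_sim).fit()
        n_hap = small_sim.haplotypes.n_haplotypes
        for b in res.blocks[:20]:
            assert res.composition(b.block_id).total == n_hap


class TestPartitionInvariants:
    def test_roles_partition_all_sites(self, small_sim):
        from ncohap.model import ArchaicNCOModel
        res = ArchaicNCOModel.from_simulation(small_sim).fit()
        roles = [s.role for s in small_sim.haplotypes.snps]
        s = res.block_summary
        assert roles.count("block") == s["n_block_snps"]
        assert roles.count("singleton") == s["n_singletons"]
        assert roles.count("omitted") == s["n_omitted"]
        n_poly = sum(1 for x in small_sim.haplotypes.snps if x.is_polymorphic)
        assert s["n_block_snps"] + s["n_singletons"] + s["n_omitted"] == n_poly

    def test_order_invariance(self, rng):
        """The partition is independent of input SNP (column) ordering."""
        cols = []
        n = 30
        base1 = (rng.random(n) < 0.5).astype(np.int8)
        base2 = (rng.random(n) < 0.5).astype(np.int8)
        for _ in range(4):
            cols.append(base1.copy())
        for _ in range(3):
            cols.append(base2.copy())
        for _ in range(5):
            noisy = base1.copy()
            f = rng.choice(n, size=2, replace=False)
            noisy[f] = 1 - noisy[f]
            cols.append(noisy)
        pos = sorted(rng.choice(50_000, size=len(cols), replace=False) + 1)

        def fingerprint(order):
            m = make_matrix([cols[i] for i in order],
                            [pos[i] for i in order])
            blocks, omitted = partition_blocks(m)
            cores = frozenset(
                frozenset(m.snps[j].pos for j in b.core.member_indices)
                for b in blocks)
            singles = frozenset(
                (m.snps[a.snp_index].pos,
                 frozenset(m.snps[j].pos
                           for j in blocks[a.block_id].core.member_indices),
                 a.ld.r2)
                for b in blocks for a in b.singletons)
            return cores, singles, frozenset(m.snps[j].pos for j in omitted)

        identity = fingerprint(list(range(len(cols))))
        shuffled = list(rng.permutation(len(cols)))
        assert fingerprint(shuffled) == identity
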