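"""Pairwise r2/D', the EM haplotype-frequency estimator, D' confidence
intervals and Gabriel block calling."""

import numpy as np
import pandas as pd
import pytest

from igqtl import ld as L


class TestGenotypeR2:
    def test_identical_vectors(self):
        a = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        assert L.genotype_r2(a, a) == pytest.approx(1.0)

    def test_complement_sign_invariance(self):
        a = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        assert L.genotype_r2(a, 2 - a) == pytest.approx(1.0)

    def test_hand_computed_pearson_squared(self):
        a = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        b = np.array([0, 1, 0, 1, 2, 2], dtype=float)
        # direct covariance formula oracle
        cov = np.mean(a * b) - a.mean() * b.mean()
        expect = cov**2 / (a.var() * b.var())
        assert L.genotype_r2(a, b) == pytest.approx(expect, rel=1e-12)

    def test_constant_vector_undefined(self):
        assert np.isnan(L.genotype_r2(np.ones(6), np.arange(6.0)))

    def test_symmetry_and_individual_order_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, 50).astype(float)
        b = rng.integers(0, 3, 50).astype(float)
        assert L.genotype_r2(a, b) == pytest.approx(L.genotype_r2(b, a))
        perm = rng.permutation(50)
        assert L.genotype_r2(a[perm], b[perm]) == pytest.approx(L.genotype_r2(a, b))


class TestHaplotypeFrequencies:
    def test_phased_counting(self):
        hA = np.array([1] * 50 + [0] * 50)
        hB = np.array([1] * 50 + [0] * 50)
        counts = L.haplotype_counts_phased(hA, hB)
        assert counts[1, 1] == 50 and counts[0, 0] == 50
        assert counts[0, 1] == 0 and counts[1, 0] == 0

    def test_em_equals_counting_without_double_hets(self):
        # genotype pairs with no (1,1) cell: phase is unambiguous
        dA = np.array([0, 0, 2, 2, 1, 1, 0, 2], dtype=float)
        dB = np.array([0, 2, 0, 2, 0, 2, 1, 1], dtype=float)
        f, conv = L.em_haplotype_frequencies(dA, dB)
        assert conv
        # direct haplotype counting oracle
        expect = np.zeros((2, 2))
        for a, b in zip(dA.astype(int), dB.astype(int)):
            ca = [0, 0] if a == 0 else [1, 1] if a == 2 else [0, 1]
            cb = [0, 0] if b == 0 else [1, 1] if b == 2 else [0, 1]
            if a == 1 or b == 1:
                expect[ca[0], cb[0]] += 1
                expect[ca[1], cb[1]] += 1
            else:
                expect[ca[0], cb[0]] += 2
        expect /= expect.sum()
        assert np.allclose(f, expect)

    def test_em_near_quarter_for_independent_loci(self):
        rng = np.random.default_rng(1)
        hA = rng.integers(0, 2, 6000)
        hB = rng.integers(0, 2, 6000)
        f, conv = L.em_haplotype_frequencies(hA[0::2] + hA[1::2], hB[0::2] + hB[1::2])
        assert conv
        assert np.allclose(f, 0.25, atol=0.03)


class TestDprimeCI:
    def test_perfect_ld_tight_interval(self):
        counts = np.array([[400, 0], [0, 400]])
        dp, lo, hi = L.dprime_ci_phased(counts)
        assert dp == pytest.approx(1.0)
        assert lo > 0.98
        assert hi == pytest.approx(1.0)

    def test_independent_loci_low_upper_bound(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(10):
            hA = rng.integers(0, 2, 400)
            hB = rng.integers(0, 2, 400)
            _, _, hi = L.dprime_ci_phased(L.haplotype_counts_phased(hA, hB))
            hits += hi < 0.9
        assert hits >= 9

    def test_allele_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        hA = rng.integers(0, 2, 300)
        hB = (hA ^ (rng.random(300) < 0.1)).astype(int)
        c = L.haplotype_counts_phased(hA, hB)
        dp1, lo1, hi1 = L.dprime_ci_phased(c)
        dp2, lo2, hi2 = L.dprime_ci_phased(c[::-1, :])  # swap labels at locus A
        assert dp1 == pytest.approx(dp2)
        assert (lo1, hi1) == pytest.approx((lo2, hi2))

    def test_monomorphic_uninformative(self):
        dp, lo, hi = L.dprime_ci_phased(np.array([[100, 0], [0, 0]]))
        assert np.isnan(dp)
        assert L.classify_pair(lo, hi) == "uninformative"

    def test_unphased_agrees_with_phased_at_high_ld(self):
        rng = np.random.default_rng(4)
        hA = rng.integers(0, 2, 600)
        flip = rng.random(600) < 0.05
        hB = (hA ^ flip).astype(int)
        dp_p, _, _ = L.dprime_ci_phased(L.haplotype_counts_phased(hA, hB))
        dA = hA[0::2] + hA[1::2]
        dB = hB[0::2] + hB[1::2]
        dp_u, _, _ = L.dprime_ci_unphased(dA.astype(float), dB.astype(float))
        assert dp_u == pytest.approx(abs(dp_p), abs=0.05)


def _random_instance(rng, m):
    """Random symmetric classification matrix and sorted positions."""
    cls = np.zeros((m, m), dtype=np.int8)
    for i in range(m):
        for j in range(i + 1, m):
            cls[i, j] = cls[j, i] = rng.choice([1, -1, 0], p=[0.5, 0.35, 0.15])
    pos = np.sort(rng.choice(np.arange(100, 10_000), size=m, replace=False))
    return pos, cls


def _bruteforce_blocks(positions, cls, min_frac=0.95):
    """Independent oracle: explicit per-pair loops, then greedy by span."""
    m = len(positions)
    cands = []
    for i in range(m - 1):
        for j in range(i + 1, m):
            n_str = n_inf = 0
            for a in range(i, j + 1):
                for b in range(a + 1, j + 1):
                    if cls[a, b] == 1:
                        n_str += 1
                        n_inf += 1
                    elif cls[a, b] == -1:
                        n_inf += 1
            if n_inf > 0 and n_str >= 1 and n_str / n_inf >= min_frac:
                cands.append((int(positions[j] - positions[i] + 1), i, j))
    chosen = []
    used = set()
    for span, i, j in sorted(cands, key=lambda t: (-t[0], t[1])):
        if any(k in used for k in range(i, j + 1)):
            continue
        used.update(range(i, j + 1))
        chosen.append((i, j))
    return sorted(chosen)


class TestGabrielBlocks:
    def test_all_recombination_no_blocks(self):
        m = 6
        cls = -np.ones((m, m), dtype=np.int8)
        np.fill_diagonal(cls, 0)
        assert L.gabriel_blocks(np.arange(m) * 100, cls) == []

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            m = int(rng.integers(2, 13))
            pos, cls = _random_instance(rng, m)
            blocks = L.gabriel_blocks(pos, cls)
            got = sorted((b.member_indices[0], b.member_indices[-1]) for b in blocks)
            assert got == _bruteforce_blocks(pos, cls)

    def test_two_founder_block_recovered(self):
        from igqtl.evaluation import block_recovery

        assert block_recovery(123)

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        pos, cls = _random_instance(rng, 10)
        b1 = L.gabriel_blocks(pos, cls)
        b2 = L.gabriel_blocks(pos, cls)
        assert [(b.start, b.end) for b in b1] == [(b.start, b.end) for b in b2]


class TestBlockSummaries:
    def test_gene_overlap_half_open_semantics(self):
        genes = pd.DataFrame(
            [{"gene": "A", "start": 100, "end": 200},
             {"gene": "B", "start": 100, "end": 200},
             {"gene": "C", "start": 250, "end": 260}]
        )
        blocks = [(150, 300), (200, 230)]
        out = L.block_gene_overlap(blocks, genes)
        by_gene = out.set_index("gene")
        assert by_gene.loc["A", "assigned"]
        assert 0 in by_gene.loc["A", "blocks"]
        # gene [100,200) does not touch block [200,230): half-open boundary
        assert 1 not in by_gene.loc["B", "blocks"]
        assert by_gene.loc["C", "blocks"] == [0]

    def test_size_composition_arithmetic(self):
        blocks = [L.LDBlock(1, 20_000, [0, 1], ["a", "b"])]
        comp = L.block_size_composition(blocks, locus_span=100_000, bins=[1_000, 20_000])
        assert comp["(1000, 20000]"] == pytest.approx(0.2)
        assert sum(comp.values()) <= 1.0

    def test_no_blocks_all_zero(self):
        comp = L.block_size_composition([], locus_span=100_000, bins=[1_000])
        assert all(v == 0 for v in comp.values())
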