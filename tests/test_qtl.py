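"""MAF filtering, perfect-LD collapsing, regression, fold changes,
region annotation and interval enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from igqtl import qtl as Q
from igqtl.containers import GenotypeMatrix, UsageMatrix


def _gm(dosage, positions=None, kinds=None):
    dosage = np.asarray(dosage, dtype=float)
    m, n = dosage.shape
    positions = positions if positions is not None else np.arange(1, m + 1) * 100
    variants = pd.DataFrame(
        {
            "id": [f"v{i}" for i in range(m)],
            "contig": "chrT",
            "pos": positions,
            "ref": "A",
            "alt": "G",
            "kind": kinds or ["SNV"] * m,
        }
    )
    return GenotypeMatrix(variants, [f"S{i}" for i in range(n)], dosage)


class TestFilterCommon:
    def test_monomorphic_dropped(self):
        gm = _gm([[0] * 10, [0, 1] * 5])
        kept = Q.filter_common(gm)
        assert kept.ids == ["v1"]

    def test_maf_boundary_inclusive(self):
        # p = 0.05 exactly: one het among 10 individuals
        row = [1] + [0] * 9
        gm = _gm([row])
        assert Q.filter_common(gm, maf_min=0.05).n_variants == 1
        assert Q.filter_common(gm, maf_min=0.051).n_variants == 0

    def test_three_hets_of_ten_retained(self):
        gm = _gm([[1, 1, 1] + [0] * 7])
        kept = Q.filter_common(gm)
        assert kept.n_variants == 1
        assert kept.maf()[0] == pytest.approx(0.15)

    def test_high_missingness_dropped(self):
        row = [1.0, 0, 1, np.nan, np.nan] + [0] * 5
        gm = _gm([row])
        assert Q.filter_common(gm, max_missing=0.10).n_variants == 0


class TestCollapsePerfectLD:
    def test_duplicate_and_complement_collapse(self):
        a = np.array([0, 1, 2, 1, 0, 2, 1, 0], dtype=float)
        gm = _gm([a, a.copy(), 2 - a, [0, 0, 1, 1, 0, 2, 2, 1]])
        classes = Q.collapse_perfect_ld(gm)
        assert len(classes) == 2
        big = next(c for c in classes if len(c.member_ids) == 3)
        assert set(big.member_ids) == {"v0", "v1", "v2"}
        assert big.rep_id == "v0"  # lowest position

    def test_recovers_planted_classes_against_bruteforce(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, size=(3, 40)).astype(float)
        rows = [base[i % 3] if i % 2 == 0 else 2 - base[i % 3] for i in range(10)]
        gm = _gm(rows)
        classes = Q.collapse_perfect_ld(gm)
        # brute-force oracle: pairwise r2 == 1 partition by union-find
        m = len(rows)
        parent = list(range(m))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for i in range(m):
            for j in range(i + 1, m):
                r = np.corrcoef(rows[i], rows[j])[0, 1]
                if abs(r * r - 1) < 1e-12:
                    parent[find(j)] = find(i)
        oracle = len({find(i) for i in range(m)})
        assert len(classes) == oracle == 3

    def test_partition_property_and_order_invariance(self):
        rng = np.random.default_rng(1)
        D = rng.integers(0, 3, size=(12, 30)).astype(float)
        D[5] = D[0]
        D[7] = 2 - D[3]
        gm = _gm(D)
        classes = Q.collapse_perfect_ld(gm)
        all_members = [v for c in classes for v in c.member_ids]
        assert sorted(all_members) == sorted(gm.ids)  # true partition
        perm = rng.permutation(12)
        gm2 = gm.subset(perm)
        classes2 = Q.collapse_perfect_ld(gm2)
        sets1 = {frozenset(c.member_ids) for c in classes}
        sets2 = {frozenset(c.member_ids) for c in classes2}
        assert sets1 == sets2

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            Q.collapse_perfect_ld(_gm([[1.0] * 6, [0, 1] * 3]))


class TestRegress:
    def test_perfect_fit(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 3, 20).astype(float)
        res = Q.regress(2 * x, x)
        assert res.beta == pytest.approx(2.0)
        assert res.adjusted_r2 == pytest.approx(1.0)
        assert res.p_value < 1e-10

    def test_shift_invariance_of_slope(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 3, 30).astype(float)
        y = 0.3 * x + rng.normal(size=30)
        r1 = Q.regress(y, x)
        r2 = Q.regress(y + 100.0, x)
        assert r1.beta == pytest.approx(r2.beta)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_matches_scipy_linregress(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            x = rng.integers(0, 3, 25).astype(float)
            if np.ptp(x) == 0:
                continue
            y = rng.normal(size=25)
            mine = Q.regress(y, x)
            ref = stats.linregress(x, y)
            assert mine.beta == pytest.approx(ref.slope, rel=1e-10)
            assert mine.se == pytest.approx(ref.stderr, rel=1e-10)
            assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-8)

    def test_constant_dosage_flagged_not_raised(self):
        res = Q.regress(np.arange(5.0), np.ones(5))
        assert not res.testable
        assert np.isnan(res.p_value)

    def test_pvalues_match_permutation_null_small_n(self):
        rng = np.random.default_rng(5)
        x = np.array([0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 1, 0], dtype=float)
        y = rng.normal(size=12)
        obs = Q.regress(y, x)
        n_perm = 4000
        betas = np.empty(n_perm)
        for k in range(n_perm):
            betas[k] = Q.regress(rng.permutation(y), x).beta
        p_perm = np.mean(np.abs(betas) >= abs(obs.beta) - 1e-12)
        assert obs.p_value == pytest.approx(p_perm, abs=0.05)


class TestMapGuqtls:
    def _usage(self, freq):
        df = pd.DataFrame(freq)
        return UsageMatrix(df, (df * 100).round(), "unmutated")

    def test_lead_tie_broken_by_position(self):
        rng = np.random.default_rng(6)
        x = rng.integers(0, 3, 40).astype(float)
        while np.ptp(x) == 0:
            x = rng.integers(0, 3, 40).astype(float)
        gm = _gm([x, x.copy() + 0.0], positions=[500, 100])
        gm.dosage[1] = 2 - gm.dosage[0]  # same class? no -- separate rows
        # make two distinct but equally-associated variants: y = x exactly
        gm = _gm([x, 2 - x], positions=[500, 100])
        samples = gm.samples
        um = self._usage({s: {"G": x[i] * 0.1} for i, s in enumerate(samples)})
        classes = Q.collapse_perfect_ld(gm)
        assert len(classes) == 1  # complement is the same class
        res = Q.map_guqtls(um, gm, classes)
        assert res[res["lead"]].iloc[0]["position"] == 100  # lowest position rep

    def test_sample_order_invariance_and_allele_flip(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 3, 50).astype(float)
        y = 0.05 * x + rng.normal(scale=0.02, size=50)
        gm = _gm([x])
        um = self._usage({s: {"G": y[i]} for i, s in enumerate(gm.samples)})
        classes = Q.collapse_perfect_ld(gm)
        r1 = Q.map_guqtls(um, gm, classes)
        perm = rng.permutation(50)
        gm2 = GenotypeMatrix(gm.variants, [gm.samples[i] for i in perm], gm.dosage[:, perm])
        r2 = Q.map_guqtls(um, gm2, Q.collapse_perfect_ld(gm2))
        assert r1.iloc[0]["p_value"] == pytest.approx(r2.iloc[0]["p_value"])
        assert r1.iloc[0]["beta"] == pytest.approx(r2.iloc[0]["beta"])
        gm3 = GenotypeMatrix(gm.variants, gm.samples, 2 - gm.dosage)
        r3 = Q.map_guqtls(um, gm3, Q.collapse_perfect_ld(gm3))
        assert r3.iloc[0]["beta"] == pytest.approx(-r1.iloc[0]["beta"])
        assert r3.iloc[0]["p_value"] == pytest.approx(r1.iloc[0]["p_value"])
        assert r3.iloc[0]["adjusted_r2"] == pytest.approx(r1.iloc[0]["adjusted_r2"])

    def test_sv_dosage_monotone_usage_means(self, small_cohort):
        # deletion SV: mean usage of the deleted gene rises with copy number
        from igqtl.evaluation import analyse

        ana = analyse(small_cohort)
        sv_rows = ana.guqtl[(ana.guqtl["gene"] == "V30")
                            & (ana.guqtl["class_rep"] == "sv1")]
        if len(sv_rows) == 1:
            r = sv_rows.iloc[0]
            m0, m1, m2 = r["mean_dosage0"], r["mean_dosage1"], r["mean_dosage2"]
            observed = [m for m in (m0, m1, m2) if np.isfinite(m)]
            assert observed == sorted(observed)


class TestFoldChange:
    def test_basic_ratio(self):
        y = np.array([0.04] * 5 + [0.01] * 5)
        d = np.array([2] * 5 + [0] * 5, dtype=float)
        fc, flag = Q.fold_change(y, d)
        assert fc == pytest.approx(4.0) and flag == "ok"

    def test_equal_means_give_one(self):
        y = np.array([0.02] * 6)
        d = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        assert Q.fold_change(y, d) == (1.0, "ok")

    def test_zero_group_mean_gives_inf_sentinel(self):
        y = np.array([0.0, 0.0, 0.05, 0.04])
        d = np.array([0, 0, 2, 2], dtype=float)
        fc, flag = Q.fold_change(y, d)
        assert np.isinf(fc) and flag == "max"

    def test_empty_homozygote_group_undefined(self):
        y = np.array([0.02, 0.03, 0.04])
        d = np.array([0, 1, 1], dtype=float)
        fc, flag = Q.fold_change(y, d)
        assert np.isnan(fc) and flag == "undefined"


class TestAnnotation:
    def _features(self, tmp_path, lines):
        p = tmp_path / "f.bed"
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_coordinate_conversion_and_priority(self, tmp_path):
        bed = self._features(tmp_path, [
            "chrT\t100\t102\tintron",
            "chrT\t100\t102\tRSS-spacer",
            "chrT\t300\t400\tV-exon",
        ])
        feats = Q.read_bed(bed)
        variants = pd.DataFrame(
            {"id": ["a", "b", "c"], "contig": "chrT", "pos": [101, 350, 999]}
        )
        labels = Q.annotate_variants(variants, feats)
        assert list(labels) == ["RSS-spacer", "V-exon", "intergenic"]

    def test_malformed_bed_reports_line_number(self, tmp_path):
        p = self._features(tmp_path, ["chrT\t100\t102\tok", "chrT\tx\ty\tbad"])
        with pytest.raises(ValueError, match=":2:"):
            Q.read_bed(p)


class TestEnrichment:
    def test_identical_sets_null(self):
        bg = {f"v{i}" for i in range(20)}
        res = Q.interval_enrichment(bg, bg, {f"v{i}" for i in range(5)})
        assert res.odds_ratio == 1.0
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hypergeometric_tail(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n_bg = int(rng.integers(20, 200))
            bg = {f"v{i}" for i in range(n_bg)}
            qset = set(rng.choice(sorted(bg), size=rng.integers(2, n_bg // 2), replace=False))
            inset = set(rng.choice(sorted(bg), size=rng.integers(1, n_bg // 2), replace=False))
            res = Q.interval_enrichment(qset, bg, inset)
            a = len(qset & inset)
            # one-sided tail of the hypergeometric sampling distribution
            expect = stats.hypergeom.sf(a - 1, n_bg, len(inset), len(qset))
            assert res.p_value == pytest.approx(expect, rel=1e-9)

    def test_requires_subset(self):
        with pytest.raises(ValueError, match="subset"):
            Q.interval_enrichment({"x"}, {"y"}, set())
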