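"""Generator invariants: founder-block LD, MAF floor, determinism, the
additive usage model, and copy-number/junction bookkeeping."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from igqtl import usage as usage_mod
from igqtl.simulate import (
    AlleleSpec,
    BlockSpec,
    EffectSpec,
    GeneSpec,
    SimConfig,
    SVSpec,
    build_truth,
    emit_genotypes,
    simulate_cohort,
    simulate_haplotypes,
    simulate_repertoire,
    build_germline_sets,
    validate_config,
)
from conftest import small_config


def _mini_genes(n_v=3, n_j=2):
    genes = [
        GeneSpec(f"V{i}", 1000 * (i + 1), "V",
                 [AlleleSpec("01", "ATGGCTAAA", "CAAAW"),
                  AlleleSpec("02", "ATGGCGAAA", "CTTTW")], [0.6, 0.4])
        for i in range(n_v)
    ]
    genes += [
        GeneSpec(f"J{i}", 50_000 + 100 * i, "J",
                 [AlleleSpec("01", "TTTGGC", "LF")], [1.0])
        for i in range(n_j)
    ]
    return genes


def _mini_config(**overrides):
    base = dict(
        n_individuals=4,
        locus_span=60_000,
        blocks=[BlockSpec(100, 5_000, 6, 2)],
        genes=_mini_genes(),
        seed=5,
    )
    base.update(overrides)
    return SimConfig(**base)


class TestHaplotypes:
    def test_two_founder_block_gives_perfect_intrablock_ld(self):
        panel = simulate_haplotypes(_mini_config())
        gm, _ = emit_genotypes(panel, _mini_config())
        corr = np.corrcoef(gm.dosage[gm.variants["kind"] == "SNV"])
        assert np.allclose(corr**2, 1.0)

    def test_cross_block_dprime_is_near_zero(self):
        # Monte-Carlo over seeds: founders independent across blocks
        from igqtl import ld

        frac_low = []
        for seed in range(3):
            cfg = _mini_config(
                n_individuals=200,
                blocks=[BlockSpec(100, 5_000, 5, 8), BlockSpec(10_000, 15_000, 5, 8)],
                seed=seed,
            )
            panel = simulate_haplotypes(cfg)
            n_low = n_tot = 0
            for i in range(5):
                for j in range(5, 10):
                    counts = ld.haplotype_counts_phased(panel.hap[i], panel.hap[j])
                    dp = ld.dprime_ci_phased(counts)[0]
                    n_tot += 1
                    n_low += abs(dp) < 0.2
            frac_low.append(n_low / n_tot)
        assert np.mean(frac_low) > 0.9

    def test_determinism_same_seed_identical_outputs(self):
        cfg = small_config(42)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert np.array_equal(a.panel.hap, b.panel.hap)
        assert np.array_equal(a.genotypes.dosage, b.genotypes.dosage)
        pd.testing.assert_frame_equal(a.records, b.records)
        assert a.germline.to_dict() == b.germline.to_dict()
        assert a.truth.to_dict() == b.truth.to_dict()

    def test_maf_floor_enforced(self):
        cfg = _mini_config(n_individuals=60,
                           blocks=[BlockSpec(100, 5_000, 30, 4)], maf_floor=0.10)
        panel = simulate_haplotypes(cfg)
        freqs = panel.hap.mean(axis=1)
        assert np.all(np.minimum(freqs, 1 - freqs) >= 0.10)

    def test_impossible_maf_floor_raises(self):
        cfg = _mini_config(n_individuals=2, maf_floor=0.45)
        with pytest.raises(RuntimeError, match="MAF floor"):
            simulate_haplotypes(cfg)


class TestGenotypes:
    def test_dosage_is_haplotype_sum(self):
        cfg = _mini_config()
        panel = simulate_haplotypes(cfg)
        gm, _ = emit_genotypes(panel, cfg)
        snv = gm.dosage[: len(panel.variants)]
        assert np.array_equal(snv, panel.hap[:, 0::2] + panel.hap[:, 1::2])

    def test_vcf_round_trip_equals_matrix(self, tmp_path):
        from igqtl import io

        cfg = _mini_config(svs=[SVSpec("sv1", 30_000, ["V2"], 0.4)])
        panel = simulate_haplotypes(cfg)
        gm, _ = emit_genotypes(panel, cfg)
        path = tmp_path / "x.vcf"
        io.write_vcf(gm, path, contig_length=cfg.locus_span)
        back = io.read_vcf(path)
        assert back.samples == gm.samples
        assert np.array_equal(back.dosage, gm.dosage)
        assert np.array_equal(back.haplotypes, gm.haplotypes)
        assert list(back.variants["kind"]) == list(
            gm.variants.sort_values("pos", kind="stable")["kind"])

    def test_sv_homozygous_deletion_removes_gene(self):
        cfg = _mini_config(n_individuals=40, svs=[SVSpec("sv1", 30_000, ["V2"], 0.5)])
        panel = simulate_haplotypes(cfg)
        gm, sv_del = emit_genotypes(panel, cfg)
        germ = build_germline_sets(panel, cfg, sv_del)
        sv_row = gm.dosage[gm.variants.index[gm.variants["id"] == "sv1"][0]]
        for s_idx, s in enumerate(gm.samples):
            cn = germ.copy_number(s, "V2")
            assert cn == sv_row[s_idx]
        zero_cn = [s for i, s in enumerate(gm.samples) if sv_row[i] == 0]
        if zero_cn:
            records = simulate_repertoire(gm, germ, cfg)
            used = records[records["sample_id"].isin(zero_cn)]
            genes = usage_mod.genes_of(used["v_call"])
            assert "V2" not in set(genes)


class TestRepertoire:
    def test_planted_effect_gives_expected_usage_ratio(self):
        # per-copy effect log 2 on V0: dosage 2 vs 0 means a 4x weight
        # ratio; with 3 equal-baseline V genes the expected usage ratio
        # after renormalisation is 4/(1 + 4/3 - 1/3) = 2 at 1e5 records
        cfg = _mini_config(
            n_individuals=30,
            repertoire_size=100_000,
            mutated_fraction=0.0,
            usage_noise_sd=0.0,  # isolate the deterministic weight model
            effects=[EffectSpec("b0v3", "V0", float(np.log(2.0)))],
            seed=3,
        )
        panel = simulate_haplotypes(cfg)
        gm, sv_del = emit_genotypes(panel, cfg)
        germ = build_germline_sets(panel, cfg, sv_del)
        records = simulate_repertoire(gm, germ, cfg)
        dosage = gm.row("b0v3")
        genes = usage_mod.genes_of(records["v_call"])
        usage_v0 = (
            records.assign(g=genes.to_numpy())
            .groupby("sample_id", observed=True)["g"]
            .apply(lambda s: (s == "V0").mean())
        )
        groups = {
            d: usage_v0[[s for i, s in enumerate(gm.samples) if dosage[i] == d]].mean()
            for d in (0, 2)
            if any(dosage == d)
        }
        assert set(groups) == {0, 2}
        expected = 4.0 / (1.0 + (4.0 - 1.0) / 3.0)
        assert groups[2] / groups[0] == pytest.approx(expected, rel=0.05)

    def test_zero_mutated_fraction_all_identities_100(self):
        cfg = _mini_config(mutated_fraction=0.0, repertoire_size=200)
        sim = simulate_cohort(cfg)
        assert (sim.records["v_identity"] == 100).all()
        assert (sim.records["j_identity"] == 100).all()

    def test_mutated_records_have_reduced_identity(self):
        cfg = _mini_config(mutated_fraction=1.0, repertoire_size=200)
        sim = simulate_cohort(cfg)
        below = (sim.records["v_identity"] < 100) | (sim.records["j_identity"] < 100)
        assert below.all()

    def test_junction_germline_parts_constant_per_allele_pair(self):
        cfg = _mini_config(repertoire_size=500, insert_len_mean=2.0)
        sim = simulate_cohort(cfg)
        contrib = sim.germline.junction_contrib
        for (v_call, j_call), grp in sim.records.groupby(
            ["v_call", "j_call"], observed=True
        ):
            vg, va = str(v_call).split("*")
            jg, ja = str(j_call).split("*")
            prefix = contrib[vg][va]
            suffix = contrib[jg][ja]
            assert grp["junction_aa"].str.startswith(prefix).all()
            assert grp["junction_aa"].str.endswith(suffix).all()


class TestConfigValidation:
    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            validate_config(_mini_config(
                blocks=[BlockSpec(100, 5_000, 4, 2), BlockSpec(4_000, 9_000, 4, 2)]))

    def test_unknown_effect_target_rejected(self):
        with pytest.raises(ValueError, match="unknown gene"):
            validate_config(_mini_config(
                effects=[EffectSpec("b0v0", "NOPE", 0.5)]))

    def test_single_founder_rejected(self):
        with pytest.raises(ValueError, match="founder"):
            validate_config(_mini_config(blocks=[BlockSpec(100, 5_000, 4, 1)]))

    def test_truth_reflects_config(self):
        cfg = _mini_config(effects=[EffectSpec("b0v1", "V1", 0.7)])
        truth = build_truth(cfg)
        assert truth.causal_variants == {"b0v1": [("V1", 0.7)]}
        assert truth.block_boundaries == [(100, 5_000)]
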