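"""End-to-end pipeline driver.

Stage order: simulate (optional) -> usage -> CDR3 properties -> guQTL
mapping -> LD blocks -> shared-guQTL network -> allele linkage, writing
each stage's outputs under one directory together with a run manifest.
Deterministic given the configuration seed.  A stage failure aborts with
the stage name and the manifest recorded so far.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, ld, linkage, networks, properties, qtl, usage
from .simulate import SimConfig, simulate_cohort


@dataclass
class PipelineParams:
    maf_min: float = 0.05
    alpha: float = 0.05
    min_gene_count: int = 10
    min_sample_seqs: int = 100
    ld_window: int = 50
    partition: str = "unmutated"
    run_ld_blocks: bool = True
    run_properties: bool = True
    bins_bp: tuple = (1_000, 20_000)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    out_dir,
    config: SimConfig | None = None,
    vcf_path=None,
    airr_path=None,
    germline_path=None,
    params: PipelineParams | None = None,
) -> dict:
    """Run the full analysis and write stage outputs under ``out_dir``.

    Either pass a SimConfig (a cohort is simulated and written first) or
    the three input paths (VCF, AIRR TSV, germline JSON).  Returns the
    in-memory stage results keyed by stage name.
    """
    params = params or PipelineParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = io.RunManifest()
    manifest.thresholds = {
        "maf_min": params.maf_min,
        "alpha": params.alpha,
        "min_gene_count": params.min_gene_count,
        "min_sample_seqs": params.min_sample_seqs,
        "gabriel_strong": [ld.STRONG_LOW, ld.STRONG_HIGH],
        "gabriel_recomb_upper": ld.RECOMB_HIGH,
    }
    results: dict = {}

    def stage(name):
        def deco(fn):
            try:
                results[name] = fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                manifest.write(out / "manifest.json")
                raise StageError(name, exc) from exc
            manifest.stages_completed.append(name)
            return results[name]

        return deco

    if config is not None:
        manifest.seed = config.seed
        manifest.config_hash = hashlib.sha256(
            json.dumps(io._plain(dataclasses.asdict(config)), sort_keys=True).encode()
        ).hexdigest()

        @stage("simulate")
        def _sim():
            sim = simulate_cohort(config)
            io.config_to_yaml(config, out / "config.yaml")
            io.write_vcf(sim.genotypes, out / "cohort.vcf", contig_length=config.locus_span)
            io.write_airr(sim.records, out / "repertoire.airr.tsv")
            io.write_germline_json(sim.germline, out / "germline.json")
            io.write_truth_json(sim.truth, out / "truth.json")
            return sim

        sim = results["simulate"]
        genotypes, records, germline = sim.genotypes, sim.records, sim.germline
        pairs = config.paralog_pairs
    else:
        for p, label in ((vcf_path, "VCF"), (airr_path, "AIRR TSV"),
                         (germline_path, "germline JSON")):
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"missing {label} input: {p}")
        manifest.input_checksums = {
            str(p): io.sha256_file(p) for p in (vcf_path, airr_path, germline_path)
        }
        genotypes = io.read_vcf(vcf_path)
        records = io.read_airr(airr_path)
        germline = io.read_germline_json(germline_path)
        pairs = []

    @stage("usage")
    def _usage():
        unmut, mut, n_dropped = usage.partition_by_mutation(records)
        part = unmut if params.partition == "unmutated" else mut
        collapsed = usage.collapse_paralogs(part, pairs, germline)
        mats = {}
        for axis in ("v", "j"):
            um = usage.compute_usage(
                collapsed, axis=axis,
                min_gene_count=params.min_gene_count,
                min_sample_seqs=params.min_sample_seqs,
                partition=params.partition,
            )
            um = usage.mask_paralog_usage(um, pairs, germline)
            um.frequency.to_csv(out / f"usage_{axis}_{params.partition}.tsv", sep="\t")
            with open(out / f"usage_{axis}_{params.partition}.provenance.json", "w") as fh:
                json.dump(io._plain(um.provenance), fh, indent=1)
            mats[axis] = um
        manifest.filter_counts["partition_records_dropped"] = n_dropped
        manifest.filter_counts["unmutated_records"] = len(unmut)
        manifest.filter_counts["mutated_records"] = len(mut)
        return mats

    @stage("genotype_filter")
    def _filter():
        common = qtl.filter_common(genotypes, maf_min=params.maf_min)
        classes = qtl.collapse_perfect_ld(common)
        manifest.filter_counts["variants_total"] = genotypes.n_variants
        manifest.filter_counts["variants_common"] = common.n_variants
        manifest.filter_counts["effective_classes"] = len(classes)
        return {"common": common, "classes": classes}

    common = results["genotype_filter"]["common"]
    classes = results["genotype_filter"]["classes"]

    @stage("guqtl")
    def _guqtl():
        res = {}
        for axis in ("v", "j"):
            um = results["usage"][axis]
            if um.frequency.empty:
                res[axis] = pd.DataFrame()
                continue
            table = qtl.map_guqtls(um, common, classes, alpha=params.alpha)
            table.to_csv(out / f"guqtl_{axis}.tsv", sep="\t", index=False)
            res[axis] = table
        return res

    if params.run_properties:
        @stage("properties")
        def _props():
            unmut, _, _ = usage.partition_by_mutation(records)
            means = properties.sample_mean_properties(
                unmut, min_sample_seqs=params.min_sample_seqs
            )
            means.to_csv(out / "cdr3_properties.tsv", sep="\t")
            pq = qtl.map_property_qtls(means, common, classes, alpha=params.alpha)
            pq.to_csv(out / "property_qtls.tsv", sep="\t", index=False)
            return {"means": means, "qtls": pq}

    if params.run_ld_blocks:
        @stage("ld_blocks")
        def _blocks():
            snvs = common.subset((common.variants["kind"] == "SNV").to_numpy())
            pairs_df = ld.pairwise_ld(snvs, max_pairs_window=params.ld_window)
            cls_m = ld.classification_matrix(pairs_df, snvs.n_variants)
            blocks = ld.gabriel_blocks(
                snvs.variants["pos"].to_numpy(), cls_m, ids=snvs.ids
            )
            pd.DataFrame(
                [{"start": b.start, "end": b.end, "size": b.size,
                  "n_snvs": len(b.member_ids),
                  "members": ",".join(b.member_ids)} for b in blocks]
            ).to_csv(out / "ld_blocks.tsv", sep="\t", index=False)
            return blocks

    @stage("network")
    def _network():
        table = results["guqtl"]["v"]
        if table.empty:
            return networks.NetworkStructure([], [])
        sets = networks.guqtl_sets(table)
        graph = networks.build_graph(sets)
        structure = networks.find_structure(graph)
        networks.jaccard_edges(sets).to_csv(out / "network_edges.tsv", sep="\t", index=False)
        with open(out / "network_cliques.json", "w") as fh:
            json.dump({"components": structure.components,
                       "cliques": structure.cliques}, fh, indent=1)
        return structure

    @stage("allele_linkage")
    def _linkage():
        table = results["guqtl"]["v"]
        if table.empty:
            return pd.DataFrame()
        link = linkage.test_allele_linkage(
            germline, table, common, alpha=params.alpha,
            seed=manifest.seed or 0,
        )
        link.to_csv(out / "allele_linkage.tsv", sep="\t", index=False)
        return link

    manifest.write(out / "manifest.json")
    return results
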