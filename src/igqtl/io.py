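"""Readers/writers for AIRR TSV, VCF, germline JSON, YAML config and run
manifests.

Coordinate conventions: VCF and AIRR positions are 1-based; BED is
0-based half-open; conversion happens here, at the boundary.  For
copy-number deletion SVs the VCF ``<DEL>`` alternate allele marks a
deleted haplotype, while the in-memory dosage is the diploid *retained*
copy number (2 minus deletion alleles) and the haplotype matrix stores
retained-copy indicators.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import GenotypeMatrix
from .simulate import (
    AlleleSpec,
    BlockSpec,
    EffectSpec,
    GeneSpec,
    GermlineSets,
    LinkageSpec,
    ParalogPairSpec,
    SimConfig,
    SimTruth,
    SVSpec,
)

AIRR_REQUIRED = [
    "sample_id", "v_call", "j_call", "junction_aa", "v_identity", "j_identity",
]


# ---------------------------------------------------------------------------
# AIRR rearrangement tables
# ---------------------------------------------------------------------------

def read_airr(path) -> pd.DataFrame:
    """Read an AIRR rearrangement TSV.

    Requires the columns sample_id, v_call, j_call, junction_aa,
    v_identity, j_identity (duplicate_count defaults to 1 when absent);
    unknown columns are preserved.  Junctions are normalised to upper
    case.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in AIRR_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required AIRR column(s): {missing}")
    if "duplicate_count" not in df.columns:
        df["duplicate_count"] = 1
    df["junction_aa"] = df["junction_aa"].astype(str).str.upper()
    return df


def write_airr(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(gm: GenotypeMatrix, path, contig_length: int | None = None) -> None:
    """Write a multi-sample VCF v4.2 with GT fields (phased when the
    matrix carries haplotypes)."""
    contigs = gm.variants["contig"].unique()
    length = contig_length or int(gm.variants["pos"].max()) + 1000
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=igqtl\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        phased = gm.haplotypes is not None
        order = np.argsort(gm.variants["pos"].to_numpy(), kind="stable")
        for i in order:
            v = gm.variants.iloc[i]
            is_sv = v["kind"] == "SV"
            info = "SVTYPE=DEL" if is_sv else "."
            gts = []
            for s in range(len(gm.samples)):
                if phased:
                    a, b = gm.haplotypes[i, 2 * s], gm.haplotypes[i, 2 * s + 1]
                    if is_sv:  # haplotype stores retained copies; ALT is the deletion
                        a, b = 1 - a, 1 - b
                    gts.append(f"{a}|{b}")
                else:
                    d = gm.dosage[i, s]
                    if np.isnan(d):
                        gts.append("./.")
                    else:
                        alt = int(2 - d) if is_sv else int(d)
                        gts.append(["0/0", "0/1", "1/1"][alt])
            fh.write(
                f"{v['contig']}\t{int(v['pos'])}\t{v['id']}\t{v['ref']}\t{v['alt']}"
                f"\t.\tPASS\t{info}\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a multi-sample VCF into a GenotypeMatrix.

    Only biallelic records are accepted; multiallelic sites must be split
    upstream (``bcftools norm -m-``).  Phase is preserved when every
    genotype in the file is phased.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosages, haps = [], [], []
    all_phased = True
    for rec in vcf:
        if rec.ALT is None or len(rec.ALT) != 1:
            raise ValueError(
                f"{path}: multiallelic record at {rec.CHROM}:{rec.POS}; "
                "split into biallelic records first (bcftools norm -m-)"
            )
        alt = rec.ALT[0]
        is_sv = alt.startswith("<")
        kind = "SV" if is_sv else "SNV"
        dos = np.empty(len(samples))
        hp = np.empty(2 * len(samples))
        for s, g in enumerate(rec.genotypes):
            a, b, phased = g[0], g[1], bool(g[2])
            if a < 0 or b < 0:
                if (a < 0) != (b < 0):
                    raise ValueError(f"{path}: malformed GT at {rec.CHROM}:{rec.POS}")
                dos[s] = np.nan
                hp[2 * s: 2 * s + 2] = 0
                all_phased = False
                continue
            if a > 1 or b > 1:
                raise ValueError(f"{path}: non-biallelic GT at {rec.CHROM}:{rec.POS}")
            alt_count = a + b
            dos[s] = 2 - alt_count if is_sv else alt_count
            hp[2 * s] = 1 - a if is_sv else a
            hp[2 * s + 1] = 1 - b if is_sv else b
            if not phased:
                all_phased = False
        rows.append({"id": rec.ID or f"{rec.CHROM}_{rec.POS}", "contig": rec.CHROM,
                     "pos": rec.POS, "ref": rec.REF, "alt": alt, "kind": kind})
        dosages.append(dos)
        haps.append(hp)
    variants = pd.DataFrame(rows)
    return GenotypeMatrix(
        variants=variants,
        samples=samples,
        dosage=np.array(dosages),
        haplotypes=np.array(haps, dtype=np.uint8) if all_phased else None,
    )


# ---------------------------------------------------------------------------
# germline sets, truth, config
# ---------------------------------------------------------------------------

def write_germline_json(germline: GermlineSets, path) -> None:
    with open(path, "w") as fh:
        json.dump(germline.to_dict(), fh, indent=1)


def read_germline_json(path) -> GermlineSets:
    with open(path) as fh:
        return GermlineSets.from_dict(json.load(fh))


def write_truth_json(truth: SimTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)


def read_truth_json(path) -> SimTruth:
    with open(path) as fh:
        return SimTruth.from_dict(json.load(fh))


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_to_yaml(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(dataclasses.asdict(config)), fh, sort_keys=False)


def config_from_yaml(path) -> SimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["blocks"] = [BlockSpec(**b) for b in d["blocks"]]
    d["genes"] = [
        GeneSpec(**{**g, "alleles": [AlleleSpec(**a) for a in g["alleles"]]})
        for g in d["genes"]
    ]
    d["paralog_pairs"] = [ParalogPairSpec(**p) for p in d.get("paralog_pairs", [])]
    d["effects"] = [EffectSpec(**e) for e in d.get("effects", [])]
    d["svs"] = [SVSpec(**s) for s in d.get("svs", [])]
    d["linked_alleles"] = [LinkageSpec(**l) for l in d.get("linked_alleles", [])]
    return SimConfig(**d)


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Traceability record: every filtering decision of a run maps to an
    entry here."""

    tool_version: str = __version__
    seed: int | None = None
    config_hash: str | None = None
    input_checksums: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    filter_counts: dict = field(default_factory=dict)
    stages_completed: list = field(default_factory=list)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(_plain(dataclasses.asdict(self)), fh, indent=1)
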