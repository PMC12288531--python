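"""Shared in-memory containers for genotype and repertoire-usage data.

Conventions
-----------
* Variant positions are 1-based (as in VCF); BED-style intervals are
  0-based half-open and converted at I/O boundaries.
* Dosage is the additive alternate-allele count in {0, 1, 2}; for
  copy-number structural variants it is the diploid copy number of the
  affected genes, also in {0, 1, 2}.  Missing dosage is NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["id", "contig", "pos", "ref", "alt", "kind"]


@dataclass
class GenotypeMatrix:
    """Variant x individual additive dosage with variant metadata.

    Parameters
    ----------
    variants : pandas.DataFrame
        One row per variant with columns ``id, contig, pos, ref, alt, kind``
        (kind is ``"SNV"`` or ``"SV"``), in the same order as ``dosage`` rows.
    samples : list of str
        Individual identifiers, in the same order as ``dosage`` columns.
    dosage : numpy.ndarray, shape (n_variants, n_samples)
        Additive dosage; NaN marks a missing genotype.
    haplotypes : numpy.ndarray or None, shape (n_variants, 2 * n_samples)
        Phased per-haplotype alternate-allele indicators, when available.
        Haplotypes ``2i`` and ``2i + 1`` belong to individual ``i``.
    """

    variants: pd.DataFrame
    samples: list[str]
    dosage: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table lacks columns: {missing}")
        if self.dosage.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        if self.haplotypes is not None and self.haplotypes.shape != (
            len(self.variants),
            2 * len(self.samples),
        ):
            raise ValueError("haplotype matrix shape mismatch")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def ids(self) -> list[str]:
        return list(self.variants["id"])

    def allele_frequency(self) -> np.ndarray:
        """Cohort alternate-allele (or retained-copy) frequency per variant."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=1) / 2.0

    def maf(self) -> np.ndarray:
        """Cohort minor-allele frequency per variant."""
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=1)

    def subset(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Row-subset by boolean mask or integer index array."""
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        variants = self.variants.iloc[idx].reset_index(drop=True)
        dosage = self.dosage[idx]
        haps = self.haplotypes[idx] if self.haplotypes is not None else None
        return GenotypeMatrix(variants, list(self.samples), dosage, haps)

    def row(self, variant_id: str) -> np.ndarray:
        idx = self.variants.index[self.variants["id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not found")
        return self.dosage[idx[0]]


@dataclass
class UsageMatrix:
    """Gene x sample usage for one repertoire partition.

    ``frequency`` holds per-sample usage fractions among all unique records of
    the partition (denominator taken before the per-gene minimum-count
    filter); ``count`` holds the unique-record counts.  NaN in ``frequency``
    marks gene/sample cells that are not evaluable (e.g. paralog labels for
    individuals whose germline allele sets cannot disambiguate the pair).
    """

    frequency: pd.DataFrame
    count: pd.DataFrame
    partition: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frequency.index.equals(self.count.index):
            raise ValueError("frequency/count gene index mismatch")
        if not self.frequency.columns.equals(self.count.columns):
            raise ValueError("frequency/count sample columns mismatch")

    @property
    def genes(self) -> list[str]:
        return list(self.frequency.index)

    @property
    def samples(self) -> list[str]:
        return list(self.frequency.columns)
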