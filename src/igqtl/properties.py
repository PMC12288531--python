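"""CDR3 physicochemical properties.

Nine per-sequence descriptors of the third complementarity-determining
region (the junction minus its two conserved anchor residues):

=============  ==============================================================
length         residue count of the CDR3
gravy          mean Kyte–Doolittle hydropathy
aromaticity    fraction of residues in {F, W, H, Y}
aliphaticity   X_A + 2.9 X_V + 3.9 (X_I + X_L), X = mole fractions (Ikai
               index on the 0–3.9 mole-fraction scale)
acidity        fraction of residues in {D, E}
basicity       fraction of residues in {R, H, K}
charge         net side-chain charge at pH 7.4 (Henderson–Hasselbalch with
               EMBOSS pK values; termini excluded, unnormalised)
polarity       mean Grantham polarity
bulkiness      mean Zimmerman bulkiness
=============  ==============================================================

Scale tables ship as a versioned JSON data file.  Sequences containing
non-standard residues (e.g. ``X``) are excluded from sample means rather
than zero-filled.
"""

from __future__ import annotations

import json
import logging
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROPERTY_NAMES = [
    "length", "gravy", "aromaticity", "aliphaticity", "acidity",
    "basicity", "charge", "polarity", "bulkiness",
]

DEFAULT_PH = 7.4

with resources.files("igqtl.data").joinpath("aa_scales.json").open() as _fh:
    SCALES = json.load(_fh)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


def _charge_table(ph: float) -> dict[str, float]:
    """Per-residue side-chain charge at the given pH."""
    pk = SCALES["emboss_pk"]
    out = {}
    for aa in SCALES["positive_side_chains"]:
        out[aa] = 1.0 / (1.0 + 10.0 ** (ph - pk[aa]))
    for aa in SCALES["negative_side_chains"]:
        out[aa] = -1.0 / (1.0 + 10.0 ** (pk[aa] - ph))
    return out


def _lookup(table: dict[str, float]) -> np.ndarray:
    arr = np.zeros(128)
    for aa, v in table.items():
        arr[ord(aa)] = v
    return arr


_KD = _lookup(SCALES["kyte_doolittle"])
_POL = _lookup(SCALES["grantham_polarity"])
_BULK = _lookup(SCALES["zimmerman_bulkiness"])
_AROM = _lookup({a: 1.0 for a in SCALES["aromatic"]})
_ACID = _lookup({a: 1.0 for a in SCALES["acidic"]})
_BASE = _lookup({a: 1.0 for a in SCALES["basic"]})
_ALIPH = _lookup(SCALES["aliphatic_weights"])
_VALID = _lookup({a: 1.0 for a in STANDARD_AA})


def cdr3_from_junction(junction_aa: str) -> str:
    """CDR3 = junction minus its first and last (conserved anchor)
    residues; junctions shorter than 3 yield an empty CDR3."""
    if len(junction_aa) < 2:
        return ""
    return junction_aa[1:-1]


def compute_properties(cdr3_aa: str, ph: float = DEFAULT_PH) -> dict[str, float]:
    """Property vector for one CDR3 sequence.

    Raises ValueError on empty input or non-standard residues; callers
    computing sample means exclude such records instead.
    """
    if not cdr3_aa:
        raise ValueError("empty CDR3")
    bad = set(cdr3_aa) - set(STANDARD_AA)
    if bad:
        raise ValueError(f"non-standard residues {sorted(bad)} in CDR3")
    arr = np.frombuffer(cdr3_aa.encode("ascii"), dtype=np.uint8)
    n = len(arr)
    charge = _lookup(_charge_table(ph)) if ph != DEFAULT_PH else _CHARGE_DEFAULT
    return {
        "length": float(n),
        "gravy": float(_KD[arr].mean()),
        "aromaticity": float(_AROM[arr].mean()),
        "aliphaticity": float(_ALIPH[arr].mean()),
        "acidity": float(_ACID[arr].mean()),
        "basicity": float(_BASE[arr].mean()),
        "charge": float(charge[arr].sum()),
        "polarity": float(_POL[arr].mean()),
        "bulkiness": float(_BULK[arr].mean()),
    }


_CHARGE_DEFAULT = _lookup(_charge_table(DEFAULT_PH))


def property_table(cdr3_seqs, ph: float = DEFAULT_PH) -> tuple[pd.DataFrame, np.ndarray]:
    """Vectorised property computation for many CDR3 sequences.

    Returns ``(table, valid)`` where ``table`` has one row per input
    sequence (NaN rows for invalid ones) and ``valid`` flags sequences
    that are non-empty and contain only standard residues.
    """
    seqs = list(cdr3_seqs)
    n = len(seqs)
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=n)
    blob = "".join(seqs)
    arr = np.frombuffer(blob.encode("ascii"), dtype=np.uint8)
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    nonempty = lengths > 0

    # reduceat misreports empty segments (and would index past the end for
    # trailing empties), so clip indices and zero empty rows afterwards
    idx = np.minimum(starts, max(arr.size - 1, 0))

    def seg_sum(values: np.ndarray) -> np.ndarray:
        if arr.size == 0 or n == 0:
            return np.zeros(n)
        out = np.add.reduceat(values, idx).astype(float)
        out[~nonempty] = 0.0
        return out

    charge_tab = _lookup(_charge_table(ph)) if ph != DEFAULT_PH else _CHARGE_DEFAULT
    valid_counts = seg_sum(_VALID[arr])
    valid = nonempty & (valid_counts == lengths)

    with np.errstate(invalid="ignore", divide="ignore"):
        safe_len = np.where(lengths > 0, lengths, 1).astype(float)
        table = pd.DataFrame(
            {
                "length": lengths.astype(float),
                "gravy": seg_sum(_KD[arr]) / safe_len,
                "aromaticity": seg_sum(_AROM[arr]) / safe_len,
                "aliphaticity": seg_sum(_ALIPH[arr]) / safe_len,
                "acidity": seg_sum(_ACID[arr]) / safe_len,
                "basicity": seg_sum(_BASE[arr]) / safe_len,
                "charge": seg_sum(charge_tab[arr]),
                "polarity": seg_sum(_POL[arr]) / safe_len,
                "bulkiness": seg_sum(_BULK[arr]) / safe_len,
            }
        )
    table[~valid] = np.nan
    return table, valid


def sample_mean_properties(
    records: pd.DataFrame,
    min_sample_seqs: int = 100,
    ph: float = DEFAULT_PH,
) -> pd.DataFrame:
    """Per-sample unweighted means of the nine CDR3 properties.

    Uses the same sample-exclusion rule as usage computation (samples
    with fewer than ``min_sample_seqs`` unique records are dropped);
    records with empty or non-standard CDR3s are excluded from the means
    and counted in a log message.
    """
    if records.empty:
        return pd.DataFrame(columns=PROPERTY_NAMES)
    totals = records.groupby("sample_id", observed=True).size()
    keep = totals.index[totals >= min_sample_seqs]
    work = records[records["sample_id"].isin(keep)]
    if work.empty:
        return pd.DataFrame(columns=PROPERTY_NAMES)
    cdr3 = [cdr3_from_junction(j) for j in work["junction_aa"]]
    table, valid = property_table(cdr3, ph=ph)
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.warning("sample_mean_properties: excluded %d records with "
                       "empty or non-standard CDR3", n_excluded)
    table["sample_id"] = work["sample_id"].to_numpy()
    means = table.loc[valid].groupby("sample_id", observed=True)[PROPERTY_NAMES].mean()
    empty = sorted(set(work["sample_id"].unique()) - set(means.index))
    if empty:
        logger.warning("sample_mean_properties: dropped samples with no "
                       "evaluable records: %s", empty)
    means.columns.name = "property"
    return means.sort_index()
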