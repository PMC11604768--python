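"""Transcription-rate estimation and count-matrix summaries.

The per-promoter transcription-rate estimate is the aggregate ratio: the sum
of reads-per-million (RPM) over a promoter's barcodes in an RNA sample,
divided by the same sum in the plasmid-input DNA library (mean RPM across
DNA replicates when more than one).  Also provided: median-RPM barcode fold
changes between arms, upper-quartile depth factors, and hierarchical
clustering / rank-2 SVD biplot summaries of rate profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage


@dataclass
class CountMatrix:
    """Barcode x sample count matrix with sample metadata.

    ``values`` is a DataFrame indexed by barcode with sample_id columns;
    ``meta`` is a DataFrame with columns sample_id, material ({DNA, RNA}),
    condition, batch.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "material", "condition", "batch"}
        missing = required - set(self.meta.columns)
        if missing:
            raise ValueError(f"metadata missing columns {sorted(missing)}")
        unknown = set(self.values.columns) - set(self.meta["sample_id"])
        if unknown:
            raise ValueError(f"samples without metadata: {sorted(unknown)}")
        bad = set(self.meta["material"]) - {"DNA", "RNA"}
        if bad:
            raise ValueError(f"unknown material labels {sorted(bad)}")
        if (self.values.values < 0).any():
            raise ValueError("counts must be nonnegative")

    def samples(self, material: str | None = None, condition: str | None = None):
        m = self.meta[self.meta["sample_id"].isin(self.values.columns)]
        if material is not None:
            m = m[m["material"] == material]
        if condition is not None:
            m = m[m["condition"] == condition]
        return list(m["sample_id"])


def rpm(matrix: pd.DataFrame) -> pd.DataFrame:
    """Reads per million: value x 1e6 / sample column total."""
    totals = matrix.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    return matrix * 1e6 / totals


def aggregate_ratio(
    rna_rpm: pd.DataFrame,
    dna_rpm: pd.DataFrame,
    barcode_to_promoter: dict,
) -> pd.DataFrame:
    """Per-promoter aggregate RNA/DNA RPM ratio.

    DNA columns are averaged on the RPM scale before summation.  Promoters
    whose summed DNA RPM is zero get NaN (flagged undefined, never imputed);
    promoters without dictionary barcodes are absent from the output.
    """
    barcodes = [bc for bc in rna_rpm.index if bc in barcode_to_promoter]
    if not barcodes:
        raise ValueError("no barcode in the matrix is covered by the dictionary")
    groups = pd.Series({bc: barcode_to_promoter[bc] for bc in barcodes})
    rna_sum = rna_rpm.loc[barcodes].groupby(groups).sum()
    dna_mean = dna_rpm.loc[barcodes].mean(axis=1)
    dna_sum = dna_mean.groupby(groups).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = rna_sum.div(dna_sum, axis=0)
    ratio[dna_sum == 0] = np.nan
    ratio.index.name = "promoter_id"
    return ratio


def barcode_fold_changes(
    treated_rpm: pd.DataFrame, control_rpm: pd.DataFrame
) -> pd.Series:
    """Median-RPM fold change per barcode, treated vs control.

    Barcodes with control median 0 are NaN (undefined)."""
    if treated_rpm.shape[1] < 1 or control_rpm.shape[1] < 1:
        raise ValueError("each arm needs at least one replicate")
    t = treated_rpm.median(axis=1)
    c = control_rpm.median(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = t / c
    fc[c == 0] = np.nan
    return fc


def upper_quartile_factors(
    raw_counts: pd.DataFrame, reference: str | None = None,
    nonzero_only: bool = False,
) -> pd.Series:
    """Per-sample depth factors from the upper quartile of raw counts.

    factor_s = Q75(counts of s) / Q75(counts of reference), with
    linear-interpolation quantiles; the reference factor is exactly 1.
    Barcodes with zero counts in every sample are excluded first; remaining
    zeros participate in the quantile (the edgeR upper-quartile convention).
    This keeps the factors scale-equivariant: truncating to nonzero counts
    per sample (``nonzero_only=True``) couples the quantile level to the
    sample's zero fraction, which biases factors of deeper samples downward.
    """
    if reference is None:
        reference = raw_counts.columns[0]
    expressed = raw_counts.loc[raw_counts.sum(axis=1) > 0]
    if expressed.empty:
        raise ValueError("all barcodes have zero counts in every sample")
    q75 = {}
    for s in raw_counts.columns:
        v = expressed[s].values
        if nonzero_only:
            v = v[v > 0]
        if v.size == 0 or v.max() == 0:
            raise ValueError(f"sample {s} has no nonzero counts")
        q = float(np.percentile(v, 75))
        if q <= 0:
            raise ValueError(
                f"sample {s}: upper quartile is zero (matrix too sparse)"
            )
        q75[s] = q
    factors = pd.Series({s: q75[s] / q75[reference] for s in raw_counts.columns})
    factors[reference] = 1.0
    factors.attrs["reference"] = reference
    factors.attrs["quantile_convention"] = (
        "linear interpolation on nonzero counts" if nonzero_only
        else "linear interpolation, all-zero rows removed"
    )
    return factors


def profile_summaries(matrix: pd.DataFrame) -> dict:
    """Hierarchical-clustering orders and rank-2 SVD biplot coordinates.

    Rows with undefined (NaN) values are dropped; clustering is
    agglomerative with Euclidean distance and complete linkage.  For the
    biplot, columns are standardized to mean 0 / sd 1 (constant columns are
    dropped with a warning) and a rank-2 SVD taken; rows (promoters) get
    principal-component scores, columns (samples) get loadings.
    """
    m = matrix.dropna(axis=0)
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("matrix needs >= 2 defined rows and >= 2 columns")
    row_order = list(m.index[leaves_list(linkage(m.values, method="complete"))])
    col_order = list(m.columns[leaves_list(linkage(m.values.T, method="complete"))])
    sd = m.std(axis=0, ddof=1)
    constant = sd[sd == 0].index
    if len(constant):
        warnings.warn(f"dropping constant column(s) {list(constant)}")
    z = (m.drop(columns=constant) - m.drop(columns=constant).mean()) / sd.drop(constant)
    u, s, vt = np.linalg.svd(z.values, full_matrices=False)
    row_coords = pd.DataFrame(
        u[:, :2] * s[:2], index=z.index, columns=["pc1", "pc2"]
    )
    col_coords = pd.DataFrame(vt[:2].T, index=z.columns, columns=["pc1", "pc2"])
    return {
        "row_order": row_order,
        "col_order": col_order,
        "row_coords": row_coords,
        "col_coords": col_coords,
        "singular_values": s[:2],
    }


# ---------------------------------------------------------------------------
# I/O


def read_count_matrix(counts_path, meta_path) -> CountMatrix:
    """Read a counts TSV and its sample-metadata sidecar (``#`` lines are
    treated as comments, e.g. the simulator's seed header)."""
    values = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    meta = pd.read_csv(meta_path, sep="\t", dtype=str, comment="#")
    return CountMatrix(values=values, meta=meta)


def write_rate_table(ratio: pd.DataFrame, path) -> None:
    ratio.to_csv(path, sep="\t")
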