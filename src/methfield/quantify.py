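"""Block-level methylation with CHH-based conversion-error correction.

For block b in sample s, with M_j/U_j the methylated/unmethylated CpG read
counts of member site j and Me_k/Ue_k the same for member CHH sites k:

    methylMean           = sum_j M_j / sum_j (M_j + U_j)
    error                = sum_k Me_k / sum_k (Me_k + Ue_k)
    corrected methylMean = (methylMean - error) / (1 - error)

CHH cytosines are essentially unmethylated in human somatic tissue, so any
apparent CHH methylation measures bisulfite conversion failure; since a
conversion failure turns a truly unmethylated read methylated with
probability e, observed = e + (1 - e) * true and the correction inverts the
error channel exactly in expectation.  Negative corrected values are
clamped to 0.  When a block has too few CHH reads the sample-wide CHH pool
supplies the error estimate (``error_source = sample_fallback``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .io import SampleRecord
from .segmentation import MethylationBlock


def block_methyl_mean(sum_m: float, sum_u: float) -> float:
    """Pooled CpG methylation fraction of a block; NaN at zero coverage."""
    total = sum_m + sum_u
    if total <= 0:
        return float("nan")
    return sum_m / total


def block_error(sum_me: float, sum_ue: float) -> float:
    """Pooled CHH (conversion-failure) fraction; NaN signals fallback needed."""
    total = sum_me + sum_ue
    if total <= 0:
        return float("nan")
    return sum_me / total


def corrected_methyl_mean(methyl_mean: float, error: float) -> float:
    """(m - e)/(1 - e), clamped into [0, 1]."""
    if not 0 <= error < 1:
        raise ValueError(f"error must be in [0, 1), got {error}")
    if np.isnan(methyl_mean):
        return float("nan")
    return min(1.0, max(0.0, (methyl_mean - error) / (1.0 - error)))


@dataclass
class BlockMatrix:
    """Blocks x samples corrected methylation with its provenance.

    ``values`` holds corrected methylMean (NaN = missing), ``methyl_mean``
    the uncorrected fractions, ``error`` the per-entry error estimate and
    ``error_source`` "block" or "sample_fallback".  ``sample_error`` is each
    sample's pooled CHH fraction — its global conversion-failure estimate.
    """

    values: pd.DataFrame
    methyl_mean: pd.DataFrame
    error: pd.DataFrame
    error_source: pd.DataFrame
    sample_error: pd.Series
    manifest: list[SampleRecord]

    @property
    def block_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def tissue_columns(self, tissue: str) -> pd.DataFrame:
        """Columns of one tissue, re-labelled by patient_id."""
        cols = {s.sample_id: s.patient_id for s in self.manifest if s.tissue == tissue}
        sub = self.values[[c for c in self.values.columns if c in cols]]
        return sub.rename(columns=cols)


def aggregate_block_counts(
    records: pd.DataFrame, blocks: Sequence[MethylationBlock]
) -> pd.DataFrame:
    """Sum site counts over block members per (block, sample, context).

    Returns a table with block_id, sample_id, sum_m, sum_u, sum_me, sum_ue,
    n_cpg_covered, n_chh_covered.  Sites not belonging to any block are
    ignored.
    """
    rows = []
    for b in blocks:
        for p in b.cpg_positions:
            rows.append((b.chrom, int(p), "CpG", b.block_id))
        for p in b.chh_positions:
            rows.append((b.chrom, int(p), "CHH", b.block_id))
    site_map = pd.DataFrame(rows, columns=["chrom", "pos", "context", "block_id"])

    df = records[["chrom", "pos", "context", "meth_count", "unmeth_count", "sample_id"]].copy()
    df["chrom"] = df["chrom"].astype(str)
    df["context"] = df["context"].astype(str)
    df["sample_id"] = df["sample_id"].astype(str)
    df = df.merge(site_map, on=["chrom", "pos", "context"], how="inner")

    grouped = (
        df.groupby(["block_id", "sample_id", "context"], observed=True)
        .agg(m=("meth_count", "sum"), u=("unmeth_count", "sum"), n=("pos", "size"))
        .unstack("context")
    )

    def _col(top, ctx, fill=0):
        key = (top, ctx)
        if key in grouped.columns:
            return grouped[key].fillna(fill).to_numpy()
        return np.full(len(grouped), fill, dtype=float)

    out = pd.DataFrame({
        "block_id": grouped.index.get_level_values("block_id"),
        "sample_id": grouped.index.get_level_values("sample_id"),
        "sum_m": _col("m", "CpG").astype(np.int64),
        "sum_u": _col("u", "CpG").astype(np.int64),
        "sum_me": _col("m", "CHH").astype(np.int64),
        "sum_ue": _col("u", "CHH").astype(np.int64),
        "n_cpg_covered": _col("n", "CpG").astype(np.int64),
        "n_chh_covered": _col("n", "CHH").astype(np.int64),
    })
    return out.sort_values(["block_id", "sample_id"]).reset_index(drop=True)


def assemble_matrix(
    sum_m: np.ndarray,
    sum_u: np.ndarray,
    sum_me: np.ndarray,
    sum_ue: np.ndarray,
    block_ids: Sequence[str],
    manifest: Sequence[SampleRecord],
    min_chh_reads: int = 20,
    error_mode: str = "block",
    correct: bool = True,
) -> BlockMatrix:
    """Assemble a :class:`BlockMatrix` from per-(block, sample) count arrays.

    *error_mode* "block" uses the block's own CHH reads when they number at
    least *min_chh_reads* and falls back to the sample-wide CHH pool
    otherwise; "sample" always uses the sample pool.  ``correct=False``
    keeps the raw methylMean (error still reported).
    """
    if error_mode not in ("block", "sample"):
        raise ValueError("error_mode must be 'block' or 'sample'")
    sample_ids = [s.sample_id for s in manifest]
    sum_m = np.asarray(sum_m, dtype=float)
    sum_u = np.asarray(sum_u, dtype=float)
    sum_me = np.asarray(sum_me, dtype=float)
    sum_ue = np.asarray(sum_ue, dtype=float)

    cpg_total = sum_m + sum_u
    with np.errstate(invalid="ignore", divide="ignore"):
        mm = np.where(cpg_total > 0, sum_m / np.where(cpg_total > 0, cpg_total, 1), np.nan)

    chh_tot_sample = sum_me.sum(axis=0) + sum_ue.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        samp_err = np.where(chh_tot_sample > 0, sum_me.sum(axis=0) / np.where(chh_tot_sample > 0, chh_tot_sample, 1), 0.0)

    chh_total = sum_me + sum_ue
    use_block = (error_mode == "block") & (chh_total >= min_chh_reads)
    with np.errstate(invalid="ignore", divide="ignore"):
        block_err = np.where(chh_total > 0, sum_me / np.where(chh_total > 0, chh_total, 1), np.nan)
    err = np.where(use_block, block_err, samp_err[None, :])
    err = np.clip(err, 0.0, 1.0 - 1e-12)

    if correct:
        corrected = np.clip((mm - err) / (1.0 - err), 0.0, 1.0)
    else:
        corrected = mm
    corrected = np.where(np.isnan(mm), np.nan, corrected)

    source = np.where(use_block, "block", "sample_fallback")
    idx = pd.Index(block_ids, name="block_id")
    cols = pd.Index(sample_ids, name="sample_id")
    return BlockMatrix(
        values=pd.DataFrame(corrected, index=idx, columns=cols),
        methyl_mean=pd.DataFrame(mm, index=idx, columns=cols),
        error=pd.DataFrame(err, index=idx, columns=cols),
        error_source=pd.DataFrame(source, index=idx, columns=cols),
        sample_error=pd.Series(samp_err, index=cols, name="sample_error"),
        manifest=list(manifest),
    )


def build_block_matrix(
    records: pd.DataFrame,
    blocks: Sequence[MethylationBlock],
    manifest: Sequence[SampleRecord],
    min_chh_reads: int = 20,
    error_mode: str = "block",
    correct: bool = True,
) -> BlockMatrix:
    """Aggregate a long site-count table over blocks and correct per sample.

    *records* must already be strand-collapsed and depth-filtered and carry
    a ``sample_id`` column.  Samples in the manifest with no records yield
    an all-missing column (with a warning).
    """
    counts = aggregate_block_counts(records, blocks)
    block_ids = [b.block_id for b in blocks]
    sample_ids = [s.sample_id for s in manifest]
    bi = {b: i for i, b in enumerate(block_ids)}
    si = {s: i for i, s in enumerate(sample_ids)}

    seen = set(counts["sample_id"].unique()) if len(counts) else set()
    for s in sample_ids:
        if s not in seen:
            warnings.warn(f"sample {s} has no site records; column will be all-missing")

    shape = (len(block_ids), len(sample_ids))
    sum_m = np.zeros(shape)
    sum_u = np.zeros(shape)
    sum_me = np.zeros(shape)
    sum_ue = np.zeros(shape)
    if len(counts):
        sub = counts[counts["block_id"].isin(bi) & counts["sample_id"].isin(si)]
        ii = sub["block_id"].map(bi).to_numpy()
        jj = sub["sample_id"].map(si).to_numpy()
        sum_m[ii, jj] = sub["sum_m"].to_numpy()
        sum_u[ii, jj] = sub["sum_u"].to_numpy()
        sum_me[ii, jj] = sub["sum_me"].to_numpy()
        sum_ue[ii, jj] = sub["sum_ue"].to_numpy()
    return assemble_matrix(
        sum_m, sum_u, sum_me, sum_ue, block_ids, manifest,
        min_chh_reads=min_chh_reads, error_mode=error_mode, correct=correct,
    )
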