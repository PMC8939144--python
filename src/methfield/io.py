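"""Readers, writers and sample-inclusion rules for the pipeline's file formats.

Per-cytosine methylation calls are exchanged as a 6-column, tab-delimited
cytosine report (no header), one line per cytosine::

    chrom  pos  strand  meth_count  unmeth_count  context

with ``pos`` 1-based and ``context`` one of CpG/CG (CpG dinucleotide),
CHH, or CHG.  CHG lines are dropped on read: only CpG sites carry signal
here and only CHH sites inform the bisulfite conversion-failure estimate.

In-memory, a collection of site counts is a :class:`pandas.DataFrame` with
columns ``chrom, pos, strand, context, meth_count, unmeth_count`` (plus
``sample_id`` when several samples are stacked).  Emitted intervals are
BED (0-based half-open); tables are TSV with a header.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TISSUES = ("TUM", "ADJ", "DIS")

REPORT_COLUMNS = ["chrom", "pos", "strand", "meth_count", "unmeth_count", "context"]

#: columns of a stacked site-count table
SITE_COLUMNS = ["chrom", "pos", "strand", "context", "meth_count", "unmeth_count"]

_CONTEXT_MAP = {"CpG": "CpG", "CG": "CpG", "CPG": "CpG", "CHH": "CHH"}


class CytosineReportError(ValueError):
    """Malformed or invalid line in a cytosine report."""


class ManifestError(ValueError):
    """Invalid sample manifest."""


@dataclass(frozen=True)
class SampleRecord:
    """One tissue sample of one patient.

    ``tissue`` is TUM (resected tumor), ADJ (normal tissue 2 cm from the
    resection margin) or DIS (normal tissue 5 cm away).  ``tumor_cell_fraction``
    applies to TUM samples; ``tumor_contaminated`` flags ADJ/DIS samples in
    which histology found any visible tumor cell.
    """

    patient_id: str
    tissue: str
    path: str = ""
    tumor_cell_fraction: float | None = None
    tumor_contaminated: bool = False
    covariates: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.tissue not in TISSUES:
            raise ManifestError(
                f"unknown tissue label {self.tissue!r} for patient "
                f"{self.patient_id!r}; expected one of {TISSUES}"
            )

    @property
    def sample_id(self) -> str:
        return f"{self.patient_id}_{self.tissue}"


@dataclass(frozen=True)
class PanelRegion:
    """A targeted panel interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"panel region {self.chrom}:{self.start}-{self.end} is empty")


def read_cytosine_report(path, min_depth: int = 5) -> pd.DataFrame:
    """Read a cytosine report, keeping CpG/CHH sites with depth >= *min_depth*.

    Returns a DataFrame with :data:`SITE_COLUMNS`, sorted by (chrom, pos).
    CHG lines are dropped; an unrecognised context, a malformed field or a
    negative count raises :class:`CytosineReportError` naming the line.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=REPORT_COLUMNS,
            dtype={"chrom": str, "strand": str, "context": str},
            comment="#",
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise CytosineReportError(f"{path}: {exc}") from exc

    for col in ("pos", "meth_count", "unmeth_count"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise CytosineReportError(f"{path}: line {line}: non-integer {col} {df[col][bad.idxmax()]!r}")
        if vals.isna().any():
            line = int(vals.isna().idxmax()) + 1
            raise CytosineReportError(f"{path}: line {line}: missing {col}")
        df[col] = vals.astype(np.int64)

    for col in ("meth_count", "unmeth_count"):
        neg = df[col] < 0
        if neg.any():
            line = int(neg.idxmax()) + 1
            raise CytosineReportError(f"{path}: line {line}: negative {col}")

    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        line = int(bad_strand.idxmax()) + 1
        raise CytosineReportError(f"{path}: line {line}: bad strand {df['strand'][bad_strand.idxmax()]!r}")

    ctx = df["context"].map(_CONTEXT_MAP)
    unknown = ctx.isna() & ~df["context"].isin(["CHG"])
    if unknown.any():
        line = int(unknown.idxmax()) + 1
        raise CytosineReportError(f"{path}: line {line}: unknown context {df['context'][unknown.idxmax()]!r}")
    df["context"] = ctx
    df = df[df["context"].notna()]

    depth = df["meth_count"] + df["unmeth_count"]
    df = df[depth >= min_depth]
    df = df[SITE_COLUMNS].sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return df


def collapse_cpg_strands(records: pd.DataFrame) -> pd.DataFrame:
    """Merge complementary CpG strand calls into one unit per CpG dinucleotide.

    A plus-strand CpG at position p and a minus-strand CpG at p+1 (same
    chromosome) are one biological CpG; their counts are summed and the unit
    anchored at p on the plus strand.  Unpaired CpGs and all CHH records pass
    through unchanged.  Total read counts are conserved.
    """
    df = records.reset_index(drop=True)
    cpg = df["context"] == "CpG"
    plus = cpg & (df["strand"] == "+")
    minus = cpg & (df["strand"] == "-")
    if not minus.any():
        return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    key = pd.MultiIndex.from_arrays([df["chrom"], df["pos"]])
    plus_lookup = {k: i for i, k in zip(df.index[plus], key[plus])}

    merged_into = {}
    drop = []
    for i in df.index[minus]:
        partner = plus_lookup.get((df.at[i, "chrom"], df.at[i, "pos"] - 1))
        if partner is not None:
            merged_into[partner] = i
            drop.append(i)
    out = df.copy()
    for anchor, mate in merged_into.items():
        out.at[anchor, "meth_count"] += df.at[mate, "meth_count"]
        out.at[anchor, "unmeth_count"] += df.at[mate, "unmeth_count"]
    out = out.drop(index=drop)
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


_MANIFEST_REQUIRED = ("patient_id", "tissue", "path")
_MANIFEST_KNOWN = _MANIFEST_REQUIRED + ("tumor_cell_fraction", "tumor_contaminated")
_TRUTHY = {"1", "true", "yes", "y"}


def read_manifest(path) -> list[SampleRecord]:
    """Read a sample manifest TSV into validated :class:`SampleRecord` rows.

    Required columns: patient_id, tissue, path.  Recognised optional
    columns: tumor_cell_fraction (proportion), tumor_contaminated (boolean);
    any further columns are kept as covariates.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _MANIFEST_REQUIRED if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing required column(s) {missing}")
    dup = df.duplicated(subset=["patient_id", "tissue"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ManifestError(f"{path}: duplicate sample ({row['patient_id']}, {row['tissue']})")

    extra = [c for c in df.columns if c not in _MANIFEST_KNOWN]
    records = []
    for _, row in df.iterrows():
        tcf = row.get("tumor_cell_fraction")
        tcf = float(tcf) if tcf is not None and not pd.isna(tcf) and tcf != "" else None
        contam = row.get("tumor_contaminated")
        contam = str(contam).strip().lower() in _TRUTHY if contam is not None and not pd.isna(contam) else False
        cov = {c: row[c] for c in extra if not pd.isna(row[c])}
        records.append(
            SampleRecord(
                patient_id=str(row["patient_id"]),
                tissue=str(row["tissue"]),
                path=str(row["path"]),
                tumor_cell_fraction=tcf,
                tumor_contaminated=contam,
                covariates=cov,
            )
        )
    return records


def apply_inclusion_rules(
    samples: Sequence[SampleRecord], min_tumor_fraction: float = 0.10
) -> list[SampleRecord]:
    """Apply the study's sample QC and keep only complete TUM+ADJ+DIS trios.

    Tumor samples with a tumor cell fraction below *min_tumor_fraction* and
    normal samples with any visible tumor cell are excluded; any patient then
    lacking one of the three tissues is dropped entirely, so the result size
    is always a multiple of three.
    """
    if not 0 <= min_tumor_fraction <= 1:
        raise ValueError("min_tumor_fraction must be in [0, 1]")
    kept = []
    for s in samples:
        if s.tissue == "TUM":
            if s.tumor_cell_fraction is not None and s.tumor_cell_fraction < min_tumor_fraction:
                continue
        elif s.tumor_contaminated:
            continue
        kept.append(s)
    by_patient: dict[str, set[str]] = {}
    for s in kept:
        by_patient.setdefault(s.patient_id, set()).add(s.tissue)
    complete = {p for p, t in by_patient.items() if t == set(TISSUES)}
    return [s for s in kept if s.patient_id in complete]


def write_manifest(samples: Sequence[SampleRecord], path) -> None:
    rows = []
    for s in samples:
        row = {
            "patient_id": s.patient_id,
            "tissue": s.tissue,
            "path": s.path,
            "tumor_cell_fraction": s.tumor_cell_fraction,
            "tumor_contaminated": int(s.tumor_contaminated),
        }
        row.update(s.covariates)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_panel_bed(path) -> list[PanelRegion]:
    """Read targeted panel regions from BED3(+name)."""
    regions = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {ln}: expected >= 3 BED fields")
            name = parts[3] if len(parts) > 3 else None
            regions.append(PanelRegion(parts[0], int(parts[1]), int(parts[2]), name))
    _check_sorted_disjoint(regions, path)
    return regions


def write_panel_bed(regions: Sequence[PanelRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            name = r.name if r.name is not None else "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\n")


def _check_sorted_disjoint(regions: Sequence[PanelRegion], origin="panel") -> None:
    prev: PanelRegion | None = None
    for r in regions:
        if prev is not None and prev.chrom == r.chrom:
            if r.start < prev.start:
                raise ValueError(f"{origin}: regions not sorted at {r.chrom}:{r.start}")
            if r.start < prev.end:
                raise ValueError(f"{origin}: overlapping regions at {r.chrom}:{r.start}")
        prev = r


def write_blocks_bed(blocks: Iterable, path, header: str | None = None) -> None:
    """Write methylation blocks as BED4 (chrom, start, end, block_id)."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.block_id}\n")


def read_bed4(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "name"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "name": str},
        comment="#",
    )


def write_table(rows: pd.DataFrame, path, header: str | None = None, float_format="%.10g") -> None:
    """Write a TSV with header and deterministic formatting.

    *header*, if given, becomes a leading ``#`` comment line (used by the
    pipeline to stamp outputs with the run's config hash).
    """
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        rows.to_csv(fh, sep="\t", index=False, float_format=float_format, lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def stack_records(per_sample: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-sample site tables into one long table with a sample_id column."""
    frames = []
    for sample_id, df in per_sample.items():
        f = df.copy()
        f["sample_id"] = sample_id
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    return out[SITE_COLUMNS + ["sample_id"]]
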