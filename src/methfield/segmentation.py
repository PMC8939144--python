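"""Co-methylation block construction and genomic annotation.

Neighbouring CpG sites on a targeted panel tend to move together: their
methylation fractions are correlated across samples, they are close in
genomic distance, and they sit at similar mean methylation levels.  A
*methylation block* is a maximal run of consecutive CpG sites for which all
three hold.  Segmentation is a greedy left-to-right scan within each panel
region: the pair gate is

    pearson_r >= r_min  AND  distance_bp <= d_max_bp  AND  level_diff <= level_diff_max

and any missing correlation (too few complete samples, or a zero-variance
site) never extends a block, so the result is always a partition of the
panel's CpG sites.  CHH sites are attached to the block whose span contains
them, else to the nearest block within the same panel region; they carry
the conversion-failure signal, not methylation signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence
import warnings

import numpy as np
import pandas as pd

from .io import PanelRegion


@dataclass(frozen=True)
class BlockParams:
    """Gates of the adjacent-pair co-methylation rule.

    The published segmentation was trained on multi-tissue panel data whose
    coefficients are unavailable, so all three gates are explicit,
    user-settable thresholds.
    """

    r_min: float = 0.5
    d_max_bp: int = 500
    level_diff_max: float = 0.3
    min_sites: int = 1
    min_samples: int = 3  # pairwise-complete samples required for a correlation

    def __post_init__(self):
        if not -1 <= self.r_min <= 1:
            raise ValueError("r_min must be in [-1, 1]")
        if self.d_max_bp <= 0:
            raise ValueError("d_max_bp must be positive")


@dataclass(frozen=True)
class MethylationBlock:
    """A contiguous run of co-methylated CpG sites (0-based half-open span)."""

    block_id: str
    chrom: str
    start: int
    end: int
    cpg_positions: tuple[int, ...]  # 1-based
    chh_positions: tuple[int, ...] = ()
    category: str | None = None  # promoter | exon | intron | intergenic
    genes: tuple[str, ...] = ()

    def __post_init__(self):
        if self.cpg_positions != tuple(sorted(self.cpg_positions)):
            raise ValueError(f"block {self.block_id}: member positions not sorted")
        for p in self.cpg_positions:
            if not self.start <= p - 1 < self.end:
                raise ValueError(f"block {self.block_id}: position {p} outside span")

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_positions)


def site_fractions(records: pd.DataFrame, min_depth: int = 1):
    """Per-site methylation fractions across samples.

    *records* is a long site-count table with a ``sample_id`` column
    (CpG rows are used; context column optional).  Entries with depth below
    *min_depth* are missing (NaN).  Returns ``(fractions, sites)`` where
    *fractions* is a (site x sample) DataFrame and *sites* the matching
    (chrom, pos) frame.
    """
    df = records
    if "context" in df.columns:
        df = df[df["context"] == "CpG"]
    depth = df["meth_count"] + df["unmeth_count"]
    frac = np.where(depth >= max(min_depth, 1), df["meth_count"] / depth.replace(0, np.nan), np.nan)
    tmp = pd.DataFrame({
        "chrom": df["chrom"].astype(str),
        "pos": df["pos"].to_numpy(),
        "sample_id": df["sample_id"].astype(str),
        "frac": frac,
    })
    mat = tmp.pivot_table(index=["chrom", "pos"], columns="sample_id", values="frac", dropna=False)
    mat = mat.sort_index()
    sites = mat.index.to_frame(index=False)
    mat = mat.reset_index(drop=True)
    mat.columns.name = None
    return mat, sites


def adjacent_pair_scores(
    fractions: pd.DataFrame,
    sites: pd.DataFrame,
    panel: Sequence[PanelRegion] | None = None,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Score every consecutive CpG pair within a panel region.

    Returns a DataFrame with columns ``left, right`` (row indices into
    *sites*), ``pearson_r, distance_bp, level_diff, same_region``.  Pairs on
    different chromosomes or in different panel regions get
    ``same_region=False`` and are never merged downstream.
    """
    vals = fractions.to_numpy(dtype=float)
    n = len(sites)
    if n < 2:
        return pd.DataFrame(
            columns=["left", "right", "pearson_r", "distance_bp", "level_diff", "same_region"]
        )
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    region_idx = _region_index(sites, panel)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(vals, axis=1)

    X, Y = vals[:-1], vals[1:]
    ok = ~(np.isnan(X) | np.isnan(Y))
    cnt = ok.sum(axis=1)
    Xm = np.where(ok, X, 0.0)
    Ym = np.where(ok, Y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sx, sy = Xm.sum(1), Ym.sum(1)
        cov = (Xm * Ym).sum(1) - sx * sy / cnt
        varx = (Xm * Xm).sum(1) - sx ** 2 / cnt
        vary = (Ym * Ym).sum(1) - sy ** 2 / cnt
        r = cov / np.sqrt(varx * vary)
    r = np.where((cnt >= min_samples) & (varx > 1e-300) & (vary > 1e-300), r, np.nan)

    same = (chrom[:-1] == chrom[1:]) & (region_idx[:-1] == region_idx[1:]) & (region_idx[:-1] >= 0)
    dist = np.where(chrom[:-1] == chrom[1:], pos[1:] - pos[:-1], -1)
    level = np.abs(means[1:] - means[:-1])
    return pd.DataFrame({
        "left": np.arange(n - 1),
        "right": np.arange(1, n),
        "pearson_r": np.where(same, r, np.nan),
        "distance_bp": dist.astype(int),
        "level_diff": np.where(same, level, np.nan),
        "same_region": same,
    })


def _region_index(sites: pd.DataFrame, panel: Sequence[PanelRegion] | None) -> np.ndarray:
    """Panel-region index of each site; -1 if outside the panel.

    With no panel given, each chromosome is one region.
    """
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    if panel is None:
        _, idx = np.unique(chrom, return_inverse=True)
        return idx
    out = np.full(len(sites), -1, dtype=int)
    for ri, r in enumerate(panel):
        inside = (chrom == r.chrom) & (pos - 1 >= r.start) & (pos - 1 < r.end)
        out[inside] = ri
    return out


def segment_blocks(
    scores: pd.DataFrame,
    sites: pd.DataFrame,
    params: BlockParams = BlockParams(),
    chh_sites: pd.DataFrame | None = None,
    panel: Sequence[PanelRegion] | None = None,
    id_prefix: str = "block",
) -> list[MethylationBlock]:
    """Greedy scan grouping consecutive CpG sites into methylation blocks.

    A pair extends the current block iff its Pearson correlation, genomic
    distance and mean-level difference all pass :class:`BlockParams`; a
    missing correlation never extends.  *chh_sites* (chrom/pos frame), if
    given, are attached to the covering or nearest block of the same panel
    region.  The returned blocks partition the CpG sites.
    """
    n = len(sites)
    if n == 0:
        return []
    extend = np.zeros(max(n - 1, 0), dtype=bool)
    if len(scores):
        left = scores["left"].to_numpy(dtype=int)
        r = scores["pearson_r"].to_numpy(dtype=float)
        dist = scores["distance_bp"].to_numpy(dtype=int)
        level = scores["level_diff"].to_numpy(dtype=float)
        same = scores["same_region"].to_numpy(dtype=bool)
        with np.errstate(invalid="ignore"):
            ok = (
                same
                & np.isfinite(r) & (r >= params.r_min)
                & (dist > 0) & (dist <= params.d_max_bp)
                & np.isfinite(level) & (level <= params.level_diff_max)
            )
        extend[left[ok]] = True

    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()

    groups: list[list[int]] = [[0]]
    for i in range(1, n):
        if extend[i - 1]:
            groups[-1].append(i)
        else:
            groups.append([i])

    width = max(4, len(str(len(groups))))
    blocks = []
    for gi, g in enumerate(groups):
        p = pos[g]
        blocks.append(
            MethylationBlock(
                block_id=f"{id_prefix}{gi:0{width}d}",
                chrom=str(chrom[g[0]]),
                start=int(p.min() - 1),
                end=int(p.max()),
                cpg_positions=tuple(int(x) for x in p),
            )
        )
    if chh_sites is not None and len(chh_sites):
        blocks = attach_chh_sites(blocks, chh_sites, panel)
    return blocks


def attach_chh_sites(
    blocks: Sequence[MethylationBlock],
    chh_sites: pd.DataFrame,
    panel: Sequence[PanelRegion] | None = None,
) -> list[MethylationBlock]:
    """Assign each CHH site to the covering block, else the nearest block in
    the same panel region (ties to the left)."""
    sites = chh_sites[["chrom", "pos"]].reset_index(drop=True)
    region_idx = _region_index(sites, panel)
    block_region = _region_index(
        pd.DataFrame({"chrom": [b.chrom for b in blocks], "pos": [b.start + 1 for b in blocks]}),
        panel,
    )
    assigned: dict[int, list[int]] = {i: [] for i in range(len(blocks))}
    for si in range(len(sites)):
        c, p = sites.at[si, "chrom"], int(sites.at[si, "pos"])
        best, best_d = None, None
        for bi, b in enumerate(blocks):
            if b.chrom != c:
                continue
            if panel is not None and block_region[bi] != region_idx[si]:
                continue
            if b.start <= p - 1 < b.end:
                best, best_d = bi, 0
                break
            d = min(abs(p - 1 - b.start), abs(p - b.end))
            if best_d is None or d < best_d:
                best, best_d = bi, d
        if best is not None:
            assigned[best].append(p)
    return [
        replace(b, chh_positions=tuple(sorted(assigned[bi])))
        for bi, b in enumerate(blocks)
    ]


def build_blocks(
    records: pd.DataFrame,
    params: BlockParams = BlockParams(),
    panel: Sequence[PanelRegion] | None = None,
    min_depth: int = 1,
) -> list[MethylationBlock]:
    """Convenience: fractions -> pair scores -> segmentation -> CHH attachment."""
    fracs, sites = site_fractions(records, min_depth=min_depth)
    scores = adjacent_pair_scores(fracs, sites, panel, min_samples=params.min_samples)
    chh = records[records["context"] == "CHH"][["chrom", "pos"]].drop_duplicates()
    return segment_blocks(scores, sites, params, chh_sites=chh, panel=panel)


# ---------------------------------------------------------------------------
# annotation

@dataclass(frozen=True)
class Transcript:
    """Minimal transcript model for block annotation (0-based half-open)."""

    gene: str
    chrom: str
    start: int
    end: int
    strand: str
    exon_starts: tuple[int, ...] = ()
    exon_ends: tuple[int, ...] = ()

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


CATEGORY_PRIORITY = ("promoter", "exon", "intron", "intergenic")


def annotate_blocks(
    blocks: Sequence[MethylationBlock],
    transcripts: Sequence[Transcript],
    promoter_upstream: int = 2000,
    promoter_downstream: int = 500,
) -> list[MethylationBlock]:
    """Label each block promoter / exon / intron / intergenic and record genes.

    Promoter windows are [TSS - upstream, TSS + downstream) on the plus
    strand and mirrored on the minus strand.  On any overlap the priority is
    promoter > exon > intron; all overlapping gene names are recorded.
    Blocks on chromosomes absent from the gene model are intergenic (with a
    warning).
    """
    from intervaltree import IntervalTree

    trees: dict[str, dict[str, IntervalTree]] = {}

    def _add(chrom, kind, start, end, gene):
        if start >= end:
            return
        trees.setdefault(chrom, {}).setdefault(kind, IntervalTree()).addi(start, end, gene)

    for t in transcripts:
        if t.strand == "+":
            pstart, pend = t.tss - promoter_upstream, t.tss + promoter_downstream
        else:
            pstart, pend = t.tss - promoter_downstream + 1, t.tss + promoter_upstream + 1
        _add(t.chrom, "promoter", max(pstart, 0), pend, t.gene)
        exons = list(zip(t.exon_starts, t.exon_ends)) or [(t.start, t.end)]
        for es, ee in exons:
            _add(t.chrom, "exon", es, ee, t.gene)
        _add(t.chrom, "intron", t.start, t.end, t.gene)  # introns = gene body minus exons, via priority

    known_chroms = {t.chrom for t in transcripts}
    out = []
    warned = set()
    for b in blocks:
        if b.chrom not in known_chroms:
            if b.chrom not in warned:
                warnings.warn(f"chromosome {b.chrom} absent from gene model; blocks labeled intergenic")
                warned.add(b.chrom)
            out.append(replace(b, category="intergenic", genes=()))
            continue
        chrom_trees = trees.get(b.chrom, {})
        category = "intergenic"
        genes: set[str] = set()
        for kind in ("promoter", "exon", "intron"):
            tree = chrom_trees.get(kind)
            hits = tree.overlap(b.start, b.end) if tree is not None else ()
            if hits and category == "intergenic":
                category = kind
            genes.update(h.data for h in hits)
        out.append(replace(b, category=category, genes=tuple(sorted(genes))))
    return out


def read_gene_model_bed12(path) -> list[Transcript]:
    """Read transcripts from BED12 (name column = gene symbol)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}: line {ln}: expected 12 BED fields, got {len(f)}")
            start = int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exon_starts = tuple(start + o for o in offsets)
            exon_ends = tuple(s + z for s, z in zip(exon_starts, sizes))
            out.append(
                Transcript(
                    gene=f[3], chrom=f[0], start=start, end=int(f[2]), strand=f[5],
                    exon_starts=exon_starts, exon_ends=exon_ends,
                )
            )
    return out


def blocks_to_frame(blocks: Sequence[MethylationBlock]) -> pd.DataFrame:
    """Flatten blocks to a TSV-friendly table (positions comma-joined)."""
    return pd.DataFrame(
        {
            "block_id": [b.block_id for b in blocks],
            "chrom": [b.chrom for b in blocks],
            "start": [b.start for b in blocks],
            "end": [b.end for b in blocks],
            "n_cpg": [b.n_cpg for b in blocks],
            "cpg_positions": [",".join(map(str, b.cpg_positions)) for b in blocks],
            "chh_positions": [",".join(map(str, b.chh_positions)) for b in blocks],
            "category": [b.category or "" for b in blocks],
            "genes": [",".join(b.genes) for b in blocks],
        }
    )


def blocks_from_frame(df: pd.DataFrame) -> list[MethylationBlock]:
    out = []
    for _, r in df.iterrows():
        def _ints(v):
            if pd.isna(v) or v == "":
                return ()
            return tuple(int(x) for x in str(v).split(","))

        genes = () if pd.isna(r.get("genes")) or r.get("genes", "") == "" else tuple(str(r["genes"]).split(","))
        cat = r.get("category")
        out.append(
            MethylationBlock(
                block_id=str(r["block_id"]), chrom=str(r["chrom"]),
                start=int(r["start"]), end=int(r["end"]),
                cpg_positions=_ints(r["cpg_positions"]),
                chh_positions=_ints(r.get("chh_positions", "")),
                category=None if cat is None or pd.isna(cat) or cat == "" else str(cat),
                genes=genes,
            )
        )
    return out
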