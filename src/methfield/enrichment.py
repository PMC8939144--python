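"""Gene-set over-representation of DMR genes by the exact hypergeometric test.

The enrichment unit is the gene, not the block: a gene hit by several DMR
blocks counts once.  With a universe of N genes (the genes spanned by the
panel's blocks), K of which belong to the set of interest (e.g.
transcription factors), and a query of n DMR genes overlapping the set in
k, the over-representation p-value is the inclusive upper tail

    P(X >= k),  X ~ Hypergeometric(N, K, n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats


@dataclass(frozen=True)
class EnrichmentResult:
    universe_size: int  # N
    set_size_in_universe: int  # K
    query_size: int  # n
    overlap: int  # k
    p_hypergeom: float
    fold_enrichment: float


def map_dmrs_to_genes(dmr_block_ids: Iterable[str], gene_map: Mapping[str, Sequence[str]]) -> list[str]:
    """Deduplicated, sorted union of gene names over DMR blocks.

    *gene_map* maps block_id to its annotated gene names; blocks with no
    genes (or absent from the map) are skipped.
    """
    genes: set[str] = set()
    for bid in dmr_block_ids:
        genes.update(g for g in gene_map.get(bid, ()) if g)
    return sorted(genes)


def hypergeometric_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), inclusive.

    Computed through the survival function of :data:`scipy.stats.hypergeom`,
    which works on log-gamma terms and is stable far into the tail.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K <= N and 0 <= n <= N, got N={N}, K={K}, n={n}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"require 0 <= k <= min(K, n), got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def test_enrichment(
    query_genes: Iterable[str],
    universe_genes: Iterable[str],
    set_genes: Iterable[str],
) -> EnrichmentResult:
    """Over-representation of *set_genes* among *query_genes* within a universe.

    Query genes outside the universe are dropped with a warning; set genes
    outside the universe do not count toward K.
    """
    universe = set(universe_genes)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query_genes)
    outside = query - universe
    if outside:
        warnings.warn(f"{len(outside)} query gene(s) outside the universe dropped")
        query &= universe
    members = set(set_genes) & universe

    N, K, n = len(universe), len(members), len(query)
    k = len(query & members)
    p = hypergeometric_upper_tail(N, K, n, k)
    fold = (k / n) / (K / N) if n > 0 and K > 0 else float("nan")
    return EnrichmentResult(N, K, n, k, p, fold)


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
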