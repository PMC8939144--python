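"""Synthetic matched-trio bisulfite datasets with planted truth.

The generator emulates the statistical structure of a targeted bisulfite
study of matched TUM / ADJ / DIS tissue trios:

* each methylation block b has a baseline fraction mu_b drawn from a
  two-component Beta mixture (mostly-unmethylated and mostly-methylated
  blocks);
* planted effect classes move the class/tissue target on the fraction
  scale: ``tumor_hyper``/``tumor_hypo`` shift only TUM by +-delta_tumor,
  ``fc_up``/``fc_down`` are stepwise fields with ADJ exactly midway
  (DIS = mu, ADJ = mu +- delta_fc/2, TUM = mu +- delta_fc);
* patient heterogeneity is a logit-scale random effect shared by the three
  tissues of a patient (so it cancels in paired contrasts);
* per-site read depth is negative binomial, and methylated counts are
  beta-binomial with intra-class correlation rho;
* bisulfite conversion failure is a per-sample rate e_s: every truly
  unmethylated cytosine reads methylated with probability e_s, so the
  observed fraction is e_s + (1 - e_s) * pi.  CHH sites have true pi = 0
  and therefore read out e_s — exactly the background that the corrected
  methylMean inverts.

Everything is drawn from a single :func:`numpy.random.default_rng` stream
in a fixed order (block-level draws, then site layout, then sample-level
draws, then read counts), so a config plus seed reproduces the dataset
byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import PanelRegion, SampleRecord, TISSUES, SITE_COLUMNS
from .segmentation import MethylationBlock
from .quantify import BlockMatrix, assemble_matrix

EFFECT_CLASSES = ("null", "tumor_hyper", "tumor_hypo", "fc_up", "fc_down")

#: margin kept between any planted target mean and the [0, 1] boundary
_MARGIN = 0.02
_TARGET_CLIP = 1e-3


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic trio dataset.

    Defaults mirror the profiled cohort: 36 complete trios, negative-
    binomial depth around 60x, a small per-sample conversion-failure rate,
    and planted effect counts roughly proportional to the reported DMR
    yield at a desk-scale block count of 1000.
    """

    n_patients: int = 36
    n_blocks: int = 1000
    sites_per_block: tuple[int, int] = (3, 12)
    chh_per_block: tuple[int, int] = (1, 4)
    depth_mean: float = 60.0
    depth_dispersion: float = 5.0
    baseline_betas: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 10.0), (10.0, 1.0))
    baseline_weights: tuple[float, float] = (0.7, 0.3)
    n_tumor_hyper: int = 200
    n_tumor_hypo: int = 10
    n_fc_up: int = 40
    n_fc_down: int = 5
    delta_tumor: float = 0.25
    delta_fc: float = 0.15
    patient_sd: float = 0.3
    rho: float = 0.05
    conversion_failure_range: tuple[float, float] = (0.002, 0.02)
    seed: int = 0

    def __post_init__(self):
        planted = self.n_tumor_hyper + self.n_tumor_hypo + self.n_fc_up + self.n_fc_down
        if planted > self.n_blocks:
            raise ValueError(
                f"planted effect counts ({planted}) exceed n_blocks ({self.n_blocks})"
            )
        if self.n_patients < 1 or self.n_blocks < 1:
            raise ValueError("n_patients and n_blocks must be positive")
        for name, (lo, hi) in (("sites_per_block", self.sites_per_block), ("chh_per_block", self.chh_per_block)):
            if lo > hi or lo < (1 if name == "sites_per_block" else 0):
                raise ValueError(f"bad {name} range ({lo}, {hi})")
        for name, v in (("delta_tumor", self.delta_tumor), ("delta_fc", self.delta_fc)):
            if not 0 <= v <= 1 - 2 * _MARGIN:
                raise ValueError(f"{name} must lie in [0, {1 - 2 * _MARGIN}]")
        lo, hi = self.conversion_failure_range
        if not 0 <= lo <= hi < 1:
            raise ValueError("conversion_failure_range must satisfy 0 <= lo <= hi < 1")
        if not 0 <= self.rho < 1:
            raise ValueError("rho (beta-binomial intra-class correlation) must be in [0, 1)")
        if self.depth_dispersion <= 0 or self.depth_mean <= 0:
            raise ValueError("depth parameters must be positive")


@dataclass
class SimulatedDataset:
    """Output bundle of :func:`simulate_dataset`."""

    records: pd.DataFrame  # long site-count table with sample_id
    manifest: list[SampleRecord]
    truth: pd.DataFrame  # block_id, effect_class, mu_baseline, pi_DIS/ADJ/TUM
    panel: list[PanelRegion]
    blocks: list[MethylationBlock]  # the true (generating) blocks
    config: SimulationConfig


# tissue -> column of the target array (ordered by distance from the tumor)
_TCOL = {"DIS": 0, "ADJ": 1, "TUM": 2}


class _Draw:
    """Internal container for all random draws of one simulation."""

    __slots__ = (
        "classes", "mu", "targets", "n_sites", "n_chh",
        "cpg_pos", "cpg_block", "chh_pos", "chh_block",
        "panel", "block_ids", "manifest", "e_s",
        "depth_cpg", "m_cpg", "depth_chh", "m_chh",
    )


def _draw_baselines(rng, cfg, n, lo, hi):
    """Mixture baselines redrawn until they (and the planted shift) fit in
    [lo, hi]; deterministic given the stream position."""
    (a0, b0), (a1, b1) = cfg.baseline_betas
    w0 = cfg.baseline_weights[0] / sum(cfg.baseline_weights)

    def draw(k):
        comp = rng.random(k) < w0
        return np.where(comp, rng.beta(a0, b0, k), rng.beta(a1, b1, k))

    mu = draw(n)
    for _ in range(1000):
        bad = (mu < lo) | (mu > hi)
        if not bad.any():
            return mu
        mu[bad] = draw(int(bad.sum()))
    raise RuntimeError("baseline redraw did not converge; check effect sizes")


def _simulate_arrays(cfg: SimulationConfig) -> _Draw:
    rng = np.random.default_rng(cfg.seed)
    nb, npat = cfg.n_blocks, cfg.n_patients
    nsamp = npat * len(TISSUES)
    d = _Draw()

    # --- block-level draws -------------------------------------------------
    labels = (
        ["tumor_hyper"] * cfg.n_tumor_hyper
        + ["tumor_hypo"] * cfg.n_tumor_hypo
        + ["fc_up"] * cfg.n_fc_up
        + ["fc_down"] * cfg.n_fc_down
    )
    labels += ["null"] * (nb - len(labels))
    classes = np.array(labels, dtype=object)[rng.permutation(nb)]
    d.classes = classes

    shift = np.zeros(nb)
    shift[classes == "tumor_hyper"] = cfg.delta_tumor
    shift[classes == "tumor_hypo"] = -cfg.delta_tumor
    shift[classes == "fc_up"] = cfg.delta_fc
    shift[classes == "fc_down"] = -cfg.delta_fc

    mu = np.empty(nb)
    for s in np.unique(shift):
        sel = shift == s
        lo = max(_MARGIN, _MARGIN - s)
        hi = min(1 - _MARGIN, 1 - _MARGIN - s)
        if s == 0:  # null blocks: unrestricted mixture draw
            lo, hi = 0.0, 1.0
        mu[sel] = _draw_baselines(rng, cfg, int(sel.sum()), lo, hi)
    d.mu = mu

    targets = np.stack([mu, mu + shift / 2, mu + shift], axis=1)  # DIS, ADJ, TUM
    targets[classes == "tumor_hyper"] = np.stack(
        [mu, mu, mu + cfg.delta_tumor], axis=1
    )[classes == "tumor_hyper"]
    targets[classes == "tumor_hypo"] = np.stack(
        [mu, mu, mu - cfg.delta_tumor], axis=1
    )[classes == "tumor_hypo"]
    d.targets = np.clip(targets, _TARGET_CLIP, 1 - _TARGET_CLIP)

    d.n_sites = rng.integers(cfg.sites_per_block[0], cfg.sites_per_block[1] + 1, nb)
    d.n_chh = rng.integers(cfg.chh_per_block[0], cfg.chh_per_block[1] + 1, nb)

    # --- site layout (one panel region per block on chr1) ------------------
    total_cpg = int(d.n_sites.sum())
    total_chh = int(d.n_chh.sum())
    region_origin = np.arange(nb, dtype=np.int64) * 4000  # 0-based region anchors
    d.cpg_block = np.repeat(np.arange(nb), d.n_sites)
    sp = rng.integers(15, 46, total_cpg)
    first_idx = np.concatenate([[0], np.cumsum(d.n_sites)[:-1]])
    sp[first_idx] = 0
    cs = np.cumsum(sp)
    within = cs - np.repeat(cs[first_idx], d.n_sites)
    d.cpg_pos = region_origin[d.cpg_block] + 101 + within  # 1-based

    last_cpg = np.zeros(nb, dtype=np.int64)
    np.maximum.at(last_cpg, d.cpg_block, d.cpg_pos)
    d.chh_block = np.repeat(np.arange(nb), d.n_chh)
    if total_chh:
        chh_rank = np.arange(total_chh) - np.repeat(
            np.concatenate([[0], np.cumsum(d.n_chh)[:-1]]), d.n_chh
        )
        d.chh_pos = last_cpg[d.chh_block] + 3 * (chh_rank + 1)
    else:
        d.chh_pos = np.zeros(0, dtype=np.int64)

    span_end = last_cpg.copy()
    if total_chh:
        np.maximum.at(span_end, d.chh_block, d.chh_pos)
    width = max(5, len(str(nb)))
    d.block_ids = [f"block{i:0{width}d}" for i in range(nb)]
    d.panel = [
        PanelRegion("chr1", int(region_origin[i] + 50), int(span_end[i] + 50), d.block_ids[i])
        for i in range(nb)
    ]

    # --- sample-level draws -------------------------------------------------
    pad = len(str(npat))
    d.manifest = [
        SampleRecord(patient_id=f"P{p + 1:0{pad}d}", tissue=t, path="", tumor_cell_fraction=0.6 if t == "TUM" else None)
        for p in range(npat)
        for t in TISSUES
    ]
    lo, hi = cfg.conversion_failure_range
    d.e_s = rng.uniform(lo, hi, nsamp) if hi > lo else np.full(nsamp, lo)
    patient_effect = rng.normal(0.0, cfg.patient_sd, (nb, npat))

    tcol = np.array([_TCOL[s.tissue] for s in d.manifest])
    pidx = np.array([i // len(TISSUES) for i in range(nsamp)])
    target_bs = d.targets[:, tcol]  # (nb, nsamp)
    pi = expit(logit(target_bs) + patient_effect[:, pidx])

    # --- read counts --------------------------------------------------------
    r = cfg.depth_dispersion
    p_nb = r / (r + cfg.depth_mean)
    d.depth_cpg = rng.negative_binomial(r, p_nb, (total_cpg, nsamp))
    d.depth_chh = rng.negative_binomial(r, p_nb, (total_chh, nsamp))

    pi_obs = d.e_s[None, :] + (1 - d.e_s[None, :]) * pi[d.cpg_block, :]
    d.m_cpg = _beta_binomial(rng, d.depth_cpg, pi_obs, cfg.rho)
    pi_obs_chh = np.broadcast_to(d.e_s[None, :], (total_chh, nsamp))
    d.m_chh = _beta_binomial(rng, d.depth_chh, pi_obs_chh, cfg.rho)
    return d


def _beta_binomial(rng, depth: np.ndarray, mean: np.ndarray, rho: float) -> np.ndarray:
    """Beta-binomial counts with mean fraction *mean* and ICC *rho*."""
    mean = np.broadcast_to(mean, depth.shape)
    if rho <= 0:
        return rng.binomial(depth, mean)
    scale = (1 - rho) / rho
    a = np.clip(mean * scale, 1e-12, None)
    b = np.clip((1 - mean) * scale, 1e-12, None)
    # beta via two gammas in float32: ~4x faster than rng.beta and accurate
    # far beyond the read-count resolution it feeds
    g1 = rng.standard_gamma(a.astype(np.float32), dtype=np.float32)
    g2 = rng.standard_gamma(b.astype(np.float32), dtype=np.float32)
    with np.errstate(invalid="ignore"):
        p = (g1 / (g1 + g2)).astype(np.float64)
    p = np.where(mean <= 0, 0.0, np.where(mean >= 1, 1.0, p))
    p = np.nan_to_num(p, nan=0.0)
    return rng.binomial(depth, np.clip(p, 0.0, 1.0))


def _truth_frame(d: _Draw) -> pd.DataFrame:
    return pd.DataFrame({
        "block_id": d.block_ids,
        "effect_class": d.classes.astype(str),
        "mu_baseline": d.mu,
        "pi_DIS": d.targets[:, 0],
        "pi_ADJ": d.targets[:, 1],
        "pi_TUM": d.targets[:, 2],
    })


def _true_blocks(d: _Draw) -> list[MethylationBlock]:
    nb = len(d.block_ids)
    cpg_by_block: list[list[int]] = [[] for _ in range(nb)]
    for b, p in zip(d.cpg_block, d.cpg_pos):
        cpg_by_block[b].append(int(p))
    chh_by_block: list[list[int]] = [[] for _ in range(nb)]
    for b, p in zip(d.chh_block, d.chh_pos):
        chh_by_block[b].append(int(p))
    return [
        MethylationBlock(
            block_id=d.block_ids[i],
            chrom="chr1",
            start=min(cpg_by_block[i]) - 1,
            end=max(cpg_by_block[i]),
            cpg_positions=tuple(cpg_by_block[i]),
            chh_positions=tuple(chh_by_block[i]),
        )
        for i in range(nb)
    ]


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full synthetic trio dataset with ground truth.

    Records are emitted strand-collapsed (one plus-strand unit per CpG) in
    a long table sorted by sample then position.
    """
    d = _simulate_arrays(config)
    nsamp = len(d.manifest)

    pos_all = np.concatenate([d.cpg_pos, d.chh_pos])
    ctx_all = np.concatenate([
        np.zeros(len(d.cpg_pos), dtype=np.int8),
        np.ones(len(d.chh_pos), dtype=np.int8),
    ])
    m_all = np.concatenate([d.m_cpg, d.m_chh], axis=0)
    depth_all = np.concatenate([d.depth_cpg, d.depth_chh], axis=0)
    order = np.argsort(pos_all, kind="stable")
    pos_all, ctx_all = pos_all[order], ctx_all[order]
    m_all, depth_all = m_all[order], depth_all[order]

    n_sites_total = len(pos_all)
    sample_ids = [s.sample_id for s in d.manifest]
    records = pd.DataFrame({
        "chrom": pd.Categorical(["chr1"] * (n_sites_total * nsamp)),
        "pos": np.tile(pos_all, nsamp),
        "strand": pd.Categorical(["+"] * (n_sites_total * nsamp)),
        "context": pd.Categorical.from_codes(
            np.tile(ctx_all, nsamp), categories=["CpG", "CHH"]
        ),
        "meth_count": m_all.ravel(order="F").astype(np.int64),
        "unmeth_count": (depth_all - m_all).ravel(order="F").astype(np.int64),
        "sample_id": pd.Categorical.from_codes(
            np.repeat(np.arange(nsamp), n_sites_total), categories=sample_ids
        ),
    })[SITE_COLUMNS + ["sample_id"]]

    return SimulatedDataset(
        records=records,
        manifest=d.manifest,
        truth=_truth_frame(d),
        panel=d.panel,
        blocks=_true_blocks(d),
        config=config,
    )


def simulate_block_matrix(
    config: SimulationConfig,
    min_depth: int = 5,
    min_chh_reads: int = 20,
    error_mode: str = "block",
    correct: bool = True,
):
    """Draw a dataset and aggregate it straight to a :class:`BlockMatrix`.

    Identical draws to :func:`simulate_dataset` (same seed, same stream),
    skipping the long-table materialisation; used for large calibration
    runs.  Returns ``(matrix, truth)``.
    """
    d = _simulate_arrays(config)
    nb = config.n_blocks

    def _sums(m, depth, block_idx, n_per_block):
        ok = depth >= min_depth
        mm = np.where(ok, m, 0)
        uu = np.where(ok, depth - m, 0)
        starts = np.concatenate([[0], np.cumsum(n_per_block)[:-1]])
        ends = starts + n_per_block
        czm = np.vstack([np.zeros((1, mm.shape[1])), np.cumsum(mm, axis=0)])
        czu = np.vstack([np.zeros((1, uu.shape[1])), np.cumsum(uu, axis=0)])
        return czm[ends] - czm[starts], czu[ends] - czu[starts]

    sum_m, sum_u = _sums(d.m_cpg, d.depth_cpg, d.cpg_block, d.n_sites)
    if len(d.chh_pos):
        sum_me, sum_ue = _sums(d.m_chh, d.depth_chh, d.chh_block, d.n_chh)
    else:
        sum_me = np.zeros_like(sum_m)
        sum_ue = np.zeros_like(sum_u)

    matrix = assemble_matrix(
        sum_m, sum_u, sum_me, sum_ue, d.block_ids, d.manifest,
        min_chh_reads=min_chh_reads, error_mode=error_mode, correct=correct,
    )
    return matrix, _truth_frame(d)


def synthetic_gene_model(
    blocks: Sequence[MethylationBlock],
    seed: int = 0,
    annotated_fraction: float = 0.84,
    tf_fraction: float = 0.146,
    genes_per_block: float = 1 / 3.2,
):
    """Synthetic transcript model and TF list covering the simulated panel.

    A stand-in for a real gene annotation, built so that roughly
    *annotated_fraction* of blocks fall in genes, consecutive blocks share
    genes (about 1/genes_per_block blocks per gene), and *tf_fraction* of
    genes are tagged as transcription factors.  Returns
    ``(transcripts, tf_genes)``.
    """
    from .segmentation import Transcript

    rng = np.random.default_rng(seed)
    transcripts: list[Transcript] = []
    gene_blocks: list[list[MethylationBlock]] = []
    current: list[MethylationBlock] = []
    for b in blocks:
        if rng.random() > annotated_fraction:
            continue
        if current and rng.random() < genes_per_block:
            gene_blocks.append(current)
            current = []
        current.append(b)
    if current:
        gene_blocks.append(current)

    pad = len(str(max(len(gene_blocks), 1)))
    for gi, gb in enumerate(gene_blocks):
        name = f"GENE{gi + 1:0{pad}d}"
        start = max(gb[0].start - 100, 0)
        end = gb[-1].end + 2500
        exon_starts = tuple(b.start for b in gb)
        exon_ends = tuple(b.end for b in gb)
        transcripts.append(
            Transcript(gene=name, chrom=gb[0].chrom, start=start, end=end,
                       strand="+", exon_starts=exon_starts, exon_ends=exon_ends)
        )
    names = [t.gene for t in transcripts]
    n_tf = int(round(tf_fraction * len(names)))
    tf_genes = sorted(rng.choice(names, size=n_tf, replace=False)) if n_tf else []
    return transcripts, [str(g) for g in tf_genes]


def truth_summary(truth: pd.DataFrame) -> pd.DataFrame:
    """Per-class planted counts and mean effect sizes."""
    if truth.empty:
        raise ValueError("empty truth table")
    g = truth.groupby("effect_class")
    out = pd.DataFrame({
        "n_blocks": g.size(),
        "mean_baseline": g["mu_baseline"].mean(),
        "mean_adj_minus_dis": (g.apply(lambda x: (x["pi_ADJ"] - x["pi_DIS"]).mean(), include_groups=False)),
        "mean_tum_minus_adj": (g.apply(lambda x: (x["pi_TUM"] - x["pi_ADJ"]).mean(), include_groups=False)),
        "mean_tum_minus_dis": (g.apply(lambda x: (x["pi_TUM"] - x["pi_DIS"]).mean(), include_groups=False)),
    })
    return out.reset_index().sort_values("effect_class").reset_index(drop=True)
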