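"""Tumor-specific and field-cancerization DMR calling.

Tumor-specific DMRs contrast TUM against DIS with a variance-moderated
paired t-test per block; a block is emitted when both the effect-size gate
|log2FC| > 0.1 (log2 of offset group-mean ratio) and the significance gate
adjusted p < 0.05 pass.  Field-cancerization (FC) DMRs require a strict
stepwise gradient across the trio: both adjacent paired contrasts
(ADJ - DIS and TUM - ADJ) significant in the same direction, with group
means strictly monotone DIS < ADJ < TUM (fc_up) or the exact reverse
(fc_down).  Within a block the three contrasts are Bonferroni-corrected;
across blocks the adjustment method is configurable (BH by default).

Variance moderation shrinks each block's paired-difference variance toward
a scaled inverse-chi-square prior fitted across blocks by matching moments
of the log sample variances (the empirical-Bayes scheme familiar from
limma); d0 = 0 disables moderation and d0 = inf pools completely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import special, stats

from .quantify import BlockMatrix

TUMOR_COMPARISON = "TUM_vs_DIS"
FC_COMPARISONS = (("ADJ", "DIS"), ("TUM", "ADJ"), ("TUM", "DIS"))


@dataclass(frozen=True)
class PairedTestResult:
    mean_diff: float
    t_stat: float
    df: float
    p_value: float
    n_pairs: int
    degenerate: bool = False


@dataclass(frozen=True)
class ModerationParams:
    """Scaled inverse-chi-square variance prior: d0 prior df, s0_sq prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self):
        if self.d0 < 0:
            raise ValueError("prior df must be >= 0")
        if self.d0 > 0 and not self.s0_sq > 0:
            raise ValueError("prior variance must be positive when d0 > 0")


@dataclass(frozen=True)
class Thresholds:
    """Gates and conventions for DMR calling."""

    log2fc_min: float = 0.1
    adj_p_max: float = 0.05
    adjust_method: str = "BH"  # across-block adjustment: BH | bonferroni
    value_transform: str = "log2_offset"  # scale on which paired tests run
    offset_eps: float = 0.01
    moderate: bool = True
    min_pairs: int = 3

    def __post_init__(self):
        if self.log2fc_min <= 0 or not 0 < self.adj_p_max <= 1:
            raise ValueError("thresholds must be positive")
        if self.adjust_method not in ("BH", "bonferroni"):
            raise ValueError("adjust_method must be 'BH' or 'bonferroni'")
        if self.value_transform not in ("log2_offset", "identity"):
            raise ValueError("value_transform must be 'log2_offset' or 'identity'")

    def transform(self, values):
        if self.value_transform == "identity":
            return values
        return np.log2(values + self.offset_eps)


def paired_t_test(x: Sequence[float], y: Sequence[float], min_pairs: int = 3) -> PairedTestResult | None:
    """Classical paired t-test on x - y; pairs with a missing value drop out.

    Returns ``None`` with fewer than *min_pairs* complete pairs.  Zero
    variance gives t = 0, p = 1 when the mean difference is zero, else a
    degenerate p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < min_pairs:
        return None
    diff = x[ok] - y[ok]
    # same reduction expressions as the matrix path so that moderation with
    # d0 = 0 reproduces this test bitwise
    mean = float(np.nanmean(diff))
    s2 = float(np.nanvar(diff, ddof=1))
    df = n - 1
    if s2 == 0:
        if mean == 0:
            return PairedTestResult(0.0, 0.0, df, 1.0, n)
        return PairedTestResult(mean, math.inf if mean > 0 else -math.inf, df, 0.0, n, degenerate=True)
    t = mean / np.sqrt(s2 / n)
    p = 2 * stats.t.sf(abs(t), df)
    return PairedTestResult(mean, float(t), df, float(p), n)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) / x < 1e-8:
            break
    return float(x)


def fit_variance_prior(sample_variances, residual_df) -> ModerationParams:
    """Fit (d0, s0_sq) by moment-matching the log sample variances.

    Under the scaled inverse-chi-square prior, s^2 / s0^2 follows an
    F(d, d0) distribution; matching the mean and variance of log s^2
    (digamma/trigamma moments) yields the prior.  All-equal variances give
    d0 = inf; fewer than two usable variances disable moderation (d0 = 0).
    """
    s2 = np.asarray(sample_variances, dtype=float)
    d = np.broadcast_to(np.asarray(residual_df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (d > 0)
    s2, d = s2[ok], d[ok]
    if len(s2) < 2:
        return ModerationParams(d0=0.0, s0_sq=float(s2[0]) if len(s2) else 1.0)
    if np.ptp(s2) == 0:  # literally constant: no sampling spread to model
        return ModerationParams(d0=math.inf, s0_sq=float(s2[0]))
    z = np.log(s2)
    e = z - special.digamma(d / 2) + np.log(d / 2)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(np.mean(special.polygamma(1, d / 2)))
    if e_var <= 0:
        return ModerationParams(d0=math.inf, s0_sq=float(np.exp(e_mean)))
    d0 = 2 * _trigamma_inverse(e_var)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return ModerationParams(d0=float(d0), s0_sq=s0_sq)


def moderated_paired_t(
    diff_matrix: pd.DataFrame,
    prior: ModerationParams | None = None,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Moderated paired t-test per row of a blocks x patients difference matrix.

    With prior (d0, s0^2) and per-block sample variance s^2 on d = n - 1 df,
    the posterior variance is s~^2 = (d0 s0^2 + d s^2) / (d0 + d) and
    t = mean / (s~ / sqrt(n)) on d + d0 df.  ``prior=None`` fits the prior
    on the matrix itself; d0 = 0 reduces to the ordinary paired t.

    Returns a DataFrame indexed like *diff_matrix* with columns
    mean_diff, s2, n, df, t, p, degenerate.
    """
    D = diff_matrix.to_numpy(dtype=float)
    n = (~np.isnan(D)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(D, axis=1)
        s2 = np.nanvar(D, axis=1, ddof=1)
    usable = n >= min_pairs
    d = np.where(n > 1, n - 1, np.nan).astype(float)

    if prior is None:
        prior = fit_variance_prior(s2[usable], d[usable])
    d0, s0 = prior.d0, prior.s0_sq

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.full_like(s2, math.inf)
    elif d0 == 0:  # moderation off: bitwise-identical to the ordinary paired t
        s2_post = s2
        df_total = d
    else:
        s2_post = (d0 * s0 + d * s2) / (d0 + d)
        df_total = d + d0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / np.sqrt(s2_post / n)
    p = 2 * stats.t.sf(np.abs(t), df_total)

    degenerate = usable & (s2_post == 0) & (mean != 0)
    zero = usable & (s2_post == 0) & (mean == 0)
    t = np.where(zero, 0.0, t)
    p = np.where(zero, 1.0, p)
    p = np.where(degenerate, 0.0, p)
    t = np.where(degenerate, np.where(mean > 0, np.inf, -np.inf), t)

    out = pd.DataFrame({
        "mean_diff": mean, "s2": s2, "n": n, "df": df_total, "t": t, "p": p,
        "degenerate": degenerate,
    }, index=diff_matrix.index)
    out.loc[~usable, ["mean_diff", "s2", "df", "t", "p"]] = np.nan
    return out


def log2_fold_change(mean_a, mean_b, eps: float = 0.01):
    """log2((a + eps) / (b + eps)); NaN when both terms vanish."""
    a = np.asarray(mean_a, dtype=float) + eps
    b = np.asarray(mean_b, dtype=float) + eps
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(a / b)
    out = np.where((a == 0) & (b == 0), np.nan, out)
    return out if out.ndim else float(out)


def adjust_pvalues(p_values, method: str = "BH"):
    """Multiple-testing adjustment (BH step-up or Bonferroni).

    NaN entries are ignored for the correction and returned NaN; input
    order is preserved.
    """
    if method not in ("BH", "bonferroni"):
        raise ValueError("method must be 'BH' or 'bonferroni'")
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    q = p[ok]
    m = len(q)
    if m:
        if method == "bonferroni":
            out[ok] = np.minimum(1.0, q * m)
        else:
            order = np.argsort(q, kind="stable")
            ranked = q[order] * m / np.arange(1, m + 1)
            adj = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
            res = np.empty(m)
            res[order] = adj
            out[ok] = res
    return out


def _paired_diffs(matrix: BlockMatrix, tissue_a: str, tissue_b: str, thresholds: Thresholds):
    """Transformed per-patient differences A - B plus raw per-group values."""
    a = matrix.tissue_columns(tissue_a)
    b = matrix.tissue_columns(tissue_b)
    patients = [p for p in a.columns if p in b.columns]
    a, b = a[patients], b[patients]
    ta = thresholds.transform(a)
    tb = thresholds.transform(b)
    return ta - tb, a, b


def _pairwise_group_means(a: pd.DataFrame, b: pd.DataFrame):
    """Group means over pairwise-complete patients only."""
    ok = ~(a.isna() | b.isna())
    return a.where(ok).mean(axis=1), b.where(ok).mean(axis=1)


def tumor_dmr_table(
    matrix: BlockMatrix, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Full TUM-vs-DIS statistics for every block (no gating)."""
    diffs, a, b = _paired_diffs(matrix, "TUM", "DIS", thresholds)
    if diffs.shape[1] < thresholds.min_pairs:
        warnings.warn("fewer than min_pairs complete TUM/DIS patient pairs")
    prior = None if thresholds.moderate else ModerationParams(0.0, 1.0)
    tests = moderated_paired_t(diffs, prior=prior, min_pairs=thresholds.min_pairs)
    mean_t, mean_d = _pairwise_group_means(a, b)
    lfc = log2_fold_change(mean_t.to_numpy(), mean_d.to_numpy(), thresholds.offset_eps)
    out = pd.DataFrame({
        "block_id": matrix.block_ids,
        "comparison": TUMOR_COMPARISON,
        "mean_TUM": mean_t.to_numpy(),
        "mean_DIS": mean_d.to_numpy(),
        "mean_diff": tests["mean_diff"].to_numpy(),
        "n_pairs": tests["n"].to_numpy(),
        "t": tests["t"].to_numpy(),
        "df": tests["df"].to_numpy(),
        "p": tests["p"].to_numpy(),
        "log2fc": lfc,
    })
    out["p_adj"] = adjust_pvalues(out["p"], thresholds.adjust_method)
    out["direction"] = np.where(out["mean_diff"] > 0, "hyper", "hypo")
    return out


def call_tumor_dmrs(
    matrix: BlockMatrix,
    thresholds: Thresholds = Thresholds(),
    gene_map: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Emit tumor-specific DMRs: |log2FC| above and adjusted p below threshold.

    Direction is hyper when TUM runs higher than DIS, hypo otherwise.
    """
    table = tumor_dmr_table(matrix, thresholds)
    keep = (
        (table["log2fc"].abs() > thresholds.log2fc_min)
        & (table["p_adj"] < thresholds.adj_p_max)
    )
    out = table[keep.fillna(False)].reset_index(drop=True)
    if gene_map is not None:
        out["genes"] = [",".join(gene_map.get(b, ())) for b in out["block_id"]]
    return out


def fc_dmr_table(matrix: BlockMatrix, thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Per-block stepwise statistics for the three paired trio contrasts.

    Raw p-values are Bonferroni-corrected within the block (x3 contrasts),
    then adjusted across blocks per contrast with the configured method.
    """
    prior_mode = None if thresholds.moderate else ModerationParams(0.0, 1.0)
    cols = {"block_id": matrix.block_ids}
    means: dict[str, pd.Series] = {}
    for ta, tb in FC_COMPARISONS:
        label = f"{ta}_vs_{tb}"
        diffs, a, b = _paired_diffs(matrix, ta, tb, thresholds)
        tests = moderated_paired_t(diffs, prior=prior_mode, min_pairs=thresholds.min_pairs)
        ma, mb = _pairwise_group_means(a, b)
        means.setdefault(ta, ma)
        means.setdefault(tb, mb)
        cols[f"mean_diff_{label}"] = tests["mean_diff"].to_numpy()
        cols[f"t_{label}"] = tests["t"].to_numpy()
        cols[f"p_{label}"] = tests["p"].to_numpy()
        p_within = np.minimum(tests["p"].to_numpy() * len(FC_COMPARISONS), 1.0)
        cols[f"p_within_{label}"] = p_within
    out = pd.DataFrame(cols)
    for t in ("DIS", "ADJ", "TUM"):
        out[f"mean_{t}"] = means[t].to_numpy()
    for ta, tb in FC_COMPARISONS:
        label = f"{ta}_vs_{tb}"
        out[f"p_adj_{label}"] = adjust_pvalues(out[f"p_within_{label}"], thresholds.adjust_method)
    return out


def call_fc_dmrs(
    matrix: BlockMatrix,
    thresholds: Thresholds = Thresholds(),
    gene_map: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Emit stepwise field-cancerization DMRs (category up or down).

    up: both adjacent contrasts significant with positive differences and
    strictly increasing group means DIS < ADJ < TUM; down is the strict
    mirror.  The TUM-vs-DIS contrast is reported but not gated.
    """
    table = fc_dmr_table(matrix, thresholds)
    alpha = thresholds.adj_p_max
    sig_ad = table["p_adj_ADJ_vs_DIS"] < alpha
    sig_ta = table["p_adj_TUM_vs_ADJ"] < alpha
    inc = (table["mean_DIS"] < table["mean_ADJ"]) & (table["mean_ADJ"] < table["mean_TUM"])
    dec = (table["mean_DIS"] > table["mean_ADJ"]) & (table["mean_ADJ"] > table["mean_TUM"])
    up = sig_ad & sig_ta & (table["mean_diff_ADJ_vs_DIS"] > 0) & (table["mean_diff_TUM_vs_ADJ"] > 0) & inc
    down = sig_ad & sig_ta & (table["mean_diff_ADJ_vs_DIS"] < 0) & (table["mean_diff_TUM_vs_ADJ"] < 0) & dec
    table = table.copy()
    table["category"] = np.where(up, "up", np.where(down, "down", ""))
    out = table[(up | down).fillna(False)].reset_index(drop=True)
    if gene_map is not None:
        out["genes"] = [",".join(gene_map.get(b, ())) for b in out["block_id"]]
    return out


def overlap_sets(fc_ids, tumor_ids):
    """Intersection size of FC and tumor DMR id sets and percent of FC shared."""
    fc = set(fc_ids)
    tum = set(tumor_ids)
    n = len(fc & tum)
    if not fc:
        return n, float("nan")
    return n, round(100.0 * n / len(fc), 1)
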