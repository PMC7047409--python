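"""Expression analysis: normalization, NB Wald differential testing, TPM,
and gene-to-distal-element assignment.

The negative-binomial Wald engine here is shared with the accessibility
module (one implementation, two threshold sets): median-of-ratios size
factors, method-of-moments dispersion shrunk toward a 1/mu trend, a Wald
test on the log fold change, and BH FDR within the contrast.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Gene, GenomicInterval

__all__ = [
    "size_factors", "nb_wald_test", "test_de", "compute_tpm",
    "assign_distal_enhancer", "concordance", "bh_fdr",
]

_EPS = 0.5  # half-count floor for log fold changes at zero means


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs propagate."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = stats.false_discovery_control(p[ok], method="bh")
    return out


def size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """DESeq-style median-of-ratios per-sample normalization factors.

    Rows with any zero count are excluded from the medians (their
    geometric mean would be zero).
    """
    x = np.asarray(counts, dtype=float)
    pos = np.all(x > 0, axis=1)
    if not pos.any():
        return np.ones(x.shape[1])
    logx = np.log(x[pos])
    logg = logx.mean(axis=1, keepdims=True)
    return np.exp(np.median(logx - logg, axis=0))


def _dispersion(y: np.ndarray, groups: Sequence[np.ndarray],
                trend_weight: float = 0.9) -> np.ndarray:
    """Per-feature NB dispersion: within-group MoM shrunk toward a fitted
    ``a0 + a1 / mu`` trend, clipped to [1e-8, 10].

    The trend carries most of the weight: with two replicates the raw
    MoM values are so noisy that weighting them strongly makes the Wald
    tails badly anticonservative.
    """
    mu = y.mean(axis=1)
    ss = np.zeros(len(y))
    dof = 0
    for g in groups:
        sub = y[:, g]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        dof += len(g) - 1
    var = ss / max(dof, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (var - mu) / np.maximum(mu, 1e-8) ** 2
    ok = mu > 0
    a0, a1 = 0.01, 1.0
    if ok.sum() >= 10:
        # untrimmed least squares: the MoM estimates are right-skewed, and
        # trimming the right tail biases the fitted dispersion low, which
        # makes the Wald tails anticonservative
        A = np.stack([np.ones(ok.sum()), 1.0 / mu[ok]], axis=1)
        coef, *_ = np.linalg.lstsq(A, raw[ok], rcond=None)
        a0, a1 = max(float(coef[0]), 1e-8), max(float(coef[1]), 0.0)
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(mu, 1e-8)
    alpha = trend_weight * trend + (1 - trend_weight) * np.clip(raw, 0, None)
    return np.clip(np.nan_to_num(alpha, nan=a0), 1e-8, 10.0)


def nb_wald_test(counts: pd.DataFrame, group1: Sequence[str],
                 group2: Sequence[str], trend_weight: float = 0.9
                 ) -> pd.DataFrame:
    """NB Wald test per feature: log2 fold change of group2 over group1.

    Returns a frame indexed like ``counts`` with base_mean, log2_fold,
    se, p, fdr.  Features with all-zero counts get NaN p (excluded from
    BH).
    """
    cols = list(group1) + list(group2)
    x = counts[cols].to_numpy(dtype=float)
    sf = size_factors(x)
    y = x / sf
    i1 = np.arange(len(group1))
    i2 = np.arange(len(group1), len(cols))
    alpha = _dispersion(y, [i1, i2], trend_weight=trend_weight)
    mu1 = y[:, i1].mean(axis=1)
    mu2 = y[:, i2].mean(axis=1)
    base_mean = y.mean(axis=1)
    m1 = np.maximum(mu1, _EPS)
    m2 = np.maximum(mu2, _EPS)
    lfc = np.log2(m2 / m1)
    v1 = (1.0 / m1 + alpha) / len(i1)
    v2 = (1.0 / m2 + alpha) / len(i2)
    se_ln = np.sqrt(v1 + v2)
    z = np.log(m2 / m1) / se_ln
    p = 2.0 * stats.norm.sf(np.abs(z))
    allzero = x.sum(axis=1) == 0
    p = np.where(allzero, np.nan, p)
    lfc = np.where(allzero, 0.0, lfc)
    return pd.DataFrame({
        "base_mean": base_mean,
        "log2_fold": lfc,
        "se": se_ln / np.log(2),
        "stat": z,
        "p": p,
        "fdr": bh_fdr(p),
        "dispersion": alpha,
    }, index=counts.index)


def test_de(counts: pd.DataFrame, group1: Sequence[str], group2: Sequence[str],
            fc_cut: float = 2.0, fdr_cut: float = 0.05) -> pd.DataFrame:
    """Differential expression (group2 vs group1) at the configured
    thresholds: up iff log2_fold > log2(fc_cut) and fdr < fdr_cut; down
    symmetric; everything else (including untestable genes) ns."""
    res = nb_wald_test(counts, group1, group2)
    lcut = np.log2(fc_cut)
    status = np.where(
        (res["log2_fold"] > lcut) & (res["fdr"] < fdr_cut), "up",
        np.where((res["log2_fold"] < -lcut) & (res["fdr"] < fdr_cut),
                 "down", "ns"),
    )
    status = np.where(np.isnan(res["p"]), "ns", status)
    res = res.copy()
    res["status"] = status
    return res


def compute_tpm(counts: pd.DataFrame, lengths: Mapping[str, float] | pd.Series
                ) -> pd.DataFrame:
    """Transcripts per million from counts and exonic lengths (bp)."""
    lens = pd.Series(lengths).reindex(counts.index)
    if lens.isna().any() or (lens <= 0).any():
        raise ValueError("every gene needs a positive exonic length")
    rate = counts.div(lens, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


def assign_distal_enhancer(genes: Sequence[Gene],
                           peaks: Sequence[GenomicInterval],
                           min_dist: int = 10_000) -> dict[str, GenomicInterval]:
    """Nearest peak per gene among peaks farther than ``min_dist`` from the
    TSS; equidistant candidates resolve to the leftmost peak.  Genes with
    no qualifying peak are absent from the map."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for v in by_chrom.values():
        v.sort(key=lambda p: (p.start, p.end))
    out: dict[str, GenomicInterval] = {}
    for g in genes:
        best: tuple[int, int, GenomicInterval] | None = None
        for p in by_chrom.get(g.interval.chrom, []):
            if p.start <= g.tss < p.end:
                d = 0
            else:
                d = min(abs(g.tss - p.start), abs(g.tss - (p.end - 1)))
            if d <= min_dist:
                continue
            key = (d, p.start)
            if best is None or key < (best[0], best[1]):
                best = (d, p.start, p)
        if best is not None:
            out[g.gene_id] = best[2]
    return out


def concordance(dars: pd.DataFrame, de: pd.DataFrame,
                nearest_gene: Mapping[tuple[str, int, int], str]) -> dict:
    """Direction agreement between DARs and their nearest genes.

    ``dars`` needs chrom/start/end/direction columns; ``de`` is indexed by
    gene with a log2_fold column; ``nearest_gene`` maps (chrom, start, end)
    to a gene id.  Reports, per DAR class, the nearest-gene fold-change
    distribution and the fraction sharing the DAR's sign.
    """
    out: dict = {}
    if len(dars) == 0:
        return out
    for direction, sign in (("gained", 1), ("lost", -1)):
        fcs = []
        for _, row in dars[dars["direction"] == direction].iterrows():
            gene = nearest_gene.get((row["chrom"], int(row["start"]),
                                     int(row["end"])))
            if gene is None or gene not in de.index:
                continue
            fcs.append(float(de.loc[gene, "log2_fold"]))
        if not fcs:
            continue
        arr = np.asarray(fcs)
        out[direction] = {
            "n": len(arr),
            "median_log2_fold": float(np.median(arr)),
            "frac_concordant": float((np.sign(arr) == sign).mean()),
            "log2_folds": arr.tolist(),
        }
    return out
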