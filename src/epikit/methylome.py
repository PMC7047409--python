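"""Differential methylation: smoothing, beta-binomial dispersion, per-CpG
Wald tests, region assembly, filtering, and replicate-null calibration.

The per-CpG two-group test models pooled methylated counts as
beta-binomial; the Wald statistic is ``(mu1 - mu2) / sqrt(var1 + var2)``
with ``var_i = mu_i (1 - mu_i) (1 + (t_i - 1) phi) / t_i``.  Candidate
regions chain significant CpGs of consistent sign, allowing short
insignificant gaps, and are then filtered on length, CpG count, the
fraction of significant CpGs, effect size, and per-group coverage.

Multiple-testing control is a fixed p-value threshold calibrated against
an empirical replicate null (DMR counts between biological replicates),
not BH.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomicInterval

__all__ = [
    "DmrCallParams", "CpGTest", "Dmr",
    "align_samples", "smooth_methylation", "estimate_dispersion",
    "wald_test", "wald_test_cpg", "call_dmrs", "filter_dmrs",
    "prepare_tests", "dmr_pipeline", "empirical_null_curve",
    "methylome_summary", "stability_fraction", "aggregate_profile",
]

_VAR_FLOOR = 1e-8
_PHI_CLIP = (1e-4, 0.5)


@dataclass
class DmrCallParams:
    delta: float = 0.0
    minlen: int = 200
    min_cg: int = 5
    dis_merge: int = 50
    pct_sig: float = 0.5
    p_threshold: float = 1e-5
    min_mean_diff: float = 0.25
    min_covered_cpgs: int = 5
    min_cov: int = 5
    # region-assembly internals (unstated upstream; fixed here)
    max_insig_run: int = 2
    max_gap: int = 300
    smooth_window: int = 500
    shrink_scale: float = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.pct_sig <= 1:
            raise ValueError("pct_sig must be in (0, 1]")
        for name in ("minlen", "min_cg", "dis_merge", "min_covered_cpgs",
                     "min_cov"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class CpGTest:
    pos: int
    mu1: float
    mu2: float
    phi: float
    wald: float
    p: float


@dataclass
class Dmr:
    interval: GenomicInterval
    n_cpgs: int
    mean_diff: float
    hypo_in: str
    area_stat: float


# ---------------------------------------------------------------------------
# alignment and smoothing
# ---------------------------------------------------------------------------

def align_samples(samples: Sequence[pd.DataFrame]
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Outer-join CpG tables on (chrom, pos); absent CpGs get zero counts.

    Returns (chrom, pos, meth[n x s], total[n x s]) sorted by (chrom, pos).
    """
    keys = sorted(
        set().union(*[set(zip(df["chrom"], df["pos"])) for df in samples])
    )
    chrom = np.asarray([k[0] for k in keys])
    pos = np.asarray([k[1] for k in keys], dtype=np.int64)
    index = {k: i for i, k in enumerate(keys)}
    meth = np.zeros((len(keys), len(samples)), dtype=np.int64)
    total = np.zeros_like(meth)
    for j, df in enumerate(samples):
        rows = [index[k] for k in zip(df["chrom"], df["pos"])]
        meth[rows, j] = np.asarray(df["meth"])
        total[rows, j] = np.asarray(df["total"])
    return chrom, pos, meth, total


def _window_stats(pos: np.ndarray, meth: np.ndarray, total: np.ndarray,
                  window_bp: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-CpG windowed (level, summed total, covered-CpG count)."""
    pos = np.asarray(pos)
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted")
    half = window_bp // 2
    lo = np.searchsorted(pos, pos - half, side="left")
    hi = np.searchsorted(pos, pos + half, side="right")
    cm = np.concatenate([[0], np.cumsum(meth)])
    ct = np.concatenate([[0], np.cumsum(total)])
    cn = np.concatenate([[0], np.cumsum(total > 0)])
    wm = cm[hi] - cm[lo]
    wt = ct[hi] - ct[lo]
    wn = cn[hi] - cn[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = np.where(wt > 0, wm / np.maximum(wt, 1), np.nan)
    return mu, wt, wn


def smooth_methylation(pos: np.ndarray, meth: np.ndarray, total: np.ndarray,
                       window_bp: int = 500) -> np.ndarray:
    """Windowed mean level: sum(meth) / sum(total) within +- window/2.

    ``pos`` must be sorted (single chromosome).  A CpG whose window has no
    coverage gets NaN (flagged missing).
    """
    return _window_stats(pos, meth, total, window_bp)[0]


def _smooth_by_chrom(chrom: np.ndarray, pos: np.ndarray, meth: np.ndarray,
                     total: np.ndarray, window_bp: int
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = np.empty(len(pos))
    wt = np.empty(len(pos))
    wn = np.empty(len(pos))
    for c in pd.unique(chrom):
        m = chrom == c
        mu[m], wt[m], wn[m] = _window_stats(pos[m], meth[m], total[m],
                                            window_bp)
    return mu, wt, wn


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def _group_phi_raw(meth: np.ndarray, total: np.ndarray) -> np.ndarray:
    """Method-of-moments beta-binomial phi per CpG from replicate variation.

    Unbiased in expectation; may be negative at low variance.  NaN where
    fewer than two covered replicates exist.
    """
    t = total.astype(float)
    covered = t > 0
    nrep = covered.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(covered, meth / np.maximum(t, 1), np.nan)
        mu = np.nansum(np.where(covered, meth, 0), axis=1) / np.maximum(
            np.nansum(np.where(covered, t, 0), axis=1), 1e-12)
        s2 = np.nanvar(r, axis=1, ddof=1)
        tbar = np.nansum(np.where(covered, t, np.nan), axis=1) / np.maximum(nrep, 1)
        denom = np.maximum(mu * (1 - mu), 1e-6)
        phi = (s2 / denom - 1.0 / tbar) * tbar / np.maximum(tbar - 1.0, 1e-12)
    phi[nrep < 2] = np.nan
    return phi


def estimate_dispersion(meth_groups: Sequence[np.ndarray],
                        total_groups: Sequence[np.ndarray],
                        mu_smoothed: np.ndarray | None = None,
                        shrink_scale: float = 50.0) -> np.ndarray:
    """Per-CpG phi, shrunk toward a genome-wide estimate by coverage weight.

    With replicates in a group, phi comes from replicate variation (MoM);
    the shrinkage target is the genome-wide mean of the raw estimates
    (mean rather than median: the median of per-CpG MoM estimates from few
    replicates is badly biased low).  With single samples in every group,
    phi falls back to a single genome-wide value estimated from local
    spatial variation: per-CpG deviation of the raw ratio from the
    smoothed mean.  Result clipped to [1e-4, 0.5].
    """
    n = meth_groups[0].shape[0]
    raws = []
    weights = []
    for meth, total in zip(meth_groups, total_groups):
        if meth.shape[1] >= 2:
            raws.append(_group_phi_raw(meth, total))
            weights.append(total.sum(axis=1).astype(float))
    if raws:
        raw = np.full(n, np.nan)
        wsum = np.zeros(n)
        for r, w in zip(raws, weights):
            ok = ~np.isnan(r)
            raw[ok] = np.where(wsum[ok] > 0, raw[ok], 0.0)
            raw[ok] += r[ok] * w[ok]
            wsum[ok] += w[ok]
        raw = np.where(wsum > 0, raw / np.maximum(wsum, 1e-12), np.nan)
        valid = ~np.isnan(raw)
        global_phi = float(np.clip(
            np.mean(np.clip(raw[valid], -0.5, 1.0)) if valid.any() else 0.01,
            *_PHI_CLIP))
        cov = np.zeros(n)
        for total in total_groups:
            cov += total.mean(axis=1)
        cov /= len(total_groups)
        w = cov / (cov + shrink_scale)
        phi = w * np.clip(np.nan_to_num(raw, nan=global_phi), 0.0, 1.0) \
            + (1 - w) * global_phi
        return np.clip(phi, *_PHI_CLIP)

    # single sample per group: spatial fallback
    if mu_smoothed is None:
        raise ValueError("single-sample groups need smoothed means")
    phis = []
    for meth, total in zip(meth_groups, total_groups):
        t = total[:, 0].astype(float)
        ok = (t > 1) & ~np.isnan(mu_smoothed)
        r = meth[ok, 0] / t[ok]
        mu = np.clip(mu_smoothed[ok], 1e-3, 1 - 1e-3)
        dev = (r - mu) ** 2 * t[ok] / (mu * (1 - mu))
        phis.append((dev - 1.0) / np.maximum(t[ok] - 1.0, 1e-12))
    allphi = np.concatenate(phis) if phis else np.array([0.01])
    global_phi = float(np.clip(np.mean(np.clip(allphi, -0.5, 1.0)), *_PHI_CLIP))
    return np.full(n, global_phi)


# ---------------------------------------------------------------------------
# Wald test
# ---------------------------------------------------------------------------

def wald_test(mu1: np.ndarray, t1: np.ndarray, mu2: np.ndarray,
              t2: np.ndarray, phi: np.ndarray,
              tbar1: np.ndarray | None = None,
              tbar2: np.ndarray | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-group beta-binomial Wald test.

    ``var_i = mu_i (1 - mu_i) (1 + (tbar_i - 1) phi) / t_i``.  When the
    level is estimated from a smoothing window, ``t_i`` is the summed
    window coverage and ``tbar_i`` the mean per-CpG coverage inside it
    (beta-binomial draws are independent across CpGs, so only the
    per-CpG depth inflates the overdispersion term); for raw per-CpG
    tests ``tbar_i`` defaults to ``t_i``.  Entries with zero coverage on
    either side are NaN.
    """
    mu1 = np.asarray(mu1, dtype=float)
    mu2 = np.asarray(mu2, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    phi = np.asarray(phi, dtype=float)
    tbar1 = t1 if tbar1 is None else np.asarray(tbar1, dtype=float)
    tbar2 = t2 if tbar2 is None else np.asarray(tbar2, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        v1 = mu1 * (1 - mu1) * (1 + (tbar1 - 1) * phi) / np.maximum(t1, 1)
        v2 = mu2 * (1 - mu2) * (1 + (tbar2 - 1) * phi) / np.maximum(t2, 1)
        var = np.maximum(v1 + v2, _VAR_FLOOR)
        wald = (mu1 - mu2) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(wald))
    skip = (t1 <= 0) | (t2 <= 0) | np.isnan(mu1) | np.isnan(mu2)
    wald = np.where(skip, np.nan, wald)
    p = np.where(skip, np.nan, p)
    return wald, p


def wald_test_cpg(m1: int, t1: int, m2: int, t2: int, phi: float,
                  pos: int = 0) -> CpGTest:
    """Scalar Wald test on raw per-CpG counts."""
    if t1 <= 0 or t2 <= 0:
        return CpGTest(pos, np.nan, np.nan, phi, np.nan, np.nan)
    mu1, mu2 = m1 / t1, m2 / t2
    wald, p = wald_test(np.array([mu1]), np.array([t1]),
                        np.array([mu2]), np.array([t2]), np.array([phi]))
    return CpGTest(pos, mu1, mu2, phi, float(wald[0]), float(p[0]))


# ---------------------------------------------------------------------------
# region assembly
# ---------------------------------------------------------------------------

def _assemble_chrom(pos: np.ndarray, sig: np.ndarray, sign: np.ndarray,
                    params: DmrCallParams) -> list[tuple[int, int]]:
    """Chain significant CpGs into candidate index spans.

    A run breaks when the genomic gap between consecutive CpGs exceeds
    ``max_gap``, when more than ``max_insig_run`` consecutive insignificant
    CpGs intervene, or when a significant CpG of opposite sign appears.
    Spans are trimmed to their significant endpoints.
    """
    runs: list[tuple[int, int]] = []
    first = last = -1
    run_sign = 0

    def close() -> None:
        nonlocal first, last, run_sign
        if first >= 0:
            runs.append((first, last))
        first = last = -1
        run_sign = 0

    for i in range(len(pos)):
        if first >= 0 and pos[i] - pos[i - 1] > params.max_gap:
            close()
        if not sig[i]:
            continue
        if first >= 0 and (
            sign[i] != run_sign or i - last - 1 > params.max_insig_run
        ):
            close()
        if first < 0:
            first = last = i
            run_sign = sign[i]
        else:
            last = i
    close()
    return runs


def call_dmrs(tests: pd.DataFrame, params: DmrCallParams,
              labels: tuple[str, str] = ("group1", "group2")) -> list[Dmr]:
    """Assemble candidate DMRs from per-CpG tests.

    ``tests`` needs columns chrom, pos, mu1, mu2, wald, p, sorted by
    (chrom, pos).  Candidate spans must reach ``minlen`` bp and ``min_cg``
    CpGs with at least ``pct_sig`` of them significant; surviving regions
    separated by <= ``dis_merge`` bp with the same direction are merged.
    """
    if len(tests) == 0:
        return []
    out: list[Dmr] = []
    for c in pd.unique(tests["chrom"]):
        sub = tests[tests["chrom"] == c]
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError("tests must be sorted by position")
        p = sub["p"].to_numpy()
        diff = sub["mu1"].to_numpy() - sub["mu2"].to_numpy()
        wald = sub["wald"].to_numpy()
        mu_diff = diff
        sig = (p < params.p_threshold) & ~np.isnan(p) \
            & (np.abs(diff) > params.delta) & (diff != 0)
        sign = np.sign(diff).astype(int)

        spans = []
        for i, j in _assemble_chrom(pos, sig, sign, params):
            start, end = int(pos[i]), int(pos[j]) + 2
            n_cg = j - i + 1
            frac = sig[i : j + 1].mean()
            if end - start >= params.minlen and n_cg >= params.min_cg \
                    and frac >= params.pct_sig:
                spans.append([i, j, int(sign[i])])

        merged: list[list[int]] = []
        for span in spans:
            if merged and span[2] == merged[-1][2] \
                    and pos[span[0]] - (pos[merged[-1][1]] + 2) <= params.dis_merge:
                merged[-1][1] = span[1]
            else:
                merged.append(span)

        for i, j, s in merged:
            d = float(np.nanmean(mu_diff[i : j + 1]))
            hypo = labels[0] if d < 0 else labels[1]
            out.append(Dmr(
                interval=GenomicInterval(str(c), int(pos[i]), int(pos[j]) + 2),
                n_cpgs=j - i + 1,
                mean_diff=d,
                hypo_in=hypo,
                area_stat=float(np.nansum(wald[i : j + 1])),
            ))
    out.sort(key=lambda d: (d.interval.chrom, d.interval.start))
    return out


def filter_dmrs(dmrs: list[Dmr], tests: pd.DataFrame,
                params: DmrCallParams) -> list[Dmr]:
    """Keep DMRs with |mean_diff| > min_mean_diff and enough well-covered
    CpGs (total >= min_cov in BOTH groups, per-group rule)."""
    if not dmrs:
        return []
    kept = []
    for d in dmrs:
        m = (tests["chrom"] == d.interval.chrom) \
            & (tests["pos"] >= d.interval.start) \
            & (tests["pos"] < d.interval.end)
        sub = tests[m]
        covered = ((sub["t1"] >= params.min_cov)
                   & (sub["t2"] >= params.min_cov)).sum()
        if abs(d.mean_diff) > params.min_mean_diff \
                and covered >= params.min_covered_cpgs:
            kept.append(d)
    return kept


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def prepare_tests(group1: Sequence[pd.DataFrame], group2: Sequence[pd.DataFrame],
                  params: DmrCallParams | None = None) -> pd.DataFrame:
    """Smooth, estimate dispersion, and Wald-test every CpG.

    Returns a frame with chrom, pos, mu1, mu2, t1, t2, phi, wald, p —
    reusable across p-value thresholds for the empirical-null curve.
    """
    params = params or DmrCallParams()
    chrom, pos, meth, total = align_samples(list(group1) + list(group2))
    k = len(group1)
    m1, t1 = meth[:, :k], total[:, :k]
    m2, t2 = meth[:, k:], total[:, k:]
    mu1, w1, n1 = _smooth_by_chrom(chrom, pos, m1.sum(axis=1), t1.sum(axis=1),
                                   params.smooth_window)
    mu2, w2, n2 = _smooth_by_chrom(chrom, pos, m2.sum(axis=1), t2.sum(axis=1),
                                   params.smooth_window)
    mu_pooled, _, _ = _smooth_by_chrom(chrom, pos, meth.sum(axis=1),
                                       total.sum(axis=1), params.smooth_window)
    phi = estimate_dispersion([m1, m2], [t1, t2], mu_smoothed=mu_pooled,
                              shrink_scale=params.shrink_scale)
    T1 = t1.sum(axis=1)
    T2 = t2.sum(axis=1)
    # the smoothed level is a window-pooled estimator: its sampling
    # variance uses the summed window coverage, with the overdispersion
    # term driven by the mean per-CpG depth inside the window
    tbar1 = w1 / np.maximum(n1, 1)
    tbar2 = w2 / np.maximum(n2, 1)
    wald, p = wald_test(mu1, w1, mu2, w2, phi, tbar1=tbar1, tbar2=tbar2)
    return pd.DataFrame({
        "chrom": chrom, "pos": pos, "mu1": mu1, "mu2": mu2,
        "t1": T1, "t2": T2, "phi": phi, "wald": wald, "p": p,
    })


def dmr_pipeline(group1: Sequence[pd.DataFrame], group2: Sequence[pd.DataFrame],
                 params: DmrCallParams | None = None,
                 labels: tuple[str, str] = ("group1", "group2")) -> list[Dmr]:
    """Full chain: smoothing -> dispersion -> Wald -> assembly -> filters."""
    params = params or DmrCallParams()
    tests = prepare_tests(group1, group2, params)
    dmrs = call_dmrs(tests, params, labels=labels)
    return filter_dmrs(dmrs, tests, params)


def empirical_null_curve(pair_replicates: dict[str, tuple[Sequence[pd.DataFrame],
                                                          Sequence[pd.DataFrame]]],
                         pair_conditions: dict[str, tuple[Sequence[pd.DataFrame],
                                                          Sequence[pd.DataFrame]]],
                         p_thresholds: Sequence[float],
                         params: DmrCallParams | None = None) -> pd.DataFrame:
    """DMR counts per threshold for replicate-null vs condition comparisons.

    Runs the complete call+filter chain per comparison at each threshold
    and tabulates counts side by side with the null ratio.
    """
    params = params or DmrCallParams()
    prepared = {
        ("replicate_null", name): prepare_tests(g1, g2, params)
        for name, (g1, g2) in pair_replicates.items()
    }
    prepared.update({
        ("condition", name): prepare_tests(g1, g2, params)
        for name, (g1, g2) in pair_conditions.items()
    })
    rows = []
    for thr in p_thresholds:
        p = replace(params, p_threshold=thr)
        for (kind, name), tests in prepared.items():
            dmrs = filter_dmrs(call_dmrs(tests, p), tests, p)
            rows.append({"p_threshold": thr, "kind": kind,
                         "comparison": name, "n_dmrs": len(dmrs)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def methylome_summary(df: pd.DataFrame, min_cov: int = 5,
                      n_hist_bins: int = 20) -> dict:
    """Global mCG/CG plus low/medium/high bin fractions and a histogram.

    Bins (computed over CpGs with total >= min_cov): low < 0.25,
    medium in [0.25, 0.75), high >= 0.75.
    """
    total = df["total"].to_numpy(dtype=float)
    meth = df["meth"].to_numpy(dtype=float)
    global_level = float(meth.sum() / total.sum()) if total.sum() else float("nan")
    ok = total >= min_cov
    ratio = meth[ok] / total[ok]
    n = max(len(ratio), 1)
    hist, edges = np.histogram(ratio, bins=n_hist_bins, range=(0, 1))
    return {
        "global_mcg": global_level,
        "frac_low": float((ratio < 0.25).sum() / n),
        "frac_medium": float(((ratio >= 0.25) & (ratio < 0.75)).sum() / n),
        "frac_high": float((ratio >= 0.75).sum() / n),
        "n_cpgs_binned": int(ok.sum()),
        "histogram": hist.tolist(),
        "histogram_edges": edges.tolist(),
    }


def _region_mean(df: pd.DataFrame, region: GenomicInterval,
                 min_cpgs: int = 1) -> float:
    m = (df["chrom"] == region.chrom) & (df["pos"] >= region.start) \
        & (df["pos"] < region.end) & (df["total"] > 0)
    sub = df[m]
    if len(sub) < min_cpgs or sub["total"].sum() == 0:
        return float("nan")
    return float(sub["meth"].sum() / sub["total"].sum())


def stability_fraction(regions: Sequence[GenomicInterval],
                       meth_t0: pd.DataFrame, meth_t4: pd.DataFrame,
                       change_threshold: float = 0.25) -> dict:
    """Fraction of regions whose methylation change stays below threshold.

    Regions lacking coverage at either timepoint are excluded from the
    denominator and reported separately.
    """
    n_stable = n_eval = n_missing = 0
    for r in regions:
        a = _region_mean(meth_t0, r)
        b = _region_mean(meth_t4, r)
        if np.isnan(a) or np.isnan(b):
            n_missing += 1
            continue
        n_eval += 1
        if abs(b - a) < change_threshold:
            n_stable += 1
    return {
        "fraction_stable": n_stable / n_eval if n_eval else float("nan"),
        "n_evaluated": n_eval,
        "n_stable": n_stable,
        "n_missing": n_missing,
    }


def aggregate_profile(intervals: Sequence[GenomicInterval],
                      signal: pd.DataFrame, flank: int = 5000,
                      n_bins: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Center-anchored per-bin mean signal matrix (intervals x bins).

    ``signal`` has columns chrom, pos, value.  Bins without data are NaN
    and excluded from the column means.
    """
    mat = np.full((len(intervals), n_bins), np.nan)
    width = 2 * flank
    by_chrom = {c: sub.sort_values("pos") for c, sub in signal.groupby("chrom")}
    for i, iv in enumerate(intervals):
        sub = by_chrom.get(iv.chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        val = sub["value"].to_numpy(dtype=float)
        left = iv.center - flank
        lo = np.searchsorted(pos, left, side="left")
        hi = np.searchsorted(pos, left + width, side="left")
        if hi <= lo:
            continue
        bins = ((pos[lo:hi] - left) * n_bins // width).astype(int)
        v = val[lo:hi]
        sums = np.bincount(bins, weights=v, minlength=n_bins)
        cnts = np.bincount(bins, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            mat[i] = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    ok = ~np.isnan(mat)
    cnt = ok.sum(axis=0)
    sums = np.where(ok, mat, 0.0).sum(axis=0)
    col_means = np.where(cnt > 0, sums / np.maximum(cnt, 1), np.nan)
    return mat, col_means
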