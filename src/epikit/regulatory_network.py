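"""Motif scanning, enrichment, footprint mixture modelling, regulatory
network assembly, mutant-response comparison, and gRNA scoring.

Motif p-values are exact under the background model: the log-odds score
distribution is computed by dynamic programming over per-position score
distributions discretized to 0.01-bit bins, so the p-value of a hit is
the probability that a random background sequence scores at least as
high.

The footprint model is a two-component mixture over 200-bp insertion
count windows: a bound component with a higher Poisson total-count rate
and a learned multinomial positional profile (core depletion), an
unbound component with a lower rate and a uniform profile, and a
logistic site prior in (motif score, conservation), fit by EM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .io_formats import GenomicInterval, Pwm
from .transcriptome import bh_fdr

__all__ = [
    "MotifHit", "FootprintFit", "RegulatoryEdge",
    "scan_pwm", "motif_enrichment", "fit_footprint_model",
    "select_upstream_tfs", "build_grn", "compare_target_response",
    "score_grna",
]

_BASES = "ACGT"
DEFAULT_BIN_BITS = 0.01


@dataclass(frozen=True)
class MotifHit:
    pwm_name: str
    interval: GenomicInterval
    strand: str
    score: float
    p: float


@dataclass
class FootprintFit:
    posterior: np.ndarray
    bound: np.ndarray
    loglik_trace: list[float]
    rate_bound: float
    rate_unbound: float
    profile: np.ndarray
    beta: np.ndarray
    converged: bool
    warning: str | None = None


@dataclass(frozen=True)
class RegulatoryEdge:
    tf: str
    target: str
    site: GenomicInterval
    dar: GenomicInterval
    edge_type: str  # tf_target | tf_tf | auto


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        code[ord(b)] = i
    return code[arr]


def _base_composition(seqs: Sequence[str]) -> np.ndarray:
    counts = np.zeros(4)
    for s in seqs:
        enc = _encode(s)
        counts += np.bincount(enc[enc >= 0], minlength=4)[:4]
    if counts.sum() == 0:
        return np.full(4, 0.25)
    bg = counts / counts.sum()
    # symmetrize so a sequence and its reverse complement score identically
    return (bg + bg[::-1]) / 2


def _score_pvalue_table(pwm: Pwm, background: np.ndarray,
                        bin_bits: float) -> tuple[np.ndarray, np.ndarray, int]:
    """Exact DP over the discretized background score distribution.

    Returns (quantized score matrix L x 4, survival function over score
    bins, minimum total bin index).
    """
    with np.errstate(divide="ignore"):
        lods = np.log2(pwm.matrix / background[None, :])
    q = np.round(lods / bin_bits).astype(np.int64)
    mins = q.min(axis=1)
    maxs = q.max(axis=1)
    size = int((maxs - mins).sum()) + 1
    dist = np.zeros(size)
    dist[0] = 1.0
    offset = 0
    for i in range(len(pwm)):
        new = np.zeros(size)
        width = offset + int(maxs[i] - mins[i]) + 1
        for b in range(4):
            shift = int(q[i, b] - mins[i])
            new[shift : shift + offset + 1] += background[b] * dist[: offset + 1]
        offset = width - 1
        dist = new
    sf = dist[::-1].cumsum()[::-1]
    return q, sf, int(mins.sum())


def scan_pwm(sequences: Mapping[str, str], pwm: Pwm,
             p_threshold: float = 1e-5,
             background: np.ndarray | None = None,
             bin_bits: float = DEFAULT_BIN_BITS) -> list[MotifHit]:
    """Scan sequences on both strands, reporting hits with exact p below
    threshold.  Background defaults to the (strand-symmetrized) base
    composition of the sequence set; overlapping hits are all reported."""
    if background is None:
        background = _base_composition(list(sequences.values()))
    background = np.asarray(background, dtype=float)
    background = background / background.sum()

    hits: list[MotifHit] = []
    L = len(pwm)
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        q, sf, min_total = _score_pvalue_table(
            Pwm(mat.name, mat.matrix, background), background, bin_bits)
        for name, seq in sequences.items():
            enc = _encode(seq)
            n = len(enc) - L + 1
            if n <= 0:
                continue
            total_q = np.zeros(n, dtype=np.int64)
            valid = np.ones(n, dtype=bool)
            for i in range(L):
                window = enc[i : i + n]
                valid &= window >= 0
                total_q += q[i, np.maximum(window, 0)]
            pvals = sf[np.clip(total_q - min_total, 0, len(sf) - 1)]
            for pos in np.nonzero(valid & (pvals < p_threshold))[0]:
                hits.append(MotifHit(
                    pwm_name=pwm.name,
                    interval=GenomicInterval(name, int(pos), int(pos) + L),
                    strand=strand,
                    score=float(total_q[pos] * bin_bits),
                    p=float(pvals[pos]),
                ))
    hits.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# motif enrichment
# ---------------------------------------------------------------------------

def _regions_with_hit(regions: Sequence[GenomicInterval],
                      hits: Sequence[MotifHit | GenomicInterval]) -> np.ndarray:
    ivs = [h.interval if isinstance(h, MotifHit) else h for h in hits]
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {iv.chrom for iv in ivs}:
        pairs = sorted((iv.start, iv.end) for iv in ivs
                       if iv.chrom == chrom)
        by_chrom[chrom] = (np.asarray([p[0] for p in pairs]),
                           np.asarray([p[1] for p in pairs]))
    out = np.zeros(len(regions), dtype=bool)
    for i, r in enumerate(regions):
        pair = by_chrom.get(r.chrom)
        if pair is None:
            continue
        starts, ends = pair
        hi = np.searchsorted(starts, r.end, side="left")
        out[i] = bool(np.any(ends[:hi] > r.start))
    return out


def motif_enrichment(hits_by_pwm: Mapping[str, Sequence[MotifHit]],
                     targets: Sequence[GenomicInterval],
                     backgrounds: Sequence[GenomicInterval],
                     length_bin: int = 100) -> pd.DataFrame:
    """Binomial enrichment of motif occurrence in targets vs background.

    The background hit rate ``q`` is the fraction of background regions
    containing at least one hit, length-matched: background regions are
    grouped into ``length_bin``-bp length bins and reweighted to the
    target length distribution.  p = upper binomial tail
    P(X >= k | n_targets, q).
    """
    n = len(targets)
    t_lens = np.asarray([t.length for t in targets]) // length_bin
    b_lens = np.asarray([b.length for b in backgrounds]) // length_bin \
        if backgrounds else np.asarray([], dtype=int)
    rows = []
    for name, hits in hits_by_pwm.items():
        k = int(_regions_with_hit(targets, hits).sum()) if n else 0
        bhit = _regions_with_hit(backgrounds, hits) if len(backgrounds) else \
            np.asarray([], dtype=bool)
        if len(backgrounds):
            overall = float(bhit.mean())
            q = 0.0
            for lb in np.unique(t_lens):
                w = float((t_lens == lb).mean())
                sel = b_lens == lb
                q += w * (float(bhit[sel].mean()) if sel.any() else overall)
        else:
            q = 0.0
        q = min(max(q, 1e-12), 1 - 1e-12)
        p = float(stats.binom.sf(k - 1, n, q)) if n else float("nan")
        rows.append({"pwm": name, "n_target_with_hit": k, "n_targets": n,
                     "background_rate": q, "expected": q * n, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = bh_fdr(df["p"].to_numpy())
        df = df.sort_values("p", kind="stable").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# footprint mixture model
# ---------------------------------------------------------------------------

def _logistic_newton(X: np.ndarray, z: np.ndarray, beta: np.ndarray,
                     n_steps: int = 5, ridge: float = 1e-6) -> np.ndarray:
    """Weighted logistic regression on fractional responses, with step
    halving so the penalized objective never decreases."""

    def obj(b: np.ndarray) -> float:
        eta = X @ b
        return float(z @ eta - np.logaddexp(0, eta).sum()
                     - 0.5 * ridge * b @ b)

    for _ in range(n_steps):
        eta = X @ beta
        mu = expit(eta)
        grad = X.T @ (z - mu) - ridge * beta
        w = np.maximum(mu * (1 - mu), 1e-8)
        H = (X * w[:, None]).T @ X + ridge * np.eye(X.shape[1])
        step = np.linalg.solve(H, grad)
        f0 = obj(beta)
        t = 1.0
        while t > 1e-4 and obj(beta + t * step) < f0:
            t /= 2
        beta = beta + t * step
    return beta


def fit_footprint_model(windows: np.ndarray,
                        motif_scores: np.ndarray,
                        conservation: np.ndarray | None = None,
                        seed: int = 0, tol: float = 1e-6,
                        max_iter: int = 200,
                        posterior_cut: float = 0.95) -> FootprintFit:
    """EM fit of the bound/unbound insertion-profile mixture.

    Identifiability: the bound component is constrained to the higher
    total-count rate.  Fewer than 20 sites: refuses to fit and returns
    flat prior-only posteriors with a warning.
    """
    X = np.asarray(windows, dtype=float)
    n, w = X.shape
    scores = np.asarray(motif_scores, dtype=float)
    if conservation is None:
        cons = np.zeros(n)
    else:
        cons = np.asarray(conservation, dtype=float).copy()
        bad = np.isnan(cons)
        cons[bad] = np.nanmean(cons) if (~bad).any() else 0.0

    if n < 20:
        msg = f"refusing to fit footprint mixture on {n} < 20 sites"
        warnings.warn(msg)
        post = np.full(n, 0.5)
        return FootprintFit(post, post > posterior_cut, [], float("nan"),
                            float("nan"), np.full(w, 1.0 / w),
                            np.zeros(3), False, warning=msg)

    T = X.sum(axis=1)
    design = np.stack([
        np.ones(n),
        (scores - scores.mean()) / (scores.std() + 1e-12),
        (cons - cons.mean()) / (cons.std() + 1e-12),
    ], axis=1)

    # seeded k-means-style init: bound sites have more insertions overall
    # but a depleted window center, so split on both axes combined
    center = X[:, int(w * 0.45) : int(w * 0.55)].sum(axis=1)
    center_frac = center / np.maximum(T, 1)
    def _std(v: np.ndarray) -> np.ndarray:
        return (v - v.mean()) / (v.std() + 1e-12)
    init_score = _std(T) - _std(center_frac)
    order = np.argsort(init_score)
    z = np.zeros(n)
    z[order[n // 2:]] = 1.0
    rng = np.random.default_rng(seed)
    z = np.clip(z + rng.uniform(-0.05, 0.05, n), 0.0, 1.0)

    beta = np.zeros(3)
    uniform = np.full(w, 1.0 / w)
    loglik_trace: list[float] = []
    converged = False
    c_lo, c_hi = int(w * 0.45), int(w * 0.55)

    def _mstep(z: np.ndarray) -> tuple[float, float, np.ndarray]:
        zs = z.sum()
        lam1 = float((z @ T) / max(zs, 1e-12))
        lam0 = float(((1 - z) @ T) / max(n - zs, 1e-12))
        prof = z @ X + 0.5
        return lam1, lam0, prof / prof.sum()

    def _run(z: np.ndarray) -> tuple[np.ndarray, float, float, np.ndarray,
                                     np.ndarray, list[float], bool]:
        beta = np.zeros(3)
        trace: list[float] = []
        converged = False
        lam1 = lam0 = 0.0
        prof = uniform.copy()
        for _ in range(max_iter):
            lam1, lam0, prof = _mstep(z)
            beta = _logistic_newton(design, z, beta)
            prior = np.clip(expit(design @ beta), 1e-9, 1 - 1e-9)
            lf1 = stats.poisson.logpmf(T, max(lam1, 1e-9)) + X @ np.log(prof)
            lf0 = stats.poisson.logpmf(T, max(lam0, 1e-9)) \
                + X @ np.log(uniform)
            a = np.log(prior) + lf1
            b = np.log1p(-prior) + lf0
            norm = np.logaddexp(a, b)
            # trace the MAP objective (likelihood + Dirichlet(1.5) prior
            # on the profile + ridge prior on beta): that is the quantity
            # this EM is guaranteed not to decrease
            loglik = float(norm.sum()) + 0.5 * float(np.log(prof).sum()) \
                - 0.5 * 1e-6 * float(beta @ beta)
            z = np.exp(a - norm)
            if trace and abs(loglik - trace[-1]) < tol:
                trace.append(loglik)
                converged = True
                break
            trace.append(loglik)
        return z, lam1, lam0, prof, beta, trace, converged

    def _oriented(lam1: float, lam0: float, prof: np.ndarray) -> bool:
        # identifiability: bound is the higher-rate component; at
        # indistinguishable rates, the one whose profile is depleted in
        # the window center (the footprint shape)
        if lam1 < lam0 * (1 - 0.02):
            return False
        if lam1 > lam0 * (1 + 0.02):
            return True
        return prof[c_lo:c_hi].sum() <= (c_hi - c_lo) / w

    z0 = z.copy()
    z, lam1, lam0, prof, beta, loglik_trace, converged = _run(z)
    if not _oriented(lam1, lam0, prof):
        # wrong basin: restart once from the flipped initialization
        z, lam1, lam0, prof, beta, loglik_trace, converged = _run(1 - z0)

    return FootprintFit(
        posterior=z, bound=z > posterior_cut, loglik_trace=loglik_trace,
        rate_bound=lam1, rate_unbound=lam0, profile=prof, beta=beta,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# GRN assembly
# ---------------------------------------------------------------------------

def select_upstream_tfs(enrichment: pd.DataFrame,
                        expression: pd.DataFrame,
                        design: pd.DataFrame,
                        motif_gene_map: Mapping[str, str],
                        fdr_cut: float = 0.05,
                        min_fold: float = 1.5) -> list[str]:
    """TFs that are motif-enriched (BH FDR < cut) AND transcriptionally
    induced: mean normalized expression at 1, 2 or 4 dpa at least
    ``min_fold`` times the 0 dpa mean."""
    from .transcriptome import size_factors

    sf = size_factors(expression)
    norm = expression / sf
    tp_of = dict(zip(design["sample"], design["timepoint"]))
    selected = []
    for _, row in enrichment.iterrows():
        if not row["fdr"] < fdr_cut:
            continue
        gene = motif_gene_map.get(row["pwm"])
        if gene is None or gene not in norm.index:
            continue
        vals = norm.loc[gene]
        mean_tp = {}
        for col in norm.columns:
            mean_tp.setdefault(tp_of.get(col), []).append(float(vals[col]))
        base = np.mean(mean_tp.get(0, [np.nan]))
        if not np.isfinite(base) or base <= 0:
            continue
        if any(np.mean(mean_tp[t]) >= min_fold * base
               for t in (1, 2, 4) if t in mean_tp):
            selected.append(row["pwm"])
    return selected


def build_grn(selected_tfs: Sequence[str],
              bound_sites: Sequence[tuple[str, GenomicInterval]],
              gained_dars: Sequence[GenomicInterval],
              tss: Sequence[tuple[str, int, str]],
              upregulated: set[str],
              motif_gene_map: Mapping[str, str]) -> list[RegulatoryEdge]:
    """Assemble TF -> target edges.

    An edge fires when a selected TF's bound site falls inside a gained
    DAR and the DAR's nearest-TSS gene is upregulated.  Edge types: auto
    (target is the TF's own gene), tf_tf (target is another selected TF's
    gene), tf_target otherwise.  Deduplicated per (TF, target), keeping
    the bound site closest to the target TSS; output order is independent
    of input order.
    """
    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for chrom, p, gene_id in tss:
        tss_by_chrom.setdefault(chrom, []).append((p, gene_id))
    for v in tss_by_chrom.values():
        v.sort()
    dars_sorted = sorted(gained_dars, key=lambda d: (d.chrom, d.start))
    tf_genes = {motif_gene_map.get(t) for t in selected_tfs}
    selected = set(selected_tfs)

    best: dict[tuple[str, str], tuple[int, RegulatoryEdge]] = {}
    for tf, site in sorted(bound_sites,
                           key=lambda s: (s[0], s[1].chrom, s[1].start)):
        if tf not in selected:
            continue
        dar = next((d for d in dars_sorted if d.overlaps(site)), None)
        if dar is None:
            continue
        cands = tss_by_chrom.get(site.chrom, [])
        if not cands:
            continue
        center = site.center
        dist, gene = min((abs(center - p), gid) for p, gid in cands)
        if gene not in upregulated:
            continue
        if gene == motif_gene_map.get(tf):
            etype = "auto"
        elif gene in tf_genes:
            etype = "tf_tf"
        else:
            etype = "tf_target"
        key = (tf, gene)
        edge = RegulatoryEdge(tf, gene, site, dar, etype)
        if key not in best or dist < best[key][0]:
            best[key] = (dist, edge)
    return [e for _, e in sorted(best.values(),
                                 key=lambda t: (t[1].tf, t[1].target))]


def compare_target_response(fc_mutant: Mapping[str, float],
                            fc_wildtype: Mapping[str, float],
                            targets: set[str], nontargets: set[str]) -> dict:
    """Paired two-sided Wilcoxon signed-rank test of mutant vs wildtype
    fold changes within targets and within nontargets."""

    def _test(genes: set[str]) -> dict:
        both = sorted(g for g in genes
                      if g in fc_mutant and g in fc_wildtype)
        a = np.asarray([fc_mutant[g] for g in both], dtype=float)
        b = np.asarray([fc_wildtype[g] for g in both], dtype=float)
        if len(both) == 0:
            return {"n": 0, "p": float("nan")}
        diff = a - b
        if np.allclose(diff, 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(a, b, alternative="two-sided",
                                     zero_method="wilcox").pvalue)
        return {
            "n": len(both), "p": p,
            "median_mutant": float(np.median(a)),
            "median_wildtype": float(np.median(b)),
            "q25_diff": float(np.percentile(diff, 25)),
            "q75_diff": float(np.percentile(diff, 75)),
        }

    return {"targets": _test(targets), "nontargets": _test(nontargets)}


# ---------------------------------------------------------------------------
# gRNA scoring
# ---------------------------------------------------------------------------

def score_grna(sequence: str, prop_transcripts: float, rel_pos: float) -> float:
    """Protospacer score:

    60 x GC proportion + 10 x proportion of transcripts targeted
    - 30 x relative position in gene + 2 if base 20 is G - 3 if base 20
    is A ("position 20" is the 20th base, 1-based).
    """
    seq = sequence.upper()
    if len(seq) != 20 or any(b not in "ACGT" for b in seq):
        raise ValueError("sequence must be a 20-mer over A/C/G/T")
    if not (0 <= prop_transcripts <= 1 and 0 <= rel_pos <= 1):
        raise ValueError("prop_transcripts and rel_pos must be in [0, 1]")
    gc = sum(b in "GC" for b in seq) / 20.0
    score = 60.0 * gc + 10.0 * prop_transcripts - 30.0 * rel_pos
    if seq[19] == "G":
        score += 2.0
    elif seq[19] == "A":
        score -= 3.0
    return score
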