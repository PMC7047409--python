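"""Tn5 insertion processing: strand-offset correction, Poisson window peak
calling, replicate reproducibility, insertion counting, differential
accessibility, and TSS-distance annotation.

Counting is insertion-centric: every event is a single base position and
interval membership is half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomicInterval
from .transcriptome import nb_wald_test

__all__ = [
    "InsertionTrack", "Peak",
    "adjust_tn5", "fragment_to_endpoints", "read_endpoint_bed",
    "call_peaks", "reproducible_peaks", "count_insertions",
    "test_dars", "annotate_peaks",
]

TN5_PLUS_OFFSET = 4
TN5_MINUS_OFFSET = -5


@dataclass
class InsertionTrack:
    """Strand-adjusted Tn5 insertion positions, sorted per chromosome."""

    sample_id: str
    positions: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def library_size(self) -> int:
        return int(sum(len(v) for v in self.positions.values()))

    @classmethod
    def from_positions(cls, sample_id: str,
                       positions: Mapping[str, Iterable[int]]) -> "InsertionTrack":
        return cls(sample_id, {
            c: np.sort(np.asarray(list(v), dtype=np.int64))
            for c, v in positions.items()
        })


@dataclass
class Peak:
    interval: GenomicInterval
    summit: int
    enrichment: float
    reproducible: bool = False

    def __post_init__(self) -> None:
        if not self.interval.start <= self.summit < self.interval.end:
            raise ValueError("summit outside peak interval")


def fragment_to_endpoints(chrom: str, start: int, end: int
                          ) -> list[tuple[str, int, str]]:
    """Both ends of a fragment are separate Tn5 insertion events: the left
    end on the + strand, the right end on the - strand."""
    return [(chrom, start, "+"), (chrom, end, "-")]


def read_endpoint_bed(path: str) -> list[tuple[str, int, str]]:
    """Read BED6 of read endpoints: position = start for +, end for -."""
    out: list[tuple[str, int, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) >= 6 else "."
            pos = int(f[1]) if strand != "-" else int(f[2])
            out.append((f[0], pos, strand))
    return out


def adjust_tn5(endpoints: Iterable[tuple[str, int, str]],
               sample_id: str = "sample",
               chrom_sizes: Mapping[str, int] | None = None
               ) -> tuple[InsertionTrack, dict]:
    """Offset read endpoints to Tn5 insertion centers: +4 bp on the +
    strand, -5 bp on the - strand.

    Records without a strand are skipped; out-of-bounds results are
    clipped; both are tallied in the returned stats.
    """
    positions: dict[str, list[int]] = {}
    stats_ = {"n_in": 0, "n_skipped_no_strand": 0, "n_clipped": 0}
    for chrom, pos, strand in endpoints:
        stats_["n_in"] += 1
        if strand == "+":
            p = pos + TN5_PLUS_OFFSET
        elif strand == "-":
            p = pos + TN5_MINUS_OFFSET
        else:
            stats_["n_skipped_no_strand"] += 1
            continue
        hi = chrom_sizes.get(chrom) if chrom_sizes else None
        if p < 0 or (hi is not None and p >= hi):
            p = min(max(p, 0), (hi - 1) if hi is not None else max(p, 0))
            stats_["n_clipped"] += 1
        positions.setdefault(chrom, []).append(p)
    return InsertionTrack.from_positions(sample_id, positions), stats_


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def call_peaks(track: InsertionTrack, chrom_sizes: Mapping[str, int],
               window: int = 200, step: int = 50, local_bg: int = 10_000,
               p_cut: float = 0.01) -> list[Peak]:
    """Sliding-window Poisson peak caller.

    Per window, the expected count is ``window`` times the larger of the
    genome-wide and local (``local_bg`` span) insertion rates; windows
    with a significant Poisson upper tail are merged into peaks.
    ``p_cut`` is a genome-wide (family-wise) level: the per-window
    threshold is Bonferroni-corrected by the total window count, so a
    uniform track yields no peaks with probability >= 1 - p_cut.
    """
    genome_len = sum(chrom_sizes.values())
    lib = track.library_size
    if lib == 0:
        return []
    genome_rate = lib / genome_len
    n_windows_total = sum(
        len(np.arange(0, max(clen - window, 1), step))
        for clen in chrom_sizes.values()
    )
    per_window_cut = p_cut / max(n_windows_total, 1)
    peaks: list[Peak] = []
    for chrom in sorted(track.positions):
        pos = track.positions[chrom]
        clen = chrom_sizes[chrom]
        starts = np.arange(0, max(clen - window, 1), step)
        counts = (np.searchsorted(pos, starts + window, side="left")
                  - np.searchsorted(pos, starts, side="left"))
        centers = starts + window // 2
        lo = np.maximum(centers - local_bg // 2, 0)
        hi = np.minimum(centers + local_bg // 2, clen)
        local_counts = (np.searchsorted(pos, hi, side="left")
                        - np.searchsorted(pos, lo, side="left"))
        local_rate = local_counts / np.maximum(hi - lo, 1)
        expected = window * np.maximum(genome_rate, local_rate)
        p = stats.poisson.sf(counts - 1, expected)
        sig = p < per_window_cut
        if not sig.any():
            continue
        # merge overlapping significant windows
        idx = np.nonzero(sig)[0]
        run_start = starts[idx[0]]
        run_end = starts[idx[0]] + window
        regions: list[tuple[int, int]] = []
        for k in idx[1:]:
            if starts[k] <= run_end:
                run_end = starts[k] + window
            else:
                regions.append((run_start, run_end))
                run_start, run_end = starts[k], starts[k] + window
        regions.append((run_start, run_end))
        for s, e in regions:
            sel = pos[(pos >= s) & (pos < e)]
            if len(sel) == 0:
                continue
            bc = np.bincount(sel - s, minlength=e - s)
            summit = int(s + bc.argmax())
            rate = len(sel) / (e - s)
            peaks.append(Peak(
                interval=GenomicInterval(chrom, int(s), int(e)),
                summit=summit,
                enrichment=float(rate / genome_rate),
            ))
    peaks.sort(key=lambda pk: (pk.interval.chrom, pk.interval.start))
    return peaks


def _reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def reproducible_peaks(peaks_rep1: Sequence[Peak], peaks_rep2: Sequence[Peak],
                       min_overlap: float = 0.5,
                       max_rank_diff: float = 0.5) -> list[Peak]:
    """Replicate-reproducible peaks by reciprocal overlap + rank concordance.

    A rep1 peak survives if some rep2 peak reciprocally overlaps it by at
    least ``min_overlap`` AND the pair's enrichment ranks (descending,
    normalized to [0, 1] within the matched pairs) differ by no more than
    ``max_rank_diff`` — a documented stand-in for the copula-based
    irreproducible-discovery-rate model.
    """
    if not peaks_rep1 or not peaks_rep2:
        return []
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks_rep2:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    pairs: list[tuple[Peak, Peak]] = []
    for p1 in peaks_rep1:
        best = None
        best_ov = min_overlap
        for p2 in by_chrom.get(p1.interval.chrom, []):
            ov = _reciprocal_overlap(p1.interval, p2.interval)
            if ov >= best_ov:
                best, best_ov = p2, ov
        if best is not None:
            pairs.append((p1, best))
    if not pairs:
        return []
    r1 = stats.rankdata([-p.enrichment for p, _ in pairs])
    r2 = stats.rankdata([-q.enrichment for _, q in pairs])
    n = len(pairs)
    keep = np.abs(r1 - r2) / n <= max_rank_diff
    out = []
    for (p1, _), k in zip(pairs, keep):
        if k:
            out.append(Peak(p1.interval, p1.summit, p1.enrichment,
                            reproducible=True))
    return out


def count_insertions(peaks: Sequence[GenomicInterval],
                     tracks: Sequence[InsertionTrack]) -> pd.DataFrame:
    """Count matrix (peaks x samples) of insertions with position in
    [start, end); carries library sizes in ``attrs``."""
    data = {}
    for tr in tracks:
        col = np.zeros(len(peaks), dtype=np.int64)
        for i, pk in enumerate(peaks):
            pos = tr.positions.get(pk.chrom)
            if pos is None:
                continue
            col[i] = (np.searchsorted(pos, pk.end, side="left")
                      - np.searchsorted(pos, pk.start, side="left"))
        data[tr.sample_id] = col
    idx = [f"{p.chrom}:{p.start}-{p.end}" for p in peaks]
    df = pd.DataFrame(data, index=idx)
    df.attrs["library_sizes"] = {t.sample_id: t.library_size for t in tracks}
    return df


def test_dars(counts: pd.DataFrame, group1: Sequence[str],
              group2: Sequence[str], fc_cut: float = 2.0,
              fdr_cut: float = 0.01) -> pd.DataFrame:
    """Differential accessibility of group2 vs group1 on the shared NB
    Wald engine.  Returns all peaks with a ``direction`` column; reported
    DARs are the rows with direction gained/lost (|log2FC| > log2(fc_cut)
    and FDR < fdr_cut)."""
    res = nb_wald_test(counts, group1, group2)
    lcut = np.log2(fc_cut)
    direction = np.where(
        (res["log2_fold"] > lcut) & (res["fdr"] < fdr_cut), "gained",
        np.where((res["log2_fold"] < -lcut) & (res["fdr"] < fdr_cut),
                 "lost", "ns"),
    )
    direction = np.where(np.isnan(res["p"]), "ns", direction)
    res = res.copy()
    res["direction"] = direction
    return res


def annotate_peaks(peaks: Sequence[GenomicInterval],
                   tss: Sequence[tuple[str, int, str]],
                   promoter_dist: int = 2_000,
                   distal_dist: int = 10_000) -> list[str]:
    """Label each peak promoter/proximal/distal by its center's distance
    to the nearest TSS (promoter boundary inclusive); TSS ties break to
    the lexicographically smallest gene id."""
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for gene_id, pos, chrom in [(g, p, c) for (c, p, g) in tss]:
        by_chrom.setdefault(chrom, []).append((pos, gene_id))
    for v in by_chrom.values():
        v.sort()
    labels = []
    for pk in peaks:
        cand = by_chrom.get(pk.chrom, [])
        if not cand:
            labels.append("distal")
            continue
        center = pk.center
        d = min(abs(center - p) for p, _ in cand)
        if d <= promoter_dist:
            labels.append("promoter")
        elif d > distal_dist:
            labels.append("distal")
        else:
            labels.append("proximal")
    return labels
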