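"""Seeded multi-omics simulator with a ground-truth ledger.

Generates methylome count tables, Tn5 insertion tracks, expression count
matrices, a random genome with planted motif instances, and gene
annotation — all sharing one deterministic genomic layout so that planted
differential regions, footprints and regulatory edges stay mutually
consistent.  Every planted element is recorded in a :class:`SyntheticTruth`
ledger sufficient to score recovery of any downstream stage.

Layout: the genome is partitioned into equal blocks, one gene per block
with its TSS at the block center.  Peaks, differential regions and
methylation elements are placed at fixed offsets from each TSS, which
makes nearest-TSS assignment of planted enhancers unambiguous.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .io_formats import (
    Gene,
    GenomicInterval,
    Pwm,
    write_bed,
    write_counts_tsv,
    write_fasta,
    write_gtf,
    write_methylc,
    write_pwm,
    CpGRecord,
)

__all__ = ["SimConfig", "SyntheticTruth", "Layout", "build_layout",
           "simulate_methylome", "simulate_atac", "simulate_rnaseq",
           "simulate_genome", "simulate_all"]

MOTIF_LEN = 10
PEAK_HALF = 200          # peaks are 400 bp
DMR_WIDTH = 500
DMR_CPGS = 8
DAR_CPGS = 5
FOOTPRINT_WINDOW = 200
# offsets of peak centers from the block TSS, cycled per placement round
_PEAK_OFFSETS = (-300, 5_000, -11_500, 11_000, 8_000, -7_000)
_DMR_OFFSETS = (13_000, -13_000, 6_400)
_GLOBAL_METH_TARGET = 0.80
_PROMOTER_MEAN = 0.08
_HYPER_MEAN = 0.85
_ENHANCER_MEAN = 0.15
_NONENHANCER_MEAN = 0.90


class SimConfig(BaseModel):
    """All knobs of the simulator; validated on construction."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_chroms: int = Field(2, ge=1)
    chrom_len: int = Field(3_000_000, ge=50_000)
    n_cpgs: int = Field(20_000, ge=100)
    n_genes: int = Field(200, ge=2)
    n_peaks: int = Field(200, ge=0)
    n_celltype_dmrs: int = Field(60, ge=0)
    n_time_dmrs: int = Field(0, ge=0)
    dmr_effect: float = Field(0.4, ge=0.0, le=0.8)
    mean_coverage: float = Field(20.0, gt=0)
    dispersion_phi: float = Field(0.05, ge=0.0, lt=0.5)
    n_dars: int = Field(60, ge=0)
    dar_fold: float = Field(4.0, ge=1.0)
    n_de_genes: int = Field(40, ge=0)
    de_fold: float = Field(4.0, ge=1.0)
    nb_dispersion: float = Field(0.05, gt=0.0)
    n_footprint_motifs: int = Field(3, ge=0)
    footprint_depletion: float = Field(0.7, ge=0.0, le=1.0)
    n_reps: int = Field(2, ge=1)
    background_insertion_rate: float = Field(0.004, gt=0)
    peak_enrichment: float = Field(25.0, gt=1)
    enhancer_fraction: float = Field(0.7, ge=0.0, le=1.0)
    n_bound_sites_per_tf: int = Field(8, ge=1)
    timepoints: tuple[int, ...] = (0, 1, 2, 4)
    celltypes: tuple[str, ...] = ("pos", "neg")

    @model_validator(mode="after")
    def _check_geometry(self) -> "SimConfig":
        if self.n_genes % self.n_chroms != 0:
            raise ValueError("n_genes must be divisible by n_chroms")
        block = self.chrom_len // (self.n_genes // self.n_chroms)
        if block < 28_000:
            raise ValueError(
                f"block size {block} bp too small for the fixed element layout "
                "(need >= 28 kb per gene); increase chrom_len or reduce n_genes"
            )
        if self.n_peaks > len(_PEAK_OFFSETS) * self.n_genes:
            raise ValueError("n_peaks exceeds available peak slots (6 per gene)")
        if self.n_celltype_dmrs + self.n_time_dmrs > len(_DMR_OFFSETS) * self.n_genes:
            raise ValueError("too many DMRs for available DMR slots (3 per gene)")
        if self.n_dars > self.n_peaks:
            raise ValueError("n_dars exceeds n_peaks")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes exceeds n_genes")
        if self.n_footprint_motifs > self.n_genes:
            raise ValueError("n_footprint_motifs exceeds n_genes")
        return self


def _iv(chrom: str, start: int, end: int, strand: str = ".") -> list:
    return [chrom, int(start), int(end), strand]


@dataclass
class SyntheticTruth:
    """Ground-truth ledger of every planted element.

    Intervals are ``[chrom, start, end, strand]`` lists so the ledger
    serializes to plain JSON.
    """

    dmrs: list[dict] = field(default_factory=list)
    time_dmrs: list[dict] = field(default_factory=list)
    peaks: list[dict] = field(default_factory=list)
    dars: list[dict] = field(default_factory=list)
    enhancers: list[dict] = field(default_factory=list)
    de_genes: list[dict] = field(default_factory=list)
    tf_genes: list[dict] = field(default_factory=list)
    bound_sites: list[dict] = field(default_factory=list)
    decoy_sites: list[dict] = field(default_factory=list)
    edges: list[dict] = field(default_factory=list)
    genes: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class Layout:
    """Deterministic element placement shared by all simulate_* stages."""

    config: SimConfig
    chrom_names: list[str]
    genes: list[Gene]
    peaks: list[GenomicInterval]
    peak_block: list[int]              # owning gene/block index per peak
    gained_dars: list[int]             # peak indices
    lost_dars: list[int]
    enhancer_dars: list[int]           # subset of gained_dars, low stable meth
    dmr_regions: list[GenomicInterval]
    time_dmr_regions: list[GenomicInterval]
    tf_gene_idx: list[int]
    target_gene_idx: list[int]
    de_up_idx: list[int]
    de_down_idx: list[int]
    bound_sites: list[dict]            # tf, core interval, window, peak idx
    decoy_sites: list[dict]
    motifs: list[Pwm]
    truth: SyntheticTruth


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def build_layout(config: SimConfig) -> Layout:
    """Place every element deterministically from the config seed."""
    cfg = config
    gpc = cfg.n_genes // cfg.n_chroms
    block = cfg.chrom_len // gpc
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    rng = _rng(cfg, 0)

    genes: list[Gene] = []
    for gi in range(cfg.n_genes):
        chrom = chrom_names[gi // gpc]
        tss = (gi % gpc) * block + block // 2
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            interval = GenomicInterval(chrom, tss, tss + 2000, "+")
        else:
            interval = GenomicInterval(chrom, tss - 1999, tss + 1, "-")
        genes.append(Gene(gene_id=f"gene{gi:04d}", interval=interval))

    peaks: list[GenomicInterval] = []
    peak_block: list[int] = []
    peak_offset: list[int] = []
    for k in range(cfg.n_peaks):
        b = k % cfg.n_genes
        off = _PEAK_OFFSETS[k % len(_PEAK_OFFSETS)] if cfg.n_peaks <= cfg.n_genes \
            else _PEAK_OFFSETS[(k // cfg.n_genes) % len(_PEAK_OFFSETS)]
        center = genes[b].tss + off
        peaks.append(GenomicInterval(genes[b].interval.chrom,
                                     center - PEAK_HALF, center + PEAK_HALF))
        peak_block.append(b)
        peak_offset.append(off)

    # DAR selection: gained DARs drawn from distal peak slots first so that
    # planted enhancers sit > 10 kb from any TSS.
    distal = [i for i, off in enumerate(peak_offset) if abs(off) > 10_000]
    nondistal = [i for i in range(cfg.n_peaks) if abs(peak_offset[i]) <= 10_000]
    n_dars = cfg.n_dars if cfg.dar_fold > 1.0 else 0
    n_gained = (n_dars + 1) // 2
    gained = distal[:n_gained]
    if len(gained) < n_gained:
        gained += nondistal[: n_gained - len(gained)]
    lost_pool = [i for i in nondistal + distal if i not in set(gained)]
    lost = lost_pool[: n_dars - len(gained)]

    n_enh = math.ceil(cfg.enhancer_fraction * len(gained))
    enhancer_dars = [i for i in gained if abs(peak_offset[i]) > 2_000][:n_enh]

    n_ct_dmrs = cfg.n_celltype_dmrs if cfg.dmr_effect > 0 else 0
    n_t_dmrs = cfg.n_time_dmrs if cfg.dmr_effect > 0 else 0
    dmr_regions: list[GenomicInterval] = []
    time_dmr_regions: list[GenomicInterval] = []
    for j in range(n_ct_dmrs + n_t_dmrs):
        b = j % cfg.n_genes
        off = _DMR_OFFSETS[j // cfg.n_genes]
        start = genes[b].tss + off - DMR_WIDTH // 2
        region = GenomicInterval(genes[b].interval.chrom, start, start + DMR_WIDTH)
        (dmr_regions if j < n_ct_dmrs else time_dmr_regions).append(region)

    # TFs and their bound sites inside enhancer (gained, hypomethylated) DARs
    n_tfs = cfg.n_footprint_motifs
    motifs: list[Pwm] = []
    seen: set[str] = set()
    while len(motifs) < n_tfs:
        cons = "".join("ACGT"[i] for i in rng.integers(0, 4, MOTIF_LEN))
        if cons in seen or "N" in cons:
            continue
        seen.add(cons)
        mat = np.full((MOTIF_LEN, 4), 0.05)
        for i, base in enumerate(cons):
            mat[i, "ACGT".index(base)] = 0.85
        motifs.append(Pwm(name=f"TF{len(motifs)}", matrix=mat))

    bound_sites: list[dict] = []
    for t in range(n_tfs):
        for pk in enhancer_dars[t::n_tfs][: cfg.n_bound_sites_per_tf]:
            center = peaks[pk].center
            core = GenomicInterval(peaks[pk].chrom,
                                   center - MOTIF_LEN // 2,
                                   center - MOTIF_LEN // 2 + MOTIF_LEN)
            window = GenomicInterval(peaks[pk].chrom,
                                     center - FOOTPRINT_WINDOW // 2,
                                     center + FOOTPRINT_WINDOW // 2)
            bound_sites.append({"tf": f"TF{t}", "core": core, "window": window,
                                "peak": pk})
    decoy_sites: list[dict] = []
    decoy_pool = [i for i in range(cfg.n_peaks)
                  if i not in set(gained)][::6]
    for j, pk in enumerate(decoy_pool):
        if n_tfs == 0:
            break
        center = peaks[pk].center
        core = GenomicInterval(peaks[pk].chrom, center - MOTIF_LEN // 2,
                               center - MOTIF_LEN // 2 + MOTIF_LEN)
        decoy_sites.append({"tf": f"TF{j % n_tfs}", "core": core, "peak": pk})

    # expression programme: TF genes rise from 1 dpa; each bound site's
    # nearest gene (= its block's gene) becomes an upregulated target
    target_gene_idx = sorted({peak_block[s["peak"]] for s in bound_sites})
    tf_pool = [i for i in range(cfg.n_genes) if i not in set(target_gene_idx)]
    tf_gene_idx = tf_pool[-n_tfs:] if n_tfs else []
    n_de = cfg.n_de_genes if cfg.de_fold > 1.0 else 0
    extra_pool = [i for i in range(cfg.n_genes)
                  if i not in set(target_gene_idx) | set(tf_gene_idx)]
    n_extra = max(0, n_de - len(target_gene_idx))
    extra = extra_pool[:n_extra]
    de_up_idx = (target_gene_idx + extra[: len(extra) // 2]) if n_de else []
    de_down_idx = extra[len(extra) // 2:] if n_de else []

    truth = SyntheticTruth()
    truth.genes = [
        {"gene_id": g.gene_id, "interval": _iv(g.interval.chrom, g.interval.start,
                                               g.interval.end, g.interval.strand),
         "tss": g.tss}
        for g in genes
    ]
    truth.peaks = [{"interval": _iv(p.chrom, p.start, p.end)} for p in peaks]
    for pk in gained:
        truth.dars.append({"interval": _iv(peaks[pk].chrom, peaks[pk].start,
                                           peaks[pk].end),
                           "direction": "gained", "peak": pk})
    for pk in lost:
        truth.dars.append({"interval": _iv(peaks[pk].chrom, peaks[pk].start,
                                           peaks[pk].end),
                           "direction": "lost", "peak": pk})
    for pk in enhancer_dars:
        truth.enhancers.append({"interval": _iv(peaks[pk].chrom, peaks[pk].start,
                                                peaks[pk].end),
                                "peak": pk,
                                "target": genes[peak_block[pk]].gene_id})
    for r in dmr_regions:
        truth.dmrs.append({"interval": _iv(r.chrom, r.start, r.end),
                           "hypo_in": "pos",
                           "mean_pos": _HYPER_MEAN - cfg.dmr_effect,
                           "mean_neg": _HYPER_MEAN})
    for r in time_dmr_regions:
        truth.time_dmrs.append({"interval": _iv(r.chrom, r.start, r.end),
                                "hypo_in": "t4",
                                "mean_t0": _HYPER_MEAN,
                                "mean_t4": _HYPER_MEAN - cfg.dmr_effect})
    for gi in de_up_idx:
        truth.de_genes.append({"gene_id": genes[gi].gene_id,
                               "log2_fold": math.log2(cfg.de_fold)})
    for gi in de_down_idx:
        truth.de_genes.append({"gene_id": genes[gi].gene_id,
                               "log2_fold": -math.log2(cfg.de_fold)})
    for t, gi in enumerate(tf_gene_idx):
        truth.tf_genes.append({"tf": f"TF{t}", "gene_id": genes[gi].gene_id})
    for s in bound_sites:
        truth.bound_sites.append({"tf": s["tf"],
                                  "core": _iv(s["core"].chrom, s["core"].start,
                                              s["core"].end),
                                  "window": _iv(s["window"].chrom,
                                                s["window"].start,
                                                s["window"].end),
                                  "peak": s["peak"]})
    for s in decoy_sites:
        truth.decoy_sites.append({"tf": s["tf"],
                                  "core": _iv(s["core"].chrom, s["core"].start,
                                              s["core"].end),
                                  "peak": s["peak"]})
    edge_seen: set[tuple[str, str]] = set()
    for s in bound_sites:
        target = genes[peak_block[s["peak"]]].gene_id
        key = (s["tf"], target)
        if key in edge_seen:
            continue
        edge_seen.add(key)
        tf_ids = {genes[i].gene_id for i in tf_gene_idx}
        etype = "auto" if target == dict(
            (f"TF{t}", genes[g].gene_id) for t, g in enumerate(tf_gene_idx)
        ).get(s["tf"]) else ("tf_tf" if target in tf_ids else "tf_target")
        truth.edges.append({"tf": s["tf"], "target": target,
                            "site": _iv(s["core"].chrom, s["core"].start,
                                        s["core"].end),
                            "dar": _iv(peaks[s["peak"]].chrom,
                                       peaks[s["peak"]].start,
                                       peaks[s["peak"]].end),
                            "type": etype})

    return Layout(config=cfg, chrom_names=chrom_names, genes=genes, peaks=peaks,
                  peak_block=peak_block, gained_dars=gained, lost_dars=lost,
                  enhancer_dars=enhancer_dars, dmr_regions=dmr_regions,
                  time_dmr_regions=time_dmr_regions, tf_gene_idx=tf_gene_idx,
                  target_gene_idx=target_gene_idx, de_up_idx=de_up_idx,
                  de_down_idx=de_down_idx, bound_sites=bound_sites,
                  decoy_sites=decoy_sites, motifs=motifs, truth=truth)


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

def _cpg_positions(layout: Layout) -> tuple[np.ndarray, np.ndarray]:
    """CpG dyad positions: guaranteed CpGs in DMR/DAR regions + random rest.

    Returns (chrom_index, pos) arrays sorted by (chrom, pos).
    """
    cfg = layout.config
    rng = _rng(cfg, 1)
    chrom_idx: list[int] = []
    pos: list[int] = []
    cidx = {c: i for i, c in enumerate(layout.chrom_names)}

    def _plant(region: GenomicInterval, n: int) -> None:
        step = region.length // (n + 1)
        for k in range(1, n + 1):
            chrom_idx.append(cidx[region.chrom])
            pos.append(region.start + k * step)

    for r in layout.dmr_regions + layout.time_dmr_regions:
        _plant(r, DMR_CPGS)
    for pk in set(layout.gained_dars) | set(layout.lost_dars):
        _plant(layout.peaks[pk], DAR_CPGS)

    n_rest = max(0, cfg.n_cpgs - len(pos))
    g = rng.integers(0, cfg.n_chroms * (cfg.chrom_len // 2 - 2), n_rest)
    chrom_idx.extend((g // (cfg.chrom_len // 2 - 2)).tolist())
    pos.extend((2 * (g % (cfg.chrom_len // 2 - 2)) + 1).tolist())

    arr = np.unique(np.stack([np.asarray(chrom_idx), np.asarray(pos)], axis=1),
                    axis=0)
    return arr[:, 0], arr[:, 1]


def _true_means(layout: Layout, chrom_idx: np.ndarray, pos: np.ndarray
                ) -> dict[tuple[str, int], np.ndarray]:
    """Per-CpG true methylation mean for every (celltype, timepoint)."""
    cfg = layout.config
    rng = _rng(cfg, 2)
    n = len(pos)
    cidx = {c: i for i, c in enumerate(layout.chrom_names)}

    def _member(regions: list[GenomicInterval]) -> np.ndarray:
        mask = np.zeros(n, dtype=bool)
        for r in regions:
            mask |= (chrom_idx == cidx[r.chrom]) & (pos >= r.start) & (pos < r.end)
        return mask

    in_ct_dmr = _member(layout.dmr_regions)
    in_t_dmr = _member(layout.time_dmr_regions)
    in_enh = _member([layout.peaks[i] for i in layout.enhancer_dars])
    other_gained = [layout.peaks[i] for i in layout.gained_dars
                    if i not in set(layout.enhancer_dars)]
    in_hyper_dar = _member(other_gained)
    prom = _member([GenomicInterval(g.interval.chrom, max(0, g.tss - 1000),
                                    g.tss + 1000) for g in layout.genes])

    special = in_ct_dmr | in_t_dmr | in_enh | in_hyper_dar
    prom = prom & ~special
    bg = ~(special | prom)

    base = np.empty(n)
    base[prom] = np.clip(rng.beta(_PROMOTER_MEAN * 10, (1 - _PROMOTER_MEAN) * 10,
                                  prom.sum()), 0.01, 0.99)
    # solve the background high-mode mean so the genome-wide level hits the
    # target despite low-methylation promoters and planted elements
    fixed = (prom.mean() * _PROMOTER_MEAN
             + in_enh.mean() * _ENHANCER_MEAN
             + in_hyper_dar.mean() * _NONENHANCER_MEAN
             + in_ct_dmr.mean() * (_HYPER_MEAN - cfg.dmr_effect / 2)
             + in_t_dmr.mean() * (_HYPER_MEAN - cfg.dmr_effect / 2))
    mu_high = (_GLOBAL_METH_TARGET - fixed) / max(bg.mean(), 1e-9)
    mu_high = float(np.clip(mu_high, 0.5, 0.95))
    base[bg] = np.clip(rng.beta(mu_high * 25, (1 - mu_high) * 25, bg.sum()),
                       0.01, 0.99)
    base[in_enh] = _ENHANCER_MEAN
    base[in_hyper_dar] = _NONENHANCER_MEAN
    base[in_ct_dmr] = _HYPER_MEAN
    base[in_t_dmr] = _HYPER_MEAN

    means: dict[tuple[str, int], np.ndarray] = {}
    for ct in cfg.celltypes:
        for tp in (0, 4):
            mu = base.copy()
            if ct == "pos":
                mu[in_ct_dmr] = _HYPER_MEAN - cfg.dmr_effect
            if tp == 4:
                mu[in_t_dmr] = _HYPER_MEAN - cfg.dmr_effect
            means[(ct, tp)] = mu
    return means


def simulate_methylome(config: SimConfig, layout: Layout | None = None
                       ) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Simulate per-sample CpG count tables for 2 cell types x 2 timepoints.

    Counts are beta-binomial: total ~ Poisson(mean_coverage) and the
    per-(CpG, sample) success probability ~ Beta with mean equal to the true
    methylation level and overdispersion ``phi = 1 / (a + b + 1)``.
    Replicates share true means.
    """
    layout = layout or build_layout(config)
    cfg = config
    chrom_idx, pos = _cpg_positions(layout)
    means = _true_means(layout, chrom_idx, pos)
    rng = _rng(cfg, 3)
    chroms = np.asarray(layout.chrom_names)[chrom_idx]

    samples: dict[str, pd.DataFrame] = {}
    for ct in cfg.celltypes:
        for tp in (0, 4):
            mu = np.clip(means[(ct, tp)], 0.01, 0.99)
            for rep in range(1, cfg.n_reps + 1):
                total = rng.poisson(cfg.mean_coverage, len(pos))
                if cfg.dispersion_phi > 0:
                    conc = 1.0 / cfg.dispersion_phi - 1.0
                    p = rng.beta(mu * conc, (1 - mu) * conc)
                else:
                    p = mu
                meth = rng.binomial(total, p)
                samples[f"{ct}_t{tp}_r{rep}"] = pd.DataFrame(
                    {"chrom": chroms, "pos": pos, "meth": meth, "total": total}
                )
    return samples, layout.truth


# ---------------------------------------------------------------------------
# ATAC
# ---------------------------------------------------------------------------

def simulate_atac(config: SimConfig, layout: Layout | None = None
                  ) -> tuple[dict[str, dict[str, np.ndarray]],
                             list[GenomicInterval], SyntheticTruth]:
    """Simulate Tn5 insertion tracks by an inhomogeneous Poisson process.

    Peaks multiply the background rate; gained DARs additionally multiply
    the 4 dpa rate by ``dar_fold`` (lost DARs: the 0 dpa rate); bound motif
    sites superimpose a trapezoid footprint (1.5x flanks, core depleted by
    ``footprint_depletion``) at 4 dpa.
    """
    layout = layout or build_layout(config)
    cfg = config
    rng = _rng(cfg, 4)
    tracks: dict[str, dict[str, np.ndarray]] = {}
    peak_rate = cfg.background_insertion_rate * cfg.peak_enrichment

    for ct in cfg.celltypes:
        for tp in (0, 4):
            rate: dict[str, np.ndarray] = {
                c: np.full(cfg.chrom_len, cfg.background_insertion_rate)
                for c in layout.chrom_names
            }
            for i, pk in enumerate(layout.peaks):
                r = peak_rate
                if i in set(layout.gained_dars) and tp == 4:
                    r *= cfg.dar_fold
                if i in set(layout.lost_dars) and tp == 0:
                    r *= cfg.dar_fold
                rate[pk.chrom][pk.start:pk.end] = r
            if tp == 4:
                for s in layout.bound_sites:
                    w, core = s["window"], s["core"]
                    local = rate[w.chrom][w.start]
                    flank = 1.5 * local
                    rate[w.chrom][w.start:w.end] = flank
                    rate[w.chrom][core.start:core.end] = (
                        (1.0 - cfg.footprint_depletion) * flank
                    )
            for rep in range(1, cfg.n_reps + 1):
                track: dict[str, np.ndarray] = {}
                for c in layout.chrom_names:
                    counts = rng.poisson(rate[c])
                    track[c] = np.repeat(
                        np.nonzero(counts)[0], counts[np.nonzero(counts)[0]]
                    )
                tracks[f"{ct}_t{tp}_r{rep}"] = track
    return tracks, list(layout.peaks), layout.truth


# ---------------------------------------------------------------------------
# RNA
# ---------------------------------------------------------------------------

def simulate_rnaseq(config: SimConfig, layout: Layout | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate a negative-binomial count matrix over the full time course.

    Returns (counts genes x samples, design table, truth).  Planted DE genes
    change by ``de_fold`` at 4 dpa; TF genes rise from 1 dpa onward.
    """
    layout = layout or build_layout(config)
    cfg = config
    rng = _rng(cfg, 5)
    n = cfg.n_genes
    base = np.clip(rng.lognormal(math.log(150.0), 0.8, n), 10.0, 5000.0)

    up = np.zeros(n, dtype=bool)
    down = np.zeros(n, dtype=bool)
    up[layout.de_up_idx] = True
    down[layout.de_down_idx] = True
    tf = np.zeros(n, dtype=bool)
    tf[layout.tf_gene_idx] = True

    cols: list[str] = []
    design_rows: list[dict] = []
    data: dict[str, np.ndarray] = {}
    for ct in cfg.celltypes:
        for tp in sorted(cfg.timepoints):
            mu = base.copy()
            if tp >= 1:
                mu[tf] *= cfg.de_fold
            if tp == 4:
                mu[up] *= cfg.de_fold
                mu[down] /= cfg.de_fold
            for rep in range(1, cfg.n_reps + 1):
                name = f"{ct}_t{tp}_r{rep}"
                shape = 1.0 / cfg.nb_dispersion
                data[name] = rng.negative_binomial(shape, shape / (shape + mu))
                cols.append(name)
                design_rows.append({"sample": name, "celltype": ct,
                                    "timepoint": tp, "replicate": rep})
    counts = pd.DataFrame(data, index=[g.gene_id for g in layout.genes])
    counts.index.name = "gene_id"
    design = pd.DataFrame(design_rows)
    return counts, design, layout.truth


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig, layout: Layout | None = None
                    ) -> tuple[dict[str, str], list[Gene], list[Pwm],
                               list[dict], SyntheticTruth]:
    """Random genome with the consensus of each TF planted at its truth sites."""
    layout = layout or build_layout(config)
    cfg = config
    rng = _rng(cfg, 6)
    seqs: dict[str, np.ndarray] = {
        c: rng.integers(0, 4, cfg.chrom_len, dtype=np.int8)
        for c in layout.chrom_names
    }
    cons = {p.name: p.consensus for p in layout.motifs}
    instances: list[dict] = []
    for s in layout.bound_sites + layout.decoy_sites:
        core: GenomicInterval = s["core"]
        enc = np.frombuffer(cons[s["tf"]].encode(), dtype=np.uint8)
        code = np.array([ "ACGT".index(chr(b)) for b in enc ], dtype=np.int8)
        seqs[core.chrom][core.start:core.end] = code
        instances.append({"tf": s["tf"], "interval": _iv(core.chrom, core.start,
                                                         core.end, "+")})
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = {c: alphabet[v].tobytes().decode() for c, v in seqs.items()}
    return out, layout.genes, layout.motifs, instances, layout.truth


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def _records_from_frame(df: pd.DataFrame) -> Iterator[CpGRecord]:
    for chrom, p, m, t in zip(df["chrom"], df["pos"], df["meth"], df["total"]):
        yield CpGRecord(str(chrom), int(p), int(m), int(t))


def simulate_all(config: SimConfig, outdir: str | Path) -> SyntheticTruth:
    """Run every generator and write all pipeline inputs plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = build_layout(config)

    meth, _ = simulate_methylome(config, layout)
    for name, df in meth.items():
        write_methylc(_records_from_frame(df), outdir / f"meth_{name}.methylc")

    tracks, peaks, _ = simulate_atac(config, layout)
    for name, track in tracks.items():
        with open(outdir / f"insertions_{name}.bed", "w") as fh:
            for chrom in sorted(track):
                for p in track[chrom]:
                    fh.write(f"{chrom}\t{p}\t{p + 1}\t.\t.\t+\n")
    write_bed([(p, {}) for p in peaks], outdir / "peaks.bed")

    counts, design, _ = simulate_rnaseq(config, layout)
    write_counts_tsv(counts, outdir / "rna_counts.tsv")
    design.to_csv(outdir / "design.tsv", sep="\t", index=False)

    seqs, genes, pwms, instances, truth = simulate_genome(config, layout)
    write_fasta(seqs, outdir / "genome.fa")
    write_gtf(genes, outdir / "genes.gtf")
    write_pwm(pwms, outdir / "motifs.meme")
    write_bed(
        [(GenomicInterval(*inst["interval"][:3], inst["interval"][3]),
          {"name": inst["tf"]}) for inst in instances],
        outdir / "motif_instances.bed",
    )
    with open(outdir / "motif_gene_map.tsv", "w") as fh:
        fh.write("motif\tgene_id\n")
        for row in truth.tf_genes:
            fh.write(f"{row['tf']}\t{row['gene_id']}\n")
    truth.to_json(outdir / "truth.json")
    with open(outdir / "config.json", "w") as fh:
        fh.write(config.model_dump_json(indent=1))
    return truth
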