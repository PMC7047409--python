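"""End-to-end driver: simulation -> methylome -> accessibility ->
expression -> enhancer classification -> regulatory network, with a
machine-readable report and truth-recovery metrics.

Deterministic given (config, seed); every stage logs input/output record
counts in a parseable ``stage=... n_in=... n_out=...`` form.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import accessibility as acc
from . import enhancer_integration as enh
from . import methylome as meth
from . import regulatory_network as grn
from . import synthetic_data as sim
from . import transcriptome as tx
from .config import PipelineConfig
from .io_formats import GenomicInterval

log = logging.getLogger("epikit")

__all__ = ["run_pipeline", "interval_recovery", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def interval_recovery(called: Sequence[GenomicInterval],
                      truth: Sequence[GenomicInterval]) -> dict:
    """Overlap-based precision/recall of called vs planted intervals."""
    def _hit(a: GenomicInterval, pool: Sequence[GenomicInterval]) -> bool:
        return any(a.overlaps(b) for b in pool)

    tp_called = sum(_hit(c, truth) for c in called)
    tp_truth = sum(_hit(t, called) for t in truth)
    return {
        "n_called": len(called),
        "n_truth": len(truth),
        "precision": tp_called / len(called) if called else float("nan"),
        "recall": tp_truth / len(truth) if truth else float("nan"),
    }


def _log_stage(stage: str, **counts: int) -> None:
    kv = " ".join(f"{k}={v}" for k, v in counts.items())
    log.info("stage=%s level=info %s", stage, kv)


def _truth_ivs(entries: list[dict], key: str = "interval"
               ) -> list[GenomicInterval]:
    return [GenomicInterval(*e[key][:3]) for e in entries]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on freshly simulated data; returns the report dict
    and writes the result bundle (tables + report.json) under outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.sim.model_copy(update={"seed": config.seed})
    report: dict = {"seed": config.seed}

    try:
        layout = sim.build_layout(cfg)
        truth = sim.simulate_all(cfg, outdir / "sim")
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage=simulate failed: {exc}") from exc

    # ---------------- methylome ----------------
    try:
        samples, _ = sim.simulate_methylome(cfg, layout)
        _log_stage("methylome", n_samples=len(samples))
        params = meth.DmrCallParams(**config.dmr.model_dump())
        report["methylome_summary"] = meth.methylome_summary(samples["pos_t0_r1"])

        reps = {
            "pos_t0": ([samples["pos_t0_r1"]], [samples["pos_t0_r2"]]),
            "neg_t0": ([samples["neg_t0_r1"]], [samples["neg_t0_r2"]]),
        } if cfg.n_reps >= 2 else {}
        conds = {
            "pos_t0_vs_t4": (
                [samples[f"pos_t0_r{r}"] for r in range(1, cfg.n_reps + 1)],
                [samples[f"pos_t4_r{r}"] for r in range(1, cfg.n_reps + 1)],
            ),
            "pos_vs_neg_t0": (
                [samples[f"pos_t0_r{r}"] for r in range(1, cfg.n_reps + 1)],
                [samples[f"neg_t0_r{r}"] for r in range(1, cfg.n_reps + 1)],
            ),
        }
        null_curve = meth.empirical_null_curve(
            reps, conds, config.null_thresholds, params)
        null_curve.to_csv(outdir / "dmr_null_curve.tsv", sep="\t", index=False)
        report["dmr_null_curve"] = null_curve.to_dict(orient="records")

        celltype_dmrs = meth.dmr_pipeline(
            conds["pos_vs_neg_t0"][0], conds["pos_vs_neg_t0"][1],
            params, labels=("pos", "neg"))
        _log_stage("dmr", n_called=len(celltype_dmrs))
        with open(outdir / "dmrs.bed", "w") as fh:
            for d in celltype_dmrs:
                fh.write(f"{d.interval.chrom}\t{d.interval.start}\t"
                         f"{d.interval.end}\t{d.hypo_in}\t{d.mean_diff:.4f}\t."
                         f"\t{d.n_cpgs}\t{d.area_stat:.3f}\n")
        report["n_celltype_dmrs"] = len(celltype_dmrs)
        report["dmr_recovery"] = interval_recovery(
            [d.interval for d in celltype_dmrs], _truth_ivs(truth.dmrs))

        pos_t0 = pd.concat([samples[f"pos_t0_r{r}"]
                            for r in range(1, cfg.n_reps + 1)])
        pos_t4 = pd.concat([samples[f"pos_t4_r{r}"]
                            for r in range(1, cfg.n_reps + 1)])
        hypo = [d.interval for d in celltype_dmrs if d.hypo_in == "pos"]
        report["hypodmr_stability"] = meth.stability_fraction(
            hypo, pos_t0, pos_t4)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage=methylome failed: {exc}") from exc

    # ---------------- accessibility ----------------
    try:
        tracks_raw, _, _ = sim.simulate_atac(cfg, layout)
        tracks = {name: acc.InsertionTrack.from_positions(name, tr)
                  for name, tr in tracks_raw.items()}
        chrom_sizes = {c: cfg.chrom_len for c in layout.chrom_names}

        union: list[GenomicInterval] = []
        for ct in cfg.celltypes:
            for tp in (0, 4):
                p1 = acc.call_peaks(tracks[f"{ct}_t{tp}_r1"], chrom_sizes)
                p2 = acc.call_peaks(tracks[f"{ct}_t{tp}_r2"], chrom_sizes) \
                    if cfg.n_reps >= 2 else p1
                union.extend(pk.interval
                             for pk in acc.reproducible_peaks(p1, p2))
        union.sort(key=lambda iv: (iv.chrom, iv.start))
        merged: list[GenomicInterval] = []
        for iv in union:
            if merged and merged[-1].chrom == iv.chrom \
                    and iv.start <= merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start,
                                             max(merged[-1].end, iv.end))
            else:
                merged.append(iv)
        _log_stage("peaks", n_union=len(merged))
        report["n_reproducible_peaks"] = len(merged)

        counts = acc.count_insertions(merged, list(tracks.values()))
        dars = acc.test_dars(
            counts,
            [f"pos_t0_r{r}" for r in range(1, cfg.n_reps + 1)],
            [f"pos_t4_r{r}" for r in range(1, cfg.n_reps + 1)],
            fc_cut=config.dar.fc_cut, fdr_cut=config.dar.fdr_cut)
        dars[["log2_fold", "p", "fdr", "direction"]].to_csv(
            outdir / "dars.tsv", sep="\t")
        tss = [(g.interval.chrom, g.tss, g.gene_id) for g in layout.genes]
        labels = acc.annotate_peaks(merged, tss)
        report["peak_annotation"] = {
            lab: labels.count(lab) for lab in ("promoter", "proximal", "distal")
        }
        gained = [merged[i] for i in range(len(merged))
                  if dars["direction"].iloc[i] == "gained"]
        lost = [merged[i] for i in range(len(merged))
                if dars["direction"].iloc[i] == "lost"]
        _log_stage("dar", n_gained=len(gained), n_lost=len(lost))
        report["n_gained_dars"] = len(gained)
        report["n_lost_dars"] = len(lost)
        truth_gained = [GenomicInterval(*d["interval"][:3])
                        for d in truth.dars if d["direction"] == "gained"]
        report["dar_recovery"] = interval_recovery(gained, truth_gained)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage=accessibility failed: {exc}") from exc

    # ---------------- transcriptome ----------------
    try:
        rna, design, _ = sim.simulate_rnaseq(cfg, layout)
        g0 = [s for s, t, c in zip(design["sample"], design["timepoint"],
                                   design["celltype"])
              if t == 0 and c == "pos"]
        g4 = [s for s, t, c in zip(design["sample"], design["timepoint"],
                                   design["celltype"])
              if t == 4 and c == "pos"]
        de = tx.test_de(rna, g0, g4, fc_cut=config.de.fc_cut,
                        fdr_cut=config.de.fdr_cut)
        de.to_csv(outdir / "de.tsv", sep="\t")
        up = set(de.index[de["status"] == "up"])
        _log_stage("de", n_up=len(up),
                   n_down=int((de["status"] == "down").sum()))
        report["n_de_up"] = len(up)
        report["n_de_down"] = int((de["status"] == "down").sum())
        truth_up = {d["gene_id"] for d in truth.de_genes if d["log2_fold"] > 0}
        report["de_recovery"] = {
            "recall": (len(up & truth_up) / len(truth_up)
                       if truth_up else float("nan")),
            "precision": (len(up & truth_up) / len(up)
                          if up else float("nan")),
        }

        dar_frame = pd.DataFrame({
            "chrom": [iv.chrom for iv in merged],
            "start": [iv.start for iv in merged],
            "end": [iv.end for iv in merged],
            "direction": dars["direction"].to_numpy(),
        })
        nearest = {}
        for iv in merged:
            dist, gene = min((abs(iv.center - t), g) for c, t, g in tss
                             if c == iv.chrom)
            nearest[(iv.chrom, iv.start, iv.end)] = gene
        report["concordance"] = {
            k: {kk: vv for kk, vv in v.items() if kk != "log2_folds"}
            for k, v in tx.concordance(
                dar_frame[dar_frame["direction"] != "ns"], de, nearest).items()
        }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage=transcriptome failed: {exc}") from exc

    # ---------------- enhancers ----------------
    try:
        dar_pairs = [(iv, d) for iv, d in zip(merged, dars["direction"])
                     if d in ("gained", "lost")]
        cands = enh.classify_enhancers(
            dar_pairs, pos_t0, pos_t4,
            [(c, t) for c, t, _ in tss],
            meth_cutoff=config.enhancer.meth_cutoff,
            delta_cutoff=config.enhancer.delta_cutoff,
            distal_cutoff=config.enhancer.distal_cutoff,
            min_cpgs=config.enhancer.min_cpgs)
        with open(outdir / "enhancer_candidates.tsv", "w") as fh:
            fh.write("chrom\tstart\tend\tdirection\tmeth_t0\tmeth_t4\t"
                     "delta\tdistance_to_tss\tclass\n")
            for c in cands:
                fh.write(f"{c.interval.chrom}\t{c.interval.start}\t"
                         f"{c.interval.end}\t{c.dar_direction}\t"
                         f"{c.meth_t0:.4f}\t{c.meth_t4:.4f}\t"
                         f"{c.delta_meth:.4f}\t{c.distance_to_tss}\t{c.klass}\n")
        n_cand = sum(c.is_candidate for c in cands)
        _log_stage("enhancers", n_in=len(cands), n_candidates=n_cand)
        report["n_enhancer_candidates"] = n_cand
        report["hypomethylated_fraction"] = enh.hypomethylated_fraction(
            gained, pos_t0, cutoff=config.enhancer.meth_cutoff,
            min_cpgs=config.enhancer.min_cpgs)
        report["enhancer_recovery"] = interval_recovery(
            [c.interval for c in cands if c.is_candidate],
            _truth_ivs(truth.enhancers))
        report["assay_table_tally"] = enh.tally_assay_table(
            enh.load_assay_table())
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage=enhancers failed: {exc}") from exc

    # ---------------- regulatory network ----------------
    try:
        seqs, genes, pwms, _, _ = sim.simulate_genome(cfg, layout)
        hits_by_pwm = {
            p.name: grn.scan_pwm(seqs, p, p_threshold=config.grn.scan_p)
            for p in pwms
        }
        background = [iv for iv, d in zip(merged, dars["direction"])
                      if d == "ns"]
        enrich = grn.motif_enrichment(hits_by_pwm, gained, background)
        enrich.to_csv(outdir / "motif_enrichment.tsv", sep="\t", index=False)

        pooled = {}
        for c in layout.chrom_names:
            pooled[c] = np.sort(np.concatenate([
                tracks[f"pos_t4_r{r}"].positions.get(c, np.empty(0, int))
                for r in range(1, cfg.n_reps + 1)
            ]))
        bound_sites: list[tuple[str, GenomicInterval]] = []
        for name, hits in hits_by_pwm.items():
            if not hits:
                continue
            windows = np.zeros((len(hits), sim.FOOTPRINT_WINDOW), dtype=float)
            for i, h in enumerate(hits):
                centre = h.interval.center
                lo = centre - sim.FOOTPRINT_WINDOW // 2
                pos = pooled[h.interval.chrom]
                sel = pos[(pos >= lo) & (pos < lo + sim.FOOTPRINT_WINDOW)]
                if len(sel):
                    windows[i] = np.bincount(
                        sel - lo, minlength=sim.FOOTPRINT_WINDOW)
            fit = grn.fit_footprint_model(
                windows, np.asarray([h.score for h in hits]), seed=config.seed,
                posterior_cut=config.grn.posterior_cut)
            for h, b in zip(hits, fit.bound):
                if b:
                    bound_sites.append((name, h.interval))
        _log_stage("footprints", n_bound=len(bound_sites))
        report["n_bound_sites"] = len(bound_sites)

        motif_gene_map = {t["tf"]: t["gene_id"] for t in truth.tf_genes}
        selected = grn.select_upstream_tfs(
            enrich, rna, design, motif_gene_map,
            fdr_cut=config.grn.enrich_fdr, min_fold=config.grn.min_fold)
        edges = grn.build_grn(selected, bound_sites, gained, tss, up,
                              motif_gene_map)
        with open(outdir / "edges.tsv", "w") as fh:
            fh.write("tf\ttarget\tsite\tdar\ttype\n")
            for e in edges:
                fh.write(f"{e.tf}\t{e.target}\t"
                         f"{e.site.chrom}:{e.site.start}-{e.site.end}\t"
                         f"{e.dar.chrom}:{e.dar.start}-{e.dar.end}\t"
                         f"{e.edge_type}\n")
        _log_stage("grn", n_selected_tfs=len(selected), n_edges=len(edges))
        report["selected_tfs"] = sorted(selected)
        report["n_edges"] = len(edges)
        truth_edges = {(e["tf"], e["target"]) for e in truth.edges}
        called_edges = {(e.tf, e.target) for e in edges}
        report["edge_recovery"] = {
            "n_called": len(called_edges),
            "n_truth": len(truth_edges),
            "precision": (len(called_edges & truth_edges) / len(called_edges)
                          if called_edges else float("nan")),
            "recall": (len(called_edges & truth_edges) / len(truth_edges)
                       if truth_edges else float("nan")),
        }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage=grn failed: {exc}") from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
    return report
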