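"""Cross-assay nomination of regeneration-enhancer candidates and the
bookkeeping of the bundled reporter-assay validation table.

A gained-accessibility element is a candidate enhancer when it is distal
to every TSS (> 2 kb), lowly-to-intermediately methylated before injury
(< 0.6), and methylation-stable across the time course (|delta| < 0.25).
Rejections carry the first failed criterion, checked in the documented
order: direction -> distance -> methylation data -> baseline methylation
-> methylation stability.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import math

import pandas as pd

from .io_formats import GenomicInterval
from .methylome import _region_mean

__all__ = [
    "EnhancerCandidate", "classify_enhancers", "hypomethylated_fraction",
    "load_assay_table", "tally_assay_table",
]


@dataclass
class EnhancerCandidate:
    interval: GenomicInterval
    dar_direction: str
    meth_t0: float
    meth_t4: float
    delta_meth: float
    distance_to_tss: int
    klass: str  # "candidate" or "rejected(<reason>)"

    @property
    def is_candidate(self) -> bool:
        return self.klass == "candidate"


def _nearest_tss_distance(iv: GenomicInterval,
                          tss: Sequence[tuple[str, int]]) -> int:
    dists = [abs(iv.center - p) for c, p in tss if c == iv.chrom]
    return min(dists) if dists else 10**12


def classify_enhancers(dars: Sequence[tuple[GenomicInterval, str]],
                       meth_t0: pd.DataFrame, meth_t4: pd.DataFrame,
                       tss: Sequence[tuple[str, int]],
                       meth_cutoff: float = 0.6,
                       delta_cutoff: float = 0.25,
                       distal_cutoff: int = 2_000,
                       min_cpgs: int = 3) -> list[EnhancerCandidate]:
    """Classify differential-accessibility elements as enhancer candidates.

    ``dars`` are (interval, direction) pairs; regional methylation is the
    coverage-weighted CpG mean over the interval and requires at least
    ``min_cpgs`` covered CpGs.  Order-independent and idempotent.
    """
    out: list[EnhancerCandidate] = []
    for iv, direction in dars:
        m0 = _region_mean(meth_t0, iv, min_cpgs=min_cpgs)
        m4 = _region_mean(meth_t4, iv, min_cpgs=min_cpgs)
        delta = m4 - m0 if not (math.isnan(m0) or math.isnan(m4)) else float("nan")
        dist = _nearest_tss_distance(iv, tss)
        if direction != "gained":
            klass = "rejected(not_gained)"
        elif dist <= distal_cutoff:
            klass = "rejected(promoter_proximal)"
        elif math.isnan(m0) or math.isnan(m4):
            klass = "rejected(no_meth_data)"
        elif m0 >= meth_cutoff:
            klass = "rejected(hypermethylated)"
        elif abs(delta) >= delta_cutoff:
            klass = "rejected(methylation_unstable)"
        else:
            klass = "candidate"
        out.append(EnhancerCandidate(iv, direction, m0, m4, delta, dist, klass))
    return out


def hypomethylated_fraction(dars: Sequence[GenomicInterval],
                            meth_t0: pd.DataFrame, cutoff: float = 0.6,
                            min_cpgs: int = 3) -> dict:
    """Fraction of regions lowly/intermediately methylated pre-injury.

    Regions without methylation data are excluded from the denominator;
    an empty evaluable set reports NaN.
    """
    n_hypo = n_eval = n_missing = 0
    for iv in dars:
        m0 = _region_mean(meth_t0, iv, min_cpgs=min_cpgs)
        if math.isnan(m0):
            n_missing += 1
            continue
        n_eval += 1
        if m0 < cutoff:
            n_hypo += 1
    return {
        "fraction": n_hypo / n_eval if n_eval else float("nan"),
        "n_evaluated": n_eval,
        "n_hypomethylated": n_hypo,
        "n_missing": n_missing,
    }


def load_assay_table() -> pd.DataFrame:
    """Load the bundled reporter-assay validation table.

    Columns: element, dar_pos/dar_neg (Yes/No: differentially accessible
    in the sorted positive / negative cell population), egfp (+/-).
    """
    path = resources.files("epikit.data") / "enhancer_assay_table.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", dtype=str)


def tally_assay_table(rows: pd.DataFrame) -> dict:
    """Tally the assay table.

    Candidates are rows differentially accessible in at least one cell
    population; the rest are negative controls.  Positives show reporter
    EGFP expression.
    """
    if len(rows) == 0:
        return {"n_candidates": 0, "n_positive": 0,
                "n_negative_controls": 0, "n_negative_positive": 0}
    is_cand = (rows["dar_pos"] == "Yes") | (rows["dar_neg"] == "Yes")
    is_pos = rows["egfp"] == "+"
    return {
        "n_candidates": int(is_cand.sum()),
        "n_positive": int((is_cand & is_pos).sum()),
        "n_negative_controls": int((~is_cand).sum()),
        "n_negative_positive": int((~is_cand & is_pos).sum()),
    }
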