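"""Pipeline configuration: a JSON-schema-validated bundle of every
module's parameter block.  Unknown keys are rejected."""

from __future__ import annotations

import json
import logging
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

from .synthetic_data import SimConfig

log = logging.getLogger("epikit")

__all__ = ["PipelineConfig", "DmrSettings", "DarSettings", "DeSettings",
           "EnhancerSettings", "GrnSettings", "validate_config"]


class DmrSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    delta: float = Field(0.0, ge=0)
    minlen: int = Field(200, gt=0)
    min_cg: int = Field(5, gt=0)
    dis_merge: int = Field(50, gt=0)
    pct_sig: float = Field(0.5, gt=0, le=1)
    p_threshold: float = Field(1e-5, gt=0, lt=1)
    min_mean_diff: float = Field(0.25, ge=0)
    min_covered_cpgs: int = Field(5, gt=0)
    min_cov: int = Field(5, gt=0)
    max_insig_run: int = Field(2, ge=0)
    max_gap: int = Field(300, gt=0)
    smooth_window: int = Field(500, gt=0)
    shrink_scale: float = Field(50.0, gt=0)


class DarSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fc_cut: float = Field(2.0, gt=1)
    fdr_cut: float = Field(0.01, gt=0, lt=1)


class DeSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fc_cut: float = Field(2.0, gt=1)
    fdr_cut: float = Field(0.05, gt=0, lt=1)


class EnhancerSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    meth_cutoff: float = Field(0.6, gt=0, le=1)
    delta_cutoff: float = Field(0.25, gt=0, le=1)
    distal_cutoff: int = Field(2_000, ge=0)
    min_cpgs: int = Field(3, gt=0)


class GrnSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    scan_p: float = Field(1e-5, gt=0, lt=1)
    enrich_fdr: float = Field(0.05, gt=0, lt=1)
    min_fold: float = Field(1.5, gt=1)
    posterior_cut: float = Field(0.95, gt=0, lt=1)


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    outdir: str = "epikit_out"
    threads: int = Field(1, ge=1)  # accepted; results never depend on it
    sim: SimConfig = Field(default_factory=SimConfig)
    dmr: DmrSettings = Field(default_factory=DmrSettings)
    dar: DarSettings = Field(default_factory=DarSettings)
    de: DeSettings = Field(default_factory=DeSettings)
    enhancer: EnhancerSettings = Field(default_factory=EnhancerSettings)
    grn: GrnSettings = Field(default_factory=GrnSettings)
    null_thresholds: tuple[float, ...] = (1e-3, 1e-5, 1e-7)


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and schema-validate a JSON pipeline config.

    Missing ``seed`` defaults to 0 with a logged warning; unknown keys or
    out-of-range values raise with the offending field named.
    """
    with open(path) as fh:
        raw = json.load(fh)
    if "seed" not in raw:
        log.warning("config %s has no seed; defaulting to 0", path)
    cfg = PipelineConfig.model_validate(raw)
    cfg.sim = cfg.sim.model_copy(update={"seed": cfg.sim.seed or cfg.seed})
    return cfg
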