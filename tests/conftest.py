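import numpy as np
import pandas as pd
import pytest

from epikit.config import PipelineConfig
from epikit.pipeline import run_pipeline
from epikit.synthetic_data import SimConfig


SMALL_SIM = dict(
    n_genes=100, chrom_len=1_500_000, n_cpgs=5_000, n_celltype_dmrs=30,
    n_dars=30, n_peaks=100, n_de_genes=20,
)


@pytest.fixture(scope="session")
def pipeline_report(tmp_path_factory):
    """One full default-config pipeline run, shared across tests."""
    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = PipelineConfig(seed=11, outdir=str(outdir))
    report = run_pipeline(cfg)
    return report, outdir, cfg


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=5, **SMALL_SIM)


def make_meth_frame(rng, pos, mu, coverage=20.0, phi=0.05):
    """Beta-binomial CpG count table on one chromosome."""
    pos = np.asarray(pos)
    mu = np.clip(np.asarray(mu, dtype=float), 0.01, 0.99)
    total = rng.poisson(coverage, len(pos))
    if phi > 0:
        conc = 1.0 / phi - 1.0
        p = rng.beta(mu * conc, (1 - mu) * conc)
    else:
        p = mu
    meth = rng.binomial(total, p)
    return pd.DataFrame({"chrom": "chr1", "pos": pos, "meth": meth,
                         "total": total})
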