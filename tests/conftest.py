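"""Shared fixtures: a small synthetic bundle run end-to-end once per session."""

from __future__ import annotations

import pytest

from stepgrn.config import PipelineConfig, SimulationConfig
from stepgrn.pipeline import run_all

#: Structure sized for a ~170-DEG network so the whole bundle runs in seconds.
SMALL_SIM = dict(
    n_genes=600,
    n_bottleneck_connectors=2,
    n_mnc_hubs=4,
    mnc_ring_size=6,
    n_dmnc_hubs=4,
    dmnc_clique_size=4,
    seed=11,
)
SMALL_PIPE = dict(k_hubs=4, k_bottlenecks=2, seed=11)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """Full pipeline products on a small planted dataset."""
    indir = tmp_path_factory.mktemp("sim_in")
    outdir = tmp_path_factory.mktemp("sim_out")
    sim = SimulationConfig(**SMALL_SIM)
    cfg = PipelineConfig(**SMALL_PIPE)
    result = run_all(cfg, indir, outdir, simulate=sim)
    return {
        "indir": indir,
        "outdir": outdir,
        "sim": sim,
        "cfg": cfg,
        "gold": result["gold"],
        "network": result["network"],
        "summary": result["summary"],
    }
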