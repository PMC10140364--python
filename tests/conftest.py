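import numpy as np
import pandas as pd
import pytest

from ploidymeth import dmr_calling as dc
from ploidymeth import site_calling as sc
from ploidymeth.synthetic_data import SimulationConfig, run_full_simulation


@pytest.fixture(scope="session")
def default_sim():
    """Full-scale synthetic experiment at the default study conditions."""
    return run_full_simulation(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_sim():
    """Compact dataset for fast module-level tests."""
    cfg = SimulationConfig(seed=3, n_chroms=1, chrom_length=200_000,
                           n_genes=24, n_tes=20, n_dmrs=12)
    return run_full_simulation(cfg)


def group_reports(sim, group):
    return [df for name, df in sim.reports.items() if name.startswith(group)]


@pytest.fixture(scope="session")
def default_dmr_products(default_sim):
    """Site tests, called DMRs and recovery metrics on the default dataset."""
    sim = default_sim
    tests = dc.test_all_sites(group_reports(sim, "2X"), group_reports(sim, "4X"))
    dmrs = []
    for ctx in ("CG", "CHG", "CHH"):
        dmrs += dc.call_dmrs(tests[tests["context"] == ctx])
    match = dc.match_planted(dmrs, sim.truth.planted_dmrs)
    return {"tests": tests, "dmrs": dmrs, "match": match}


@pytest.fixture(scope="session")
def default_calls(default_sim):
    """Per-sample methylation calls for one replicate of each group."""
    out = {}
    for sample in ("2X_1", "4X_1"):
        conv = sc.estimate_nonconversion(default_sim.lambda_reports[sample])
        out[sample] = sc.call_sites(default_sim.reports[sample], conv)
    return out


def make_report(rows):
    """Site table from (chrom, start, strand, context, m, u) tuples."""
    return pd.DataFrame(
        rows, columns=["chrom", "start", "strand", "context",
                       "count_m", "count_u"]
    ).astype({"start": np.int64, "count_m": np.int64, "count_u": np.int64})
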