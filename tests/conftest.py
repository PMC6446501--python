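from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from richnet.enrichment import classify_direction, run_enrichment
from richnet.synthetic import PlantedDesign, generate_gene_stats, generate_library


@pytest.fixture
def tiny_gmt(tmp_path):
    path = tmp_path / "tiny.gmt"
    path.write_text(
        "S1\tdesc\tg1\tg2\n"
        "S2\tdesc\tg2\tg3\n"
        "S3\tdesc\tg4\tg5\tg6\n"
    )
    return path


@pytest.fixture(scope="session")
def default_design():
    return PlantedDesign()


@pytest.fixture(scope="session")
def planted(default_design):
    """Default planted benchmark: (library, truth, stats DataFrame)."""
    lib, truth = generate_library(default_design)
    stats = generate_gene_stats(lib, truth, default_design)
    return lib, truth, stats


@pytest.fixture(scope="session")
def null_simulation():
    """200 null replicates (effect = 0) of the enrichment + classification.

    Returns per-replicate retained fractions, the pooled fraction of raw
    directional p-values <= 0.05 at rho = 0, and the count of replicates
    retaining at least one set. Shared (session scope) because it is the
    most expensive simulation in the suite.
    """
    n_rep = 200
    retained_fracs = np.empty(n_rep)
    any_retained = 0
    n_raw_sig_rho0 = 0
    n_sets_total = 0
    for rep in range(n_rep):
        design = PlantedDesign(effect=0.0, seed=1000 + rep)
        lib, truth = generate_library(design)
        stats = generate_gene_stats(lib, truth, design)
        s = pd.Series(stats["stat"].to_numpy(), index=stats["gene_id"].to_numpy())
        raw = run_enrichment(s, lib)
        raw_rho0 = run_enrichment(s, lib, inter_gene_cor=0.0)
        table = classify_direction(raw, alpha=0.05)
        retained_fracs[rep] = len(table) / len(raw)
        any_retained += int(len(table) > 0)
        n_raw_sig_rho0 += int((raw_rho0["PValue"] <= 0.05).sum())
        n_sets_total += len(raw)
    return {
        "n_replicates": n_rep,
        "retained_fracs": retained_fracs,
        "any_retained": any_retained,
        "raw_sig_frac_rho0": n_raw_sig_rho0 / n_sets_total,
        "n_sets_total": n_sets_total,
    }
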