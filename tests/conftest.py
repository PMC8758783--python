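import warnings

import numpy as np
import pytest

from pdcorenet import io as io_mod
from pdcorenet import network as net
from pdcorenet import synth

# module-score warnings about dropped genes are expected in several tests
warnings.filterwarnings("ignore", message=".*module gene.*")


@pytest.fixture(scope="session")
def small_counts():
    """One-timepoint, 100-cells-per-group count matrix with planted DEGs."""
    cfg = synth.SimConfig(
        n_genes=500,
        n_cells_per_group_per_timepoint=100,
        timepoints=("D6",),
        n_true_deg=20,
        frac_inconsistent=0.0,
        seed=42,
    )
    return synth.generate_counts(cfg)


@pytest.fixture(scope="session")
def timecourse_counts():
    """Four-timepoint matrix with consistent DEGs and sign-flip decoys."""
    cfg = synth.SimConfig(
        n_genes=400,
        n_cells_per_group_per_timepoint=60,
        n_true_deg=30,
        frac_inconsistent=0.2,
        seed=7,
    )
    return synth.generate_counts(cfg)


@pytest.fixture(scope="session")
def ppi_universe():
    return [f"G{i:04d}" for i in range(400)]


@pytest.fixture(scope="session")
def hub_edge_tables(tmp_path_factory, ppi_universe):
    """Parsed + merged edge set with 20 planted hubs, plus the hub list."""
    hubs = ppi_universe[:20]
    sdf, gdf = synth.generate_ppi_tables(
        synth.NetSimConfig(seed=0), ppi_universe, hubs
    )
    d = tmp_path_factory.mktemp("ppi")
    io_mod.write_edge_table(sdf, str(d / "string.tsv"), "string")
    io_mod.write_edge_table(gdf, str(d / "gm.tsv"), "genemania")
    se = net.parse_string_edges(str(d / "string.tsv"))
    ge = net.parse_genemania_edges(str(d / "gm.tsv"))
    return net.merge_edge_sets(se, ge), hubs, str(d / "string.tsv"), str(d / "gm.tsv")


@pytest.fixture(scope="session")
def flat_edge_table(tmp_path_factory, ppi_universe):
    """Exchangeable (hubless) merged edge set for null calibration."""
    sdf, gdf = synth.generate_ppi_tables(
        synth.NetSimConfig(hub_degree_boost=1.0, seed=0), ppi_universe, []
    )
    d = tmp_path_factory.mktemp("ppi_flat")
    io_mod.write_edge_table(sdf, str(d / "string.tsv"), "string")
    io_mod.write_edge_table(gdf, str(d / "gm.tsv"), "genemania")
    return net.merge_edge_sets(
        net.parse_string_edges(str(d / "string.tsv")),
        net.parse_genemania_edges(str(d / "gm.tsv")),
    )


def random_edge_set(rng, genes, n_edges):
    """Random canonical edge set over ``genes`` (test helper)."""
    import pandas as pd

    rows = set()
    while len(rows) < n_edges:
        a, b = rng.choice(genes, size=2, replace=False)
        rows.add((min(a, b), max(a, b)))
    rows = sorted(rows)
    return pd.DataFrame(
        {
            "gene_a": [r[0] for r in rows],
            "gene_b": [r[1] for r in rows],
            "source": "string",
            "channel": "experimental",
            "weight": 1.0,
        }
    )
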