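"""Shared fixtures: synthetic populations reused across the suite.

The expensive planted populations are session-scoped so the compartment,
local-environment and acceptance tests share one simulation each.
"""

import numpy as np
import pandas as pd
import pytest

from chromtrace import synthetic as syn


@pytest.fixture(scope="session")
def planted():
    """Planted-block population: 2 chromosomes x 80 loci, gamma=0.4, 500 cells."""
    params = syn.SimulationParams(
        chromosomes=[syn.ChromosomeSpec("chr1", n_loci=80),
                     syn.ChromosomeSpec("chr2", n_loci=80)],
        cell_types=[syn.CellTypeParams("neuron", gamma=0.4)],
        n_cells_per_type=500, seed=7)
    panel, truth = syn.make_truth_panel(params)
    traces = syn.simulate_population(panel, truth, params)
    return params, panel, truth, traces


@pytest.fixture(scope="session")
def ko_pair():
    """WT + KO (de-segregation weight 0.5) populations, 150 cells each."""
    params = syn.SimulationParams(
        chromosomes=[syn.ChromosomeSpec("chr1", n_loci=80),
                     syn.ChromosomeSpec("chr2", n_loci=80)],
        cell_types=[syn.CellTypeParams("neuron", gamma=0.4, ko_response=1.0)],
        n_cells_per_type=150, ko_mixing=0.5, seed=5)
    panel, truth = syn.make_truth_panel(params)
    traces = syn.simulate_population(panel, truth, params, genotypes=("WT", "KO"))
    return params, panel, truth, traces


@pytest.fixture()
def tiny_panel():
    """Three 20-kb loci on one chromosome."""
    return pd.DataFrame({
        "locus_id": ["chr1_L0", "chr1_L1", "chr1_L2"],
        "chrom": "chr1",
        "start": [0, 2_500_000, 5_000_000],
        "end": [20_000, 2_520_000, 5_020_000],
        "panel_group": "genome_wide",
        "cpg_density": [1.0, 2.0, 3.0],
        "barcode_id": [np.nan] * 3,
    })


def make_cell(points, cell_id="c0", chrom="chr1", cell_type="ct", genotype="WT",
              locus_ids=None, homolog=0):
    """Build a minimal single-cell trace table from an (n, 3) point array."""
    points = np.asarray(points, float)
    n = len(points)
    if locus_ids is None:
        locus_ids = [f"L{i:05d}" for i in range(n)]
    return pd.DataFrame({
        "cell_id": cell_id, "cell_type": cell_type, "genotype": genotype,
        "chrom": chrom, "locus_id": locus_ids, "homolog": homolog,
        "x": points[:, 0], "y": points[:, 1], "z": points[:, 2],
        "score": np.nan,
    })
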