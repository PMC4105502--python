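import numpy as np
import pandas as pd
import pytest

import gbskit as gk


@pytest.fixture(scope="session")
def small_cfg():
    return gk.SimConfig(
        n_linkage_groups=2,
        lg_length=100.0,
        n_framework_loci=11,
        n_candidate_loci=10,
        generation=6,
        outcross_rate=0.0,
        seq_error_rate=0.0,
        depth_index=2.0,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_map(small_cfg):
    return gk.simulate_consensus_map(small_cfg)


@pytest.fixture(scope="session")
def ril_population(small_map, small_cfg):
    G, truth = gk.simulate_ril_population(small_map, 120, 6, small_cfg)
    return G, truth


@pytest.fixture(scope="session")
def family_panel():
    cfg = gk.SimConfig(
        n_linkage_groups=3,
        n_framework_loci=60,
        n_candidate_loci=0,
        outcross_rate=0.0,
        seq_error_rate=0.0,
        rng_seed=11,
    )
    G, truth = gk.simulate_diversity_panel(6, 15, cfg)
    return G, truth


def geno(rows, lines=None, loci=None):
    """Build a GenotypeMatrix from a list of row strings like 'ABHN'."""
    table = pd.DataFrame(
        [[gk.core.CHAR_TO_CODE[c] for c in row] for row in rows],
        index=lines or [f"l{i}" for i in range(len(rows))],
        columns=loci or [f"m{j}" for j in range(len(rows[0]))],
    )
    return gk.GenotypeMatrix(table)
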