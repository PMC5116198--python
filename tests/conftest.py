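import numpy as np
import pandas as pd
import pytest

import poolgwas as pg


@pytest.fixture(scope="session")
def panel50():
    return pg.simulate_panel(50, 0.05, 0.5, seed=11)


@pytest.fixture(scope="session")
def small_cohort(panel50):
    return pg.simulate_genotypes(panel50, 60, 60, seed=12)


def make_array(paf_by_snp, n_probes=10, intensity=2000.0, pool_id="pool1",
               group="case", array_id="a0", strand="top"):
    """Hand-built noiseless balanced-channel array with given per-SNP PAFs."""
    rows = []
    for snp, p in paf_by_snp.items():
        for j in range(n_probes):
            rows.append((snp, j, intensity * p, intensity * (1 - p)))
    probes = pd.DataFrame(rows, columns=["snp_id", "probe_index", "red", "green"])
    return pg.BeadArrayMeasurement(
        array_id=array_id, pool_id=pool_id, group=group, strand=strand, probes=probes
    )


@pytest.fixture
def make_array_fn():
    return make_array
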