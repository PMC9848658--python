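import numpy as np
import pandas as pd
import pytest

from popsweep.variants import MISSING, PopulationMap, VariantTable


def make_table(genotypes, depths=None, chrom="chr1", samples=None,
               positions=None):
    """Build a VariantTable from a (n_sites, n_samples) dosage list."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    if depths is None:
        d = np.full_like(g, 10, dtype=np.int32)
    else:
        d = np.asarray(depths, dtype=np.int32)
        if d.ndim == 0 or d.shape != g.shape:
            d = np.full(g.shape, int(depths), dtype=np.int32)
    samples = samples or [f"s{i + 1:02d}" for i in range(n_samples)]
    positions = positions or list(range(100, 100 + 10 * n_sites, 10))
    sites = pd.DataFrame({
        "chrom": chrom, "pos": positions,
        "ref": ["A"] * n_sites, "alt": ["G"] * n_sites,
    })
    return VariantTable(sites=sites, genotypes=g, depths=d, samples=samples)


@pytest.fixture
def toy_popmap():
    """Two populations of two samples each."""
    return PopulationMap(assignments={
        "s01": "pop1", "s02": "pop1", "s03": "pop2", "s04": "pop2"})


@pytest.fixture
def filter_toy_table():
    """28-sample, 4-site table exercising each filter rule.

    Site 0: full calls, MAF 14/56 = 0.25, depth 10      -> kept
    Site 1: full calls, MAF 2/56 ≈ 0.036                -> dropped (MAF)
    Site 2: 11/28 called (rate ≈ 0.39), MAF fine        -> dropped (call rate)
    Site 3: all depths 3 -> every call masked           -> dropped (rate 0)
    """
    n = 28
    g = np.zeros((4, n), dtype=np.int8)
    g[0, :14] = 1
    g[1, :2] = 1
    g[2, :] = MISSING
    g[2, :11] = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
    g[3, :14] = 1
    d = np.full((4, n), 10, dtype=np.int32)
    d[3, :] = 3
    return make_table(g, d)
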