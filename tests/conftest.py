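import numpy as np
import pytest

from chromodyn.hic import ContactMatrix, GenomeLayout
from chromodyn.trajectories import Track

import scipy.sparse as sp


@pytest.fixture
def ballistic_track():
    """1D-as-2D constant-velocity track: positions (k, 0), dt = 1 s."""
    pos = np.column_stack([np.arange(4.0), np.zeros(4)])
    return Track(id="ballistic", dt=1.0, positions=pos)


@pytest.fixture
def random_walk_track():
    rng = np.random.default_rng(123)
    pos = np.cumsum(rng.standard_normal((50, 2)), axis=0) * 0.05
    return Track(id="rw", dt=0.02, positions=pos)


@pytest.fixture
def two_chrom_layout():
    """Two 100 kb chromosomes, centromeres at 40 kb, 2 kb bins (50 bins each)."""
    return GenomeLayout(chroms=("I", "II"), lengths=(100_000, 100_000),
                        centromeres=(40_000, 40_000), binsize=2000)


def dense_cm(layout, arr, normalization="raw"):
    return ContactMatrix(layout, sp.csr_matrix(np.asarray(arr, dtype=float)),
                         normalization=normalization)


@pytest.fixture
def uniform_cm(two_chrom_layout):
    n = two_chrom_layout.n_bins
    return dense_cm(two_chrom_layout, np.ones((n, n)))
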