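import numpy as np
import pytest
import scipy.sparse as sp

from gwasmix.ldstruct import LdHistogram
from gwasmix.modelpdf import ModelParams, ZGrid


@pytest.fixture(scope="session")
def zgrid():
    return ZGrid()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_histogram():
    """A hand-sized LD block: 6 neighbours across 3 r2 windows."""
    return LdHistogram(
        counts=np.array([3.0, 2.0, 1.0]),
        mean_het=np.array([0.2, 0.4, 0.3]),
        mean_r2=np.array([0.2, 0.6, 0.95]),
        total_ld=3.0,
        block_size=6.0,
    )


@pytest.fixture
def isolated_histogram():
    """A SNP in LD with nothing but itself."""
    return LdHistogram(
        counts=np.array([1.0]),
        mean_het=np.array([0.3]),
        mean_r2=np.array([1.0]),
        total_ld=1.0,
        block_size=1.0,
    )


@pytest.fixture
def default_params():
    return ModelParams(pi1=0.05, sigma_beta2=2e-4, sigma0_2=1.1)


def sparse_from_dense(dense):
    """Helper: symmetric csr from a dense r2 block (zeros dropped)."""
    return sp.csr_matrix(np.asarray(dense, dtype=float))


def single_bin_grid(counts, het, r2):
    """An H-L grid with one occupied bin and a prescribed histogram."""
    from gwasmix.ldstruct import HLGrid

    return HLGrid(
        h_edges=np.array([0.0, 0.5]),
        l_edges=np.array([1.0, 2.0]),
        bin_index=np.zeros(0, dtype=int),
        counts=np.atleast_2d(np.asarray(counts, float)),
        mean_het=np.atleast_2d(np.asarray(het, float)),
        mean_r2=np.asarray(r2, float),
        bin_counts=np.array([1.0]),
        bin_mean_H=np.array([0.25]),
        bin_mean_L=np.array([1.5]),
    )
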