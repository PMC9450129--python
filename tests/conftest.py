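import numpy as np
import pandas as pd
import pytest

from citrusnir.spectra_io import AnalysisSet, ReferenceTable, SpectraSet, WavelengthGrid


def make_spectra(A, grid=None, pop="1", variety="Newhall", start_fruit=1):
    """Wrap a raw matrix in a SpectraSet with generated metadata."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    grid = grid or WavelengthGrid(np.arange(650.0, 650.0 + 2 * A.shape[1], 2.0))
    meta = pd.DataFrame({
        "spectrum_id": [f"S{start_fruit + i:03d}" for i in range(A.shape[0])],
        "fruit_id": [f"F{start_fruit + i:03d}" for i in range(A.shape[0])],
        "population_id": pop,
        "replicate_index": 1,
        "variety": variety,
    })
    return SpectraSet(grid, A, meta)


def make_analysis(A, y, **kw):
    s = make_spectra(A, **kw)
    ref = ReferenceTable(pd.DataFrame({"spectrum_id": s.meta["spectrum_id"], "ssc": y}))
    return AnalysisSet(s, ref)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return WavelengthGrid(np.arange(650.0, 950.0 + 1e-9, 2.0))
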