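import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from morphrisk.tissue import CELL_COLUMNS, Structure, TissueMap


def build_map(cells=None, structures=None, extent=(2000.0, 2000.0)) -> TissueMap:
    """Assemble a TissueMap from raw pieces with sensible defaults."""
    if cells is None:
        cells = pd.DataFrame({c: [] for c in CELL_COLUMNS})
    return TissueMap(cells=cells, structures=structures or [], field_extent_um=extent)


def cells_frame(rows) -> pd.DataFrame:
    """rows: list of (x, y, cell_type, nuclear_area)."""
    return pd.DataFrame(rows, columns=list(CELL_COLUMNS))


def square(x0, y0, side) -> Polygon:
    return Polygon([(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)])


@pytest.fixture
def square_epithelium_map():
    """One 100x100 µm square epithelial structure centred in a 2 mm field,
    with 3 lymphocytes at boundary distances 10, 49 and 51 µm."""
    sq = square(950.0, 950.0, 100.0)
    lym = cells_frame(
        [
            (1050.0 + 10.0, 1000.0, "lymphocyte", 12.0),
            (1050.0 + 49.0, 1000.0, "lymphocyte", 12.0),
            (1050.0 + 51.0, 1000.0, "lymphocyte", 12.0),
        ]
    )
    return build_map(
        cells=lym,
        structures=[Structure(polygon=sq, region="epithelium", structure_id=0)],
    )


@pytest.fixture
def simple_survival_toy():
    """8 patients, 3 censored; small enough for exhaustive pair enumeration."""
    rng = np.random.default_rng(7)
    time = np.array([3.0, 5.0, 5.0, 9.0, 12.0, 15.0, 20.0, 24.0])
    event = np.array([1, 1, 0, 1, 0, 1, 0, 1])
    scores = rng.normal(size=8)
    return scores, time, event
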