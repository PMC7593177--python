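import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from florizone.grid import GridSpec, OccurrenceRecord, rasterize


@pytest.fixture
def grid_4x5() -> GridSpec:
    return GridSpec(x_min=0.0, y_min=0.0, cell_w=1.0, cell_h=1.0, n_cols=5, n_rows=4)


@pytest.fixture
def tiny_pa(grid_4x5):
    """Small presence-absence matrix: 2 taxa over 3 surveyed cells."""
    records = [
        OccurrenceRecord("Abies", "Pinaceae", 0.5, 0.5),
        OccurrenceRecord("Abies", "Pinaceae", 1.5, 0.5),
        OccurrenceRecord("Carex", "Cyperaceae", 2.5, 1.5),
    ]
    return rasterize(records, grid_4x5)


def random_pa(rng: np.random.Generator, n_rows=6, n_cols=6, n_taxa=25, p=0.4):
    """Random presence-absence matrix with every cell surveyed."""
    from florizone.grid import PresenceAbsenceMatrix

    grid = GridSpec(
        x_min=0.0, y_min=0.0, cell_w=1.0, cell_h=1.0, n_cols=n_cols, n_rows=n_rows
    )
    values = (rng.random((grid.n_cells, n_taxa)) < p).astype(np.uint8)
    taxa = [f"sp{t:03d}" for t in range(n_taxa)]
    surveyed = np.ones(grid.n_cells, dtype=bool)
    return PresenceAbsenceMatrix(values=values, taxa=taxa, surveyed=surveyed, grid=grid)
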