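import numpy as np
import pandas as pd
import pytest

from tilspatial.io import CellRecord, PointPattern, RegionOfInterest


def make_pattern(rows, area_mm2=1.0, patient_id="fixture", outcome="unlabeled",
                 boundary=None):
    """Build a pattern from (x, y, phenotype, tissue_category) tuples."""
    cells = [CellRecord(f"c{i}", x, y, ph, tc)
             for i, (x, y, ph, tc) in enumerate(rows)]
    roi = RegionOfInterest(area_mm2=area_mm2, boundary=boundary)
    return PointPattern(cells, roi, patient_id=patient_id, outcome=outcome)


@pytest.fixture
def three_cell_pattern():
    """One B in stroma, one T in a cancer island, one cancer cell."""
    return make_pattern([
        (10.0, 10.0, "B", "stroma"),
        (500.0, 500.0, "T", "cancer_island"),
        (505.0, 505.0, "cancer", "cancer_island"),
    ], area_mm2=1.0)


@pytest.fixture
def collinear_lymphocytes():
    """Five lymphocytes at 10 μm spacing along a line (spanning 40 μm)."""
    return make_pattern(
        [(10.0 * i, 0.0, "T", "stroma") for i in range(5)], area_mm2=1.0)


def random_lymphocyte_pattern(rng, n, extent=400.0, b_fraction=0.3):
    """n lymphocytes scattered uniformly; used by the oracle-equivalence tests."""
    xy = rng.uniform(0, extent, size=(n, 2))
    phen = np.where(rng.uniform(size=n) < b_fraction, "B", "T")
    rows = [(x, y, ph, "stroma") for (x, y), ph in zip(xy, phen)]
    return make_pattern(rows, area_mm2=(extent / 1000.0) ** 2)
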