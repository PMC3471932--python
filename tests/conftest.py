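import numpy as np
import pandas as pd
import pytest

from scritscreen.plate_core import FEATURE_COLUMNS, CellFeatureTable


def make_feature_frame(rows):
    """Build a CellFeatureTable from a list of dicts with sensible defaults."""
    defaults = {
        "well": "A01",
        "field": 1,
        "cell": 1,
        "tmrm_peripheral_integral": 5.0e4,
        "tmrm_max_pixel": 8.0e3,
        "hoechst_integral": 4.0e6,
        "hoechst_mean": 6.0e3,
        "nuclear_area": 110.0,
        "nuclear_circularity": 0.8,
        "topro_mean": 300.0,
    }
    records = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["cell"] = i + 1
        rec.update(row)
        records.append(rec)
    if not records:
        return CellFeatureTable.empty()
    return CellFeatureTable(pd.DataFrame(records))


@pytest.fixture
def random_table():
    """Randomised feature table spanning several wells."""
    rng = np.random.default_rng(7)
    rows = []
    for well in ("A01", "A02", "B05"):
        for cell in range(5):
            rows.append(
                {
                    "well": well,
                    "cell": cell + 1,
                    **{
                        c: float(rng.uniform(1, 1e5))
                        for c in FEATURE_COLUMNS
                        if c != "nuclear_circularity"
                    },
                    "nuclear_circularity": float(rng.uniform(0.1, 1.0)),
                }
            )
    return make_feature_frame(rows)
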