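import numpy as np
import pandas as pd
import pytest

import stromascope as st
from stromascope.core import ASINH_PREFIX


@pytest.fixture(scope="session")
def panel():
    return st.default_panel()


@pytest.fixture(scope="session")
def small_roi():
    """A rendered 250×250 ROI with ~120 cells and a few hot pixels."""
    cfg = st.SyntheticCohortConfig(seed=2, n_patients=2, rois_per_patient=1,
                                   cells_per_roi=120, roi_size_px=(250, 250))
    return st.simulate_roi(cfg, 0)


@pytest.fixture(scope="session")
def phenotyped_table(panel):
    """3000 cells from the default nine profiles, transformed and normalized."""
    tab = st.simulate_cell_table(3000, seed=5)
    truth = tab[["population", "subtype"]].copy()
    tab = tab.drop(columns=["population", "subtype"])
    tab = st.transform_normalize(tab, panel.names)
    return tab, truth


def make_qc_clean_table(n, panel, rng=None, roi_id="R1"):
    """A cell table engineered to pass every QC rule."""
    rng = rng or np.random.default_rng(0)
    tab = pd.DataFrame({
        "cell_id": np.arange(1, n + 1),
        "roi_id": roi_id,
        "patient_id": "P01",
        "area_um2": rng.uniform(40, 200, n),
    })
    for m in panel.names:
        tab[ASINH_PREFIX + m] = rng.uniform(0.1, 1.5, n)
    return tab
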