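import numpy as np
import pytest

import facegrad as fg


@pytest.fixture(scope="session")
def four_run_apertures() -> fg.ApertureStack:
    """All four retinotopy runs (cw/ccw wedges, expand/contract rings),
    two cycles each at 64x64 resolution — the joint stimulus used for fitting."""
    ap = fg.make_wedge_apertures(n_cycles=2, direction="ccw")
    ap = ap.concat(fg.make_wedge_apertures(n_cycles=2, direction="cw"))
    ap = ap.concat(fg.make_ring_apertures(n_cycles=2, direction="expand"))
    ap = ap.concat(fg.make_ring_apertures(n_cycles=2, direction="contract"))
    return ap


@pytest.fixture(scope="session")
def css_bank(four_run_apertures) -> fg.CSSPredictorBank:
    return fg.build_predictor_bank(four_run_apertures)


@pytest.fixture(scope="session")
def small_patch() -> fg.CorticalPatch:
    return fg.make_patch(10, 10, 1.2)


@pytest.fixture()
def straight_axis() -> fg.AnatomicalAxis:
    return fg.AnatomicalAxis(np.array([[0.0, 0.0], [10.0, 0.0]]))
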