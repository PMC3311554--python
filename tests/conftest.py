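import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import rgcflow as rf

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

#: The six published percentile-matched size pairs (Q; area um^2; D_a um;
#: FSC; apparent D_v um) used as a desk-scale regression fixture.
PRINTED_Q = [5.0, 20.0, 40.0, 60.0, 80.0, 95.0]
PRINTED_AREA = [15.14, 17.30, 25.95, 36.77, 62.72, 140.57]
PRINTED_DA = [4.39, 4.69, 5.75, 6.84, 8.94, 13.38]
PRINTED_FSC = [78.0, 104.0, 187.0, 290.0, 445.0, 603.0]
PRINTED_DV = [4.04, 4.86, 7.33, 10.28, 14.45, 18.33]


@pytest.fixture(scope="session")
def printed_pairs() -> rf.QuantilePairSet:
    return rf.QuantilePairSet.from_printed(
        PRINTED_Q, PRINTED_DA, PRINTED_DV,
        area_q_um2=PRINTED_AREA, fsc_q=PRINTED_FSC)


@pytest.fixture(scope="session")
def paper_gates() -> rf.SizeGateScheme:
    """FSC gates derived from the published calibration coefficients."""
    return rf.derive_fsc_gates([15.0, 70.0, 125.0], rf.PAPER_2012_BRIDGE,
                               rf.PAPER_2012_BEAD, round_intermediates=True)


@pytest.fixture()
def small_table() -> rf.EventTable:
    return rf.EventTable(pd.DataFrame({
        "FSC": [150.0, 500.0, 700.0],
        "SSC": [80.0, 200.0, 260.0],
        "FL1": [1.0, 2.0, 50.0],
        "FL2": [100.0, 30.0, 5.0],
        "FL3": [40.0, 90.0, 3.0],
    }))


def make_events(fsc, fl1=None, fl2=None, fl3=None, compensated=False):
    """Build an EventTable from channel arrays, defaulting FLs to zero."""
    fsc = np.asarray(fsc, dtype=float)
    zeros = np.zeros_like(fsc)
    frame = pd.DataFrame({
        "FSC": fsc,
        "FL1": zeros if fl1 is None else np.asarray(fl1, float),
        "FL2": zeros if fl2 is None else np.asarray(fl2, float),
        "FL3": zeros if fl3 is None else np.asarray(fl3, float),
    })
    return rf.EventTable(frame, compensated=compensated)
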