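import io

import numpy as np
import pandas as pd
import pytest

import matetime as mt

#: hand-written two-cell, three-frame dual-channel trace CSV (default headers)
SMALL_CSV = """\
cell_id,replicate_id,frame_time,channel,nuclear_mean,cytoplasmic_mean,nuclear_area,cell_area
c1,r1,-2,RFP,10,10,25,400
c1,r1,0,RFP,12,10,25,400
c1,r1,5,RFP,20,10,25,400
c1,r1,-2,YFP,11,10,25,400
c1,r1,0,YFP,11,10,25,400
c1,r1,5,YFP,15,10,25,400
c2,r1,-2,RFP,10,10,24,390
c2,r1,0,RFP,10,10,24,390
c2,r1,5,RFP,30,10,24,390
c2,r1,-2,YFP,10,10,24,390
c2,r1,0,YFP,10,10,24,390
c2,r1,5,YFP,12,10,24,390
"""


@pytest.fixture
def small_table() -> pd.DataFrame:
    return mt.read_trace_table(io.StringIO(SMALL_CSV))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fig1f_small():
    """A modest fig1f population shared across tests (deterministic)."""
    params = mt.preset("fig1f", n_cells=150, seed=7)
    return mt.simulate_population(params)


@pytest.fixture(scope="session")
def fig1f_processed(fig1f_small):
    """QC-filtered corrected traces and timing records for both channels."""
    from matetime.expression_timing import preprocess_channel, timing_table

    table, truth = fig1f_small
    filtered, report = mt.apply_qc(table, mt.QCConfig())
    corrected = {ch: preprocess_channel(filtered, ch) for ch in ("YFP", "RFP")}
    timing = {ch: timing_table(corrected[ch], ch) for ch in ("YFP", "RFP")}
    return {"table": filtered, "truth": truth, "corrected": corrected,
            "timing": timing, "report": report}
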