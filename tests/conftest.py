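import numpy as np
import pandas as pd
import pytest

from expobayes.cohort import CURRENT_ROWS, HISTORICAL_ROWS


def row(job_title: str, historical: bool = False):
    rows = HISTORICAL_ROWS if historical else CURRENT_ROWS
    return next(r for r in rows if r.job_title == job_title)


@pytest.fixture
def exposure_csv(tmp_path):
    """Write an exposure CSV from a list of (job, heg, year, conc) tuples."""

    def _write(rows, name="exposures.csv", columns=None):
        cols = columns or ["job_title", "heg_id", "year", "twa8h_mg_m3"]
        path = tmp_path / name
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
        return path

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(20230)
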