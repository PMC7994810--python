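import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import plumelag as pl

settings.register_profile("plumelag", database=None, deadline=None, derandomize=True)
settings.load_profile("plumelag")


@pytest.fixture(scope="session")
def config() -> pl.AnalysisConfig:
    return pl.AnalysisConfig()


@pytest.fixture(scope="session")
def wind_default() -> pd.DataFrame:
    """One 11-year daily wind record under the default simulation settings."""
    return pl.gen_wind(pl.WindSimParams(), seed=0)


@pytest.fixture(scope="session")
def templates():
    return pl.make_call_templates()


def annotations_to_events(ann: pd.DataFrame) -> list:
    return [
        pl.DetectionEvent(r.start_s, r.end_s, r.low_hz, r.high_hz) for r in ann.itertuples()
    ]
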