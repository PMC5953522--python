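import pandas as pd
import pytest

import hewcost as h


@pytest.fixture(scope="session")
def taxonomy():
    return h.default_taxonomy()


@pytest.fixture()
def small_log():
    """Tiny hand-written rural/urban observation log."""
    rows = [
        ("w1", "rural", "2014-04-14", "Provide TB related services", 5.0),
        ("w1", "rural", "2014-04-14", "Provide TB related services", 3.0),
        ("w1", "rural", "2014-04-14", "Hygiene and environmental sanitation", 12.0),
        ("w1", "rural", "2014-04-15", "travel", 30.0),
        ("w2", "rural", "2014-04-14", "Provide contraceptives", 8.0),
        ("w2", "rural", "2014-04-15", "recordkeeping", 20.0),
        ("w3", "urban", "2014-04-14", "Provide vaccinations", 25.0),
        ("w3", "urban", "2014-04-15", "Provide TB related services", 6.0),
        ("w3", "urban", "2014-04-15", "Health education", 14.0),
    ]
    return pd.DataFrame(
        rows, columns=["worker_id", "setting", "date", "activity_label", "duration_min"]
    )


@pytest.fixture(scope="session")
def rural_schedule():
    return h.build_reference_schedule("rural")


@pytest.fixture(scope="session")
def urban_schedule():
    return h.build_reference_schedule("urban")
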