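import numpy as np
import pytest

import lastsight as ls


@pytest.fixture(scope="session")
def reference_records():
    """The packaged 23-date cave-bear table, range-filtered."""
    return ls.apply_range_filter(ls.load_reference_records())


@pytest.fixture(scope="session")
def variants(reference_records):
    return {v: ls.select_variant(reference_records, v) for v in ls.records.VARIANTS}


@pytest.fixture(scope="session")
def identity_curve():
    return ls.synth_curve("identity", 50_000, step=50.0)


@pytest.fixture()
def even_series():
    """21 evenly spaced sightings 1000..3000 BP (exact dates)."""
    return ls.SightingSeries(np.linspace(1000.0, 3000.0, 21))
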