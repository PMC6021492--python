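import numpy as np
import pandas as pd
import pytest

from ifnsig import (
    MarkerSimConfig,
    ScoringConfig,
    generate_marker_tubes,
    load_reference_cellcycle_table,
    load_reference_marker_table,
    profiles_from_table,
)


@pytest.fixture(scope="session")
def marker_table():
    return load_reference_marker_table()


@pytest.fixture(scope="session")
def cellcycle_table():
    return load_reference_cellcycle_table()


@pytest.fixture(scope="session")
def profiles(marker_table):
    return profiles_from_table(marker_table, ScoringConfig())


@pytest.fixture(scope="session")
def profile_by_line(profiles):
    return {p.line_id: p for p in profiles}


@pytest.fixture(scope="session")
def clean_tube_pair():
    """A 20k-event stained/FMO pair with no dead cells or doublets."""
    cfg = MarkerSimConfig(true_relative_mfi=4.0, n_events=20_000, seed=42)
    return generate_marker_tubes(cfg)


def normalized_fractions(raw):
    """Rescale printed phase percentages (which may sum near 100) to 100."""
    total = sum(raw)
    return tuple(100.0 * f / total for f in raw)
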