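import pytest

from lexidiag.pseudowords import ClusterInventory, builtin_inventory, builtin_lexicon
from lexidiag.reader import ReaderProfile, TIME_GRID_MS


@pytest.fixture(scope="session")
def german_inventory() -> ClusterInventory:
    return builtin_inventory("de")


@pytest.fixture(scope="session")
def german_lexicon() -> list[str]:
    return builtin_lexicon("de")


@pytest.fixture
def example_reader() -> ReaderProfile:
    """The worked diagnostic example: capacity grows from 3 letters at 250 ms
    to 6 at 500 ms; pronunciation needs 1400 ms."""
    return ReaderProfile(
        capacity_by_time={250: 3, 300: 4, 350: 4, 400: 5, 450: 5, 500: 6},
        required_vrt_ms=1400.0,
        lapse_rate=0.0,
    )


@pytest.fixture
def unconstrained_reader() -> ReaderProfile:
    return ReaderProfile(
        capacity_by_time={t: 8 for t in TIME_GRID_MS},
        required_vrt_ms=1.0,
        lapse_rate=0.0,
    )


@pytest.fixture
def failing_reader() -> ReaderProfile:
    """Never recognizes anything: capacity zero at every fixation time."""
    return ReaderProfile(
        capacity_by_time={t: 0 for t in TIME_GRID_MS},
        required_vrt_ms=1000.0,
        lapse_rate=0.0,
    )
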