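import numpy as np
import pytest

from towcam import datasets
from towcam.annotations import FrameRecord


@pytest.fixture(scope="session")
def taxonomy():
    return datasets.default_taxonomy()


@pytest.fixture(scope="session")
def catch_table():
    return datasets.catch_table()


@pytest.fixture(scope="session")
def beam_trawl_counts():
    return datasets.catch_column("beam_trawl")


@pytest.fixture(scope="session")
def test_set_counts():
    return datasets.catch_column("test_set")


@pytest.fixture(scope="session")
def transect_counts():
    return datasets.catch_column("transects_1_7")


@pytest.fixture
def small_frames():
    """Three annotated frames holding three organisms in total."""
    return [
        FrameRecord("T1", 1, {"sand_dollar": 2}),
        FrameRecord("T1", 2, {}),
        FrameRecord("T1", 3, {"hermit": 1}),
    ]


def deterministic_stream(n_frames, counts_per_taxon, transect="T1"):
    """Spread fixed per-taxon totals over n_frames with a fixed stride."""
    frames = [FrameRecord(transect, i + 1, {}) for i in range(n_frames)]
    j = 0
    for taxon, total in counts_per_taxon.items():
        for _ in range(total):
            c = frames[(j * 7) % n_frames].counts
            c[taxon] = c.get(taxon, 0) + 1
            j += 1
    return frames


@pytest.fixture
def stream_200():
    return deterministic_stream(200, {"A": 30, "B": 10, "C": 5})
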