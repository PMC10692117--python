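import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def colombia_fixture():
    """The Colombia-scale synthetic fixture (3517 raw rows, 3303 clean)."""
    from conflict_spectroscopy.synthetic import make_colombia_fixture

    return make_colombia_fixture(seed=7)


@pytest.fixture(scope="session")
def colombia_csv(tmp_path_factory, colombia_fixture):
    table, _ = colombia_fixture
    path = tmp_path_factory.mktemp("fixture") / "events.csv"
    table.to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def colombia_filter(colombia_fixture):
    from conflict_spectroscopy.io_ged import FilterConfig

    _, manifest = colombia_fixture
    return FilterConfig(actor_whitelist=frozenset(manifest["actors"]))


@pytest.fixture(scope="session")
def colombia_segments(colombia_csv, colombia_filter):
    """Parsed, filtered, segmented fixture."""
    from conflict_spectroscopy.io_ged import filter_events, read_events
    from conflict_spectroscopy.segmentation import RegionMap, segment_events

    result = read_events(colombia_csv)
    kept, audit = filter_events(result.events, colombia_filter)
    segmented = segment_events(kept, RegionMap.default())
    return segmented, audit
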