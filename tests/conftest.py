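import matplotlib
import pytest

matplotlib.use("Agg")

from pubfig.theme import default_theme  # noqa: E402


@pytest.fixture()
def small_theme():
    """Publication theme shrunk for fast rasterization in tests."""
    return default_theme().with_(figure_size=(2.5, 2.0), resolution=150)


@pytest.fixture()
def pinned_timestamp():
    return "2021-06-15T12:00:00+00:00"
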