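import pytest

from printability import reference_panel


@pytest.fixture
def panel():
    """Bundled ten-substrate reference panel (verbatim values)."""
    return reference_panel()


@pytest.fixture
def panel_corrected():
    """Reference panel with the documented S2 DT-after correction applied."""
    return reference_panel(corrected_dt=True)
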