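from __future__ import annotations

import hypothesis
import pytest
from hypothesis import strategies as st

from cagscore import RepeatTrace

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=100, deadline=None
)
hypothesis.settings.load_profile("default")


@st.composite
def traces(draw, max_peaks: int = 10) -> RepeatTrace:
    """Random small repeat traces with at least one positive-height peak."""
    n = draw(st.integers(min_value=1, max_value=max_peaks))
    cags = draw(
        st.lists(
            st.integers(min_value=50, max_value=200),
            min_size=n, max_size=n, unique=True,
        )
    )
    heights = draw(
        st.lists(
            st.floats(min_value=0.0, max_value=1e5, allow_nan=False),
            min_size=n, max_size=n,
        )
    )
    hypothesis.assume(any(h > 0 for h in heights))
    return RepeatTrace(peaks=dict(zip(cags, heights)))


@pytest.fixture
def liver_like_trace() -> RepeatTrace:
    """Bimodal ladder: constitutive mode at 139 plus expanded mode at 152."""
    return RepeatTrace(
        peaks={139: 1000.0, 140: 300.0, 152: 800.0, 153: 400.0},
        sample_id="m001",
        tissue="liver",
        constitutive_cag=139,
    )
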