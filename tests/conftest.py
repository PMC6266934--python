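import hypothesis
import pytest
from hypothesis import strategies as st

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@st.composite
def seed_patterns(draw, max_span: int = 45, max_weight: int = 32):
    """Valid spaced-seed patterns: 1...1 over {0,1}, weight capped."""
    span = draw(st.integers(min_value=1, max_value=max_span))
    if span == 1:
        return "1"
    interior = draw(
        st.lists(st.sampled_from("01"), min_size=span - 2, max_size=span - 2)
    )
    pattern = "1" + "".join(interior) + "1"
    hypothesis.assume(pattern.count("1") <= max_weight)
    return pattern


@st.composite
def dna_sequences(draw, min_size: int = 0, max_size: int = 200, with_n: bool = False):
    alphabet = "ACGTN" if with_n else "ACGT"
    return draw(st.text(alphabet=alphabet, min_size=min_size, max_size=max_size))


@pytest.fixture
def example_seed():
    from fishash import parse_seed

    return parse_seed("1101110011111")
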