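import hypothesis
import hypothesis.strategies as st
import pytest

from zntrace import AbundanceVector, SourcePair, labeled_abundances

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=100, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def natural():
    return AbundanceVector.natural()


@pytest.fixture
def direct_pair(natural):
    """Direct-labeling source pair: natural soil, heavily labeled compost."""
    return SourcePair(soil=natural, fertilizer=labeled_abundances(31.0))


@pytest.fixture
def indirect_pair(natural):
    """Indirect-labeling pair: labeled soil pool, near-natural compost."""
    return SourcePair(soil=labeled_abundances(8.1), fertilizer=labeled_abundances(4.1))


def abundance_vectors(min_frac: float = 0.5, max_frac: float = 60.0):
    """Strategy for valid abundance vectors with all entries bounded away
    from zero (so ratio conversion is well-conditioned)."""
    return st.lists(
        st.floats(min_frac, max_frac, allow_nan=False), min_size=5, max_size=5
    ).map(
        lambda vals: AbundanceVector(
            {
                m: 100.0 * v / sum(vals)
                for m, v in zip((64, 66, 67, 68, 70), vals)
            },
            rel_tol=1e-6,
        )
    )


def source_pairs(min_ratio_gap: float = 0.01):
    """Strategy for resolvable source pairs (67:66 ratios well separated)."""
    return (
        st.tuples(abundance_vectors(), abundance_vectors())
        .filter(lambda t: abs(t[0].ratio() - t[1].ratio()) > min_ratio_gap)
        .map(lambda t: SourcePair(soil=t[0], fertilizer=t[1]))
    )
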