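import hypothesis
import pytest

import cmca

hypothesis.settings.register_profile(
    "cmca", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("cmca")


@pytest.fixture
def tiny_alignment() -> cmca.Alignment:
    """4 sequences x 6 columns with a gap-heavy column (col 5) and a
    conserved column (col 1)."""
    rows = (
        "ACDE-A",
        "ACDF-C",
        "AGHE-A",
        "AGHFWC",
    )
    return cmca.Alignment(tuple(f"s{i}" for i in range(4)), rows)


@pytest.fixture(scope="session")
def pdz_family():
    """Desk-scale fixture family (240 x 129) with planted structure."""
    return cmca.pdz_like_fixture()


@pytest.fixture(scope="session")
def pdz_analysis(pdz_family):
    """Reduced frequencies, position map and mutation correlation of the
    fixture, shared across tests (the fixture is deterministic)."""
    alignment, truth = pdz_family
    freq0 = cmca.position_frequencies(cmca.encode(alignment))
    freq, position_map = cmca.reduce_gaps(freq0)
    r_mut = cmca.mutation_correlation(freq)
    return {
        "alignment": alignment,
        "truth": truth,
        "freq0": freq0,
        "freq": freq,
        "position_map": position_map,
        "r_mut": r_mut,
    }
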