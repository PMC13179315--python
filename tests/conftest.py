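import warnings

import numpy as np
import pytest

from fto.annotation_io import DyadAnnotation, IntervalTier
from fto.simulate import paper_preset, simulate_corpus
from fto.turn_extraction import TransitionTable, extract_transitions

# arviz emits a refactor FutureWarning on import; irrelevant to the suite
warnings.filterwarnings("ignore", message=".*ArviZ is undergoing a major refactor.*")


def make_annotation(spurts_a, spurts_b, total=10.0, dyad_id="D01", group=None, context=None):
    """Build a DyadAnnotation from two lists of (start, end) speech spans."""
    return DyadAnnotation(
        dyad_id=dyad_id,
        tier_a=IntervalTier.from_speech_intervals("S1", spurts_a, total),
        tier_b=IntervalTier.from_speech_intervals("S2", spurts_b, total),
        group=group,
        context=context,
    )


@pytest.fixture()
def rng():
    # fresh, identically seeded generator per test: results never depend on
    # which other tests ran first
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def preset_corpus():
    """A seeded study-scale preset corpus with shortened (150 s) contexts —
    large enough for distributional checks, small enough to share across
    the whole suite."""
    config = paper_preset(seed=11, context_duration_s=150.0)
    return simulate_corpus(config)


@pytest.fixture(scope="session")
def preset_table(preset_corpus):
    tables = [extract_transitions(a.normalised()) for a in preset_corpus.annotations]
    return TransitionTable.concat(tables)
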