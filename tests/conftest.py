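import numpy as np
import pytest
from hypothesis import settings

import animrsa as ar
from animrsa.design import LexItem, build_design

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def make_lexicon(n_per_subgroup, nouns_per_classifier, subgroups=None):
    """Tiny deterministic lexicon for scaled designs."""
    subgroups = subgroups or list(ar.design.SUBGROUPS)
    classifiers, nouns = [], {}
    for sg in subgroups:
        for i in range(n_per_subgroup):
            cid = f"c_{sg}{i}"
            classifiers.append(LexItem(cid, "classifier", sg))
            nouns[cid] = [
                LexItem(f"n_{sg}{i}_{j}", "noun", sg)
                for j in range(nouns_per_classifier)
            ]
    return classifiers, nouns


@pytest.fixture(scope="session")
def canonical_design():
    return ar.default_design(rng_seed=0)


@pytest.fixture
def minimal_design():
    """1 human + 1 artifact classifier, 1 noun each: 2 congruent + 2 incongruent."""
    classifiers, nouns = make_lexicon(1, 1, subgroups=["human", "artifact"])
    return build_design(classifiers, nouns, rng_seed=0)


@pytest.fixture
def mini_design():
    """All four subgroups, 1 classifier x 2 nouns each: 16 trials."""
    classifiers, nouns = make_lexicon(1, 2)
    return build_design(classifiers, nouns, rng_seed=0)


def make_epochs(data, design, fs=500.0, t0_ms=0.0, ch_names=None):
    """Wrap a raw (subjects, trials, channels, time) array as an EpochSet."""
    data = np.asarray(data, dtype=float)
    n_time = data.shape[-1]
    times = t0_ms + np.arange(n_time) * 1000.0 / fs
    if ch_names is None:
        ch_names = ar.CHANNELS_62[: data.shape[2]]
    return ar.EpochSet(
        data=data, times=times, fs=fs, ch_names=ch_names, design=design
    )
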