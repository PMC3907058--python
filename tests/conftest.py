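import numpy as np
import pytest

from erpool.io import SampleMeta, SitePanel
from erpool.synth import StudyConfig, generate_founders


def make_panel(counts, treatments=None, generations=None, chrom=None, pos=None):
    """Convenience panel builder for hand-written fixtures.

    ``counts`` is (n_sites, n_samples, 6); default metadata is one base and
    one evolved sample per replicate pair.
    """
    counts = np.asarray(counts, dtype=np.int64)
    n_sites, n_samples, _ = counts.shape
    if treatments is None:
        half = n_samples // 2
        treatments = ["base"] * half + ["evolved"] * (n_samples - half)
    if generations is None:
        generations = [0 if t == "base" else 15 for t in treatments]
    reps = {}
    samples = []
    for i, (t, g) in enumerate(zip(treatments, generations)):
        reps[t] = reps.get(t, 0) + 1
        samples.append(SampleMeta(f"s{i + 1}", t, reps[t], g))
    return SitePanel(
        chrom=np.asarray(chrom if chrom is not None else ["2L"] * n_sites, dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(1, n_sites + 1)),
        ref=np.asarray(["N"] * n_sites, dtype=object),
        counts=counts,
        samples=samples,
    )


@pytest.fixture(scope="session")
def desk_config():
    return StudyConfig.desk_scale(seed=3)


@pytest.fixture(scope="session")
def _founder_pool(desk_config):
    return generate_founders(desk_config)


@pytest.fixture(scope="session")
def founders(_founder_pool):
    """Coalescent founder pool shared across forward-simulation tests."""
    return _founder_pool[0]


@pytest.fixture(scope="session")
def founder_lines(_founder_pool):
    return _founder_pool[1]
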