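import pytest

from famvote import pipeline, synthetic
from famvote.synthetic import DivergenceSpec

EASY_BINS = ((DivergenceSpec(substitution_rate=0.05, indel_rate=0.01), 1.0),)


@pytest.fixture(scope="session")
def easy_benchmark():
    """Small well-separated benchmark: 5 families x 15 members + 2 novel."""
    return synthetic.generate_benchmark(
        n_families=5,
        members_per_family=15,
        divergence_bins=EASY_BINS,
        n_novel_families=2,
        novel_members_per_family=8,
        n_profile_models=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def easy_run(easy_benchmark):
    """One full train/predict/evaluate round on the easy benchmark."""
    dataset, novel, seeds = easy_benchmark
    return pipeline.run_benchmark(dataset, novel, seeds, seed=11)
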