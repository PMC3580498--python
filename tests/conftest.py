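import pytest
from hypothesis import settings

from hogseq import ScenarioConfig, run_all
from hogseq.simulate import CLASSES

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

DEFAULT_SEED = 20124


def small_config(seed=7, n_per_class=10, depth=50_000, **overrides) -> ScenarioConfig:
    kwargs = dict(
        seed=seed,
        n_genes={c: n_per_class for c in CLASSES},
        chip_depth=depth,
        mnase_depth=depth,
    )
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


@pytest.fixture(scope="session")
def default_results():
    """One full analysis of the default scenario (500 genes, depth 5e5)."""
    return run_all(ScenarioConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def small_results():
    """A small end-to-end run shared by cheap integration checks."""
    return run_all(small_config())
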