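import pytest

from tlmnet.synthetic import SyntheticWorld, WorldParams, generate_world

# A compact world for unit tests and a default-sized benchmark world for
# the end-to-end checks; both are generated once per session.
SMALL_PARAMS = WorldParams(
    n_genes=200,
    n_pathways=12,
    n_complexes=24,
    n_go_terms=12,
    n_anchors=6,
    seed=11,
)
BENCH_PARAMS = WorldParams(seed=7)


@pytest.fixture(scope="session")
def small_world() -> SyntheticWorld:
    return generate_world(SMALL_PARAMS)


@pytest.fixture(scope="session")
def bench_world() -> SyntheticWorld:
    return generate_world(BENCH_PARAMS)
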