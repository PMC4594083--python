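import pytest

from patentchem.synthetic import (
    ErrorRates,
    GeneratorConfig,
    corrupt_to_automated,
    generate_gold_standard,
    write_fixtures,
)

# Small study conditions reused across tests: 6 patents, ~15 compounds each,
# two corrupted sources (the second with heavier stereo loss).
SMALL_CONFIG = GeneratorConfig(n_patents=6, compounds_per_patent_mean=15, seed=11)
RATES_A = ErrorRates()
RATES_B = ErrorRates(stereo_loss=0.3, noise_multiplier=2.0)


@pytest.fixture(scope="session")
def small_gold():
    return generate_gold_standard(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_sources(small_gold):
    ex_a, tr_a = corrupt_to_automated(small_gold, RATES_A, seed=101, source_tag="src_a")
    ex_b, tr_b = corrupt_to_automated(small_gold, RATES_B, seed=102, source_tag="src_b")
    return {"src_a": (ex_a, tr_a), "src_b": (ex_b, tr_b)}


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_gold, small_sources):
    out = tmp_path_factory.mktemp("synthetic_db")
    extracts = [pair[0] for pair in small_sources.values()]
    truths = [pair[1] for pair in small_sources.values()]
    return write_fixtures(small_gold, extracts, out, truths=truths)
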