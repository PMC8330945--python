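"""Shared fixtures: the default synthetic scenario and its TLA analysis are
built once per session (the host k-mer index dominates the cost)."""

import pytest

from tgmap import (
    default_long_read_target,
    run_tla,
    simulate_long_reads,
    simulate_scenario,
    simulate_tla_reads,
)


@pytest.fixture(scope="session")
def bundle():
    return simulate_scenario()


@pytest.fixture(scope="session")
def tla_reads(bundle):
    return simulate_tla_reads(bundle)


@pytest.fixture(scope="session")
def tla_result(bundle, tla_reads):
    return run_tla(
        tla_reads,
        bundle.wildtype,
        bundle.sources[bundle.config.transgene_name],
        fosmid_sequence=bundle.transgene_sequence,
    )


@pytest.fixture(scope="session")
def long_reads(bundle):
    return simulate_long_reads(bundle, default_long_read_target(bundle))
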