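from importlib import resources

import pytest

from mhcdiv import (
    PbrMask,
    SynthConfig,
    read_unit_table,
    simulate_allele_panel,
    simulate_study,
    translate_and_flag,
)


@pytest.fixture(scope="session")
def mask() -> PbrMask:
    return PbrMask.default()


@pytest.fixture(scope="session")
def table1():
    """The published per-unit allele-count table shipped with the package."""
    path = resources.files("mhcdiv.data").joinpath("unit_table.tsv")
    return read_unit_table(path)


@pytest.fixture(scope="session")
def small_bundle():
    """Desk-scale synthetic study: 12 allotypes, 6 bears per unit."""
    cfg = SynthConfig(
        seed=5, n_allotypes=12, synonymous_variants=4, individuals_per_unit=(6,) * 12
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def default_panel():
    """Study-sized synthetic allele panel (31 allotypes, 44 variants)."""
    aln, truth = simulate_allele_panel(SynthConfig(seed=1))
    return aln, truth


@pytest.fixture(scope="session")
def default_coding(default_panel):
    aln, _ = default_panel
    return aln.subset(translate_and_flag(aln).coding_variants)
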