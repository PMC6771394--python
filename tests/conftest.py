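import pytest

from citrusdiag.synthetic import (
    HybridSpec,
    SimulationConfig,
    derive_haploid,
    simulate_panel,
)

#: small clean panel: a trio with haploid derivative, an F1 and a backcross
SMALL_CONFIG = SimulationConfig(
    n_genes=6,
    gene_length_range=(400, 900),
    exons_per_gene_range=(1, 4),
    snps_per_gene_range=(10, 25),
    seed=11,
    missing_rate=0.0,
)

#: backcross panel: many BC1-to-R accessions over mostly fixed differences
BC_CONFIG = SimulationConfig(
    n_genes=24,
    gene_length_range=(400, 900),
    exons_per_gene_range=(1, 4),
    snps_per_gene_range=(10, 20),
    p_fixed_interspecific=0.6,
    p_intra_R=0.05,
    p_intra_M=0.05,
    n_pure_R=4,
    n_pure_M=4,
    n_outgroup=3,
    hybrid_specs=tuple(HybridSpec(f"bc{i + 1}", "BC-to-R") for i in range(12)),
    missing_rate=0.0,
    seed=7,
)


@pytest.fixture(scope="session")
def clean_sim():
    """(panel, genes, config, truth) with zero missingness and a haploid
    derivative of the recorded trio offspring."""
    panel, genes, config, truth = simulate_panel(SMALL_CONFIG)
    derive_haploid(panel, config, "trio_child", truth, which=0)
    return panel, genes, config, truth


@pytest.fixture(scope="session")
def bc_sim():
    """(panel, genes, config, truth) with twelve BC1-to-R accessions."""
    return simulate_panel(BC_CONFIG)
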