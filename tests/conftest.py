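import numpy as np
import pandas as pd
import pytest

from mbgblup import popsim as ps


@pytest.fixture(scope="session")
def tiny_config():
    """A four-breed configuration small enough for per-test simulation."""
    return ps.SimConfig(
        seed=1,
        n_base=120,
        ld_generations=10,
        effective_size=60,
        divergence_generations=(20, 15, 10, 10),
        snps_per_chromosome=200,
        n_qtl=60,
        family_size_range=(8, 15),
    )


@pytest.fixture(scope="session")
def tiny_breeds(tiny_config):
    base = ps.simulate_founders(tiny_config)
    breeds = ps.derive_breeds(base, tiny_config)
    breeds.qtl = ps.sample_qtl(breeds, tiny_config)
    return breeds


@pytest.fixture(scope="session")
def tiny_population(tiny_config, tiny_breeds):
    design = ps.DesignSpec(
        n_purebred={"MER": 120},
        f1_crosses=[("BL", "MER", 80)],
        three_way=[("PD", "BL", "MER", 40)],
        n_sires={"MER": 10, "BL": 8, "PD": 5},
        validation_sires={"MER": 8, "BL": 5},
    )
    pop = ps.build_design(tiny_breeds, tiny_config, design)
    pop.qtl = tiny_breeds.qtl
    return pop


@pytest.fixture()
def toy_genotypes():
    """A handmade 4-animal x 5-SNP genotype table."""
    from mbgblup.geno_qc import GenotypeTable

    calls = np.array(
        [
            [0, 1, 2, 1, 0],
            [1, 1, 0, 2, 0],
            [2, 0, 1, 1, 1],
            [1, 2, 1, 0, 2],
        ],
        dtype=np.int8,
    )
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(5)],
            "chrom": "1",
            "pos": np.arange(5, dtype=float),
            "a1": "1",
            "a2": "2",
        }
    )
    return GenotypeTable([f"a{i}" for i in range(4)], snps, calls)
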