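import numpy as np
import pytest

from landgen.genotypes import MISSING, GenotypeTable
from landgen.simulate import ScenarioConfig, make_landscape, migration_matrix, simulate_genotypes


def make_table(pop_calls: dict[str, list[list[tuple[int, int] | None]]],
               loci: list[str] | None = None) -> GenotypeTable:
    """Build a GenotypeTable from {pop: [per-individual list of calls]}.

    A call is an (a1, a2) tuple or None for missing.
    """
    individuals, populations, rows = [], [], []
    n_loci = len(next(iter(pop_calls.values()))[0])
    loci = loci or [f"L{i + 1}" for i in range(n_loci)]
    k = 0
    for pop, inds in pop_calls.items():
        for calls in inds:
            k += 1
            individuals.append(f"ind{k}")
            populations.append(pop)
            row = np.full((n_loci, 2), MISSING, dtype=np.int32)
            for li, call in enumerate(calls):
                if call is not None:
                    row[li] = call
            rows.append(row)
    return GenotypeTable(individuals, loci, np.stack(rows), populations)


@pytest.fixture(scope="session")
def ibd_scenario():
    """One seeded IBD-scenario simulation with its landscape and truth."""
    cfg = ScenarioConfig(scenario="ibd", seed=11)
    rng = np.random.default_rng(cfg.seed)
    raster, sites = make_landscape(cfg, rng)
    truth = migration_matrix(cfg, sites, raster)
    gt = simulate_genotypes(cfg, truth, rng, deme_names=sites.populations)
    gt.hierarchy = sites.hierarchy()
    return cfg, raster, sites, truth, gt


@pytest.fixture(scope="session")
def packaged_sites():
    from landgen.genotypes import load_packaged_sites

    return load_packaged_sites()
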