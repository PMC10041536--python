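import warnings

import numpy as np
import pandas as pd
import pytest

import tempsweep as ts
from tempsweep import sim

warnings.filterwarnings("ignore", message="no depth annotation")


@pytest.fixture(scope="session")
def small_sim():
    """One small selected simulation shared across tests: full populations,
    sampled cohorts, truth tables."""
    cfg = ts.SimConfig(
        pop_size=400,
        n_snps=300,
        n_causal=10,
        n_chromosomes=2,
        chrom_length_bp=250_000,
        recomb_rate=4e-6,
        seed=11,
    )
    pops = sim.run_simulation(cfg)
    gm, meta, pheno = sim.sample_cohorts(pops, cfg.sample_schedule)
    traj, registry = sim.export_truth(pops)
    return dict(cfg=cfg, pops=pops, gm=gm, meta=meta, pheno=pheno, traj=traj, registry=registry)


@pytest.fixture()
def toy_genotypes():
    """Tiny deterministic GenotypeMatrix (4 samples x 5 sites, phased)."""
    hap = np.array(
        [
            [0, 1, 0, 1, 1],
            [0, 0, 0, 1, 0],
            [1, 1, 0, 0, 1],
            [0, 1, 0, 0, 0],
            [1, 0, 1, 1, 1],
            [1, 1, 0, 1, 0],
            [0, 0, 0, 0, 1],
            [0, 0, 1, 0, 1],
        ],
        dtype=np.int8,
    )
    dosage = hap[0::2] + hap[1::2]
    return ts.GenotypeMatrix(
        chrom=np.array(["chr1"] * 5, dtype=object),
        pos=np.array([100, 200, 300, 400, 500]),
        ref=np.array(list("ACGTA"), dtype=object),
        alt=np.array(list("GTACG"), dtype=object),
        dosage=dosage,
        samples=["s1", "s2", "s3", "s4"],
        haplotypes=hap,
    )


@pytest.fixture()
def toy_meta():
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "generation": [1, 1, 10, 10],
            "sex": ["M", "F", "M", "F"],
        }
    )
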