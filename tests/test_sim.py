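import math

import numpy as np
import pandas as pd
import pytest

import tempsweep as ts
from tempsweep import sim
from tempsweep.sim import SimConfig, bmw_from_measurements


class TestBmwFormula:
    @pytest.mark.parametrize(
        "bb,kl,bmt,expected",
        [
            (0, 0, 0, 17.042),  # regression intercept
            (1, 1, 1, 17.6648),  # 0.6228 + 17.042
            (10, 10, 2, 141.602),  # 0.6228 * 200 + 17.042
        ],
    )
    def test_values(self, bb, kl, bmt, expected):
        assert bmw_from_measurements(bb, kl, bmt) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [(-1, 1, 1), (1, float("nan"), 1), (1, 1, float("inf"))])
    def test_invalid_measurements_raise(self, bad):
        with pytest.raises(ValueError):
            bmw_from_measurements(*bad)

    def test_backfill_round_trip(self):
        bb, kl, bmt, bmv = sim.measurements_from_bmw(150.0)
        assert bmw_from_measurements(bb, kl, bmt) == pytest.approx(150.0)
        assert bmv == pytest.approx(float(bb) * float(kl) * float(bmt))


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(pop_size=0)
    with pytest.raises(ValueError):
        SimConfig(female_retention=1.5)
    with pytest.raises(ValueError):
        SimConfig(h2=1.2)
    with pytest.raises(ValueError):
        SimConfig(n_causal=10, n_snps=5)


def test_retention_ceiling_arithmetic():
    """750 birds, 375 males at 7.5% male retention -> 29 sires retained."""
    cfg = SimConfig(
        pop_size=750,
        n_snps=20,
        n_causal=0,
        n_chromosomes=2,
        founder_maf_law={"law": "fixed", "p": 0.5},
        seed=1,
    )
    pop = sim.simulate_founders(cfg)
    sires, dams = sim._truncate(pop, cfg)
    assert len(sires) == math.ceil(0.075 * (pop.sex == "M").sum()) == 29
    assert len(dams) == math.ceil(0.375 * (pop.sex == "F").sum())
    # retained sires really are the top male phenotypes
    males = pop.phenotype[pop.sex == "M"]
    assert np.min(pop.phenotype[sires]) >= np.quantile(males, 1 - 29 / 375 - 0.01)


def test_founder_frequency_matches_law():
    cfg = SimConfig(
        pop_size=500,
        n_snps=40,
        n_causal=0,
        n_chromosomes=2,
        founder_maf_law={"law": "fixed", "p": 0.5},
        seed=3,
    )
    pop = sim.simulate_founders(cfg)
    freq = pop.haplotypes.mean(axis=0)
    sd = math.sqrt(0.25 / (2 * cfg.pop_size))
    assert abs(freq.mean() - 0.5) < 3 * sd


def test_no_causal_loci_gives_flat_genetic_values():
    cfg = SimConfig(
        pop_size=100, n_snps=30, n_causal=0, n_chromosomes=2,
        founder_maf_law={"law": "uniform"}, seed=5,
    )
    pop = sim.simulate_founders(cfg)
    assert np.ptp(pop.genetic_value) == 0


def test_same_seed_bitwise_identical():
    cfg = SimConfig(
        pop_size=120, n_snps=50, n_causal=5, n_chromosomes=2,
        chrom_length_bp=100_000, seed=42,
    )
    a = sim.run_simulation(cfg)
    b = sim.run_simulation(cfg)
    for pa, pb in zip(a, b):
        np.testing.assert_array_equal(pa.haplotypes, pb.haplotypes)
        np.testing.assert_array_equal(pa.phenotype, pb.phenotype)
        np.testing.assert_array_equal(pa.sex, pb.sex)
    ga, ma, fa = sim.sample_cohorts(a, ((1, 5, 5), (3, 5, 5)))
    gb, mb, fb = sim.sample_cohorts(b, ((1, 5, 5), (3, 5, 5)))
    assert list(ma.sample_id) == list(mb.sample_id)
    np.testing.assert_array_equal(ga.dosage, gb.dosage)


def test_dosage_is_haplotype_sum(small_sim):
    for pop in small_sim["pops"]:
        np.testing.assert_array_equal(
            pop.dosage(), pop.haplotypes[0::2] + pop.haplotypes[1::2]
        )


def test_phenotype_decomposition(small_sim):
    # phenotype = genetic value + environmental deviation with the calibrated SD
    for pop in small_sim["pops"]:
        dev = pop.phenotype - pop.genetic_value
        assert np.std(dev) == pytest.approx(pop.genome.sigma_e, rel=0.35)


def test_h2_zero_means_no_response():
    """With h2 = 0 selection sees pure noise: no systematic trait response."""
    slopes = []
    for seed in range(8):
        cfg = SimConfig(
            pop_size=150, n_generations=6, n_snps=40, n_causal=8,
            n_chromosomes=2, h2=0.0,
            founder_maf_law={"law": "uniform", "low": 0.2, "high": 0.8},
            seed=seed,
        )
        pops = sim.run_simulation(cfg)
        means = [p.genetic_value.mean() for p in pops]
        slopes.append(np.polyfit(np.arange(len(means)), means, 1)[0])
    t = np.mean(slopes) / (np.std(slopes, ddof=1) / math.sqrt(len(slopes)))
    assert t < 3.0  # no significant upward genetic trend


def test_selected_trait_responds(small_sim):
    pheno = small_sim["pheno"]
    assert (
        pheno.loc[pheno.generation == 10, "BMW"].mean()
        > pheno.loc[pheno.generation == 1, "BMW"].mean()
    )


def test_default_schedule_yields_119(small_sim):
    meta = small_sim["meta"]
    assert len(meta) == 119
    counts = meta.groupby("generation").size()
    assert counts.to_dict() == {1: 30, 4: 29, 7: 30, 10: 30}
    assert meta["sample_id"].is_unique


def test_empty_cohort_and_bad_schedule():
    cfg = SimConfig(
        pop_size=60, n_snps=20, n_causal=0, n_chromosomes=2,
        founder_maf_law={"law": "uniform"}, seed=2,
    )
    pops = sim.run_simulation(cfg)
    gm, meta, pheno = sim.sample_cohorts(pops, ((1, 0, 0),))
    assert len(meta) == 0 and gm.n_samples == 0
    with pytest.raises(ValueError, match="generation 99"):
        sim.sample_cohorts(pops, ((99, 5, 5),))


def test_export_truth_trajectories(small_sim):
    traj, registry = small_sim["traj"], small_sim["registry"]
    gens = traj.filter(like="gen").to_numpy()
    assert gens.shape[1] == small_sim["cfg"].n_generations
    assert ((gens >= 0) & (gens <= 1)).all()
    # monomorphic founder loci stay flat under no mutation
    fixed = np.isin(gens[:, 0], [0.0, 1.0])
    assert np.all(gens[fixed].std(axis=1) == 0)
    assert len(registry) == small_sim["cfg"].n_causal
    # selection moves causal loci more than neutral ones on average
    causal = traj.pos.isin(registry.pos)
    d_causal = np.abs(gens[causal, -1] - gens[causal, 0]).mean()
    d_neutral = np.abs(gens[~causal, -1] - gens[~causal, 0]).mean()
    assert d_causal > d_neutral


def test_causal_alleles_rise_but_do_not_all_fix(small_sim):
    traj, registry = small_sim["traj"], small_sim["registry"]
    gens = traj[traj.pos.isin(registry.pos)].filter(like="gen").to_numpy()
    assert np.max(np.abs(gens[:, -1] - gens[:, 0])) < 1.0


def test_annotation_track_covers_categories():
    track = sim.make_annotation_track(2, 100_000)
    cats = {c for _, _, _, c in track.to_intervals()}
    assert cats == {"exon", "UTR", "intron"}


def test_cnv_matrix_shapes_and_truth(toy_meta):
    values, coords, truth = sim.simulate_cnv_matrix(toy_meta, n_cnvr=12, seed=4)
    assert values.shape == (12, 4)
    assert (values.to_numpy() >= 0).all()
    assert truth["selected"].sum() == 1
    sel = truth[truth.selected].iloc[0]
    assert sel["gen10"] > sel["gen1"]
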