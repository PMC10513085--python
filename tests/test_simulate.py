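"""Tests for the synthetic cohort generator and its file round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cortnet import SimulationConfig, simulate_cohort, simulate_replication
from cortnet.causal import linkage_llr, llr_null_pvalue, supernormalize
from cortnet.io import read_cohort, write_cohort
from cortnet.replicate import abs_corr_matrix, offdiag_values


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_samples=0)
    with pytest.raises(ValueError):
        SimulationConfig(maf_range=(0.0, 0.5))
    with pytest.raises(ValueError):
        SimulationConfig(replication_attenuation=1.2)
    with pytest.raises(ValueError):
        SimulationConfig(n_genes_per_tissue=10, n_trans_genes=5,
                         n_regulators=3, targets_per_regulator=10)


def test_truth_edge_count_forced_by_config():
    cfg = SimulationConfig(n_samples=100, n_genes_per_tissue=120,
                           n_trans_genes=5, n_regulators=3,
                           targets_per_regulator=10, n_tissues=1, seed=1)
    cohort = simulate_cohort(cfg)
    assert len(cohort.truth.true_edges) == 30
    for reg in cohort.truth.regulators():
        assert reg in cohort.truth.instrument_map


def test_seed_determinism(small_config, small_cohort):
    again = simulate_cohort(small_config)
    for tissue in small_config.tissues():
        pd.testing.assert_frame_equal(small_cohort.expression[tissue],
                                      again.expression[tissue])
        pd.testing.assert_frame_equal(small_cohort.replication[tissue],
                                      again.replication[tissue])
    pd.testing.assert_frame_equal(small_cohort.genotypes, again.genotypes)
    assert small_cohort.truth.true_edges == again.truth.true_edges


def test_trans_effect_recovered_by_ols():
    """Regressing a planted trans gene on its SNP recovers the slope."""
    cfg = SimulationConfig(n_samples=300, n_genes_per_tissue=120,
                           n_trans_genes=5, trans_effect_size=0.8,
                           n_regulators=0, targets_per_regulator=0,
                           n_tissues=1, seed=2)
    cohort = simulate_cohort(cfg)
    tissue = cfg.tissues()[0]
    snp, gene, _ = sorted(cohort.truth.true_trans_pairs)[0]
    E = cohort.genotypes.loc[snp].to_numpy().astype(float)
    y = cohort.expression[tissue].loc[gene].to_numpy()
    res = stats.linregress(E, y)
    assert abs(res.slope - 0.8) < 3 * res.stderr


def test_ld_within_blocks():
    cfg = SimulationConfig(n_samples=400, n_genes_per_tissue=120,
                           n_trans_genes=0, n_regulators=0,
                           targets_per_regulator=0, n_tissues=1, seed=3)
    cohort = simulate_cohort(cfg)
    blocks = cohort.snp_info[cohort.snp_info["block"] > 0]
    b1 = blocks[blocks["block"] == 1].index
    b2 = blocks[blocks["block"] == 2].index
    g1 = cohort.genotypes.loc[b1].to_numpy().astype(float)
    g2 = cohort.genotypes.loc[b2].to_numpy().astype(float)
    within = np.corrcoef(g1)[np.triu_indices(len(b1), k=1)]
    across = np.corrcoef(g1.mean(0), g2.mean(0))[0, 1]
    # per-copy flips at (1-r)/2 give each SNP correlation ~r with the latent
    # haplotype, hence pairwise SNP-SNP correlation ~r^2 (attenuated further
    # away from maf 0.5); blocks are mutually independent
    assert within.mean() > 0.3
    assert abs(across) < 0.15


def test_planted_llr_dominates_null():
    cfg = SimulationConfig(n_samples=300, n_genes_per_tissue=300,
                           n_trans_genes=20, trans_effect_size=0.5,
                           n_regulators=0, targets_per_regulator=0,
                           n_tissues=1, seed=4)
    cohort = simulate_cohort(cfg)
    tissue = cfg.tissues()[0]
    expr = cohort.expression[tissue]
    rng = np.random.default_rng(0)
    true_llrs, null_llrs = [], []
    trans = cohort.truth.trans_genes(tissue)
    null_genes = sorted(set(expr.index) - trans)
    for snp, gene, _ in sorted(cohort.truth.true_trans_pairs):
        E = cohort.genotypes.loc[snp].to_numpy()
        true_llrs.append(linkage_llr(E, supernormalize(expr.loc[gene])))
        g0 = null_genes[rng.integers(len(null_genes))]
        null_llrs.append(linkage_llr(E, supernormalize(expr.loc[g0])))
    assert stats.mannwhitneyu(true_llrs, null_llrs,
                              alternative="greater").pvalue < 0.01


def test_null_gene_pvalues_uniform():
    """Genes without planted effects are independent of every SNP."""
    cfg = SimulationConfig(n_samples=200, n_genes_per_tissue=200,
                           n_trans_genes=5, n_regulators=0,
                           targets_per_regulator=0, n_tissues=1, seed=5)
    cohort = simulate_cohort(cfg)
    tissue = cfg.tissues()[0]
    expr = cohort.expression[tissue]
    trans = cohort.truth.trans_genes(tissue)
    null_genes = sorted(set(expr.index) - trans)
    rng = np.random.default_rng(1)
    snps = list(cohort.genotypes.index)
    pvals = []
    for _ in range(800):
        sid = snps[rng.integers(len(snps))]
        gene = null_genes[rng.integers(len(null_genes))]
        E = cohort.genotypes.loc[sid].to_numpy()
        k = np.unique(E).size
        llr = linkage_llr(E, supernormalize(expr.loc[gene]))
        pvals.append(llr_null_pvalue(llr, cfg.n_samples, k))
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


@pytest.mark.parametrize("attenuation", [0.0, 1.0])
def test_replication_attenuation(attenuation):
    cfg = SimulationConfig(n_samples=400, n_genes_per_tissue=300,
                           n_trans_genes=1, n_regulators=1,
                           targets_per_regulator=30, edge_effect_size=0.8,
                           n_tissues=1, replication_attenuation=attenuation,
                           seed=6)
    cohort = simulate_cohort(cfg)
    tissue = cfg.tissues()[0]
    reg = sorted(cohort.truth.regulators(tissue))[0]
    targets = sorted(cohort.truth.targets_of(reg, tissue))
    repl = cohort.replication[tissue]
    target_corr = offdiag_values(abs_corr_matrix(repl, targets))
    rng = np.random.default_rng(2)
    null_pool = sorted(set(repl.index) - set(targets) - {reg})
    bg_genes = rng.choice(null_pool, size=30, replace=False)
    bg_corr = offdiag_values(abs_corr_matrix(repl, bg_genes))
    if attenuation == 1.0:
        assert target_corr.mean() > 2 * bg_corr.mean()
    else:
        assert abs(target_corr.mean() - bg_corr.mean()) < 0.02


def test_replication_determinism(small_config, small_cohort):
    again = simulate_replication(small_cohort.truth, small_config)
    for tissue in small_config.tissues():
        pd.testing.assert_frame_equal(small_cohort.replication[tissue],
                                      again[tissue])


def test_write_read_round_trip(small_cohort, tmp_path):
    write_cohort(small_cohort, tmp_path)
    back = read_cohort(tmp_path)
    # genotype dosages exactly equal after the VCF round trip
    pd.testing.assert_frame_equal(
        small_cohort.genotypes,
        back.genotypes.loc[small_cohort.genotypes.index,
                           small_cohort.genotypes.columns])
    # expression TSV has gene ids in the first column
    header = (tmp_path / "expression_liver.tsv").read_text().splitlines()[0]
    assert header.split("\t")[0] == "gene"
    # truth ledger round-trips exactly
    assert back.truth.true_edges == small_cohort.truth.true_edges
    assert back.truth.true_trans_pairs == small_cohort.truth.true_trans_pairs
    assert back.truth.instrument_map == small_cohort.truth.instrument_map
    np.testing.assert_allclose(
        small_cohort.expression["liver"].to_numpy(),
        back.expression["liver"].to_numpy(), atol=1e-8)
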