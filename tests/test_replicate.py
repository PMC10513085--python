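"""Tests for co-expression replication: correlations, Kruskal-Wallis,
background sampling and cluster-order transfer."""

import numpy as np
import pandas as pd
import pytest

from cortnet.replicate import (abs_corr_matrix, background_corr_sample,
                               compare_distributions, offdiag_values,
                               replicate_network, transfer_cluster_order)


def _expr(mat, genes=None):
    mat = np.asarray(mat, dtype=float)
    genes = genes or [f"g{i}" for i in range(mat.shape[0])]
    return pd.DataFrame(mat, index=genes,
                        columns=[f"s{j}" for j in range(mat.shape[1])])


def test_abs_corr_perfect_anticorrelation():
    y = np.linspace(0, 1, 10)
    corr = abs_corr_matrix(_expr([y, -y]), ["g0", "g1"])
    assert corr.iloc[0, 1] == pytest.approx(1.0)


def test_abs_corr_independent_permutation_near_zero():
    rng = np.random.default_rng(0)
    y = rng.standard_normal(1000)
    corr = abs_corr_matrix(_expr([y, rng.permutation(y)]), ["g0", "g1"])
    assert corr.iloc[0, 1] < 0.1


def test_abs_corr_contract():
    rng = np.random.default_rng(1)
    corr = abs_corr_matrix(_expr(rng.standard_normal((3, 20))),
                           ["g0", "g1", "g2"])
    arr = corr.to_numpy()
    assert np.allclose(arr, arr.T)
    assert np.allclose(np.diag(arr), 1.0)
    assert ((arr >= 0) & (arr <= 1)).all()


def test_abs_corr_drops_missing_and_validates():
    rng = np.random.default_rng(2)
    e = _expr(rng.standard_normal((3, 10)))
    corr = abs_corr_matrix(e, ["g0", "g2", "missing"])
    assert list(corr.index) == ["g0", "g2"]
    with pytest.raises(ValueError, match="2 genes"):
        abs_corr_matrix(e, ["g0", "missing"])
    with pytest.raises(ValueError, match="3 samples"):
        abs_corr_matrix(_expr(rng.standard_normal((3, 2))), ["g0", "g1"])


def test_background_sample_counts_and_determinism():
    rng = np.random.default_rng(3)
    e = _expr(rng.standard_normal((30, 50)))
    vals = background_corr_sample(e, set_size=2, n_draws=5, seed=7)
    assert vals.shape == (5,)  # one off-diagonal pair per draw
    again = background_corr_sample(e, set_size=2, n_draws=5, seed=7)
    np.testing.assert_array_equal(vals, again)
    with pytest.raises(ValueError, match="smaller"):
        background_corr_sample(e, set_size=31)


def test_background_sample_matches_null_corr_distribution():
    """On white noise the pooled |r| values follow the analytic null of the
    Pearson correlation for that sample size."""
    from scipy import stats

    rng = np.random.default_rng(4)
    n = 40
    e = _expr(rng.standard_normal((200, n)))
    vals = background_corr_sample(e, set_size=20, n_draws=8, seed=1)
    # |r| has CDF 2*F_r(x) - 1 with r ~ beta-shaped null on [-1, 1]
    null = stats.beta(0.5 * (n - 2), 0.5 * (n - 2), loc=-1, scale=2)
    ks = stats.kstest(vals, lambda x: 2 * null.cdf(x) - 1)
    assert ks.pvalue > 0.01


def test_kruskal_wallis_hand_computed_example():
    h, p = compare_distributions([1, 2, 3], [4, 5, 6])
    # ranks 1..6: R1=6, R2=15 -> H = 12/(6*7) * (36/3 + 225/3) - 3*7
    h_hand = 12 / 42 * (36 / 3 + 225 / 3) - 21
    assert h == pytest.approx(h_hand, abs=1e-10)
    assert p == pytest.approx(0.0495, abs=5e-4)


def test_kruskal_wallis_identical_samples():
    h, p = compare_distributions([0.2, 0.4, 0.4], [0.2, 0.4, 0.4])
    assert h == 0.0 and p == 1.0
    with pytest.raises(ValueError, match="nonempty"):
        compare_distributions([], [1.0])


def test_transfer_cluster_order_blocks():
    # two planted clusters: the discovery leaf order keeps blocks contiguous
    rng = np.random.default_rng(5)
    base = np.full((6, 6), 0.05)
    base[:3, :3] = 0.9
    base[3:, 3:] = 0.9
    np.fill_diagonal(base, 1.0)
    genes = [f"g{i}" for i in range(6)]
    disc = pd.DataFrame(base, index=genes, columns=genes)
    perm = list(rng.permutation(genes))
    repl = disc.loc[perm, perm]
    order, disc_re, repl_re = transfer_cluster_order(disc, disc)
    assert sorted(order) == list(range(6))  # a permutation
    labels = [int(g[1]) < 3 for g in disc_re.index]
    # each block contiguous: exactly one switch point
    assert sum(l1 != l2 for l1, l2 in zip(labels, labels[1:])) == 1
    # identical matrices reorder identically
    _, a, b = transfer_cluster_order(disc, disc.copy())
    pd.testing.assert_frame_equal(a, b)
    with pytest.raises(ValueError, match="shared"):
        transfer_cluster_order(disc, disc.rename(index=str.upper,
                                                 columns=str.upper))


def test_replicate_network_planted_vs_null(small_cohort):
    tissue = small_cohort.config.tissues()[0]
    truth = small_cohort.truth
    reg = sorted(truth.regulators(tissue))[0]
    targets = sorted(truth.targets_of(reg, tissue))
    res = replicate_network(reg, targets, small_cohort.expression[tissue],
                            small_cohort.replication[tissue], seed=0)
    assert res.pvalue < 1e-4  # attenuation 0.8, strong edges
    assert res.n_targets == len(targets)
    assert sorted(res.leaf_order) == list(range(len(targets)))
    assert res.target_corr.size == len(targets) * (len(targets) - 1) // 2
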