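"""Unit and property tests for the likelihood-ratio test suite."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cortnet import causal as C

from conftest import draw_genotype


# ---------------------------------------------------------------------------
# supernormalization
# ---------------------------------------------------------------------------

def test_supernormalize_closed_form():
    # ranks 3,1,2 -> quantiles (2.5, 0.5, 1.5)/3, then centred/rescaled
    z = C.supernormalize([3.0, 1.0, 2.0])
    q = stats.norm.ppf(np.array([2.5, 0.5, 1.5]) / 3)
    q = (q - q.mean()) / q.std()
    np.testing.assert_allclose(z, q, atol=1e-12)
    assert abs(z.mean()) < 1e-6 and abs(z.var() - 1.0) < 1e-6


@pytest.mark.parametrize("bad", [[1.0, 1.0], [2.0, 2.0, 2.0], [5.0]])
def test_supernormalize_degenerate(bad):
    with pytest.raises(ValueError):
        C.supernormalize(bad)


@settings(max_examples=25, derandomize=True)
@given(st.lists(st.integers(-1000, 1000), min_size=5, max_size=40,
                unique=True))
def test_supernormalize_monotone_invariance_and_idempotence(values):
    x = np.asarray(values, dtype=float) / 7.3
    z = C.supernormalize(x)
    # any strictly monotone transform gives the same output
    np.testing.assert_allclose(C.supernormalize(np.exp(x / 300)), z,
                               atol=1e-10)
    # idempotence
    np.testing.assert_allclose(C.supernormalize(z), z, atol=1e-10)


# ---------------------------------------------------------------------------
# linkage LLR and its analytic null
# ---------------------------------------------------------------------------

def test_linkage_llr_worked_example():
    """Six samples, three genotype groups, checked against explicit
    maximum-likelihood sums of squares."""
    E = np.array([0, 0, 1, 1, 2, 2])
    y = np.array([1.0, 2.0, 2.0, 3.0, 3.0, 4.0])
    # oracle: weighted between-group and total sums of squares
    grand = y.mean()
    ssb = sum((E == g).sum() * (y[E == g].mean() - grand) ** 2 for g in range(3))
    sst = ((y - grand) ** 2).sum()
    expected = -0.5 * len(y) * np.log(1 - ssb / sst)
    assert abs(C.linkage_llr(E, y) - expected) < 1e-9
    assert abs(ssb / sst - 4 / 5.5) < 1e-12


def test_linkage_llr_no_between_group_variance():
    assert C.linkage_llr([0, 0, 1, 1], [1.0, -1.0, 1.0, -1.0]) == 0.0


def test_linkage_llr_monomorphic():
    with pytest.raises(ValueError, match="monomorphic"):
        C.linkage_llr([1, 1, 1, 1], [1.0, 2.0, 3.0, 4.0])


def test_planted_association_beats_permutations():
    rng = np.random.default_rng(0)
    E = draw_genotype(rng, 120)
    y = C.supernormalize(0.8 * E + rng.standard_normal(120))
    observed = C.linkage_llr(E, y)
    perm = np.mean([C.linkage_llr(E, rng.permutation(y)) for _ in range(200)])
    assert observed > perm


def test_llr_null_pvalue_boundaries():
    assert C.llr_null_pvalue(0.0, 10, 2) == 1.0
    # n=4, k=2, R^2=0.25: Beta(1/2, 1) CDF is sqrt(x) -> p = 1 - 0.5
    llr = -2.0 * np.log(0.75)
    assert abs(C.llr_null_pvalue(llr, 4, 2) - 0.5) < 1e-12
    with pytest.raises(ValueError, match="degrees of freedom"):
        C.llr_null_pvalue(1.0, 2, 2)


def test_analytic_null_matches_permutation():
    """Beta-null p-values agree with permutation p-values within MC error."""
    rng = np.random.default_rng(7)
    n, k, n_perm = 60, 3, 2000
    for _ in range(10):
        E = draw_genotype(rng, n, k=k)
        inv, _ = C._encode_genotype(E)
        y = C.supernormalize(rng.standard_normal(n))
        obs = C.linkage_llr(E, y)
        Yperm = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
        perm_llrs = C._anova_llr(inv, k, Yperm)
        p_perm = (perm_llrs >= obs - 1e-12).mean()
        p_analytic = C.llr_null_pvalue(obs, n, k)
        se = np.sqrt(max(p_analytic * (1 - p_analytic), 1e-4) / n_perm)
        assert abs(p_perm - p_analytic) < 3 * se + 1 / n_perm


def test_null_pvalues_uniform():
    rng = np.random.default_rng(1)
    n = 200
    llrs = np.array([
        C.linkage_llr(draw_genotype(rng, n),
                      C.supernormalize(rng.standard_normal(n)))
        for _ in range(400)
    ])
    p = C.llr_null_pvalue(llrs, n, 3)
    assert stats.kstest(p, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# posterior estimation
# ---------------------------------------------------------------------------

def _null_llrs(rng, n, m, beta=0.0):
    out = np.empty(m)
    for i in range(m):
        E = draw_genotype(rng, n)
        y = beta * E + rng.standard_normal(n)
        out[i] = C.linkage_llr(E, C.supernormalize(y))
    return out


def test_posteriors_pure_null_small():
    rng = np.random.default_rng(2)
    null = C.NullModel(n=200, k=3)
    post = C.estimate_posteriors(_null_llrs(rng, 200, 500), null)
    assert null.pi0 > 0.85
    assert post.mean() <= 0.05


def test_posteriors_strong_mixture():
    rng = np.random.default_rng(3)
    llrs = np.concatenate([_null_llrs(rng, 200, 350),
                           _null_llrs(rng, 200, 150, beta=0.8)])
    post = C.estimate_posteriors(llrs, C.NullModel(n=200, k=3))
    assert post[350:].mean() >= 0.9
    assert post[:350].mean() < 0.2


def test_posteriors_isotone_and_minimum_ensemble():
    rng = np.random.default_rng(4)
    llrs = _null_llrs(rng, 100, 150, beta=0.3)
    post = C.estimate_posteriors(llrs, C.NullModel(n=100, k=3))
    order = np.argsort(llrs)
    assert np.all(np.diff(post[order]) >= -1e-12)
    assert np.all((post >= 0) & (post <= 1))
    with pytest.raises(ValueError, match="[Pp]ool"):
        C.estimate_posteriors(llrs[:50], C.NullModel(n=100, k=3))


def test_selection_fdr_is_honest_on_mixture():
    """1 - mean(posterior) of a top-ranked selection bounds the realized
    false-discovery proportion up to binomial error."""
    rng = np.random.default_rng(5)
    m_null, m_alt = 700, 300
    llrs = np.concatenate([_null_llrs(rng, 200, m_null),
                           _null_llrs(rng, 200, m_alt, beta=0.8)])
    post = C.estimate_posteriors(llrs, C.NullModel(n=200, k=3))
    sel = np.argsort(-post)[:m_alt]
    fdp = (sel < m_null).mean()
    est_fdr = 1 - post[sel].mean()
    se = np.sqrt(max(est_fdr * (1 - est_fdr), 1e-4) / m_alt)
    assert fdp <= est_fdr + 3 * se + 0.02


# ---------------------------------------------------------------------------
# five-test suite and composite score
# ---------------------------------------------------------------------------

def _chain_data(rng, n=300, n_genes=200, beta_cis=0.8, beta_edge=0.8,
                n_targets=20):
    """E -> A -> targets, remaining genes independent noise."""
    E = draw_genotype(rng, n)
    A = beta_cis * E + rng.standard_normal(n)
    B = rng.standard_normal((n, n_genes))
    B[:, :n_targets] += beta_edge * A[:, None]
    return E, A, B


def test_suite_recovers_planted_chain():
    rng = np.random.default_rng(6)
    E, A, B = _chain_data(rng)
    table = C.causal_posterior_table(E, A, B)
    planted = table["posterior"].to_numpy()[:20]
    nulls = table["posterior"].to_numpy()[20:]
    assert planted.mean() > np.median(nulls)
    assert planted.mean() > 0.5
    assert nulls.mean() < 0.2


def test_suite_duplicate_target_matches_primary():
    rng = np.random.default_rng(8)
    E, A, B = _chain_data(rng)
    res = C.causal_test_suite(E, A, A.copy(), ensemble=B)
    assert res["secondary"].llr == pytest.approx(res["primary"].llr, rel=1e-9)
    assert res["secondary"].posterior == pytest.approx(res["primary"].posterior)
    for tid, r in res.items():
        assert 0.0 <= r.posterior <= 1.0 and 0.0 <= r.pvalue <= 1.0
        assert r.llr >= 0.0


def test_combined_posterior_formula():
    def mk(p2, p5, p4):
        out = {}
        for tid in C.TEST_IDS:
            p = {"secondary": p2, "controlled": p5, "relevance": p4}.get(tid, 0.5)
            out[tid] = C.TestResult(tid, 1.0, 0.5, p)
        return out

    assert C.combined_causal_posterior(mk(1, 1, 1)) == 1.0
    assert C.combined_causal_posterior(mk(0.8, 0.5, 0.6)) == pytest.approx(0.5)
    assert C.combined_causal_posterior(mk(0, 0, 0)) == 0.0
    with pytest.raises(ValueError, match="missing"):
        C.combined_causal_posterior({"secondary": C.TestResult("secondary", 1, 0.5, 1)})
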