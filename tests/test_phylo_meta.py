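"""Phylogenetic meta-analysis: correlation matrices, Gibbs sampler,
heterogeneity and signal summaries, tree chaining, meta-regression."""

import dendropy
import numpy as np
import pytest
from statsmodels.stats.meta_analysis import combine_effects

from aviantrends import phylo_meta as pm


def _es(y, se, species=None, x=None):
    y = np.asarray(y, float)
    species = species or tuple(f"s{i}" for i in range(y.size))
    return pm.EffectSizeSet(tuple(species), y, np.asarray(se, float) ** 2, x=x)


# ----------------------------------------------------- correlation matrices

def test_star_tree_gives_identity():
    tree = pm.star_tree(["a", "b", "c", "d"])
    np.testing.assert_allclose(
        pm.phylo_correlation(tree, ["a", "b", "c", "d"]), np.eye(4), atol=1e-12
    )


def test_three_taxon_shared_branch_arithmetic():
    tree = dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")
    corr = pm.phylo_correlation(tree, ["A", "B", "C"])
    np.testing.assert_allclose(np.diag(corr), 1.0, atol=1e-12)
    assert corr[0, 1] == pytest.approx(0.5)
    assert corr[0, 2] == pytest.approx(0.0)


def test_correlation_invariant_to_depth_rescaling():
    t1 = dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")
    t2 = dendropy.Tree.get(data="((A:5,B:5):5,C:10);", schema="newick")
    np.testing.assert_allclose(
        pm.phylo_correlation(t1, ["A", "B", "C"]),
        pm.phylo_correlation(t2, ["A", "B", "C"]),
        atol=1e-12,
    )


def test_correlation_follows_species_order():
    tree = dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")
    c1 = pm.phylo_correlation(tree, ["A", "B", "C"])
    c2 = pm.phylo_correlation(tree, ["C", "A", "B"])
    perm = [1, 2, 0]  # position of A, B, C inside c2
    np.testing.assert_allclose(c2[np.ix_(perm, perm)], c1, atol=1e-12)


def test_missing_species_is_an_error():
    tree = pm.star_tree(["a", "b"])
    with pytest.raises(ValueError, match="missing"):
        pm.phylo_correlation(tree, ["a", "zz"])


def test_bundled_tree_matches_effect_table():
    es = pm.read_effects_table(pm.bundled_effects_path(), "wing")
    corr = pm.phylo_correlation(pm.load_tree(pm.bundled_tree_path()), es.species)
    assert corr.shape == (15, 15)
    np.testing.assert_allclose(np.diag(corr), 1.0, atol=1e-9)
    assert np.all(np.linalg.eigvalsh(corr) > 0)


# ----------------------------------------------------- sampling variance

def test_typical_sampling_variance_identities():
    assert pm.typical_sampling_variance(np.full(7, 0.3)) == pytest.approx(0.3)
    # k=2, v=(1,3): w=(1,1/3), (4/3*1)/((16/9)-(10/9)) = 2
    assert pm.typical_sampling_variance(np.array([1.0, 3.0])) == pytest.approx(2.0)


def test_typical_sampling_variance_on_published_wing_ses():
    es = pm.read_effects_table(pm.bundled_effects_path(), "wing")
    w = 1.0 / es.v
    k = es.k
    expected = w.sum() * (k - 1) / (w.sum() ** 2 - (w**2).sum())
    assert pm.typical_sampling_variance(es.v) == pytest.approx(expected)
    assert 1e-5 < expected < 1e-4


# ----------------------------------------------------- Gibbs sampler

def test_same_seed_identical_draws():
    es = _es([0.01, -0.02, 0.005, 0.0, 0.015], [0.005] * 5)
    corr = np.eye(5)
    c1, _ = pm.gibbs_meta(es, corr, n_iter=200, seed=7, record_every=1)
    c2, _ = pm.gibbs_meta(es, corr, n_iter=200, seed=7, record_every=1)
    np.testing.assert_array_equal(c1.theta, c2.theta)
    np.testing.assert_array_equal(c1.sigma2_p, c2.sigma2_p)


def test_degenerate_equal_effects_concentrate_posterior():
    es = _es([0.02] * 10, [1e-5] * 10)
    chain, _ = pm.gibbs_meta(es, np.eye(10), n_iter=3000, seed=0, record_every=3)
    assert chain.theta[:, 0].mean() == pytest.approx(0.02, abs=5e-4)
    res = pm.summarize_chain(chain, pm.typical_sampling_variance(es.v))
    assert res.estimates["intercept"]["pmcmc"] == pytest.approx(2 / chain.nsamp)


def test_posterior_mean_matches_dersimonian_laird():
    """Star tree, equal sampling variances: the random-effects mean equals
    the unweighted mean for any tau2, so the Gibbs posterior mean must
    agree with an independent DerSimonian-Laird fit."""
    rng = np.random.default_rng(5)
    k = 20
    y = -0.01 + rng.normal(0, 0.008, k)
    se = np.full(k, 0.004)
    es = _es(y, se)
    dl = combine_effects(y, se**2, method_re="dl")
    dl_mean = float(dl.summary_frame().loc["random effect", "eff"])
    chain, _ = pm.gibbs_meta(es, np.eye(k), n_iter=20_000, seed=1, record_every=10)
    draws = chain.theta[:, 0]
    mcse = draws.std() / np.sqrt(draws.size / 10)  # generous autocorr allowance
    assert draws.mean() == pytest.approx(dl_mean, abs=max(3 * mcse, 1e-4))


def test_scaling_equivariance():
    """Doubling all effects and SEs doubles the posterior of the mean."""
    rng = np.random.default_rng(2)
    y = rng.normal(0.01, 0.01, 12)
    se = np.full(12, 0.006)
    c1, _ = pm.gibbs_meta(_es(y, se), np.eye(12), n_iter=30_000, seed=3, record_every=10)
    c2, _ = pm.gibbs_meta(_es(2 * y, 2 * se), np.eye(12), n_iter=30_000, seed=4,
                          record_every=10)
    m1, m2 = c1.theta[:, 0].mean(), c2.theta[:, 0].mean()
    assert m2 == pytest.approx(2 * m1, abs=6 * c1.theta[:, 0].std() / np.sqrt(300))


def test_parameter_recovery_and_interval_calibration():
    """Simulated effect sets from mu = -0.01: posterior mean lands near the
    truth and the 95% interval covers it at least nominally (the weak
    variance priors make intervals conservative at small k)."""
    k, mu, s2s = 15, -0.01, 5e-5
    cover, err = 0, []
    n_rep = 40
    for r in range(n_rep):
        rng = np.random.default_rng(900 + r)
        true = mu + np.sqrt(s2s) * rng.standard_normal(k)
        se = rng.uniform(0.003, 0.011, k)
        es = _es(true + se * rng.standard_normal(k), se)
        sampler_rng = np.random.default_rng(5000 + r)
        _, st = pm.gibbs_meta(es, np.eye(k), n_iter=500, seed=sampler_rng)
        chain, _ = pm.gibbs_meta(es, np.eye(k), n_iter=2000, seed=sampler_rng,
                                 state=st, record_every=2)
        lo, hi = np.percentile(chain.theta[:, 0], [2.5, 97.5])
        cover += lo <= mu <= hi
        err.append(chain.theta[:, 0].mean() - mu)
    assert cover / n_rep >= 0.93
    assert abs(np.mean(err)) < 0.003


# ----------------------------------------------------- I2 and signal

def _manual_chain(s2p, s2s):
    n = len(s2p)
    return pm.MetaChain(np.zeros((n, 1)), np.asarray(s2p, float), np.asarray(s2s, float))


def test_i2_identities():
    assert pm.heterogeneity_i2(_manual_chain([0, 0], [0, 0]), 1.0).max() == 0.0
    np.testing.assert_allclose(
        pm.heterogeneity_i2(_manual_chain([0.3, 0.1], [0.7, 0.9]), 1.0), 0.5
    )


def test_signal_identities():
    assert pm.phylo_signal(_manual_chain([0.0, 0.0], [1.0, 2.0])).max() == 0.0
    np.testing.assert_allclose(pm.phylo_signal(_manual_chain([1.0, 2.0], [0.0, 0.0])), 1.0)


def test_i2_recovers_planted_heterogeneity():
    """k = 50 effects with tau2/(tau2 + sigma2_m) = 0.8 planted."""
    k = 50
    rng = np.random.default_rng(8)
    v = np.full(k, 1e-4)
    s2m = pm.typical_sampling_variance(v)  # = 1e-4
    tau2 = 4 * s2m  # I2 = 0.8
    y = np.sqrt(tau2) * rng.standard_normal(k) + np.sqrt(v) * rng.standard_normal(k)
    es = _es(y, np.sqrt(v))
    chain, _ = pm.gibbs_meta(es, np.eye(k), n_iter=8000, seed=2, record_every=4)
    i2 = pm.heterogeneity_i2(chain, s2m)
    assert np.all((i2 >= 0) & (i2 <= 1))
    assert i2.mean() == pytest.approx(0.8, abs=0.1)


def test_signal_detected_for_brownian_effects():
    """Effects simulated with all between-species variance phylogenetic on
    a deep tree must yield high posterior signal."""
    from aviantrends import synthetic_data as syn

    tree = syn.simulate_tree(50, seed=3)
    species = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    corr = pm.phylo_correlation(tree, species)
    rng = np.random.default_rng(4)
    a = np.linalg.cholesky(corr + 1e-10 * np.eye(50)) @ rng.standard_normal(50)
    y = a + 0.01 * rng.standard_normal(50)
    es = _es(y, np.full(50, 0.01), species=species)
    srng = np.random.default_rng(5)
    _, st = pm.gibbs_meta(es, corr, n_iter=4000, seed=srng)  # burn-in
    chain, _ = pm.gibbs_meta(es, corr, n_iter=8000, seed=srng, state=st,
                             record_every=4)
    assert pm.phylo_signal(chain).mean() > 0.5


# ----------------------------------------------------- tree chaining

def test_tree_set_sample_size_arithmetic():
    es = pm.read_effects_table(pm.bundled_effects_path(), "wing")
    tree = pm.load_tree(pm.bundled_tree_path())
    chain = pm.run_tree_set(es, [tree] * 13, iters_per_tree=50, burnin_trees=3, seed=0)
    assert chain.nsamp == 10
    with pytest.raises(ValueError, match="more trees"):
        pm.run_tree_set(es, [tree] * 3, burnin_trees=3)


def test_chained_trees_agree_with_single_long_chain():
    """Identical trees repeated: tree chaining must match one long chain
    within Monte-Carlo error."""
    es = pm.read_effects_table(pm.bundled_effects_path(), "wing")
    tree = pm.load_tree(pm.bundled_tree_path())
    chained = pm.run_tree_set(es, [tree] * 230, iters_per_tree=200, burnin_trees=30,
                              seed=6)
    long = pm.run_long_chain(es, tree, n_iter=46_000, burnin=6000, thin=100, seed=7)
    sd_pool = long.theta[:, 0].std()
    assert chained.theta[:, 0].mean() == pytest.approx(
        long.theta[:, 0].mean(), abs=4 * sd_pool / np.sqrt(200)
    )


# ----------------------------------------------------- meta-regression

def test_meta_regression_recovers_deterministic_relation():
    rng = np.random.default_rng(9)
    x = rng.normal(0, 1.0, 12)
    es = _es(2 * x, np.full(12, 0.01), x=x)
    res, chain = pm.meta_regression(es, [pm.star_tree(es.species)] * 60,
                                    iters_per_tree=200, burnin_trees=10, seed=1)
    assert res.estimates["slope"]["mean"] == pytest.approx(2.0, abs=0.1)
    assert res.estimates["slope"]["lo"] > 1.5


def test_meta_regression_null_covers_zero():
    rng = np.random.default_rng(10)
    cover = 0
    n_rep = 20
    for r in range(n_rep):
        y = rng.normal(0, 0.01, 15)
        x = rng.permutation(rng.normal(0, 0.01, 15))
        es = _es(y, np.full(15, 0.005), x=x)
        res, _ = pm.meta_regression(es, [pm.star_tree(es.species)] * 40,
                                    iters_per_tree=150, burnin_trees=10, seed=100 + r)
        lo, hi = res.estimates["slope"]["lo"], res.estimates["slope"]["hi"]
        cover += lo <= 0 <= hi
    assert cover >= 17


def test_meta_regression_rejects_constant_covariate():
    es = _es([0.01, 0.02, 0.03], [0.01] * 3, x=np.zeros(3))
    with pytest.raises(ValueError, match="variance"):
        pm.meta_regression(es, [pm.star_tree(es.species)] * 5, burnin_trees=1)


# ----------------------------------------------------- bounds

def test_pmcmc_and_interval_bounds():
    rng = np.random.default_rng(11)
    es = _es(rng.normal(0, 0.01, 10), np.full(10, 0.005))
    chain, _ = pm.gibbs_meta(es, np.eye(10), n_iter=2000, seed=12, record_every=2)
    res = pm.summarize_chain(chain, pm.typical_sampling_variance(es.v))
    est = res.estimates["intercept"]
    assert 0 < est["pmcmc"] <= 1
    assert est["lo"] <= est["mean"] <= est["hi"]
    assert 0 <= res.i2_mean <= 1 and 0 <= res.signal_mean <= 1
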