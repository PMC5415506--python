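"""Bayesian phylogenetic random-effects meta-analysis of temporal effects.

Per-species slopes y_i (units/year) with known sampling variances
v_i = SE_i^2 are modelled as

    y_i = x_i' theta + a_i + u_i + m_i,
    a ~ N(0, sigma2_p * A),   u_i ~ N(0, sigma2_s),   m_i ~ N(0, v_i),

where A is the Brownian-motion phylogenetic correlation matrix, a the
phylogenetic species effects, u the non-phylogenetic species effects and m
the fixed sampling errors.  x_i is 1 for the intercept-only model and
(1, covariate) for the effect-on-effect meta-regression.

Estimation is by conjugate Gibbs sampling: normal updates for the location
terms, a scaled-inverse-chi-square update for sigma2_s under a weak prior,
and a parameter-expanded update (a = alpha * eta, with a normal working
prior on alpha) for sigma2_p, which mixes far better than a plain
inverse-gamma update when the phylogenetic variance is near zero.
Phylogenetic uncertainty is handled by chaining short chains across a set
of candidate trees, warm-starting each tree's chain from the previous
tree's final state and retaining one draw per post-burn-in tree.

Summaries: posterior mean and 95% credible interval per fixed effect with
a two-sided pMCMC; heterogeneity I^2 (non-sampling variance over total,
with the typical sampling variance sigma2_m from the Nakagawa-Santos
weight formula); and the lambda-like phylogenetic signal
sigma2_p / (sigma2_p + sigma2_s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "EffectSizeSet",
    "PriorConfig",
    "MetaChain",
    "MetaResult",
    "load_tree",
    "load_tree_set",
    "star_tree",
    "phylo_correlation",
    "typical_sampling_variance",
    "gibbs_meta",
    "run_tree_set",
    "run_long_chain",
    "heterogeneity_i2",
    "phylo_signal",
    "meta_regression",
    "summarize_chain",
    "bundled_tree_path",
    "bundled_effects_path",
    "read_effects_table",
]


@dataclass(frozen=True)
class EffectSizeSet:
    """Per-species effects y with sampling variances v (= SE^2).

    ``x`` is an optional second-trait effect used as a meta-regression
    covariate (treated as fixed, its own SE not propagated).
    """

    species: tuple[str, ...]
    y: np.ndarray
    v: np.ndarray
    x: np.ndarray | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.y, float)
        v = np.asarray(self.v, float)
        if len(set(self.species)) != len(self.species):
            raise ValueError("species labels must be unique")
        if y.shape != v.shape or y.ndim != 1:
            raise ValueError("y and v must be aligned 1-d arrays")
        if np.any(v <= 0):
            raise ValueError("sampling variances must be positive")
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "v", v)
        if self.x is not None:
            x = np.asarray(self.x, float)
            if x.shape != y.shape:
                raise ValueError("x must align with y")
            object.__setattr__(self, "x", x)

    @property
    def k(self) -> int:
        return self.y.size

    def design(self) -> np.ndarray:
        ones = np.ones(self.k)
        if self.x is None:
            return ones[:, None]
        return np.column_stack([ones, self.x])

    def drop(self, species: str) -> "EffectSizeSet":
        if species not in self.species:
            raise KeyError(species)
        keep = [i for i, s in enumerate(self.species) if s != species]
        return EffectSizeSet(
            species=tuple(self.species[i] for i in keep),
            y=self.y[keep],
            v=self.v[keep],
            x=None if self.x is None else self.x[keep],
        )


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters (field-standard weakly informative defaults).

    Fixed effects: N(0, fixed_v).  sigma2_s: scaled-inverse-chi-square
    (V=resid_v, nu=resid_nu).  sigma2_p: parameter expanded, eta-variance
    scaled-inverse-chi-square (V=px_v, nu=px_nu) and working scalar
    alpha ~ N(px_alpha_mu, px_alpha_v).
    """

    fixed_v: float = 1e10
    resid_v: float = 1.0
    resid_nu: float = 0.002
    px_v: float = 1.0
    px_nu: float = 1.0
    px_alpha_mu: float = 0.0
    px_alpha_v: float = 625.0


@dataclass
class MetaChain:
    """Retained posterior draws."""

    theta: np.ndarray  # (nsamp, p)
    sigma2_p: np.ndarray
    sigma2_s: np.ndarray
    param_names: list[str] = field(default_factory=lambda: ["intercept"])

    @property
    def nsamp(self) -> int:
        return self.theta.shape[0]


@dataclass(frozen=True)
class MetaResult:
    """Posterior summaries of one meta-analytic model."""

    estimates: dict  # name -> dict(mean, lo, hi, pmcmc)
    i2_mean: float
    i2_ci: tuple[float, float]
    signal_mean: float
    signal_ci: tuple[float, float]
    sigma2_m: float
    nsamp: int

    def __str__(self) -> str:  # forest-plot-style text summary
        lines = [f"posterior sample size: {self.nsamp}"]
        for name, est in self.estimates.items():
            lines.append(
                f"  {name:<12} {est['mean']:+.5f}  "
                f"95% CI [{est['lo']:+.5f}, {est['hi']:+.5f}]  pMCMC {est['pmcmc']:.3g}"
            )
        lines.append(
            f"  I^2          {self.i2_mean:.3f}  95% CI [{self.i2_ci[0]:.3f}, {self.i2_ci[1]:.3f}]"
        )
        lines.append(
            f"  phylo signal {self.signal_mean:.3f}  "
            f"95% CI [{self.signal_ci[0]:.3f}, {self.signal_ci[1]:.3f}]"
        )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# trees


def bundled_tree_path() -> Path:
    """Path of the bundled synthetic stand-in phylogeny for the 15 species."""
    import importlib.resources

    return Path(str(importlib.resources.files("aviantrends.data")
                    / "meliphagoidea_tree_synthetic.nwk"))


def bundled_effects_path() -> Path:
    """Path of the bundled published per-species trend table."""
    import importlib.resources

    return Path(str(importlib.resources.files("aviantrends.data") / "species_trends.csv"))


def load_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def load_tree_set(path) -> list[dendropy.Tree]:
    """Read a tree set: newick, one tree per line."""
    trees = dendropy.TreeList.get(path=str(path), schema="newick",
                                  preserve_underscores=True)
    return list(trees)


def star_tree(species: Sequence[str]) -> dendropy.Tree:
    """Unit-depth star phylogeny (no shared history)."""
    newick = "(" + ",".join(f"'{s}':1.0" for s in species) + ");"
    return dendropy.Tree.get(data=newick, schema="newick")


def phylo_correlation(tree: dendropy.Tree, species: Sequence[str]) -> np.ndarray:
    """Brownian-motion correlation matrix over ``species`` (unit diagonal).

    Entry (i, j) is the root-to-MRCA path length shared by the two tips,
    scaled by the geometric mean of their root-to-tip depths, so the
    matrix is invariant to rescaling the tree's total depth.
    """
    labels = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    missing = [s for s in species if s not in labels]
    if missing:
        raise ValueError(f"species missing from tree: {missing}")
    tree.calc_node_root_distances()
    pdm = tree.phylogenetic_distance_matrix()
    k = len(species)
    depth = np.array([labels[s].root_distance for s in species])
    corr = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            dist = pdm.patristic_distance(labels[species[i]].taxon,
                                          labels[species[j]].taxon)
            shared = 0.5 * (depth[i] + depth[j] - dist)
            corr[i, j] = corr[j, i] = shared / np.sqrt(depth[i] * depth[j])
    return corr


# ---------------------------------------------------------------------------
# heterogeneity bookkeeping


def typical_sampling_variance(v: np.ndarray) -> float:
    """Typical (study-weighted) sampling variance sigma2_m.

    With weights w_i = 1/v_i and k effects:
    sigma2_m = sum(w) (k-1) / (sum(w)^2 - sum(w^2)); equals v when all
    sampling variances are identical.
    """
    v = np.asarray(v, float)
    w = 1.0 / v
    k = v.size
    return float(w.sum() * (k - 1) / (w.sum() ** 2 - (w**2).sum()))


def heterogeneity_i2(chain: MetaChain, sigma2_m: float) -> np.ndarray:
    """Per-draw I^2 = (sigma2_p + sigma2_s) / (sigma2_p + sigma2_s + sigma2_m)."""
    tau2 = chain.sigma2_p + chain.sigma2_s
    return tau2 / (tau2 + sigma2_m)


def phylo_signal(chain: MetaChain) -> np.ndarray:
    """Per-draw lambda-equivalent sigma2_p / (sigma2_p + sigma2_s)."""
    total = chain.sigma2_p + chain.sigma2_s
    out = np.zeros(chain.nsamp)
    nz = total > 0
    out[nz] = chain.sigma2_p[nz] / total[nz]
    return out


# ---------------------------------------------------------------------------
# Gibbs sampler


@dataclass
class _State:
    theta: np.ndarray
    eta: np.ndarray
    alpha: float
    sigma2_eta: float
    u: np.ndarray
    sigma2_s: float


def _scaled_inv_chi2(rng: np.random.Generator, df: float, scale: float) -> float:
    return df * scale / rng.chisquare(df)


def _init_state(es: EffectSizeSet, rng: np.random.Generator) -> _State:
    p = es.design().shape[1]
    spread = max(float(np.var(es.y)), 1e-12)
    # start with an even phylogenetic / independent variance split so the
    # chain does not have to random-walk sigma2_p up from near zero
    return _State(
        theta=np.zeros(p),
        eta=rng.normal(0, 1.0, es.k),
        alpha=np.sqrt(spread),
        sigma2_eta=1.0,
        u=rng.normal(0, np.sqrt(spread) * 0.5, es.k),
        sigma2_s=spread,
    )


def gibbs_meta(
    es: EffectSizeSet,
    corr: np.ndarray,
    prior: PriorConfig = PriorConfig(),
    n_iter: int = 1000,
    seed: int | np.random.Generator = 0,
    state: _State | None = None,
    record_every: int | None = None,
) -> tuple[MetaChain | None, _State]:
    """Run ``n_iter`` Gibbs iterations; deterministic given the seed.

    If ``record_every`` is None only the final state is returned (used by
    the tree-chaining driver); otherwise every ``record_every``-th draw is
    retained in a :class:`MetaChain`.  ``state`` warm-starts the chain.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = es.k
    a_mat = np.asarray(corr, float)
    if a_mat.shape != (k, k):
        raise ValueError("correlation matrix does not match the effect set")
    try:
        np.linalg.cholesky(a_mat + 1e-12 * np.eye(k))
    except np.linalg.LinAlgError:
        raise ValueError("phylogenetic correlation matrix is not positive definite")
    a_inv = np.linalg.inv(a_mat + 1e-12 * np.eye(k))

    x = es.design()
    p = x.shape[1]
    y, v = es.y, es.v
    vinv = 1.0 / v
    xtvx = (x * vinv[:, None]).T @ x

    st = state if state is not None else _init_state(es, rng)
    if st.theta.size != p:
        raise ValueError("warm-start state does not match the design")

    n_rec = 0 if record_every is None else n_iter // record_every
    rec_theta = np.empty((n_rec, p))
    rec_s2p = np.empty(n_rec)
    rec_s2s = np.empty(n_rec)
    idx = 0

    eye_k = np.eye(k)
    for it in range(n_iter):
        a = st.alpha * st.eta
        # fixed effects
        r = y - a - st.u
        prec = xtvx + eye_k[:p, :p] / prior.fixed_v
        mean = np.linalg.solve(prec, x.T @ (r * vinv))
        chol = np.linalg.cholesky(np.linalg.inv(prec))
        st.theta = mean + chol @ rng.standard_normal(p)
        mu_vec = x @ st.theta
        # parameter-expanded phylogenetic effects, with the independent
        # species effects u integrated out (partially collapsed update:
        # u + m ~ N(0, sigma2_s + v); breaks the a/u single-site deadlock)
        r = y - mu_vec
        dinv = 1.0 / (st.sigma2_s + v)
        prec_eta = a_inv / st.sigma2_eta + (st.alpha**2) * np.diag(dinv)
        chol_prec = np.linalg.cholesky(prec_eta)
        mean_eta = np.linalg.solve(prec_eta, st.alpha * (r * dinv))
        z = rng.standard_normal(k)
        st.eta = mean_eta + np.linalg.solve(chol_prec.T, z)
        prec_a = float(st.eta @ (st.eta * dinv)) + 1.0 / prior.px_alpha_v
        mean_a = (float(st.eta @ (r * dinv)) + prior.px_alpha_mu / prior.px_alpha_v) / prec_a
        st.alpha = mean_a + rng.standard_normal() / np.sqrt(prec_a)
        # non-phylogenetic species effects, redrawn given the new a
        a = st.alpha * st.eta
        r = y - mu_vec - a
        prec_u = 1.0 / st.sigma2_s + vinv
        mean_u = (r * vinv) / prec_u
        st.u = mean_u + rng.standard_normal(k) / np.sqrt(prec_u)
        quad = float(st.eta @ a_inv @ st.eta)
        st.sigma2_eta = _scaled_inv_chi2(
            rng, prior.px_nu + k, (prior.px_nu * prior.px_v + quad) / (prior.px_nu + k)
        )
        # non-phylogenetic variance
        st.sigma2_s = _scaled_inv_chi2(
            rng,
            prior.resid_nu + k,
            (prior.resid_nu * prior.resid_v + float(st.u @ st.u)) / (prior.resid_nu + k),
        )
        if record_every is not None and (it + 1) % record_every == 0:
            rec_theta[idx] = st.theta
            rec_s2p[idx] = st.alpha**2 * st.sigma2_eta
            rec_s2s[idx] = st.sigma2_s
            idx += 1

    names = ["intercept"] if p == 1 else ["intercept", "slope"]
    chain = (
        MetaChain(rec_theta[:idx], rec_s2p[:idx], rec_s2s[:idx], names)
        if record_every is not None
        else None
    )
    return chain, st


def run_tree_set(
    es: EffectSizeSet,
    trees: Sequence[dendropy.Tree],
    iters_per_tree: int = 1000,
    burnin_trees: int = 300,
    prior: PriorConfig = PriorConfig(),
    seed: int = 0,
) -> MetaChain:
    """Chain short MCMC runs across candidate phylogenies.

    Each tree's chain warm-starts from the previous tree's final state and
    contributes its last draw; draws from the first ``burnin_trees`` trees
    are discarded, giving a posterior sample of
    ``len(trees) - burnin_trees``.
    """
    n_trees = len(trees)
    if n_trees <= burnin_trees:
        raise ValueError("need more trees than burn-in trees")
    rng = np.random.default_rng(seed)
    p = es.design().shape[1]
    rec_theta = np.empty((n_trees - burnin_trees, p))
    rec_s2p = np.empty(n_trees - burnin_trees)
    rec_s2s = np.empty(n_trees - burnin_trees)

    state: _State | None = None
    corr_cache: dict[int, np.ndarray] = {}
    idx = 0
    for t_i, tree in enumerate(trees):
        key = id(tree)
        if key not in corr_cache:
            corr_cache[key] = phylo_correlation(tree, es.species)
        _, state = gibbs_meta(
            es, corr_cache[key], prior=prior, n_iter=iters_per_tree, seed=rng, state=state
        )
        if t_i >= burnin_trees:
            rec_theta[idx] = state.theta
            rec_s2p[idx] = state.alpha**2 * state.sigma2_eta
            rec_s2s[idx] = state.sigma2_s
            idx += 1
    names = ["intercept"] if p == 1 else ["intercept", "slope"]
    return MetaChain(rec_theta, rec_s2p, rec_s2s, names)


def run_long_chain(
    es: EffectSizeSet,
    tree: dendropy.Tree,
    n_iter: int = 110_000,
    burnin: int = 10_000,
    thin: int = 100,
    prior: PriorConfig = PriorConfig(),
    seed: int = 0,
) -> MetaChain:
    """Single long chain on one tree (convergence-diagnostic mode)."""
    corr = phylo_correlation(tree, es.species)
    rng = np.random.default_rng(seed)
    _, state = gibbs_meta(es, corr, prior=prior, n_iter=burnin, seed=rng)
    chain, _ = gibbs_meta(
        es, corr, prior=prior, n_iter=n_iter - burnin, seed=rng,
        state=state, record_every=thin,
    )
    return chain


# ---------------------------------------------------------------------------
# summaries and high-level wrappers


def _pmcmc(draws: np.ndarray) -> float:
    pos = float(np.mean(draws > 0))
    neg = float(np.mean(draws < 0))
    p = 2 * min(pos, neg)
    floor = 2.0 / draws.size
    return max(min(p, 1.0), floor)


def summarize_chain(chain: MetaChain, sigma2_m: float) -> MetaResult:
    estimates = {}
    for j, name in enumerate(chain.param_names):
        draws = chain.theta[:, j]
        lo, hi = np.percentile(draws, [2.5, 97.5])
        estimates[name] = {
            "mean": float(draws.mean()),
            "lo": float(lo),
            "hi": float(hi),
            "pmcmc": _pmcmc(draws),
        }
    i2 = heterogeneity_i2(chain, sigma2_m)
    sig = phylo_signal(chain)
    return MetaResult(
        estimates=estimates,
        i2_mean=float(i2.mean()),
        i2_ci=tuple(np.percentile(i2, [2.5, 97.5])),
        signal_mean=float(sig.mean()),
        signal_ci=tuple(np.percentile(sig, [2.5, 97.5])),
        sigma2_m=sigma2_m,
        nsamp=chain.nsamp,
    )


def meta_regression(
    es: EffectSizeSet,
    trees: Sequence[dendropy.Tree],
    iters_per_tree: int = 1000,
    burnin_trees: int = 300,
    prior: PriorConfig = PriorConfig(),
    seed: int = 0,
) -> tuple[MetaResult, MetaChain]:
    """Effect-on-effect meta-regression (slope of y on the covariate x)."""
    if es.x is None:
        raise ValueError("effect set has no covariate for meta-regression")
    if float(np.var(es.x)) == 0:
        raise ValueError("zero variance in the meta-regression covariate")
    chain = run_tree_set(es, trees, iters_per_tree, burnin_trees, prior, seed)
    return summarize_chain(chain, typical_sampling_variance(es.v)), chain


def read_effects_table(
    path, trait: str = "wing", covariate_trait: str | None = None
) -> EffectSizeSet:
    """Read a per-species trend table (layout: species, <trait>_beta, <trait>_se).

    ``trait`` picks the response columns (``wing`` or ``colour``);
    ``covariate_trait`` optionally attaches a second trait's beta column as
    the meta-regression covariate.
    """
    tab = pd.read_csv(path)
    species = tuple(tab["species"])
    y = tab[f"{trait}_beta"].to_numpy(float)
    v = tab[f"{trait}_se"].to_numpy(float) ** 2
    x = None
    if covariate_trait is not None:
        x = tab[f"{covariate_trait}_beta"].to_numpy(float)
    return EffectSizeSet(species=species, y=y, v=v, x=x)
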