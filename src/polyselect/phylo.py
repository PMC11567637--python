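"""Cumulative-link (ordinal threshold) models with a phylogenetic random effect.

The observed ordinal score y_i in {0..K-1} is generated by a latent
liability crossed with ordered cutpoints tau_1 < ... < tau_{K-1}:

    l_i = x_i' beta + a_i + e_i,      y_i = k  iff  tau_k < l_i <= tau_{k+1}

with a ~ MVN(0, sigma2_phylo * C) for a phylogenetic covariance matrix C
(shared root-to-MRCA branch lengths, scaled to unit height) and e_i iid
standard normal (probit link).  The posterior is sampled by a
Metropolis-within-Gibbs scheme: conjugate draws for the latent liabilities,
beta and the rotated phylogenetic effects, a Cowles-type joint
Metropolis-Hastings step for the cutpoints (which mixes far better than
one-at-a-time uniform draws at realistic n), and a random-walk step on
log sigma2_phylo under a half-normal prior on sigma_phylo.

Model uncertainty in the tree is handled by refitting over a sample of
trees and concatenating the posterior draws with equal weight per tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri

logger = logging.getLogger(__name__)

__all__ = [
    "PhyloCovariance",
    "PosteriorDraws",
    "PooledPosterior",
    "vcv_from_tree",
    "standardize_predictors",
    "vif",
    "fit_cumulative_phylo",
    "fit_cumulative",
    "pool_draws",
    "marginal_r2",
    "sample_trees",
]

_BETA_PRIOR_SD = 2.5
_TAU_PRIOR_SD = 5.0
_EIG_TOL = 1e-10


@dataclass
class PhyloCovariance:
    """Species-by-species Brownian covariance from a rooted tree."""

    labels: List[str]
    C: np.ndarray = field(repr=False)

    def reorder(self, labels: Sequence[str]) -> "PhyloCovariance":
        idx = [self.labels.index(l) for l in labels]
        return PhyloCovariance(list(labels), self.C[np.ix_(idx, idx)])


def vcv_from_tree(tree, scale_to_unit_height: bool = True) -> PhyloCovariance:
    """Shared-path covariance: C[i,j] = root-to-MRCA distance of tips i, j.

    The diagonal holds root-to-tip distances; for an ultrametric tree it is
    constant.  With ``scale_to_unit_height`` the matrix is divided by the
    maximum root-to-tip distance so sigma2_phylo is comparable across trees
    of different depth.
    """
    seed = tree.seed_node
    if tree.is_rooted is False and len(seed.child_nodes()) != 2:
        raise ValueError("tree must be rooted")
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels in tree")
    if any(l is None for l in labels):
        raise ValueError("all tips must be named")
    tip_index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)

    # node depths from the root (root edge ignored)
    depth: Dict[int, float] = {id(seed): 0.0}
    for node in tree.preorder_node_iter():
        if node is seed:
            continue
        el = node.edge.length or 0.0
        if el < 0:
            raise ValueError("negative branch length")
        depth[id(node)] = depth[id(node.parent_node)] + el

    C = np.zeros((n, n))
    tipsets: Dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = tip_index[id(node)]
            C[i, i] = depth[id(node)]
            tipsets[id(node)] = np.array([i])
            continue
        child_sets = [tipsets.pop(id(ch)) for ch in node.child_nodes()]
        d = depth[id(node)]
        for ai in range(len(child_sets)):
            for bi in range(ai + 1, len(child_sets)):
                A, B = child_sets[ai], child_sets[bi]
                C[np.ix_(A, B)] = d
                C[np.ix_(B, A)] = d
        tipsets[id(node)] = np.concatenate(child_sets)
    if scale_to_unit_height:
        h = C.diagonal().max()
        if h > 0:
            C = C / h
    return PhyloCovariance(labels, C)


# ---------------------------------------------------------------------------
# design matrix

def standardize_predictors(
    traits: pd.DataFrame,
    binary_cols: Sequence[str] = ("trophic", "migration", "territoriality"),
    seasonality_col: str = "seasonality",
    interactions: Sequence[Tuple[str, str]] = (
        ("trophic", "territoriality"),
        ("trophic", "seasonality"),
    ),
) -> Tuple[pd.DataFrame, Dict[str, Dict[str, float]]]:
    """Design matrix with the study's scaling conventions.

    Seasonality is log-transformed and standardized to 2 standard
    deviations (Gelman scaling, so a one-unit change is comparable to a
    binary contrast); binary predictors (0/1) are centered on their means;
    interaction columns are products of the transformed main effects.
    Returns the design frame and a scaling record for back-transformation.
    """
    X = pd.DataFrame(index=traits.index)
    scaling: Dict[str, Dict[str, float]] = {}
    for col in binary_cols:
        v = traits[col].to_numpy(float)
        if np.var(v) == 0:
            raise ValueError(f"zero-variance column: {col}")
        mean = float(v.mean())
        X[col] = v - mean
        scaling[col] = {"center": mean}
    s = traits[seasonality_col].to_numpy(float)
    if np.any(s <= 0):
        raise ValueError("seasonality must be strictly positive for the log transform")
    ls = np.log(s)
    mean, sd = float(ls.mean()), float(ls.std(ddof=1))
    if sd == 0:
        raise ValueError(f"zero-variance column: {seasonality_col}")
    X[seasonality_col] = (ls - mean) / (2.0 * sd)
    scaling[seasonality_col] = {"log": True, "center": mean, "scale": 2.0 * sd}
    for a, b in interactions:
        X[f"{a}:{b}"] = X[a] * X[b]
    return X, scaling


def vif(X) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R2_j).

    R2_j comes from regressing column j on the remaining columns plus an
    intercept.  Perfectly collinear columns report ``inf``.
    """
    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 columns")
    out = {}
    for col in X.columns:
        yj = X[col].to_numpy(float)
        others = X.drop(columns=[col]).to_numpy(float)
        A = np.column_stack([np.ones(len(yj)), others])
        coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot == 0:
            raise ValueError(f"zero-variance column: {col}")
        r2 = 1.0 - ss_res / ss_tot
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


# ---------------------------------------------------------------------------
# samplers

@dataclass
class PosteriorDraws:
    """MCMC draws from one ordinal model fit: shape (chains, draws, params)."""

    draws: np.ndarray = field(repr=False)
    param_names: List[str]
    link: str
    tree_id: Optional[str] = None
    rhat: Optional[Dict[str, float]] = None
    ess: Optional[Dict[str, float]] = None

    @property
    def n_beta(self) -> int:
        return sum(1 for p in self.param_names if p.startswith("beta:"))

    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.flat(), columns=self.param_names)


@dataclass
class PooledPosterior:
    """Equal-weight concatenation of per-tree posterior draws."""

    draws: np.ndarray = field(repr=False)
    param_names: List[str]
    n_fits: int

    def summary(self) -> pd.DataFrame:
        d = self.draws
        q = np.quantile(d, [0.17, 0.83, 0.025, 0.975], axis=0)
        p_pos = (d > 0).mean(axis=0)
        p_two = 2.0 * np.minimum(p_pos, 1.0 - p_pos)
        return pd.DataFrame(
            {
                "mean": d.mean(axis=0),
                "sd": d.std(axis=0, ddof=1),
                "ci66_lo": q[0],
                "ci66_hi": q[1],
                "ci95_lo": q[2],
                "ci95_hi": q[3],
                "p_two_sided": p_two,
            },
            index=self.param_names,
        )


def _check_inputs(y, X):
    y = np.asarray(y, dtype=int)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        raise ValueError("y and X misaligned")
    if y.min() < 0:
        raise ValueError("ordinal responses must be coded 0..K-1")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate response: all observations in one category")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant column in X: cutpoints absorb the intercept")
    return y, X


def _init_tau(y, K):
    props = np.clip(np.bincount(y, minlength=K) / len(y), 1e-3, None)
    cum = np.cumsum(props)[:-1] / props.sum()
    return ndtri(np.clip(cum, 1e-4, 1 - 1e-4))


def _tau_step(tau, y, mu, cdf, step, rng):
    """Cowles joint MH update of the cutpoints given the latent mean."""
    K1 = len(tau)
    ext = np.concatenate([[-np.inf], tau, [np.inf]])
    new = np.empty(K1)
    # sequential truncated-normal proposal: tau'_k in (tau'_{k-1}, tau_{k+1})
    log_q_fwd = 0.0
    log_q_rev = 0.0
    for k in range(K1):
        lo = new[k - 1] if k > 0 else -np.inf
        hi = ext[k + 2]
        a = ndtr((lo - tau[k]) / step) if np.isfinite(lo) else 0.0
        b = ndtr((hi - tau[k]) / step) if np.isfinite(hi) else 1.0
        u = rng.uniform(a + 1e-12, b - 1e-12)
        new[k] = tau[k] + step * ndtri(u)
        log_q_fwd -= np.log(max(b - a, 1e-300))
    next_ext = np.concatenate([[-np.inf], new, [np.inf]])
    for k in range(K1):
        lo = tau[k - 1] if k > 0 else -np.inf
        hi = next_ext[k + 2]
        a = ndtr((lo - new[k]) / step) if np.isfinite(lo) else 0.0
        b = ndtr((hi - new[k]) / step) if np.isfinite(hi) else 1.0
        log_q_rev -= np.log(max(b - a, 1e-300))
    lo_old = ext[y] - mu
    hi_old = ext[y + 1] - mu
    lo_new = next_ext[y] - mu
    hi_new = next_ext[y + 1] - mu
    p_old = np.clip(cdf(hi_old) - cdf(lo_old), 1e-300, None)
    p_new = np.clip(cdf(hi_new) - cdf(lo_new), 1e-300, None)
    log_lik = float(np.log(p_new).sum() - np.log(p_old).sum())
    log_prior = float(-(new**2).sum() / (2 * _TAU_PRIOR_SD**2)
                      + (tau**2).sum() / (2 * _TAU_PRIOR_SD**2))
    log_acc = log_lik + log_prior + log_q_rev - log_q_fwd
    if np.log(rng.uniform()) < log_acc:
        return new, True
    return tau, False


def _gibbs_probit_chain(y, X, eigvecs, eigvals, K, warmup, draws, rng,
                        sigma2_init=0.5, sigma2_fixed=None):
    """One chain of the probit latent-liability sampler.

    ``eigvecs``/``eigvals`` are the eigendecomposition of C (None for the
    non-phylogenetic model).
    """
    n, p = X.shape
    has_phylo = eigvecs is not None
    emit_sigma = has_phylo
    prior_prec = np.eye(p) / _BETA_PRIOR_SD**2
    V = np.linalg.inv(X.T @ X + prior_prec)
    V_chol = np.linalg.cholesky(V)

    tau = _init_tau(y, K)
    beta = np.zeros(p)
    a = np.zeros(n)
    at = np.zeros(n)
    ones_rot = eigvecs.T @ np.ones(n) if has_phylo else None
    sigma2 = sigma2_init if has_phylo else 0.0
    if sigma2_fixed is not None:
        sigma2 = float(sigma2_fixed)
        if sigma2 == 0.0:
            has_phylo = False  # random effect degenerates to zero
    tau_step_size = 0.05 + 0.2 / np.sqrt(n)
    sig_step = 0.4
    shift_step = 0.5
    tau_acc = sig_acc = shift_acc = tau_try = sig_try = shift_try = 0

    n_par = p + K - 1 + (1 if emit_sigma else 0)
    out = np.empty((draws, n_par))
    ext = lambda t: np.concatenate([[-np.inf], t, [np.inf]])

    for it in range(warmup + draws):
        mu = X @ beta + a
        # cutpoints (Cowles MH)
        tau, accepted = _tau_step(tau, y, mu, ndtr, tau_step_size, rng)
        tau_try += 1
        tau_acc += accepted
        if it < warmup and it > 0 and it % 50 == 0:
            rate = tau_acc / tau_try
            tau_step_size *= np.exp(0.6 * (rate - 0.3))
            tau_acc = tau_try = 0
        # latent liabilities (truncated normal, inverse-CDF)
        te = ext(tau)
        lo = ndtr(te[y] - mu)
        hi = ndtr(te[y + 1] - mu)
        u = lo + rng.uniform(size=n) * np.maximum(hi - lo, 1e-14)
        l = mu + ndtri(np.clip(u, 1e-14, 1 - 1e-14))
        # beta (conjugate normal)
        m = V @ (X.T @ (l - a))
        beta = m + V_chol @ rng.standard_normal(p)
        if has_phylo:
            # phylogenetic effects in the eigenbasis of C
            r = eigvecs.T @ (l - X @ beta)
            d = eigvals
            post_var = np.where(d > _EIG_TOL, 1.0 / (1.0 + 1.0 / (sigma2 * np.maximum(d, _EIG_TOL))), 0.0)
            at = post_var * r + np.sqrt(post_var) * rng.standard_normal(n)
            a = eigvecs @ at
            if sigma2_fixed is None:
                # sigma2 (random-walk MH on log scale, half-normal prior on sigma)
                mask = d > _EIG_TOL

                def logpost(ls2):
                    s2 = np.exp(ls2)
                    ll = -0.5 * np.sum(np.log(s2 * d[mask])) - 0.5 * np.sum(
                        at[mask] ** 2 / (s2 * d[mask])
                    )
                    lp = -s2 / 2.0 + 0.5 * ls2  # half-normal on sigma + Jacobian
                    return ll + lp

                ls2 = np.log(sigma2)
                prop = ls2 + sig_step * rng.standard_normal()
                sig_try += 1
                if np.log(rng.uniform()) < logpost(prop) - logpost(ls2):
                    sigma2 = float(np.exp(prop))
                    sig_acc += 1
                if it < warmup and it > 0 and it % 50 == 0:
                    rate = sig_acc / max(sig_try, 1)
                    sig_step *= np.exp(0.6 * (rate - 0.44))
                    sig_acc = sig_try = 0
                # ASIS interweaving on the scale: re-draw the signed scale s of
                # the non-centered effect u = a/sigma (exact; s ~ N(0,1) prior
                # is the half-normal prior on sigma)
                sigma = np.sqrt(sigma2)
                if sigma > 1e-8:
                    u_nc = a / sigma
                    resid = l - X @ beta
                    prec = float(u_nc @ u_nc) + 1.0
                    mean_s = float(u_nc @ resid) / prec
                    s = mean_s + rng.standard_normal() / np.sqrt(prec)
                    sigma2 = max(s * s, 1e-12)
                    a = s * u_nc
                    at = at * (s / sigma)
            # joint location shift of (l, tau, a): kills the ridge between
            # the cutpoints and the weakly-identified mean of a
            delta = shift_step * rng.standard_normal()
            shift_try += 1
            at_new = at + delta * ones_rot
            ok = d > _EIG_TOL
            lp_new = -0.5 * np.sum(at_new[ok] ** 2 / (sigma2 * d[ok]))
            lp_old = -0.5 * np.sum(at[ok] ** 2 / (sigma2 * d[ok]))
            lp_tau = (-np.sum((tau + delta) ** 2) + np.sum(tau**2)) / (2 * _TAU_PRIOR_SD**2)
            if np.all(np.abs(at_new[~ok]) < 1e-9) and np.log(rng.uniform()) < (
                lp_new - lp_old + lp_tau
            ):
                at = at_new
                a = a + delta
                l = l + delta
                tau = tau + delta
                shift_acc += 1
            if it < warmup and it > 0 and it % 50 == 0:
                rate = shift_acc / max(shift_try, 1)
                shift_step *= np.exp(0.6 * (rate - 0.44))
                shift_acc = shift_try = 0
        if it >= warmup:
            row = np.concatenate([beta, tau, [sigma2] if emit_sigma else []])
            out[it - warmup] = row
    return out


def _mh_ordinal_chain(y, X, K, link, warmup, draws, rng):
    """Random-walk MH on (beta, tau) under the marginal ordinal likelihood.

    Used for the logit link, where the latent augmentation is not
    conjugate.  Componentwise Gaussian proposals with warmup adaptation.
    """
    cdf = expit if link == "logit" else ndtr
    n, p = X.shape
    tau = _init_tau(y, K)
    if link == "logit":
        tau = tau * np.pi / np.sqrt(3.0)
    beta = np.zeros(p)

    def loglik(beta_, tau_):
        ext = np.concatenate([[-np.inf], tau_, [np.inf]])
        mu = X @ beta_
        pr = np.clip(cdf(ext[y + 1] - mu) - cdf(ext[y] - mu), 1e-300, None)
        return float(np.log(pr).sum()) - float((beta_**2).sum()) / (2 * _BETA_PRIOR_SD**2) \
            - float((tau_**2).sum()) / (2 * _TAU_PRIOR_SD**2)

    cur = loglik(beta, tau)
    steps = np.full(p + K - 1, 0.2)
    acc = np.zeros(p + K - 1)
    tries = np.zeros(p + K - 1)
    out = np.empty((draws, p + K - 1))
    for it in range(warmup + draws):
        for j in range(p + K - 1):
            b_new, t_new = beta.copy(), tau.copy()
            if j < p:
                b_new[j] += steps[j] * rng.standard_normal()
            else:
                t_new[j - p] += steps[j] * rng.standard_normal()
                if np.any(np.diff(t_new) <= 0):
                    tries[j] += 1
                    continue
            cand = loglik(b_new, t_new)
            tries[j] += 1
            if np.log(rng.uniform()) < cand - cur:
                beta, tau, cur = b_new, t_new, cand
                acc[j] += 1
        if it < warmup and it > 0 and it % 50 == 0:
            rate = acc / np.maximum(tries, 1)
            steps *= np.exp(0.8 * (rate - 0.35))
            acc[:] = 0
            tries[:] = 0
        if it >= warmup:
            out[it - warmup] = np.concatenate([beta, tau])
    return out


def _diagnostics(draws3: np.ndarray, names: List[str]):
    """Split-Rhat and bulk ESS via arviz."""
    import arviz as az

    ds = az.convert_to_dataset({n: draws3[:, :, i] for i, n in enumerate(names)})
    rhat = {n: float(az.rhat(ds)[n].values) for n in names}
    ess = {n: float(az.ess(ds)[n].values) for n in names}
    return rhat, ess


def _run_fit(y, X, C, link, chains, iterations, warmup, seed, names, tree_id,
             x_names, sigma2_fixed=None):
    y, X = _check_inputs(y, X)
    K = int(y.max()) + 1
    if C is not None:
        if link != "probit":
            raise NotImplementedError(
                "the phylogenetic cumulative model is probit-only: the latent-normal "
                "liability composes with the Gaussian phylogenetic effect; use "
                "fit_cumulative for a logit fit without the random effect"
            )
        Cm = np.asarray(C, dtype=float)
        if Cm.shape != (len(y), len(y)):
            raise ValueError("C misaligned with y")
        eigvals, eigvecs = np.linalg.eigh(Cm)
        if eigvals.min() < -1e-8 * max(eigvals.max(), 1.0):
            raise ValueError(
                "C is not positive semi-definite; consider adding a small "
                "diagonal jitter (e.g. 1e-8)"
            )
        eigvals = np.clip(eigvals, 0.0, None)
    else:
        eigvals = eigvecs = None

    warmup = iterations if warmup is None else warmup
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(chains)
    all_draws = []
    for cs in chain_seeds:
        rng = np.random.default_rng(cs)
        if link == "probit":
            d = _gibbs_probit_chain(y, X, eigvecs, eigvals, K, warmup, iterations, rng,
                                    sigma2_fixed=sigma2_fixed)
        else:
            d = _mh_ordinal_chain(y, X, K, link, warmup, iterations, rng)
        all_draws.append(d)
    draws3 = np.stack(all_draws)
    rhat = ess = None
    if chains >= 2:
        try:
            rhat, ess = _diagnostics(draws3, names)
            bad = [n for n, v in rhat.items() if v > 1.1]
            if bad:
                logger.warning("convergence warning: Rhat > 1.1 for %s", bad)
        except Exception as exc:  # diagnostics must never kill a fit
            logger.warning("diagnostics failed: %s", exc)
    return PosteriorDraws(draws3, names, link=link, tree_id=tree_id,
                          rhat=rhat, ess=ess)


def fit_cumulative_phylo(
    y,
    X,
    C,
    link: str = "probit",
    chains: int = 4,
    iterations: int = 2500,
    warmup: Optional[int] = None,
    seed: Optional[int] = None,
    tree_id: Optional[str] = None,
    x_names: Optional[Sequence[str]] = None,
    sigma2_fixed: Optional[float] = None,
) -> PosteriorDraws:
    """Posterior draws for the phylogenetic cumulative probit model.

    ``C`` is the species covariance aligned to the rows of ``y``/``X``
    (pass ``PhyloCovariance.C`` after reordering to the data's species
    order).  Priors: beta ~ N(0, 2.5^2), sigma_phylo ~ half-normal(0, 1),
    cutpoints ordered with N(0, 5^2) margins.
    """
    y_arr = np.asarray(y, dtype=int)
    K = int(y_arr.max()) + 1
    p = np.atleast_2d(np.asarray(X)).shape[1]
    xn = list(x_names) if x_names is not None else (
        list(X.columns) if hasattr(X, "columns") else [f"x{j}" for j in range(p)]
    )
    names = [f"beta:{n}" for n in xn] + [f"tau:{k+1}" for k in range(K - 1)] + ["sigma2_phylo"]
    return _run_fit(y, np.asarray(X, dtype=float), C, link, chains, iterations,
                    warmup, seed, names, tree_id, xn, sigma2_fixed=sigma2_fixed)


def fit_cumulative(
    y,
    X,
    link: str = "probit",
    chains: int = 4,
    iterations: int = 2500,
    warmup: Optional[int] = None,
    seed: Optional[int] = None,
    x_names: Optional[Sequence[str]] = None,
) -> PosteriorDraws:
    """Cumulative-link fit without the phylogenetic random effect."""
    y_arr = np.asarray(y, dtype=int)
    K = int(y_arr.max()) + 1
    p = np.atleast_2d(np.asarray(X)).shape[1]
    xn = list(x_names) if x_names is not None else (
        list(X.columns) if hasattr(X, "columns") else [f"x{j}" for j in range(p)]
    )
    names = [f"beta:{n}" for n in xn] + [f"tau:{k+1}" for k in range(K - 1)]
    return _run_fit(y, np.asarray(X, dtype=float), None, link, chains, iterations,
                    warmup, seed, names, None, xn)


def pool_draws(fits: Sequence[PosteriorDraws]) -> PooledPosterior:
    """Concatenate per-tree posteriors with equal weight per tree."""
    if not fits:
        raise ValueError("no fits to pool")
    names = fits[0].param_names
    for f in fits[1:]:
        if f.param_names != names:
            raise ValueError("parameter sets differ across fits")
    draws = np.concatenate([f.flat() for f in fits], axis=0)
    return PooledPosterior(draws=draws, param_names=names, n_fits=len(fits))


def marginal_r2(fit, X, link: Optional[str] = None) -> Dict[str, float]:
    """Fixed-effects (marginal) R2 on the latent scale, per posterior draw.

    R2 = var(X beta) / (var(X beta) + sigma2_phylo + sigma2_link), with
    sigma2_link = 1 for probit and pi^2/3 for logit.  Returns the posterior
    mean, 95% interval, and the per-draw values.
    """
    if isinstance(fit, PosteriorDraws):
        draws = fit.flat()
        names = fit.param_names
        link = link or fit.link
    else:
        draws = fit.draws
        names = fit.param_names
        link = link or "probit"
    X = np.asarray(X, dtype=float)
    bidx = [i for i, n in enumerate(names) if n.startswith("beta:")]
    sidx = names.index("sigma2_phylo") if "sigma2_phylo" in names else None
    sigma2_link = 1.0 if link == "probit" else np.pi**2 / 3.0
    eta = X @ draws[:, bidx].T  # (n, ndraws)
    var_fixed = eta.var(axis=0, ddof=0)
    sigma2_phylo = draws[:, sidx] if sidx is not None else 0.0
    r2 = var_fixed / (var_fixed + sigma2_phylo + sigma2_link)
    return {
        "mean": float(r2.mean()),
        "ci95_lo": float(np.quantile(r2, 0.025)),
        "ci95_hi": float(np.quantile(r2, 0.975)),
        "draws": r2,
    }


def sample_trees(tree_set: Sequence, k: int = 50, seed: Optional[int] = None) -> list:
    """Sample ``k`` trees, without replacement when possible.

    If ``k`` exceeds the number of available trees the sample is drawn with
    replacement and a warning is logged.
    """
    trees = list(tree_set)
    if not trees:
        raise ValueError("empty tree set")
    rng = np.random.default_rng(seed)
    if k <= len(trees):
        idx = rng.permutation(len(trees))[:k]
    else:
        logger.warning("k=%d exceeds %d available trees; sampling with replacement",
                       k, len(trees))
        idx = rng.integers(0, len(trees), size=k)
    return [trees[i] for i in idx]
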