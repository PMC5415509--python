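"""Continuous-trait machinery: Brownian-motion covariance, Pagel's lambda,
Blomberg's K, and maximum-likelihood ancestral states.

Model.  A trait y over the tips of a rooted, branch-length-bearing tree is
modelled as multivariate normal with mean mu * 1 and covariance
sigma^2 * C(lambda), where C is the Brownian-motion covariance (C[i, j] =
shared root-to-MRCA path length of tips i and j) and C(lambda) scales the
off-diagonal entries by lambda in [0, 1].  lambda = 1 recovers Brownian
motion, lambda = 0 an independent-tips model with tip-depth variances.
mu and sigma^2 are profiled analytically; lambda is estimated by bounded
one-dimensional optimisation of the profile log-likelihood.

Blomberg's K compares the observed ratio of phylogenetically uncorrected
to corrected mean squared error against its analytic Brownian expectation;
K has expectation 1 under Brownian motion, values below 1 indicate less
resemblance among relatives than Brownian motion predicts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import minimize_scalar

from .tree import Phylogeny, TreeValidationError

__all__ = [
    "vcv",
    "lambda_transform",
    "SignalEstimate",
    "PagelLambda",
    "estimate_lambda",
    "blomberg_k",
    "ancestral_continuous",
]

TraitLike = Union[Mapping[str, float], "pd.Series"]


def _trait_vector(trait: TraitLike, labels: Sequence[str]) -> np.ndarray:
    missing = [t for t in labels if t not in trait]
    if missing:
        raise ValueError(f"trait values missing for tips {missing}")
    y = np.asarray([float(trait[t]) for t in labels])
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite trait values")
    return y


def vcv(tree: Phylogeny) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance over tips plus the tip-label order.

    C[i, j] is the root-to-MRCA shared path length; the diagonal holds
    root-to-tip depths.  Requires branch lengths on every non-root branch.
    """
    depths = tree.depths()     # raises naming the branch if a length is absent
    labels = tree.tip_labels
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    # tips below each node, assembled postorder; pairs first meeting at a
    # node share that node's depth
    below: dict[int, list[int]] = {}
    for nd in tree.postorder():
        if nd.is_leaf:
            below[nd.id] = [idx[nd.label]]
            C[idx[nd.label], idx[nd.label]] = depths[nd.id]
        else:
            groups = [below[c.id] for c in nd.children]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        for j in groups[b]:
                            C[i, j] = C[j, i] = depths[nd.id]
            below[nd.id] = [i for g in groups for i in g]
    return C, labels


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Scale off-diagonal covariance by lambda; diagonal unchanged."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    out = C * lam
    np.fill_diagonal(out, np.diag(C))
    return out


def _profile_loglik(y: np.ndarray, C: np.ndarray, lam: float
                    ) -> tuple[float, float, float]:
    """Profile log-likelihood at lambda; returns (ll, mu_hat, sigma2_hat)."""
    V = lambda_transform(C, lam)
    n = len(y)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        raise ValueError("singular phylogenetic covariance matrix") from None
    ones = np.ones(n)
    wy = solve_triangular(L, y, lower=True)
    w1 = solve_triangular(L, ones, lower=True)
    mu = float(w1 @ wy) / float(w1 @ w1)
    resid = wy - mu * w1
    sigma2 = float(resid @ resid) / n
    if sigma2 <= 0:
        sigma2 = 1e-300
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
    return ll, mu, sigma2


@dataclass
class SignalEstimate:
    """Phylogenetic-signal estimates for one trait."""
    lambda_hat: Optional[float] = None
    K: Optional[float] = None
    sigma2: Optional[float] = None
    mu: Optional[float] = None
    loglik: Optional[float] = None
    loglik_lambda0: Optional[float] = None
    loglik_lambda1: Optional[float] = None
    p_permutation: Optional[float] = None
    n: int = 0

    def summary(self) -> str:
        bits = [f"n = {self.n}"]
        if self.lambda_hat is not None:
            bits.append(f"lambda = {self.lambda_hat:.4f} "
                        f"(logL = {self.loglik:.3f}; "
                        f"logL[lambda=0] = {self.loglik_lambda0:.3f})")
        if self.K is not None:
            bits.append(f"K = {self.K:.4f}")
            if self.p_permutation is not None:
                bits.append(f"P[perm] = {self.p_permutation:.4f}")
        if self.sigma2 is not None:
            bits.append(f"sigma^2 = {self.sigma2:.5g}, "
                        f"ancestral mean = {self.mu:.5g}")
        return "phylogenetic signal: " + "; ".join(bits)


class PagelLambda:
    """Maximum-likelihood Pagel-lambda model for one continuous trait.

    Parameters
    ----------
    tree : Phylogeny with branch lengths (a warning is issued when the tree
        is noticeably non-ultrametric).
    trait : mapping from tip label to value; must cover >= 4 tips.
    """

    def __init__(self, tree: Phylogeny, trait: TraitLike):
        C, labels = vcv(tree)
        keep = [i for i, lab in enumerate(labels) if lab in trait]
        if len(keep) < 4:
            raise ValueError("lambda estimation needs >= 4 tips with data")
        self.labels = [labels[i] for i in keep]
        self.C = C[np.ix_(keep, keep)]
        self.y = _trait_vector(trait, self.labels)
        if np.var(self.y) == 0:
            raise ValueError("trait has zero variance")
        if not tree.is_ultrametric(rel_tol=1e-3):
            warnings.warn("tree is not ultrametric; lambda estimates are "
                          "better behaved on chronograms", stacklevel=2)

    def loglik(self, lam: float) -> float:
        return _profile_loglik(self.y, self.C, lam)[0]

    def fit(self, xatol: float = 1e-8) -> SignalEstimate:
        res = minimize_scalar(lambda l: -self.loglik(l), bounds=(0.0, 1.0),
                              method="bounded", options={"xatol": xatol})
        cands = [(self.loglik(0.0), 0.0), (self.loglik(1.0), 1.0),
                 (-res.fun, float(res.x))]
        ll_hat, lam_hat = max(cands, key=lambda t: t[0])
        ll0 = cands[0][0]
        ll1 = cands[1][0]
        _, mu, s2 = _profile_loglik(self.y, self.C, lam_hat)
        return SignalEstimate(lambda_hat=lam_hat, sigma2=s2, mu=mu,
                              loglik=ll_hat, loglik_lambda0=ll0,
                              loglik_lambda1=ll1, n=len(self.y))


def estimate_lambda(tree: Phylogeny, trait: TraitLike) -> SignalEstimate:
    return PagelLambda(tree, trait).fit()


def _k_statistic(y: np.ndarray, Cinv: np.ndarray, expected: float) -> float:
    n = len(y)
    ones = np.ones(n)
    mu = float(ones @ Cinv @ y) / float(ones @ Cinv @ ones)
    d = y - mu
    mse0 = float(d @ d) / (n - 1)
    mse = float(d @ Cinv @ d) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_k(tree: Phylogeny, trait: TraitLike,
               n_permutations: int = 0,
               seed: Optional[int] = None) -> SignalEstimate:
    """Blomberg's K, optionally with a tip-shuffling permutation test.

    The permutation p-value is the (add-one) proportion of shuffles whose K
    is at least the observed K; a seed is mandatory when permuting.
    """
    C, labels = vcv(tree)
    keep = [i for i, lab in enumerate(labels) if lab in trait]
    if len(keep) < 4:
        raise ValueError("K needs >= 4 tips with data")
    labels = [labels[i] for i in keep]
    C = C[np.ix_(keep, keep)]
    y = _trait_vector(trait, labels)
    if np.var(y) == 0:
        raise ValueError("trait has zero variance")
    n = len(y)
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    expected = (np.trace(C) - n / float(ones @ Cinv @ ones)) / (n - 1)
    k_obs = _k_statistic(y, Cinv, expected)
    p = None
    if n_permutations:
        if seed is None:
            raise ValueError("a seed is mandatory for the permutation test")
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            if _k_statistic(rng.permutation(y), Cinv, expected) >= k_obs:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
    return SignalEstimate(K=float(k_obs), p_permutation=p, n=n)


def ancestral_continuous(tree: Phylogeny, trait: TraitLike
                         ) -> dict[int, float]:
    """Maximum-likelihood (GLS) ancestral states under Brownian motion.

    Internal node estimates minimise the weighted sum of squared changes
    sum((x_child - x_parent)^2 / branch length); the root estimate equals
    the GLS phylogenetic mean.  Returns node id -> estimate (tips included,
    at their observed values).
    """
    labels = tree.tip_labels
    y = _trait_vector(trait, labels)
    tipval = dict(zip(labels, y))
    internal = [nd for nd in tree.nodes if not nd.is_leaf]
    index = {nd.id: k for k, nd in enumerate(internal)}
    m = len(internal)
    A = np.zeros((m, m))
    b = np.zeros(m)
    for nd in tree.nodes:
        if nd is tree.root:
            continue
        t = nd.length
        if t is None:
            raise TreeValidationError(
                f"missing branch length above node {nd.label or nd.id}")
        if t <= 0:
            t = 1e-9        # zero-length branch: effectively fuse the nodes
        w = 1.0 / t
        pi = index[nd.parent.id]
        if nd.is_leaf:
            A[pi, pi] += w
            b[pi] += w * tipval[nd.label]
        else:
            ci = index[nd.id]
            A[pi, pi] += w
            A[ci, ci] += w
            A[pi, ci] -= w
            A[ci, pi] -= w
    x = np.linalg.solve(A, b)
    out = {nd.id: float(x[index[nd.id]]) for nd in internal}
    for lab, v in tipval.items():
        out[tree.tip(lab).id] = float(v)
    return out
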