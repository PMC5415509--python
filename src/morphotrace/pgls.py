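"""Phylogenetic generalised least squares.

Regression of a continuous trait on predictors with residual covariance
proportional to the tree's shared-path-length matrix:

    y = X beta + e,   e ~ N(0, sigma^2 * C(lambda))

with C the Brownian-motion covariance and lambda an optional Pagel
branch-length transform (covariance="lambda" estimates it jointly by ML;
covariance="brownian" fixes lambda = 1; an identity covariance reduces the
fit to ordinary least squares exactly).  Estimation is deterministic GLS
via Cholesky whitening; t-based Wald inference per coefficient with
n - p degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.optimize import minimize_scalar
from scipy.stats import t as t_dist

from .characters import CharacterMatrix
from .phylosignal import lambda_transform, vcv
from .tree import Phylogeny

__all__ = ["PGLS", "PGLSResults", "pgls_fit", "complexity_score"]


@dataclass
class PGLSResults:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    sigma2: float
    loglik: float
    lam: Optional[float]
    covariance: str
    nobs: int
    df_resid: int
    design: str
    dropped_tips: list[str] = field(default_factory=list)

    def summary(self) -> str:
        head = (f"PGLS: {self.design}\n"
                f"covariance: {self.covariance}"
                + (f" (lambda = {self.lam:.4f})" if self.lam is not None
                   else "")
                + f"; n = {self.nobs}; sigma^2 = {self.sigma2:.5g}; "
                f"logL = {self.loglik:.3f}\n")
        rows = [f"{'term':<28}{'coef':>10}{'se':>10}{'t':>8}{'p':>10}"]
        for name in self.params.index:
            rows.append(f"{name:<28}{self.params[name]:>10.4f}"
                        f"{self.bse[name]:>10.4f}{self.tvalues[name]:>8.2f}"
                        f"{self.pvalues[name]:>10.4f}")
        if self.dropped_tips:
            rows.append(f"dropped tips without data: {self.dropped_tips}")
        return head + "\n".join(rows)


class PGLS:
    """Model object; build from aligned arrays or a tidy DataFrame."""

    def __init__(self, y: np.ndarray, X: np.ndarray, C: np.ndarray,
                 term_names: Sequence[str], covariance: str = "brownian",
                 design: str = "y ~ X", dropped: Sequence[str] = ()):
        y = np.asarray(y, float)
        X = np.asarray(X, float)
        if covariance not in ("brownian", "lambda", "identity"):
            raise ValueError(f"unknown covariance spec {covariance!r}")
        n, p = X.shape
        if n != len(y) or n != C.shape[0]:
            raise ValueError("y, X and C dimensions disagree")
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            # name the columns implicated via tiny R diagonal in a QR
            _, R = np.linalg.qr(X)
            diag = np.abs(np.diag(R))
            bad = [term_names[i] for i in range(p)
                   if diag[i] < 1e-8 * diag.max()]
            raise ValueError(f"design matrix is rank deficient; collinear "
                             f"columns: {bad}")
        self.y, self.X, self.C = y, X, C
        self.term_names = list(term_names)
        self.covariance = covariance
        self.design = design
        self.dropped = list(dropped)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str,
                       predictors: Sequence[str], tree: Phylogeny,
                       covariance: str = "brownian") -> "PGLS":
        """Build the design from a species-indexed DataFrame.

        Numeric predictors enter as-is; categorical/object columns are
        expanded into treatment dummies (first level alphabetically is the
        reference).  Species missing the response, any predictor, or a
        matching tree tip are dropped with a record in ``dropped``.
        """
        C_full, labels = vcv(tree)
        cols = [response] + list(predictors)
        avail = data.loc[data.index.intersection(labels), cols].dropna()
        keep = [lab for lab in labels if lab in avail.index]
        dropped = sorted(set(data.index) - set(keep))
        if len(keep) < len(predictors) + 2:
            raise ValueError("too few complete cases for the design")
        idx = [labels.index(lab) for lab in keep]
        C = C_full[np.ix_(idx, idx)]
        sub = avail.loc[keep]
        y = sub[response].to_numpy(float)
        pieces = [pd.Series(1.0, index=sub.index, name="intercept")]
        for pred in predictors:
            col = sub[pred]
            if col.dtype.kind in "OUS" or isinstance(col.dtype,
                                                     pd.CategoricalDtype):
                dummies = pd.get_dummies(col, prefix=pred, drop_first=True,
                                         dtype=float)
                pieces.extend(dummies[c] for c in dummies.columns)
            else:
                pieces.append(col.astype(float))
        Xdf = pd.concat(pieces, axis=1)
        design = f"{response} ~ {' + '.join(predictors)}"
        return cls(y, Xdf.to_numpy(), C, list(Xdf.columns),
                   covariance=covariance, design=design, dropped=dropped)

    # -- fitting -----------------------------------------------------------

    def _gls(self, V: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
        L = np.linalg.cholesky(V)
        wy = solve_triangular(L, self.y, lower=True)
        wX = solve_triangular(L, self.X, lower=True)
        beta, *_ = np.linalg.lstsq(wX, wy, rcond=None)
        resid = wy - wX @ beta
        rss = float(resid @ resid)
        n, p = self.X.shape
        sigma2 = rss / (n - p)
        # ML log-likelihood with the ML variance rss/n
        s2_ml = max(rss / n, 1e-300)
        logdet = 2.0 * float(np.log(np.diag(L)).sum())
        ll = -0.5 * (n * math.log(2 * math.pi * s2_ml) + logdet + n)
        return beta, wX, sigma2, ll

    def fit(self) -> PGLSResults:
        lam: Optional[float] = None
        if self.covariance == "identity":
            V = np.eye(len(self.y))
        elif self.covariance == "brownian":
            V = self.C
        else:
            res = minimize_scalar(
                lambda l: -self._gls(lambda_transform(self.C, l))[3],
                bounds=(0.0, 1.0), method="bounded",
                options={"xatol": 1e-8})
            cands = [(self._gls(lambda_transform(self.C, l))[3], l)
                     for l in (0.0, 1.0)] + [(-res.fun, float(res.x))]
            _, lam = max(cands)
            V = lambda_transform(self.C, lam)
        beta, wX, sigma2, ll = self._gls(V)
        n, p = self.X.shape
        XtXi = np.linalg.inv(wX.T @ wX)
        se = np.sqrt(np.diag(XtXi) * sigma2)
        tvals = beta / se
        pvals = 2.0 * t_dist.sf(np.abs(tvals), n - p)
        names = self.term_names
        return PGLSResults(
            params=pd.Series(beta, index=names),
            bse=pd.Series(se, index=names),
            tvalues=pd.Series(tvals, index=names),
            pvalues=pd.Series(pvals, index=names),
            sigma2=sigma2, loglik=ll, lam=lam,
            covariance=self.covariance, nobs=n, df_resid=n - p,
            design=self.design, dropped_tips=self.dropped)


def pgls_fit(data: pd.DataFrame, response: str, predictors: Sequence[str],
             tree: Phylogeny, covariance: str = "brownian") -> PGLSResults:
    return PGLS.from_dataframe(data, response, predictors, tree,
                               covariance=covariance).fit()


def complexity_score(matrix: CharacterMatrix, species: str,
                     chars: Sequence[int] = tuple(range(37, 45))) -> int:
    """Copulatory-organ complexity: number of accessory structures scored
    present (state 1) among characters 37-44.  Missing or inapplicable
    cells count as absent (only confirmed presences are tallied)."""
    if species not in matrix.taxa:
        raise KeyError(f"species {species!r} not in matrix")
    return sum(1 for c in chars if matrix.state(species, c) == 1)
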