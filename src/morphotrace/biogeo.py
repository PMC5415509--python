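"""Latitudinal diversity-gradient analysis.

Pipeline: species occurrence records are binned into fixed-width latitude
bands (default 10 degrees, half-open ``[lo, hi)`` bands anchored at the
equator and mirrored toward both poles); per-band species richness is then
summarised by a 95th-percentile B-spline quantile regression whose
polynomial degree is chosen by small-sample-corrected AIC; finally the
latitude of maximal diversity (argmax of the fitted curve on a 0.1-degree
grid) gets a percentile bootstrap confidence interval from resampled
(band, richness) pairs.

Quantile fits minimise the pinball (check) loss by linear programming, so
results are deterministic for a given input.  The quasi-log-likelihood
behind the AICc is the asymmetric-Laplace form conventional in quantile
regression:  n * (log(tau * (1 - tau)) - 1 - log(mean pinball loss)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import linprog

from .characters import validate_occurrences

__all__ = [
    "RichnessProfile",
    "QuantileSplineFit",
    "OptimumEstimate",
    "bin_richness",
    "fit_quantile_spline",
    "select_degree",
    "optimum_with_ci",
]


# -- binning ----------------------------------------------------------------

@dataclass
class RichnessProfile:
    edges: np.ndarray        # band edges, length k + 1
    midpoints: np.ndarray    # band midpoints, length k
    counts: np.ndarray       # species richness per band
    width: float
    axis: str = "lat"


def bin_richness(occurrences: pd.DataFrame, width: float = 10.0,
                 axis: str = "lat") -> RichnessProfile:
    """Species richness per fixed-width band.

    Bands are half-open ``[k*width, (k+1)*width)`` for integer k of either
    sign, so the first northern band is [0, width) and the first southern
    band is [-width, 0).  A species is counted at most once per band,
    however many records fall there.  Bands between the outermost occupied
    ones are kept (with zero counts) so the profile tiles the observed
    range.
    """
    occurrences = validate_occurrences(occurrences)
    if occurrences.empty:
        raise ValueError("no occurrence records")
    vals = occurrences[axis].to_numpy(float)
    bins = np.floor(vals / width).astype(int)
    per_bin: dict[int, set[str]] = {}
    for b, sp in zip(bins, occurrences["species"]):
        per_bin.setdefault(int(b), set()).add(sp)
    lo, hi = min(per_bin), max(per_bin)
    ks = np.arange(lo, hi + 1)
    counts = np.array([len(per_bin.get(int(k), ())) for k in ks])
    edges = np.append(ks * width, (hi + 1) * width)
    mids = ks * width + width / 2.0
    return RichnessProfile(edges=edges, midpoints=mids, counts=counts,
                           width=width, axis=axis)


# -- quantile spline --------------------------------------------------------

def _basis(x: np.ndarray, degree: int, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
    """Clamped B-spline basis of the given degree with no interior knots
    (spans the polynomials of that degree on [lo, hi])."""
    if hi <= lo:
        raise ValueError("degenerate x-range for the spline basis")
    knots = np.r_[[lo] * (degree + 1), [hi] * (degree + 1)]
    B = BSpline.design_matrix(np.clip(x, lo, hi), knots, degree).toarray()
    return B, knots


def _pinball(resid: np.ndarray, tau: float) -> float:
    return float(np.sum(np.where(resid >= 0, tau * resid,
                                 (tau - 1.0) * resid)))


@dataclass
class QuantileSplineFit:
    tau: float
    degree: int
    knots: np.ndarray
    coef: np.ndarray
    loss: float
    aicc: float
    n: int
    x_range: tuple[float, float]

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, float), *self.x_range)
        return BSpline(self.knots, self.coef, self.degree)(x)

    def __call__(self, x):
        return self.predict(x)


def fit_quantile_spline(x: Sequence[float], y: Sequence[float],
                        tau: float = 0.95, degree: int = 3
                        ) -> QuantileSplineFit:
    """tau-quantile B-spline regression by linear programming.

    Minimises sum of pinball losses rho_tau(y - B c) over the spline
    coefficients c.  The LP has free coefficients and split positive /
    negative residual parts; the HiGHS solver makes the fit deterministic.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    n = len(x)
    k = degree + 1
    if n < degree + 2:
        raise ValueError(f"need at least degree + 2 = {degree + 2} points, "
                         f"got {n}")
    lo, hi = float(x.min()), float(x.max())
    B, knots = _basis(x, degree, lo, hi)
    # variables: c (k, free), u (n, >=0), v (n, >=0); B c + u - v = y
    c_obj = np.r_[np.zeros(k), tau * np.ones(n), (1 - tau) * np.ones(n)]
    A_eq = np.hstack([B, np.eye(n), -np.eye(n)])
    bounds = [(None, None)] * k + [(0, None)] * (2 * n)
    res = linprog(c_obj, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"quantile LP failed: {res.message}")
    coef = res.x[:k]
    loss = _pinball(y - B @ coef, tau)
    mean_loss = loss / n
    # fits at (numerical) zero loss are all "perfect"; give them a common
    # infinite quasi-likelihood so ties resolve by degree, not rounding
    if mean_loss <= 1e-9 * max(1.0, float(np.mean(np.abs(y)))):
        quasi_ll = math.inf
    else:
        quasi_ll = n * (math.log(tau * (1 - tau)) - 1 - math.log(mean_loss))
    if n - k - 1 > 0:
        aicc = -2 * quasi_ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    else:
        aicc = math.inf
    return QuantileSplineFit(tau=tau, degree=degree, knots=knots, coef=coef,
                             loss=loss, aicc=aicc, n=n, x_range=(lo, hi))


def select_degree(x: Sequence[float], y: Sequence[float], tau: float = 0.95,
                  degrees: Sequence[int] = (1, 2, 3, 4, 5)
                  ) -> QuantileSplineFit:
    """Fit each candidate degree and return the smallest-AICc fit.

    Candidates whose basis cannot be estimated (too few points for the
    small-sample correction) are skipped; AICc ties go to the smaller
    degree.  Perfect (zero-loss) fits compare by degree as well.
    """
    best: Optional[QuantileSplineFit] = None
    tried = 0
    for d in sorted(degrees):
        n = len(x)
        if n < d + 2 or n - (d + 1) - 1 <= 0:
            continue
        fit = fit_quantile_spline(x, y, tau=tau, degree=d)
        tried += 1
        if best is None or fit.aicc < best.aicc - 1e-12:
            best = fit
    if best is None or tried < 1:
        raise ValueError("no candidate degree is estimable for this profile")
    return best


# -- optimum + bootstrap ----------------------------------------------------

@dataclass
class OptimumEstimate:
    optimum: float
    ci: tuple[float, float]
    degree: int
    tau: float
    n_boot: int
    n_skipped: int
    seed: int
    boundary: bool
    profile: RichnessProfile
    fit: QuantileSplineFit
    replicates: np.ndarray = field(repr=False, default=None)

    def summary(self) -> str:
        edge = " (boundary optimum)" if self.boundary else ""
        return (f"diversity optimum at {self.optimum:.1f} deg{edge}; "
                f"95% bootstrap CI [{self.ci[0]:.1f}, {self.ci[1]:.1f}] "
                f"({self.n_boot} replicates, degree {self.degree}, "
                f"tau {self.tau})")


def _argmax_on_grid(fit: QuantileSplineFit, lo: float, hi: float
                    ) -> tuple[float, bool]:
    grid = np.arange(lo, hi + 1e-9, 0.1)
    vals = fit.predict(grid)
    i = int(np.argmax(vals))
    return float(grid[i]), i == 0 or i == len(grid) - 1


def optimum_with_ci(occurrences: pd.DataFrame, tau: float = 0.95,
                    n_boot: int = 10000, seed: Optional[int] = None,
                    width: float = 10.0, axis: str = "lat",
                    degrees: Sequence[int] = (1, 2, 3, 4, 5)
                    ) -> OptimumEstimate:
    """Latitude of maximal diversity with a 95% percentile bootstrap CI.

    The spline degree is selected once on the original profile and held
    fixed across bootstrap replicates, which resample the (midpoint,
    richness) pairs with replacement.  Replicates whose resampled x-values
    are degenerate (too few distinct bands for the basis) are skipped and
    counted; more than 5% skips triggers a warning.
    """
    if seed is None:
        raise ValueError("a seed is mandatory for the bootstrap")
    prof = bin_richness(occurrences, width=width, axis=axis)
    x, y = prof.midpoints, prof.counts.astype(float)
    base = select_degree(x, y, tau=tau, degrees=degrees)
    lo, hi = float(x.min()), float(x.max())
    opt, boundary = _argmax_on_grid(base, lo, hi)
    rng = np.random.default_rng(seed)
    reps = []
    skipped = 0
    n = len(x)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        bx, by = x[idx], y[idx]
        if len(np.unique(bx)) < 2:      # all-identical x: no curve
            skipped += 1
            continue
        try:
            bfit = fit_quantile_spline(bx, by, tau=tau, degree=base.degree)
        except (ValueError, RuntimeError):
            skipped += 1
            continue
        reps.append(_argmax_on_grid(bfit, float(bx.min()), float(bx.max()))[0])
    if skipped > 0.05 * n_boot:
        import warnings
        warnings.warn(f"{skipped} of {n_boot} bootstrap replicates were "
                      "degenerate and skipped", stacklevel=2)
    reps = np.asarray(reps)
    if reps.size == 0:
        raise RuntimeError("all bootstrap replicates were degenerate")
    ci = (float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5)))
    return OptimumEstimate(optimum=opt, ci=ci, degree=base.degree, tau=tau,
                           n_boot=n_boot, n_skipped=skipped, seed=seed,
                           boundary=boundary, profile=prof, fit=base,
                           replicates=reps)
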