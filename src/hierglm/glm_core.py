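"""Exponential-family GLM machinery.

Families, canonical links, deviances, the classical iteratively weighted
least squares (IWLS) solver, Wald inference, and Benjamini-Hochberg
adjustment.  This is the substrate on which the hierarchical (shrinkage
prior) fitters in :mod:`hierglm.bglm` and :mod:`hierglm.multiplicative`
are built.

A GLM has three parts: a linear predictor ``eta = X @ beta``, a link
``eta = h(mu)`` relating the predictor to the mean of the response, and a
data distribution with variance ``phi * V(mu)`` where ``phi`` is the
dispersion.  Four families are provided (gaussian, binomial, poisson,
gamma), each with its canonical link.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Family",
    "Link",
    "LinkDomainError",
    "SingularDesignError",
    "WaldSummary",
    "IWLSResult",
    "get_family",
    "apply_link",
    "deviance",
    "iwls_classical",
    "wald_test",
    "bh_adjust",
]

_MU_EPS = 1e-10


class LinkDomainError(ValueError):
    """A mean value lies outside the open domain of the link function."""


class SingularDesignError(np.linalg.LinAlgError):
    """The (possibly augmented) weighted normal equations are singular."""


# --------------------------------------------------------------------------
# links
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Link:
    """An invertible link function with its derivative d eta / d mu."""

    name: str
    func: Callable[[np.ndarray], np.ndarray]
    inverse: Callable[[np.ndarray], np.ndarray]
    deriv: Callable[[np.ndarray], np.ndarray]
    domain: tuple[float, float]  # open interval of valid means

    def check_domain(self, mu) -> None:
        lo, hi = self.domain
        mu = np.asarray(mu, dtype=float)
        if np.any(~np.isfinite(mu)) or np.any(mu <= lo) or np.any(mu >= hi):
            raise LinkDomainError(
                f"mean outside the open domain ({lo}, {hi}) of the {self.name} link"
            )


_IDENTITY = Link("identity", lambda m: np.asarray(m, float), lambda e: np.asarray(e, float),
                 lambda m: np.ones_like(np.asarray(m, float)), (-np.inf, np.inf))
_LOGIT = Link("logit", lambda m: special.logit(m), lambda e: special.expit(e),
              lambda m: 1.0 / (m * (1.0 - m)), (0.0, 1.0))
_LOG = Link("log", np.log, np.exp, lambda m: 1.0 / m, (0.0, np.inf))
_INVERSE = Link("inverse", lambda m: 1.0 / np.asarray(m, float),
                lambda e: 1.0 / np.asarray(e, float),
                lambda m: -1.0 / np.asarray(m, float) ** 2, (0.0, np.inf))

_LINKS = {lk.name: lk for lk in (_IDENTITY, _LOGIT, _LOG, _INVERSE)}


# --------------------------------------------------------------------------
# families
# --------------------------------------------------------------------------

def _xlogy(x, y):
    return special.xlogy(x, y)


def _dev_gaussian(y, mu):
    return float(np.sum((y - mu) ** 2))


def _dev_binomial(y, mu):
    return float(2.0 * np.sum(_xlogy(y, y / mu) + _xlogy(1.0 - y, (1.0 - y) / (1.0 - mu))))


def _dev_poisson(y, mu):
    return float(2.0 * np.sum(_xlogy(y, y / mu) - (y - mu)))


def _dev_gamma(y, mu):
    return float(2.0 * np.sum(-np.log(y / mu) + (y - mu) / mu))


@dataclass(frozen=True)
class Family:
    """An exponential family with canonical link and variance function."""

    name: str
    link: Link
    variance: Callable[[np.ndarray], np.ndarray]
    dispersion_fixed: bool
    _deviance: Callable = field(repr=False, default=None)

    def deviance(self, y, mu) -> float:
        y = np.asarray(y, float)
        mu = np.asarray(mu, float)
        if y.shape != mu.shape:
            raise ValueError("y and mu must have the same length")
        self._check_mu(mu)
        return self._deviance(y, mu)

    def _check_mu(self, mu) -> None:
        lo, hi = self.link.domain
        if np.any(mu <= lo) or np.any(mu >= hi):
            raise LinkDomainError(f"mean outside valid domain for family {self.name}")

    def clip_mu(self, mu: np.ndarray) -> np.ndarray:
        """Clip means into the open domain; used inside IWLS for stability."""
        lo, hi = self.link.domain
        lo = lo + _MU_EPS if np.isfinite(lo) else -np.inf
        hi = hi - _MU_EPS if np.isfinite(hi) else np.inf
        return np.clip(mu, lo, hi)

    def init_mu(self, y: np.ndarray) -> np.ndarray:
        if self.name == "gaussian":
            return np.asarray(y, float)
        if self.name == "binomial":
            return (np.asarray(y, float) + 0.5) / 2.0
        if self.name == "poisson":
            return np.asarray(y, float) + 0.1
        return np.asarray(y, float)  # gamma: requires y > 0


_FAMILIES = {
    "gaussian": Family("gaussian", _IDENTITY, lambda m: np.ones_like(np.asarray(m, float)),
                       False, _dev_gaussian),
    "binomial": Family("binomial", _LOGIT, lambda m: m * (1.0 - m), True, _dev_binomial),
    "poisson": Family("poisson", _LOG, lambda m: np.asarray(m, float), True, _dev_poisson),
    "gamma": Family("gamma", _INVERSE, lambda m: np.asarray(m, float) ** 2,
                    False, _dev_gamma),
}


def get_family(name) -> Family:
    """Return a :class:`Family` by name (or pass one through unchanged)."""
    if isinstance(name, Family):
        return name
    try:
        return _FAMILIES[str(name).lower()]
    except KeyError:
        raise ValueError(
            f"unknown family {name!r}; choose from {sorted(_FAMILIES)}"
        ) from None


def apply_link(mean, family) -> np.ndarray | float:
    """Apply the family's link ``eta = h(mu)``, checking the open domain."""
    fam = get_family(family)
    fam.link.check_domain(mean)
    out = fam.link.func(np.asarray(mean, dtype=float))
    return float(out) if np.ndim(mean) == 0 else out


def deviance(y, mu, family, dispersion: float = 1.0) -> float:
    """Family deviance, scaled by ``dispersion`` (phi = 1 gives the usual value)."""
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    return get_family(family).deviance(y, mu) / dispersion


# --------------------------------------------------------------------------
# classical IWLS
# --------------------------------------------------------------------------

@dataclass
class IWLSResult:
    params: np.ndarray
    cov_params: np.ndarray
    deviance: float
    n_iter: int
    converged: bool
    deviance_trace: np.ndarray
    dispersion: float


def iwls_classical(y, X, family, max_iter: int = 100, tol: float = 1e-8,
                   offset=None) -> IWLSResult:
    """Maximum-likelihood GLM fit by iteratively weighted least squares.

    Convergence uses the glm-style criterion
    ``|D_t - D_{t-1}| / (|D_t| + 0.1) < tol``.  Non-convergence is flagged
    in the result, not raised.  The covariance is
    ``dispersion * (X' W X)^{-1}`` with the Pearson dispersion estimate
    ``chi2 / (n - p)`` for gaussian/gamma and phi = 1 otherwise.
    """
    fam = get_family(family)
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("y and X have incompatible shapes")
    if n < p:
        raise SingularDesignError("need n >= p for a classical fit")
    if np.linalg.matrix_rank(X) < p:
        raise SingularDesignError("design matrix is rank deficient")
    offset = np.zeros(n) if offset is None else np.asarray(offset, float)

    mu = fam.clip_mu(fam.init_mu(y))
    eta = fam.link.func(mu)
    trace: list[float] = []
    converged = False
    A = None
    beta = np.zeros(p)
    for it in range(1, max_iter + 1):
        gprime = fam.link.deriv(mu)
        w = 1.0 / (gprime ** 2 * fam.variance(mu))
        z = (eta - offset) + (y - mu) * gprime
        A = X.T @ (w[:, None] * X)
        beta = np.linalg.solve(A, X.T @ (w * z))
        eta = X @ beta + offset
        mu = fam.clip_mu(fam.link.inverse(eta))
        dev = fam.deviance(y, mu)
        trace.append(dev)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) / (abs(trace[-1]) + 0.1) < tol:
            converged = True
            break

    if fam.dispersion_fixed:
        phi = 1.0
    else:
        pearson = float(np.sum((y - mu) ** 2 / fam.variance(mu)))
        phi = pearson / (n - p) if n > p else np.nan
    cov = phi * np.linalg.inv(A)
    return IWLSResult(beta, cov, trace[-1], len(trace), converged,
                      np.asarray(trace), phi)


# --------------------------------------------------------------------------
# inference utilities
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WaldSummary:
    estimate: float
    std_error: float
    z_or_t: float
    p_value: float


def wald_test(estimate: float, std_error: float, df: float = np.inf) -> WaldSummary:
    """Two-sided Wald test of ``estimate = 0``.

    Normal reference when ``df`` is infinite, Student t otherwise.
    """
    if not std_error > 0:
        raise ValueError("std_error must be positive")
    if not df > 0:
        raise ValueError("df must be positive")
    z = estimate / std_error
    if np.isinf(df):
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        p = 2.0 * stats.t.sf(abs(z), df)
    return WaldSummary(float(estimate), float(std_error), float(z), float(p))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-D array")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
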