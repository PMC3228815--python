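"""Hierarchical GLMs fitted by EM within IWLS (posterior modes).

A single-stage hierarchical GLM with a fixed design: coefficients carry one
of the package's shrinkage priors and the fit alternates

* an E-step that refreshes the expected prior precision of every penalized
  coefficient (half-Cauchy scale-mixture updates for weight-like columns,
  the Gamma(0.5, 0.5) conditional-mode variance update for group-effect-like
  columns), and
* an M-step that takes one IWLS step on the data augmented with one
  pseudo-observation per penalized coefficient (pseudo-response = prior
  mean, pseudo-precision = expected prior precision; for gaussian/gamma the
  augmented weight is scaled by the current dispersion so the prior acts on
  the coefficient scale).

Because each pseudo-observation touches a single coefficient, augmentation
reduces to adding the expected prior precisions to the diagonal of the
weighted normal equations.  The dispersion (gaussian/gamma) is updated from
the weighted working residuals including the augmented rows under the
scale-invariant prior p(phi) ∝ 1/phi.  Iteration stops on the glm-style
criterion |D_t - D_{t-1}| / (|D_t| + 0.1) < tol.

This engine is used standalone (:class:`HierarchicalGLM`, and
:func:`fit_all_variants` for the per-variant main-effects model) and as the
conditional-update workhorse of :class:`hierglm.multiplicative.GroupScoreGLM`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .glm_core import Family, SingularDesignError, get_family, wald_test
from .priors import (
    PSI_MIN,
    group_effect_variance_update,
    group_scale_update,
    halfcauchy_estep,
)

__all__ = [
    "ColumnPrior",
    "HierDesign",
    "EmState",
    "HierarchicalGLM",
    "HierGLMResults",
    "MonomorphicVariantError",
    "fit_all_variants",
    "group_min_pvalue",
]

_INTERCEPT_VARIANCE = 1e6


class MonomorphicVariantError(ValueError):
    """A genotype column carries no variation and cannot be a predictor."""


@dataclass(frozen=True)
class ColumnPrior:
    """Prior tag for one design column.

    kind:
        ``"intercept"``  near-flat normal N(0, 1e6);
        ``"shrunk"``     weakly informative N(0, psi), psi ~ Gamma(0.5, 0.5);
        ``"weight"``     hierarchical half-Cauchy scale mixture centred at
                         ``mean``, pooled through ``group``;
        ``"fixed"``      normal with known ``mean`` and ``variance``;
        ``"pinned"``     coefficient held exactly at ``mean`` (zero variance).
    """

    kind: str
    mean: float = 0.0
    variance: float | None = None
    group: str | None = None

    def __post_init__(self):
        if self.kind not in ("intercept", "shrunk", "weight", "fixed", "pinned"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.kind == "fixed" and (self.variance is None or self.variance <= 0):
            raise ValueError("fixed prior requires a positive variance")
        if self.kind == "weight" and self.group is None:
            raise ValueError("weight prior requires a group label")


@dataclass
class HierDesign:
    """Response, named design, offset and per-column prior tags for one fit."""

    y: np.ndarray
    X: np.ndarray
    names: list[str]
    priors: list[ColumnPrior]
    family: Family
    offset: np.ndarray | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, float)
        self.X = np.asarray(self.X, float)
        n = self.y.shape[0]
        if n < 2:
            raise ValueError("need at least 2 observations")
        if self.X.shape != (n, len(self.names)):
            raise ValueError("X, y and names are not conformable")
        if len(self.priors) != len(self.names):
            raise ValueError("every design column needs exactly one prior tag")
        self.offset = (np.zeros(n) if self.offset is None
                       else np.asarray(self.offset, float))
        if self.offset.shape[0] != n:
            raise ValueError("offset length must equal n")


@dataclass
class EmState:
    """Mutable iteration state of the EM-IWLS fitter."""

    beta: np.ndarray                  # coefficients of the solved columns
    lam: np.ndarray                   # local auxiliaries, one per weight column
    s: dict[str, float]               # group scales
    psi: np.ndarray                   # variances of the shrunk columns
    phi: float                        # dispersion
    deviance: float = np.nan
    A: np.ndarray | None = None       # last augmented normal-equations matrix


class _EmIwls:
    """EM-IWLS engine on plain arrays (one instance per fixed design)."""

    def __init__(self, design: HierDesign, scale_value: float | None = None):
        self.design = design
        self.family = design.family
        self.scale_value = scale_value
        kinds = np.array([p.kind for p in design.priors])
        self.i_solved = np.flatnonzero(kinds != "pinned")
        self.i_pinned = np.flatnonzero(kinds == "pinned")
        self.X = design.X[:, self.i_solved]
        self.names = [design.names[i] for i in self.i_solved]
        self.priors = [design.priors[i] for i in self.i_solved]
        self.offset = design.offset.copy()
        for i in self.i_pinned:
            self.offset += design.X[:, i] * design.priors[i].mean
        self.y = design.y
        self.n, self.p = self.X.shape

        k = np.array([pr.kind for pr in self.priors])
        self.j_intercept = np.flatnonzero(k == "intercept")
        self.j_shrunk = np.flatnonzero(k == "shrunk")
        self.j_weight = np.flatnonzero(k == "weight")
        self.j_fixed = np.flatnonzero(k == "fixed")
        self.target = np.array([pr.mean if pr.kind in ("weight", "fixed") else 0.0
                                for pr in self.priors])
        self.fixed_prec = np.array([1.0 / pr.variance for pr in self.priors
                                    if pr.kind == "fixed"])
        self.w_mean = self.target[self.j_weight]
        groups = [self.priors[j].group for j in self.j_weight]
        self.group_names = list(dict.fromkeys(groups))
        self.group_idx = {g: np.flatnonzero(np.array(groups, object) == g)
                          for g in self.group_names}

    # -- initialization ----------------------------------------------------
    def initial_state(self) -> EmState:
        beta = np.zeros(self.p)
        ybar = float(np.mean(self.y))
        fam = self.family
        mu0 = float(fam.clip_mu(np.atleast_1d(ybar))[0])
        if self.j_intercept.size:
            beta[self.j_intercept] = fam.link.func(mu0)
        beta[self.j_weight] = self.w_mean
        s0 = self.scale_value if self.scale_value is not None else 0.5
        return EmState(
            beta=beta,
            lam=np.ones(self.j_weight.size),
            s={g: s0 for g in self.group_names},
            psi=np.ones(self.j_shrunk.size),
            phi=1.0,
        )

    # -- one EM + IWLS step ------------------------------------------------
    def step(self, st: EmState) -> EmState:
        fam = self.family
        beta = st.beta
        prec = np.zeros(self.p)
        prec[self.j_intercept] = 1.0 / _INTERCEPT_VARIANCE
        if self.j_fixed.size:
            prec[self.j_fixed] = self.fixed_prec
        psi = st.psi
        if self.j_shrunk.size:
            psi = group_effect_variance_update(beta[self.j_shrunk])
            psi = np.atleast_1d(psi)
            prec[self.j_shrunk] = 1.0 / psi
        lam = st.lam
        s = dict(st.s)
        if self.j_weight.size:
            s_per_col = np.array([st.s[self.priors[j].group] for j in self.j_weight])
            pw, lam = halfcauchy_estep(beta[self.j_weight], self.w_mean, st.lam,
                                       s_per_col)
            prec[self.j_weight] = pw
            for g, idx in self.group_idx.items():
                s[g] = (self.scale_value if self.scale_value is not None
                        else group_scale_update(lam[idx]))

        eta = self.X @ beta + self.offset
        mu = fam.clip_mu(fam.link.inverse(eta))
        gprime = fam.link.deriv(mu)
        w = 1.0 / (gprime ** 2 * fam.variance(mu))
        z = (eta - self.offset) + (self.y - mu) * gprime

        d = prec * (1.0 if fam.dispersion_fixed else st.phi)
        A = self.X.T @ (w[:, None] * self.X)
        A[np.diag_indices_from(A)] += d
        rhs = self.X.T @ (w * z) + d * self.target
        try:
            beta_new = linalg.solve(A, rhs, assume_a="pos")
        except linalg.LinAlgError:
            diag = np.sqrt(np.abs(np.diag(A)))
            bad = [self.names[j] for j in range(self.p)
                   if diag[j] <= 1e-10 * max(diag.max(), 1.0)]
            raise SingularDesignError(
                f"singular augmented system; offending columns: {bad or self.names}"
            ) from None

        if fam.dispersion_fixed:
            phi = 1.0
        else:
            r = z - self.X @ beta_new
            ssr = float(w @ r ** 2 + d @ (beta_new - self.target) ** 2)
            phi = ssr / (self.n + self.p + 2.0)

        eta2 = self.X @ beta_new + self.offset
        mu2 = fam.clip_mu(fam.link.inverse(eta2))
        dev = fam.deviance(self.y, mu2)
        if not np.isfinite(dev):
            raise FloatingPointError("non-finite deviance in EM-IWLS")
        return EmState(beta=beta_new, lam=lam, s=s, psi=psi, phi=phi,
                       deviance=dev, A=A)

    # -- run to convergence ------------------------------------------------
    def run(self, state: EmState | None = None, tol: float = 1e-5,
            max_iter: int = 200) -> tuple[EmState, np.ndarray, bool]:
        st = self.initial_state() if state is None else state
        trace: list[float] = []
        converged = False
        for _ in range(max_iter):
            st = self.step(st)
            trace.append(st.deviance)
            if len(trace) > 1 and (abs(trace[-1] - trace[-2])
                                   / (abs(trace[-1]) + 0.1) < tol):
                converged = True
                break
        return st, np.asarray(trace), converged

    # -- posterior-curvature covariance -----------------------------------
    def covariance(self, st: EmState) -> np.ndarray:
        scale = 1.0 if self.family.dispersion_fixed else st.phi
        return scale * linalg.inv(st.A)


# --------------------------------------------------------------------------
# model / results facade
# --------------------------------------------------------------------------

class HierGLMResults:
    """Posterior-mode fit of a hierarchical GLM.

    Attributes follow statsmodels conventions: ``params``, ``bse``,
    ``tvalues``, ``pvalues`` are pandas Series indexed by design column.
    """

    def __init__(self, model, engine: _EmIwls, state: EmState,
                 trace: np.ndarray, converged: bool):
        self.model = model
        self._engine = engine
        self._state = state
        fam = engine.family
        names = engine.design.names
        cov = engine.covariance(state)
        se = np.sqrt(np.diag(cov))
        params = np.empty(len(names))
        bse = np.zeros(len(names))
        params[engine.i_solved] = state.beta
        bse[engine.i_solved] = se
        for i in engine.i_pinned:
            params[i] = engine.design.priors[i].mean
        self.params = pd.Series(params, index=names)
        self.bse = pd.Series(bse, index=names)
        self.df_resid = (max(engine.n - engine.p, 1)
                         if not fam.dispersion_fixed else np.inf)
        tv = np.full(len(names), np.nan)
        pv = np.full(len(names), np.nan)
        for i in engine.i_solved:
            ws = wald_test(params[i], bse[i], df=self.df_resid)
            tv[i], pv[i] = ws.z_or_t, ws.p_value
        self.tvalues = pd.Series(tv, index=names)
        self.pvalues = pd.Series(pv, index=names)
        self.cov_params = pd.DataFrame(cov, index=engine.names,
                                       columns=engine.names)
        self.dispersion = state.phi
        self.deviance = state.deviance
        self.deviance_trace = trace
        self.converged = converged
        self.n_iter = len(trace)
        self.hyper = {
            "lambda": pd.Series(state.lam,
                                index=[names[engine.i_solved[j]]
                                       for j in engine.j_weight]),
            "s": dict(state.s),
            "psi": pd.Series(state.psi,
                             index=[names[engine.i_solved[j]]
                                    for j in engine.j_shrunk]),
        }

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "estimate": self.params,
            "se": self.bse,
            "z_or_t": self.tvalues,
            "p": self.pvalues,
        })
        out.index.name = "term"
        return out

    def __repr__(self):  # pragma: no cover
        return (f"<HierGLMResults n_iter={self.n_iter} "
                f"converged={self.converged} deviance={self.deviance:.4g}>")


class HierarchicalGLM:
    """Single-stage hierarchical GLM (fixed design) fitted by EM-IWLS.

    Parameters
    ----------
    endog : array-like
        Response vector.
    exog : pandas.DataFrame
        Named design columns.  If no ``"intercept"`` column is present, one
        is prepended automatically (with the near-flat intercept prior).
    priors : mapping column name -> ColumnPrior
        Prior tag for every design column (the auto-added intercept gets
        its tag automatically).
    family : str or Family
    offset : array-like, optional
    scale_value : float, optional
        Freeze all half-Cauchy group scales at this value (the fixed-scale
        model variant) instead of estimating them.
    """

    def __init__(self, endog, exog: pd.DataFrame, priors, family="gaussian",
                 offset=None, scale_value: float | None = None):
        exog = pd.DataFrame(exog).astype(float)
        y = np.asarray(endog, float)
        if "intercept" not in exog.columns:
            exog = exog.copy()
            exog.insert(0, "intercept", 1.0)
        priors = dict(priors)
        priors.setdefault("intercept", ColumnPrior("intercept"))
        missing = [c for c in exog.columns if c not in priors]
        if missing:
            raise ValueError(f"no prior tag for columns {missing}")
        tags = [priors[c] for c in exog.columns]
        self.design = HierDesign(y, exog.to_numpy(), list(exog.columns), tags,
                                 get_family(family), offset)
        self.scale_value = scale_value
        self._engine = _EmIwls(self.design, scale_value=scale_value)

    def fit(self, tol: float = 1e-5, max_iter: int = 200,
            start: EmState | None = None) -> HierGLMResults:
        state, trace, converged = self._engine.run(start, tol=tol,
                                                   max_iter=max_iter)
        return HierGLMResults(self, self._engine, state, trace, converged)


def fit_all_variants(endog, covariates: pd.DataFrame | None,
                     genotypes: pd.DataFrame, family="gaussian",
                     tol: float = 1e-5, max_iter: int = 200) -> HierGLMResults:
    """Per-variant main-effects model (no group effects).

    Every variant column enters with the hierarchical half-Cauchy prior
    centred at 0 in its own group; covariates carry the weakly informative
    prior.  Genotypes must be imputed (no missing values) and polymorphic.
    """
    genotypes = pd.DataFrame(genotypes).astype(float)
    if genotypes.isna().any().any():
        raise ValueError("genotypes contain missing values; impute first")
    monomorphic = [c for c in genotypes.columns
                   if float(genotypes[c].std(ddof=0)) == 0.0]
    if monomorphic:
        raise MonomorphicVariantError(
            f"zero-variance (monomorphic) genotype columns: {monomorphic}")
    priors: dict[str, ColumnPrior] = {}
    parts = []
    if covariates is not None and len(pd.DataFrame(covariates).columns):
        covariates = pd.DataFrame(covariates).astype(float)
        parts.append(covariates)
        priors.update({c: ColumnPrior("shrunk") for c in covariates.columns})
    parts.append(genotypes)
    priors.update({c: ColumnPrior("weight", mean=0.0, group=str(c))
                   for c in genotypes.columns})
    exog = pd.concat(parts, axis=1)
    model = HierarchicalGLM(endog, exog, priors, family=family)
    return model.fit(tol=tol, max_iter=max_iter)


def group_min_pvalue(fit: HierGLMResults, group) -> float:
    """Minimum per-variant p-value over a group (no multiplicity adjustment)."""
    ids = list(group)
    unknown = [v for v in ids if v not in fit.pvalues.index]
    if unknown:
        raise KeyError(f"unknown variant ids: {unknown}")
    return float(fit.pvalues.loc[ids].min())
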