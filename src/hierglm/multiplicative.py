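"""Joint estimation of group effects and per-variant weights.

The linear predictor couples, for every group G_k of variants, a common
group effect g_k with per-variant weights b_j through the genetic score
S_ik = sum_{j in G_k} b_j z_ij:

    eta_i = beta_0 + sum_j x_ij beta_j + sum_k g_k sum_{j in G_k} b_j z_ij.

Fitting alternates two conditional hierarchical GLMs: given the weights,
the group-effect model regresses on the K score columns (weakly informative
priors on covariate and group coefficients); given the group effects, the
weight model regresses on the per-variant predictors g_{k[j]} z_ij with the
intercept + covariate part held as an offset (hierarchical half-Cauchy
priors centred at the prior means mu_j).  One EM-IWLS step is taken per
sub-model per outer iteration and the outer loop stops on the glm-style
relative deviance criterion of the group-effect fit.

The fitted predictor decomposes identically as

    g_k sum_j b_j z_ij = g_k sum_j mu_j z_ij + sum_j g_k (b_j - mu_j) z_ij,

i.e. a fixed weighted sum plus a deviation term whose per-variant
coefficient g_k (b_j - mu_j) is reported as the *adjusted main effect* of
variant j, with a delta-method standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bglm import ColumnPrior, EmState, HierDesign, _EmIwls
from .glm_core import bh_adjust, get_family, wald_test

__all__ = [
    "GroupedVariants",
    "GroupScoreGLM",
    "GroupScoreResults",
    "genetic_score",
    "adjusted_effects",
    "SUMMARY_COLUMNS",
    "write_summary", "read_summary",
]

SUMMARY_COLUMNS = ["term", "kind", "group", "estimate", "se",
                   "lower2se", "upper2se", "p", "p_bh", "total_effect"]


@dataclass
class GroupedVariants:
    """Imputed dosage matrix with a partition into groups of size >= 2.

    ``prior_means`` defaults to 1 for every variant (the simple-sum
    baseline); functional scores in (0, 1] may be supplied instead.
    """

    dosages: pd.DataFrame                      # individuals x variants
    groups: dict[str, list[str]]               # group label -> variant ids
    prior_means: pd.Series | None = None

    def __post_init__(self):
        self.dosages = pd.DataFrame(self.dosages).astype(float)
        if self.dosages.isna().any().any():
            raise ValueError("dosages contain missing values; impute first")
        if len(self.groups) == 0:
            raise ValueError(
                "no variant groups given; for per-variant main effects use "
                "hierglm.bglm.fit_all_variants")
        seen: set[str] = set()
        for k, ids in self.groups.items():
            ids = list(ids)
            if len(ids) < 2:
                raise ValueError(
                    f"group {k!r} has {len(ids)} variant(s); singleton groups "
                    "must be passed as covariates")
            unknown = [v for v in ids if v not in self.dosages.columns]
            if unknown:
                raise KeyError(f"group {k!r} references unknown variants {unknown}")
            dup = seen.intersection(ids)
            if dup:
                raise ValueError(f"variants assigned to more than one group: {sorted(dup)}")
            seen.update(ids)
            self.groups[k] = ids
        self.variant_ids = [v for ids in self.groups.values() for v in ids]
        if self.prior_means is None:
            self.prior_means = pd.Series(1.0, index=self.variant_ids)
        else:
            self.prior_means = pd.Series(self.prior_means, dtype=float).reindex(
                self.variant_ids)
            if self.prior_means.isna().any() or not np.isfinite(
                    self.prior_means.to_numpy()).all():
                raise ValueError("prior means must be finite for every grouped variant")


def genetic_score(z: pd.DataFrame, b: pd.Series, group) -> pd.Series:
    """Genetic score S_i = sum_{j in group} b_j z_ij."""
    ids = list(group)
    unknown = [v for v in ids if v not in z.columns]
    if unknown:
        raise KeyError(f"unknown variant ids: {unknown}")
    b = pd.Series(b, dtype=float)
    return pd.Series(z[ids].to_numpy() @ b.loc[ids].to_numpy(), index=z.index)


def adjusted_effects(g: float, se_g: float, b: np.ndarray, se_b: np.ndarray,
                     mu: np.ndarray) -> pd.DataFrame:
    """Adjusted main effects theta_j = g (b_j - mu_j) with delta-method SEs.

    Var(theta) = g^2 Var(b) + (b - mu)^2 Var(g); the cross-covariance is
    not available from the alternating scheme and is omitted.  A zero SE
    (no deviation and a pinned weight) reports p = 1.
    """
    b = np.asarray(b, float)
    se_b = np.asarray(se_b, float)
    mu = np.asarray(mu, float)
    if np.any(~np.isfinite(se_b)) or not np.isfinite(se_g):
        raise ValueError("missing standard errors for the delta method")
    dev = b - mu
    theta = g * dev
    se = np.sqrt(g ** 2 * se_b ** 2 + dev ** 2 * se_g ** 2)
    p = np.ones_like(theta)
    nz = se > 0
    p[nz] = [wald_test(t, s).p_value for t, s in zip(theta[nz], se[nz])]
    return pd.DataFrame({"estimate": theta, "se": se, "p": p})


class GroupScoreResults:
    """Converged joint fit: group effects, weights, adjusted effects, scores."""

    def __init__(self, model, state7, state8, engine7, engine8, b, trace,
                 converged, degenerate):
        gv = model.grouped
        fam = model.family
        self.model = model
        self.converged = bool(converged)
        self.n_outer = len(trace)
        self.deviance_trace = np.asarray(trace)
        self.deviance = float(trace[-1])
        self.dispersion = state7.phi
        K = len(gv.groups)
        names7 = engine7.names
        cov7 = engine7.covariance(state7)
        se7 = np.sqrt(np.diag(cov7))
        df7 = max(engine7.n - engine7.p, 1) if not fam.dispersion_fixed else np.inf

        est7 = pd.Series(state7.beta, index=names7)
        bse7 = pd.Series(se7, index=names7)
        pv7 = pd.Series(
            [wald_test(e, s, df=df7).p_value if s > 0 else 1.0
             for e, s in zip(state7.beta, se7)], index=names7)

        cov_names = [c for c in names7 if c != "intercept"
                     and c not in model._score_names]
        self.intercept = float(est7["intercept"])
        self.covariate_effects = pd.DataFrame({
            "estimate": est7[cov_names], "se": bse7[cov_names],
            "p": pv7[cov_names]})

        glab = list(gv.groups)
        g_est, g_se, g_p = [], [], []
        for k, sc in zip(glab, model._score_names):
            if k in degenerate:
                g_est.append(0.0); g_se.append(np.inf); g_p.append(1.0)
            else:
                g_est.append(float(est7[sc])); g_se.append(float(bse7[sc]))
                g_p.append(float(pv7[sc]))
        self.group_effects = pd.DataFrame(
            {"estimate": g_est, "se": g_se, "p": g_p}, index=pd.Index(glab, name="group"))
        self.group_effects["p_bh"] = bh_adjust(self.group_effects["p"].to_numpy())

        mu = gv.prior_means
        vids = gv.variant_ids
        if state8 is not None:
            cov8 = engine8.covariance(state8)
            se8 = np.sqrt(np.diag(cov8))
            self.weights = pd.DataFrame(
                {"estimate": state8.beta, "se": se8}, index=pd.Index(vids, name="variant"))
        else:  # weights held fixed at the prior means
            self.weights = pd.DataFrame(
                {"estimate": mu.to_numpy(),
                 "se": np.full(len(vids), np.nan)},
                index=pd.Index(vids, name="variant"))
        self._b = self.weights["estimate"]

        # adjusted main effects (only defined when weights were estimated)
        self.variant_group = pd.Series(
            {v: k for k, ids in gv.groups.items() for v in ids})
        if state8 is not None:
            parts = []
            for k in glab:
                ids = gv.groups[k]
                ge, gs = self.group_effects.loc[k, ["estimate", "se"]]
                if not np.isfinite(gs):
                    ge, gs = 0.0, 0.0
                adj = adjusted_effects(ge, gs,
                                       self._b.loc[ids].to_numpy(),
                                       self.weights.loc[ids, "se"].to_numpy(),
                                       mu.loc[ids].to_numpy())
                adj.index = pd.Index(ids, name="variant")
                adj["total_effect"] = ge * self._b.loc[ids].to_numpy()
                parts.append(adj)
            self.adjusted = pd.concat(parts)
        else:
            self.adjusted = None

        # per-individual genetic scores and the predictor decomposition
        Z = gv.dosages
        self.scores = pd.DataFrame(
            {k: genetic_score(Z, self._b, gv.groups[k]) for k in glab},
            index=Z.index)
        self.decomposition_error = self._check_identity()

    def _check_identity(self) -> float:
        """Fixed-sum + deviation decomposition of the genetic predictor."""
        gv = self.model.grouped
        Z = gv.dosages
        mu = gv.prior_means
        lhs = np.zeros(len(Z))
        rhs = np.zeros(len(Z))
        for k, ids in gv.groups.items():
            g = self.group_effects.loc[k, "estimate"]
            bk = self._b.loc[ids].to_numpy()
            zk = Z[ids].to_numpy()
            lhs += g * (zk @ bk)
            rhs += g * (zk @ mu.loc[ids].to_numpy()) + zk @ (g * (bk - mu.loc[ids].to_numpy()))
        err = float(np.max(np.abs(lhs - rhs))) if len(Z) else 0.0
        if err > 1e-8:
            raise AssertionError(
                f"score decomposition violated: max deviation {err:.3e}")
        return err

    def summary(self) -> pd.DataFrame:
        """Tidy per-term table: covariates, group effects, adjusted effects."""
        rows = []
        ce = self.covariate_effects
        for t in ce.index:
            rows.append((t, "covariate", "", ce.at[t, "estimate"], ce.at[t, "se"],
                         np.nan, ce.at[t, "p"]))
        for k in self.group_effects.index:
            r = self.group_effects.loc[k]
            rows.append((str(k), "group_effect", str(k), r["estimate"], r["se"],
                         r["p_bh"], r["p"]))
        if self.adjusted is not None:
            for k in self.group_effects.index:
                for v in self.model.grouped.groups[k]:
                    r = self.adjusted.loc[v]
                    rows.append((str(v), "adjusted_effect", str(k), r["estimate"],
                                 r["se"], np.nan, r["p"]))
        out = pd.DataFrame(rows, columns=["term", "kind", "group", "estimate",
                                          "se", "p_bh", "p"])
        out["lower2se"] = out["estimate"] - 2.0 * out["se"]
        out["upper2se"] = out["estimate"] + 2.0 * out["se"]
        out["total_effect"] = np.nan
        if self.adjusted is not None:
            adj = out["kind"] == "adjusted_effect"
            out.loc[adj, "total_effect"] = self.adjusted["total_effect"].to_numpy()
        return out[SUMMARY_COLUMNS]

    def __repr__(self):  # pragma: no cover
        return (f"<GroupScoreResults K={len(self.group_effects)} "
                f"n_outer={self.n_outer} converged={self.converged}>")


def write_summary(summary: pd.DataFrame, path) -> None:
    """Write the tidy result table as TSV (lossless round-trip)."""
    summary.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"term": str, "kind": str},
                     keep_default_na=True, float_precision="round_trip")
    df["group"] = df["group"].fillna("").astype(str)
    return df[SUMMARY_COLUMNS]


class GroupScoreGLM:
    """Hierarchical GLM with multiplicative group effects x variant weights.

    Parameters
    ----------
    endog : array-like
        Response (continuous, or 0/1 for the binomial family).
    covariates : DataFrame or None
        Numeric covariate columns (dummy-expand factors first; singleton
        variants belong here too).  An intercept is always added.
    grouped : GroupedVariants
        Imputed dosages with the group partition and prior means.
    family : str or Family

    ``fit(scale_mode=...)`` selects the model variant: ``"estimated"``
    (group scales s_k estimated from the data), ``"fixed"`` (all s_k frozen,
    default 0.5), or ``"weights_fixed"`` (b_j pinned at the prior means,
    i.e. the fixed-weights burden/weighted-sum model).
    """

    def __init__(self, endog, covariates, grouped: GroupedVariants,
                 family="gaussian"):
        self.y = np.asarray(endog, float)
        self.grouped = grouped
        self.family = get_family(family)
        n = self.y.shape[0]
        if covariates is None:
            covariates = pd.DataFrame(index=pd.RangeIndex(n))
        self.covariates = pd.DataFrame(covariates).astype(float)
        if len(self.covariates) != n or len(grouped.dosages) != n:
            raise ValueError("endog, covariates and dosages are not conformable")
        self._score_names = [f"__score_{k}" for k in grouped.groups]

    @classmethod
    def from_model_frame(cls, mf) -> "GroupScoreGLM":
        """Build from a :class:`hierglm.data_io.ModelFrame`."""
        gv = GroupedVariants(mf.genotypes[[v for ids in mf.groups.values()
                                           for v in ids]],
                             {k: list(v) for k, v in mf.groups.items()},
                             mf.prior_means)
        return cls(mf.y.to_numpy(), mf.covariates, gv, family=mf.family)

    # -- fitting -----------------------------------------------------------
    def fit(self, scale_mode: str = "estimated", scale_value: float = 0.5,
            tol: float = 1e-5, max_outer: int = 200) -> GroupScoreResults:
        if scale_mode not in ("estimated", "fixed", "weights_fixed"):
            raise ValueError(f"unknown scale_mode {scale_mode!r}")
        gv = self.grouped
        fam = self.family
        glab = list(gv.groups)
        K = len(glab)
        vids = gv.variant_ids
        Z = gv.dosages[vids].to_numpy()
        mu = gv.prior_means.to_numpy()
        kidx = np.concatenate([np.full(len(ids), i)
                               for i, ids in enumerate(gv.groups.values())])
        n = len(self.y)
        C = self.covariates.to_numpy()
        cov_names = list(self.covariates.columns)

        priors7 = ([ColumnPrior("intercept")]
                   + [ColumnPrior("shrunk") for _ in cov_names]
                   + [ColumnPrior("shrunk") for _ in glab])
        names7 = ["intercept"] + cov_names + self._score_names
        priors8 = [ColumnPrior("weight", mean=float(m), group=glab[k])
                   for m, k in zip(mu, kidx)]
        s_fixed = scale_value if scale_mode == "fixed" else None

        b = mu.copy()
        state7: EmState | None = None
        state8: EmState | None = None
        engine7 = engine8 = None
        degenerate: set[str] = set()
        trace: list[float] = []
        converged = False
        p_cov = 1 + len(cov_names)

        for it in range(max_outer):
            S = np.empty((n, K))
            for i, ids in enumerate(gv.groups.values()):
                S[:, i] = Z[:, kidx == i] @ b[kidx == i]
            if it == 0:
                for i, k in enumerate(glab):
                    if float(np.std(S[:, i])) < 1e-12:
                        degenerate.add(k)
                        warnings.warn(
                            f"group {k!r} has a constant genetic score; its "
                            "group effect is not estimable", RuntimeWarning,
                            stacklevel=2)
            X7 = np.concatenate([np.ones((n, 1)), C, S], axis=1)
            design7 = HierDesign(self.y, X7, names7, priors7, fam)
            eng7 = _EmIwls(design7)
            if state7 is None:
                state7 = eng7.initial_state()
            state7 = eng7.step(state7)
            engine7 = eng7

            if scale_mode != "weights_fixed":
                g = state7.beta[p_cov:]
                g_eff = g.copy()
                for i, k in enumerate(glab):
                    if k in degenerate:
                        g_eff[i] = 0.0
                X8 = Z * g_eff[kidx]
                offset8 = X7[:, :p_cov] @ state7.beta[:p_cov]
                design8 = HierDesign(self.y, X8, vids, priors8, fam,
                                     offset=offset8)
                eng8 = _EmIwls(design8, scale_value=s_fixed)
                if state8 is None:
                    state8 = eng8.initial_state()
                state8.phi = state7.phi
                state8 = eng8.step(state8)
                state7 = EmState(**{**state7.__dict__, "phi": state8.phi})
                b = state8.beta
                engine8 = eng8

            trace.append(state7.deviance)
            if len(trace) > 1 and (abs(trace[-1] - trace[-2])
                                   / (abs(trace[-1]) + 0.1) < tol):
                converged = True
                break

        return GroupScoreResults(self, state7, state8, engine7, engine8, b,
                                 trace, converged, degenerate)
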