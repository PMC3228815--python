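"""Replicate engine: empirical power and type-I error across methods.

For each replicate a dataset is simulated, non-segregating variants are
removed (as in the real-data preprocessing), and up to four methods are
fitted:

* ``proposed``          joint group-effect x weight model, scales estimated;
* ``fixed_scale``       same, with all half-Cauchy group scales frozen (0.5);
* ``weights_fixed``     fixed-weight (burden / weighted-sum) model;
* ``all_variants_minp`` per-variant main-effects model; a group's p-value
                        is the unadjusted minimum over its variants.

Significance frequencies at each threshold are tallied per effect term over
converged replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .bglm import fit_all_variants, group_min_pvalue
from .data_io import drop_non_segregating
from .multiplicative import GroupScoreGLM, GroupedVariants
from .simulate import Scenario, simulate_dataset

__all__ = ["PowerTable", "run_study", "compare_methods", "METHODS", "ALPHAS"]

METHODS = ("proposed", "fixed_scale", "weights_fixed", "all_variants_minp")
ALPHAS = (0.05, 0.01, 0.001)

_SCALE_MODE = {"proposed": "estimated", "fixed_scale": "fixed",
               "weights_fixed": "weights_fixed"}


@dataclass
class PowerTable:
    """Per-(method, term, alpha) significance frequencies."""

    table: pd.DataFrame          # columns: method, term, alpha, frequency, n_converged
    n_replicates: int
    n_converged: dict[str, int]
    scenario: Scenario | None = None
    pvalues: dict[str, pd.DataFrame] | None = None   # raw p-values if retained

    def frequency(self, method: str, term: str, alpha: float) -> float:
        t = self.table
        row = t[(t.method == method) & (t.term == term) & (t.alpha == alpha)]
        if row.empty:
            raise KeyError(f"no cell for ({method}, {term}, {alpha})")
        return float(row.frequency.iloc[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @staticmethod
    def read_tsv(path) -> pd.DataFrame:
        return pd.read_csv(path, sep="\t", float_precision="round_trip")


def _dummy_covariates(pheno: pd.DataFrame) -> pd.DataFrame:
    race = pd.Categorical(pheno["race"], categories=sorted(pheno["race"].unique()))
    dm = pd.get_dummies(race, prefix="race", drop_first=True, dtype=float)
    dm.index = pheno.index
    return pd.concat([dm, pheno[["age", "sex", "bmi"]].astype(float)], axis=1)


def _replicate_pvalues(scenario: Scenario, seed: int, methods) -> dict[str, dict]:
    ds = simulate_dataset(scenario, seed)
    gm = drop_non_segregating(ds.genotypes)
    pheno = ds.pheno
    cov = _dummy_covariates(pheno)
    singles = [s for s in ds.singletons if s in gm.variant_ids]
    cov = pd.concat([cov, gm.dosages[singles].set_axis(cov.index)], axis=1)
    y = pheno["y"].to_numpy()

    grouped_ids = [v for v in gm.variant_ids
                   if isinstance(gm.groups.get(v), str)]
    gmap: dict[str, list[str]] = {}
    for k in sorted(set(gm.groups[grouped_ids])):
        gmap[k] = [v for v in grouped_ids if gm.groups[v] == k]
    Z = gm.dosages[grouped_ids].reset_index(drop=True)
    Z.index = cov.index

    out: dict[str, dict] = {}
    cov_terms = list(cov.columns)
    for method in methods:
        pvals: dict[str, float] = {}
        if method == "all_variants_minp":
            fit = fit_all_variants(y, cov, Z, family="binomial"
                                   if scenario.trait == "binary" else "gaussian")
            for t in cov_terms:
                pvals[t] = float(fit.pvalues[t])
            for k, ids in gmap.items():
                pvals[k] = group_min_pvalue(fit, ids)
            out[method] = {"p": pvals, "converged": bool(fit.converged)}
        else:
            gv = GroupedVariants(Z, {k: list(v) for k, v in gmap.items()})
            model = GroupScoreGLM(y, cov, gv,
                                  family="binomial" if scenario.trait == "binary"
                                  else "gaussian")
            res = model.fit(scale_mode=_SCALE_MODE[method])
            for t in cov_terms:
                pvals[t] = float(res.covariate_effects.loc[t, "p"])
            for k in gmap:
                pvals[k] = float(res.group_effects.loc[k, "p"])
            out[method] = {"p": pvals, "converged": res.converged}
    return out


def run_study(scenario: Scenario, methods=METHODS, n_replicates: int = 200,
              base_seed: int = 0, alphas=ALPHAS,
              keep_pvalues: bool = False) -> PowerTable:
    """Simulate ``n_replicates`` datasets and tally significance frequencies.

    Replicate r uses seed ``base_seed + r``.  Non-converged fits are
    excluded from the tallies and counted in ``n_converged``.  With
    ``keep_pvalues`` the raw per-replicate p-values are retained on the
    result (one DataFrame per method, rows = converged replicates).
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    methods = tuple(methods)
    records: dict[str, list[dict[str, float]]] = {m: [] for m in methods}
    for r in range(n_replicates):
        reps = _replicate_pvalues(scenario, base_seed + r, methods)
        for m in methods:
            if reps[m]["converged"]:
                records[m].append(reps[m]["p"])

    rows = []
    n_conv = {m: len(records[m]) for m in methods}
    frames = {m: pd.DataFrame(records[m]) for m in methods if records[m]}
    for m, df in frames.items():
        for term in df.columns:
            for a in alphas:
                freq = float((df[term] < a).mean())
                rows.append((m, term, a, freq, len(df)))
    table = pd.DataFrame(rows, columns=["method", "term", "alpha",
                                        "frequency", "n_converged"])
    return PowerTable(table, n_replicates, n_conv, scenario,
                      frames if keep_pvalues else None)


def compare_methods(power: PowerTable | pd.DataFrame, term: str,
                    alpha: float) -> pd.DataFrame:
    """Rank methods on one cell with Wilson 95% intervals.

    The result is sorted by frequency (descending) and carries a boolean
    attribute column ``significantly_ordered`` set on every row when all
    consecutive intervals are disjoint.
    """
    table = power.table if isinstance(power, PowerTable) else power
    cell = table[(table.term == term) & (table.alpha == alpha)]
    if cell.method.nunique() < 2:
        raise ValueError(f"need >= 2 methods with cell ({term}, {alpha})")
    rows = []
    for _, r in cell.iterrows():
        count = int(round(r.frequency * r.n_converged))
        lo, hi = proportion_confint(count, int(r.n_converged), alpha=0.05,
                                    method="wilson")
        rows.append((r.method, float(r.frequency), float(lo), float(hi),
                     int(r.n_converged)))
    out = pd.DataFrame(rows, columns=["method", "frequency", "ci_low",
                                      "ci_high", "n_converged"])
    out = out.sort_values(["frequency", "method"],
                          ascending=[False, True]).reset_index(drop=True)
    disjoint = all(out.ci_low[i] > out.ci_high[i + 1]
                   for i in range(len(out) - 1))
    out["significantly_ordered"] = disjoint
    return out
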