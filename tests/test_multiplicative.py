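"""Joint group-effect x weight model: identities, reductions, summaries."""

import numpy as np
import pandas as pd
import pytest

import hierglm.bglm as bglm_mod
from hierglm.bglm import ColumnPrior, HierarchicalGLM
from hierglm.glm_core import bh_adjust
from hierglm.multiplicative import (
    GroupScoreGLM,
    GroupedVariants,
    adjusted_effects,
    genetic_score,
    read_summary,
    write_summary,
)


def _toy_grouped(rng, n=150, sizes=(3, 4)):
    cols, groups = [], {}
    mats = []
    for k, J in enumerate(sizes, start=1):
        ids = [f"G{k}_v{j}" for j in range(J)]
        groups[f"G{k}"] = ids
        cols += ids
        mats.append(rng.binomial(2, rng.uniform(0.05, 0.4, J), size=(n, J)))
    Z = pd.DataFrame(np.concatenate(mats, axis=1).astype(float), columns=cols)
    return GroupedVariants(Z, groups)


class TestGroupedVariants:
    def test_rejects_singleton_group(self, rng):
        Z = pd.DataFrame(rng.binomial(2, 0.3, size=(20, 3)).astype(float),
                         columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="singleton"):
            GroupedVariants(Z, {"G1": ["a", "b"], "G2": ["c"]})

    def test_rejects_empty_grouping(self, rng):
        Z = pd.DataFrame(rng.binomial(2, 0.3, size=(20, 2)).astype(float),
                         columns=["a", "b"])
        with pytest.raises(ValueError, match="fit_all_variants"):
            GroupedVariants(Z, {})

    def test_rejects_overlap_and_unknown(self, rng):
        Z = pd.DataFrame(rng.binomial(2, 0.3, size=(20, 3)).astype(float),
                         columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="more than one group"):
            GroupedVariants(Z, {"G1": ["a", "b"], "G2": ["b", "c"]})
        with pytest.raises(KeyError):
            GroupedVariants(Z, {"G1": ["a", "zzz"]})


class TestGeneticScore:
    def test_unit_weights_are_row_sums(self, rng):
        gv = _toy_grouped(rng)
        ids = gv.groups["G1"]
        b = pd.Series(1.0, index=gv.variant_ids)
        np.testing.assert_allclose(genetic_score(gv.dosages, b, ids),
                                   gv.dosages[ids].sum(axis=1))

    def test_zero_weights_and_linearity(self, rng):
        gv = _toy_grouped(rng)
        ids = gv.groups["G2"]
        b = pd.Series(rng.normal(size=len(gv.variant_ids)),
                      index=gv.variant_ids)
        assert np.all(genetic_score(gv.dosages, 0.0 * b, ids) == 0.0)
        np.testing.assert_allclose(genetic_score(gv.dosages, 2.0 * b, ids),
                                   2.0 * genetic_score(gv.dosages, b, ids))

    def test_unknown_variant(self, rng):
        gv = _toy_grouped(rng)
        b = pd.Series(1.0, index=gv.variant_ids)
        with pytest.raises(KeyError):
            genetic_score(gv.dosages, b, ["nope"])


class TestAdjustedEffects:
    def test_delta_se_worked_example(self):
        out = adjusted_effects(0.3, 0.1, np.array([1.4]), np.array([0.2]),
                               np.array([1.0]))
        assert out["estimate"].iloc[0] == pytest.approx(0.3 * 0.4)
        assert out["se"].iloc[0] == pytest.approx(
            np.sqrt(0.3 ** 2 * 0.2 ** 2 + 0.4 ** 2 * 0.1 ** 2), abs=1e-6)

    def test_zero_group_effect_zeroes_adjusted(self):
        out = adjusted_effects(0.0, 0.0, np.array([1.3, 0.2]),
                               np.array([0.0, 0.0]), np.array([1.0, 1.0]))
        np.testing.assert_allclose(out["estimate"], 0.0)
        np.testing.assert_allclose(out["p"], 1.0)  # zero SE edge reports p = 1

    def test_weight_at_prior_mean(self):
        out = adjusted_effects(0.5, 0.0, np.array([1.0]), np.array([0.0]),
                               np.array([1.0]))
        assert out["estimate"].iloc[0] == 0.0
        assert out["p"].iloc[0] == 1.0

    def test_missing_se_rejected(self):
        with pytest.raises(ValueError):
            adjusted_effects(0.5, np.nan, np.array([1.0]), np.array([0.1]),
                             np.array([1.0]))


class TestFit:
    def test_weights_fixed_equals_burden_glm(self, small_grouped):
        """With unit prior means and fixed weights the model is exactly the
        hierarchical GLM on simple-sum burden scores."""
        y, cov, gv = small_grouped
        res = GroupScoreGLM(y, cov, gv).fit(scale_mode="weights_fixed")
        scores = pd.DataFrame(
            {k: gv.dosages[ids].sum(axis=1) for k, ids in gv.groups.items()})
        scores.index = cov.index
        exog = pd.concat([cov, scores], axis=1)
        priors = {c: ColumnPrior("shrunk") for c in exog.columns}
        ref = HierarchicalGLM(y, exog, priors).fit()
        for k in gv.groups:
            assert res.group_effects.loc[k, "estimate"] == \
                pytest.approx(ref.params[k], abs=1e-10)
            assert res.group_effects.loc[k, "se"] == \
                pytest.approx(ref.bse[k], abs=1e-10)
        assert res.deviance == pytest.approx(ref.deviance, abs=1e-8)

    def test_forced_scale_reproduces_fixed_variant(self, small_grouped,
                                                   monkeypatch):
        y, cov, gv = small_grouped
        fixed = GroupScoreGLM(y, cov, gv).fit(scale_mode="fixed",
                                              scale_value=0.5)
        monkeypatch.setattr(bglm_mod, "group_scale_update",
                            lambda lam, t_min=1e-6: 0.5)
        forced = GroupScoreGLM(y, cov, gv).fit(scale_mode="estimated")
        np.testing.assert_allclose(forced.weights["estimate"],
                                   fixed.weights["estimate"], atol=1e-6)
        np.testing.assert_allclose(forced.group_effects["estimate"],
                                   fixed.group_effects["estimate"], atol=1e-6)

    def test_predictor_decomposition_identity(self, small_grouped):
        y, cov, gv = small_grouped
        res = GroupScoreGLM(y, cov, gv).fit()
        assert res.converged
        assert res.decomposition_error <= 1e-8

    def test_group_order_invariance(self, small_grouped):
        y, cov, gv = small_grouped
        res1 = GroupScoreGLM(y, cov, gv).fit()
        flipped = GroupedVariants(gv.dosages,
                                  dict(reversed(list(gv.groups.items()))),
                                  gv.prior_means)
        res2 = GroupScoreGLM(y, cov, flipped).fit()
        for k in gv.groups:
            assert res1.group_effects.loc[k, "estimate"] == \
                pytest.approx(res2.group_effects.loc[k, "estimate"], abs=1e-10)

    def test_row_permutation_invariance(self, small_grouped, rng):
        y, cov, gv = small_grouped
        res1 = GroupScoreGLM(y, cov, gv).fit()
        perm = rng.permutation(len(y))
        gv2 = GroupedVariants(gv.dosages.iloc[perm].reset_index(drop=True),
                              gv.groups, gv.prior_means)
        res2 = GroupScoreGLM(y[perm], cov.iloc[perm].reset_index(drop=True),
                             gv2).fit()
        np.testing.assert_allclose(res1.group_effects["estimate"],
                                   res2.group_effects["estimate"], atol=1e-8)

    def test_degenerate_group_flagged(self, rng):
        n = 100
        Z = pd.DataFrame({
            "a": rng.binomial(2, 0.3, n).astype(float),
            "b": rng.binomial(2, 0.2, n).astype(float),
            "c": np.zeros(n), "d": np.zeros(n)})
        gv = GroupedVariants(Z, {"G1": ["a", "b"], "G2": ["c", "d"]})
        y = rng.normal(size=n)
        with pytest.warns(RuntimeWarning, match="constant genetic score"):
            res = GroupScoreGLM(y, None, gv).fit()
        assert res.group_effects.loc["G2", "se"] == np.inf
        assert res.group_effects.loc["G2", "p"] == 1.0

    def test_opposite_weights_recovered_when_identifiable(self):
        """With strong grouped signal and 40% protective variants the fitted
        weights take opposite signs for risk and protective variants in most
        replicates."""
        from hierglm.simulate import Scenario, simulate_dataset
        from hierglm.data_io import drop_non_segregating
        wins = 0
        for r in range(5):
            sc = Scenario(n=1500, group_sizes=(12, 8), h=(0.08, 0.0),
                          p_neg=(0.4, 0.0), common_groups=())
            ds = simulate_dataset(sc, 600 + r)
            gm = drop_non_segregating(ds.genotypes)
            ids = [v for v in gm.variant_ids if gm.groups.get(v) == "G1"]
            other = [v for v in gm.variant_ids if gm.groups.get(v) == "G2"]
            gv = GroupedVariants(gm.dosages[ids + other],
                                 {"G1": ids, "G2": other})
            res = GroupScoreGLM(ds.pheno["y"].to_numpy(), None, gv).fit()
            g = res.group_effects.loc["G1", "estimate"]
            eff = g * res.weights.loc[ids, "estimate"]
            truth = ds.true_beta.reindex(ids)
            big = truth.abs() > np.median(truth.abs())
            if (np.sign(eff[big]) == np.sign(truth[big])).mean() > 0.5:
                wins += 1
        assert wins >= 3


class TestSummary:
    def test_structure_and_bh(self, small_grouped):
        y, cov, gv = small_grouped
        res = GroupScoreGLM(y, cov, gv).fit()
        tab = res.summary()
        ge = tab[tab["kind"] == "group_effect"]
        assert len(ge) == len(gv.groups)
        np.testing.assert_allclose(ge["p_bh"].to_numpy(),
                                   bh_adjust(ge["p"].to_numpy()))
        assert np.all(ge["p_bh"].to_numpy() >= ge["p"].to_numpy() - 1e-15)
        est, lo, hi = (tab["estimate"].to_numpy(), tab["lower2se"].to_numpy(),
                       tab["upper2se"].to_numpy())
        np.testing.assert_allclose(est - lo, hi - est, atol=1e-12)
        n_adj = len(tab[tab["kind"] == "adjusted_effect"])
        assert n_adj == sum(len(v) for v in gv.groups.values())

    def test_tsv_roundtrip(self, small_grouped, tmp_path):
        y, cov, gv = small_grouped
        tab = GroupScoreGLM(y, cov, gv).fit().summary()
        path = tmp_path / "res.tsv"
        write_summary(tab, path)
        back = read_summary(path)
        pd.testing.assert_frame_equal(tab.reset_index(drop=True), back,
                                      check_exact=False, rtol=0, atol=0)
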