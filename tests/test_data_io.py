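"""Genotype/phenotype IO, imputation, MAF classification, frame assembly."""

import textwrap

import numpy as np
import pandas as pd
import pytest

from hierglm.data_io import (
    GenotypeMatrix,
    build_model_frame,
    classify_by_maf,
    drop_non_segregating,
    impute_mean,
    read_genotypes,
    read_groups,
    read_phenotype,
    write_genotypes,
    write_groups,
    write_phenotype,
)

VCF_HEADER = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=1>
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
    """)


def _write_vcf(tmp_path, body, name="toy.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + body)
    return path


class TestVCF:
    def test_additive_dosages(self, tmp_path):
        path = _write_vcf(tmp_path, "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n")
        g = read_genotypes(path)
        np.testing.assert_allclose(g.dosages["rs1"], [0.0, 1.0, 2.0])

    def test_missing_genotype_flagged(self, tmp_path):
        path = _write_vcf(tmp_path, "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\t./.\t0/0\n")
        g = read_genotypes(path)
        assert bool(g.missing_mask.loc[g.sample_ids[1], "rs1"])
        assert g.maf["rs1"] == pytest.approx(0.25)

    def test_ref_minor_is_flipped(self, tmp_path):
        # ALT frequency 5/6 > 0.5, so REF is the minor allele
        path = _write_vcf(tmp_path, "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t1/1\t1/1\t0/1\n")
        g = read_genotypes(path)
        np.testing.assert_allclose(g.dosages["rs1"], [0.0, 0.0, 1.0])

    def test_multiallelic_rejected(self, tmp_path):
        path = _write_vcf(tmp_path, "1\t100\trs9\tA\tG,T\t.\tPASS\t.\tGT\t0/0\t0/1\t0/0\n")
        with pytest.raises(ValueError, match="rs9"):
            read_genotypes(path)


class TestTSVRoundTrips:
    def test_genotype_roundtrip(self, tmp_path, rng):
        dos = pd.DataFrame(
            rng.binomial(2, 0.3, size=(8, 3)).astype(float),
            index=pd.Index([f"s{i}" for i in range(8)], name="sample_id"),
            columns=["v1", "v2", "v3"])
        dos.iloc[0, 0] = np.nan
        g = GenotypeMatrix(dos)
        path = tmp_path / "g.tsv"
        write_genotypes(g, path)
        back = read_genotypes(path)
        pd.testing.assert_frame_equal(back.dosages, g.dosages)

    def test_phenotype_and_groups_roundtrip(self, tmp_path, rng):
        pheno = pd.DataFrame(
            {"y": rng.normal(size=5), "race": list("ABABA"),
             "age": rng.uniform(20, 60, 5)},
            index=pd.Index([f"s{i}" for i in range(5)], name="sample_id"))
        write_phenotype(pheno, tmp_path / "p.tsv")
        back = read_phenotype(tmp_path / "p.tsv")
        pd.testing.assert_frame_equal(back, pheno)
        groups = pd.Series(["G1", "G1", "G2"], index=["v1", "v2", "v3"])
        write_groups(groups, tmp_path / "gr.tsv")
        back = read_groups(tmp_path / "gr.tsv")
        assert dict(back) == dict(groups)


class TestImpute:
    def test_fills_with_observed_mean(self):
        g = GenotypeMatrix(pd.DataFrame({"v1": [0.0, 1.0, np.nan]}))
        out = impute_mean(g)
        np.testing.assert_allclose(out.dosages["v1"], [0.0, 1.0, 0.5])

    def test_identity_without_missing(self, rng):
        g = GenotypeMatrix(pd.DataFrame(
            rng.binomial(2, 0.3, size=(10, 2)).astype(float), columns=["a", "b"]))
        pd.testing.assert_frame_equal(impute_mean(g).dosages, g.dosages)

    def test_mean_and_maf_preserved(self, rng):
        dos = pd.DataFrame(rng.binomial(2, 0.2, size=(50, 4)).astype(float),
                           columns=list("abcd"))
        mask = rng.random(dos.shape) < 0.2
        dos[mask] = np.nan
        g = GenotypeMatrix(dos)
        out = impute_mean(g)
        assert not out.dosages.isna().any().any()
        np.testing.assert_allclose(out.dosages.mean(),
                                   g.dosages.mean(skipna=True), atol=1e-12)
        np.testing.assert_allclose(out.maf, g.maf, atol=1e-12)

    def test_fully_missing_column_rejected(self):
        g = GenotypeMatrix(pd.DataFrame({"v1": [np.nan, np.nan]}))
        with pytest.raises(ValueError, match="v1"):
            impute_mean(g)


class TestMafClassification:
    def test_threshold_convention(self):
        n = 1000
        dos = pd.DataFrame({
            "below": np.r_[np.ones(18), np.zeros(n - 18)],       # MAF 0.009
            "at": np.r_[np.ones(20), np.zeros(n - 20)],          # MAF 0.010
            "common": np.r_[np.ones(600), np.zeros(n - 600)],    # MAF 0.300
        })
        g = GenotypeMatrix(dos)
        labels = classify_by_maf(g)
        assert labels["below"] == "rare"
        assert labels["at"] == "common"       # boundary assigned common
        assert labels["common"] == "common"
        assert set(labels.unique()) <= {"rare", "common"}

    def test_every_variant_labelled(self, rng):
        g = GenotypeMatrix(pd.DataFrame(
            rng.binomial(2, rng.uniform(0.001, 0.5, 7), size=(200, 7)).astype(float)))
        labels = classify_by_maf(g)
        assert len(labels) == 7 and labels.notna().all()


class TestDropNonSegregating:
    def test_removes_constant_columns(self, rng):
        dos = pd.DataFrame({
            "mono": np.zeros(10),
            "poly": np.r_[np.ones(3), np.zeros(7)],
            "const2": np.full(10, 2.0)})
        g = GenotypeMatrix(dos)
        out = drop_non_segregating(g)
        assert list(out.variant_ids) == ["poly"]

    def test_count_matches_zero_variance_columns(self, rng):
        dos = pd.DataFrame(rng.binomial(2, 0.02, size=(30, 10)).astype(float))
        g = GenotypeMatrix(dos)
        n_zero = int((dos.var(axis=0, ddof=0) == 0).sum())
        assert len(drop_non_segregating(g).variant_ids) == 10 - n_zero


class TestBuildModelFrame:
    def _toy(self, rng, n=30):
        dos = pd.DataFrame(
            rng.binomial(2, [0.3, 0.2, 0.1, 0.25], size=(n, 4)).astype(float),
            index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
            columns=["v1", "v2", "v3", "v4"])
        pheno = pd.DataFrame({
            "y": rng.normal(size=n),
            "race": rng.choice(["AA", "EA", "H"], n),
            "age": rng.uniform(20, 60, n)}, index=dos.index)
        groups = pd.Series(["G1", "G1", "G2"], index=["v1", "v2", "v3"])
        return GenotypeMatrix(dos), pheno, groups

    def test_factor_expansion_and_singletons(self, rng):
        g, pheno, groups = self._toy(rng)
        groups = pd.concat([groups.drop("v3"), pd.Series({"v3": "solo"})])
        mf = build_model_frame(g, pheno, groups)   # v4 is ungrouped -> dropped
        assert {"race_EA", "race_H", "age", "v3"} <= set(mf.covariates.columns)
        assert "race_AA" not in mf.covariates.columns  # alphabetical reference
        assert mf.singletons == ["v3"]
        assert mf.groups == {"G1": ["v1", "v2"]}
        assert "v4" not in mf.genotypes.columns
        # ungrouped variants can instead be routed to the covariates
        mf2 = build_model_frame(g, pheno, groups, uncovered_action="covariate")
        assert "v4" in mf2.covariates.columns

    def test_strict_join_rejects_mismatch(self, rng):
        g, pheno, groups = self._toy(rng)
        with pytest.raises(ValueError, match="intersect"):
            build_model_frame(g, pheno.iloc[:-2], groups)
        mf = build_model_frame(g, pheno.iloc[:-2], groups, join="intersect")
        assert len(mf.y) == 28

    def test_missing_covariate_rows_dropped(self, rng):
        g, pheno, groups = self._toy(rng)
        pheno.loc[pheno.index[0], "age"] = np.nan
        mf = build_model_frame(g, pheno, groups, join="intersect")
        assert len(mf.y) == 29

    def test_row_permutation_leaves_fit_unchanged(self, rng):
        from hierglm.glm_core import iwls_classical
        g, pheno, groups = self._toy(rng, n=60)
        mf1 = build_model_frame(g, pheno, groups)
        perm = rng.permutation(60)
        g2 = GenotypeMatrix(g.dosages.iloc[perm])
        mf2 = build_model_frame(g2, pheno.iloc[perm], groups)
        for mf in (mf1, mf2):
            X = np.column_stack([np.ones(len(mf.y)),
                                 mf.covariates.to_numpy(),
                                 mf.genotypes.to_numpy()])
            mf.coef = iwls_classical(mf.y.to_numpy(), X, "gaussian").params
        np.testing.assert_allclose(mf1.coef, mf2.coef, atol=1e-10)
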