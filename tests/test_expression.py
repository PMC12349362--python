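"""FPKM, DE statistics, FDR, DEG filtering, clustering, PCA and 2^-ddCt."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score
from statsmodels.stats.multitest import multipletests

from rugosity.errors import (
    InsufficientReplicationError,
    InvalidParameterError,
    MeasurementWarning,
)
from rugosity.expression import (
    CtTable,
    ExpressionMatrix,
    bh_fdr,
    de_test,
    delta_delta_ct,
    filter_degs,
    fpkm,
    kmeans_modules,
    pca_samples,
    zscore_profiles,
)
from rugosity.synthetic import CountsConfig, generate_counts


def _tiny_matrix(values: np.ndarray, lengths=None, samples=None) -> ExpressionMatrix:
    n_genes, n_samples = values.shape
    genes = [f"g{i}" for i in range(n_genes)]
    if samples is None:
        samples = [f"M6_r{j + 1}" for j in range(n_samples)]
    frame = pd.DataFrame(values, index=genes, columns=samples)
    lengths = pd.Series(lengths if lengths is not None else 1000, index=genes)
    return ExpressionMatrix(values=frame, gene_length_bp=lengths)


class TestFPKM:
    def test_unit_definition(self):
        # 100 counts on a 1 kb gene in a library of 1e6 reads -> FPKM 100
        m = _tiny_matrix(np.array([[100], [999_900]]), lengths=[1000, 5000], samples=["M6_r1"])
        result = fpkm(m)
        assert result.values.loc["g0", "M6_r1"] == pytest.approx(100.0)

    def test_scale_invariance(self):
        base = np.array([[10, 20], [30, 40], [5, 5]])
        doubled = base.copy()
        doubled[:, 0] *= 2
        f1 = fpkm(_tiny_matrix(base, samples=["M6_r1", "M6_r2"]))
        f2 = fpkm(_tiny_matrix(doubled, samples=["M6_r1", "M6_r2"]))
        np.testing.assert_allclose(
            f1.values["M6_r1"].to_numpy(), f2.values["M6_r1"].to_numpy()
        )

    def test_matches_percell_formula(self, rng):
        counts = rng.integers(0, 500, size=(20, 6))
        lengths = rng.integers(200, 4000, size=20)
        samples = [f"G{s}_r{r}" for s in (6, 10, 14) for r in (1, 2)]
        m = _tiny_matrix(counts, lengths=lengths, samples=samples)
        result = fpkm(m).values.to_numpy()
        expected = counts * 1e9 / (lengths[:, None] * counts.sum(axis=0)[None, :])
        np.testing.assert_allclose(result, expected, rtol=1e-12)


class TestDETest:
    def test_identical_groups_zero_fc(self):
        counts = np.tile(np.array([[10], [100], [1000]]), (1, 4))
        m = _tiny_matrix(counts, samples=["M6_r1", "M6_r2", "G6_r1", "G6_r2"])
        res = de_test(m, ["M6_r1", "M6_r2"], ["G6_r1", "G6_r2"])
        np.testing.assert_allclose(res["log2fc"].to_numpy(), 0.0, atol=1e-12)

    def test_planted_genes_rank_top(self, planted_counts):
        matrix, truth = planted_counts
        res = de_test(
            matrix,
            matrix.samples_matching(genotype="M"),
            matrix.samples_matching(genotype="G"),
        )
        top = set(res.sort_values("p").index[: len(truth.de_genes)])
        assert len(top & set(truth.de_genes)) >= 45

    def test_null_p_values_approximately_uniform(self):
        counts, lengths, _ = generate_counts(
            CountsConfig(n_genes=2000, n_de=0, dispersion=0.05, seed=23)
        )
        m = ExpressionMatrix(values=counts, gene_length_bp=lengths)
        res = de_test(m, m.samples_matching(genotype="M", stage=6), m.samples_matching(genotype="G", stage=6))
        from scipy.stats import kstest

        assert kstest(res["p"], "uniform").statistic < 0.05

    def test_insufficient_replication(self):
        m = _tiny_matrix(np.ones((3, 3)), samples=["M6_r1", "M6_r2", "G6_r1"])
        with pytest.raises(InsufficientReplicationError):
            de_test(m, ["M6_r1", "M6_r2"], ["G6_r1"])


class TestBHFDR:
    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.04])), [0.04])

    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(
            bh_fdr(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr(np.ones(5)), np.ones(5))

    def test_matches_statsmodels_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.uniform(size=int(rng.integers(1, 120)))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_fdr(p), expected, rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            bh_fdr(np.array([0.5, 1.2]))


class TestFilterDEGs:
    def test_boundary_fold_change_inclusive(self):
        table = pd.DataFrame({"log2fc": [1.0], "q": [0.005]}, index=["g"])
        assert filter_degs(table).table["pass"].iloc[0]

    def test_boundary_fdr_strict(self):
        table = pd.DataFrame({"log2fc": [3.0], "q": [0.01]}, index=["g"])
        assert not filter_degs(table).table["pass"].iloc[0]

    def test_matches_exhaustive_filter(self, rng):
        table = pd.DataFrame(
            {"log2fc": rng.normal(0, 2, 20), "q": rng.uniform(0, 0.05, 20)},
            index=[f"g{i}" for i in range(20)],
        )
        result = filter_degs(table)
        expected = {
            g
            for g, row in table.iterrows()
            if abs(row["log2fc"]) >= 1.0 and row["q"] < 0.01
        }
        assert set(result.passing) == expected


class TestZScoreProfiles:
    def test_constant_gene_dropped_with_warning(self):
        counts = np.vstack([np.full(18, 50), np.arange(18) * 10 + 10])
        samples = [f"{g}{s}_r{r}" for g in "GM" for s in (6, 10, 14) for r in (1, 2, 3)]
        m = _tiny_matrix(counts, samples=samples)
        fm = ExpressionMatrix(values=m.values.astype(float), gene_length_bp=m.gene_length_bp, kind="fpkm")
        with pytest.warns(MeasurementWarning):
            profiles = zscore_profiles(fm)
        assert "g0" not in profiles.index

    def test_rows_standardized(self, planted_counts):
        matrix, _ = planted_counts
        profiles = zscore_profiles(fpkm(matrix))
        np.testing.assert_allclose(profiles.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(profiles.std(axis=1, ddof=0), 1.0, atol=1e-9)

    def test_monotone_profile_stays_monotone(self):
        samples = [f"{g}{s}_r1" for g in "GM" for s in (6, 10, 14)]
        counts = np.array([[10, 20, 40, 80, 160, 320]])
        fm = ExpressionMatrix(
            values=pd.DataFrame(counts.astype(float), index=["g0"], columns=samples),
            gene_length_bp=pd.Series([1000], index=["g0"]),
            kind="fpkm",
        )
        profiles = zscore_profiles(fm, group_order=[("G", 6), ("G", 10), ("G", 14), ("M", 6), ("M", 10), ("M", 14)])
        assert np.all(np.diff(profiles.loc["g0"].to_numpy()) > 0)


class TestKMeansModules:
    def _archetype_profiles(self, rng, n_per=40):
        up = np.array([-1.2, -1.0, -0.8, 0.8, 1.0, 1.2])
        down = -up
        rows = []
        for arch in (up, down):
            for _ in range(n_per):
                rows.append(arch + rng.normal(0, 0.05, 6))
        frame = pd.DataFrame(rows, index=[f"g{i}" for i in range(2 * n_per)])
        truth = np.repeat([0, 1], n_per)
        return frame, truth

    def test_two_archetypes_recovered_perfectly(self, rng):
        profiles, truth = self._archetype_profiles(rng)
        assignment = kmeans_modules(profiles, k=2, seed=0)
        assert adjusted_rand_score(truth, assignment.modules.to_numpy()) == 1.0

    def test_module_profiles_are_member_means(self, rng):
        profiles, _ = self._archetype_profiles(rng)
        assignment = kmeans_modules(profiles, k=2, seed=0)
        for module, sub in profiles.groupby(assignment.modules):
            np.testing.assert_allclose(
                assignment.module_profiles.loc[module].to_numpy(),
                sub.mean(axis=0).to_numpy(),
                atol=1e-9,
            )

    def test_deterministic_for_seed(self, rng):
        profiles, _ = self._archetype_profiles(rng)
        a = kmeans_modules(profiles, k=4, seed=3)
        b = kmeans_modules(profiles, k=4, seed=3)
        assert a.modules.equals(b.modules)

    def test_k_exceeding_genes_rejected(self, rng):
        profiles, _ = self._archetype_profiles(rng, n_per=2)
        with pytest.raises(InvalidParameterError):
            kmeans_modules(profiles, k=10, seed=0)


class TestPCASamples:
    def test_duplicated_samples_coincide(self):
        counts = np.array([[10.0, 10.0, 50.0], [90.0, 90.0, 20.0], [5.0, 5.0, 40.0]])
        fm = ExpressionMatrix(
            values=pd.DataFrame(counts, index=list("abc"), columns=["M6_r1", "M6_r2", "G6_r1"]),
            gene_length_bp=pd.Series(1000, index=list("abc")),
            kind="fpkm",
        )
        coords, _ = pca_samples(fm)
        np.testing.assert_allclose(
            coords.loc["M6_r1"].to_numpy(), coords.loc["M6_r2"].to_numpy(), atol=1e-9
        )

    def test_genotype_separation_on_pc1(self, planted_counts):
        matrix, _ = planted_counts
        coords, evr = pca_samples(fpkm(matrix))
        genotypes = [s[0] for s in coords.index]
        score = silhouette_score(coords[["PC1"]].to_numpy(), genotypes)
        assert score > 0

    def test_explained_fractions_non_increasing(self, planted_counts):
        matrix, _ = planted_counts
        _, evr = pca_samples(fpkm(matrix))
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1.0 + 1e-9


class TestDeltaDeltaCt:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "sample", "replicate", "ct_target", "ct_reference"])

    def test_calibrator_is_unity(self):
        data = self._table(
            [
                ["g", "cal", 1, 25.0, 20.0],
                ["g", "s1", 1, 25.0, 20.0],
            ]
        )
        rel = delta_delta_ct(CtTable(data=data, calibrator_sample="cal"))
        assert rel.loc["g", "s1"] == pytest.approx(1.0)

    @pytest.mark.parametrize("ddct, expected", [(1.0, 0.5), (-2.0, 4.0), (0.0, 1.0)])
    def test_exponent_arithmetic(self, ddct, expected):
        data = self._table(
            [
                ["g", "cal", 1, 25.0, 20.0],
                ["g", "s1", 1, 25.0 + ddct, 20.0],
            ]
        )
        rel = delta_delta_ct(CtTable(data=data, calibrator_sample="cal"))
        assert rel.loc["g", "s1"] == pytest.approx(expected)

    def test_technical_replicates_averaged_on_ct_scale(self):
        data = self._table(
            [
                ["g", "cal", 1, 25.0, 20.0],
                ["g", "cal", 2, 25.0, 20.0],
                ["g", "s1", 1, 24.0, 20.0],
                ["g", "s1", 2, 26.0, 20.0],
            ]
        )
        rel = delta_delta_ct(CtTable(data=data, calibrator_sample="cal"))
        assert rel.loc["g", "s1"] == pytest.approx(1.0)  # mean Ct 25 == calibrator

    def test_missing_reference_detected(self):
        data = self._table([["g", "cal", 1, 25.0, 20.0]])
        ct = CtTable(data=data, calibrator_sample="cal")
        data2 = data.copy()
        data2.loc[1] = ["g2", "s1", 1, 22.0, 20.0]
        with pytest.raises(InvalidParameterError):
            delta_delta_ct(CtTable(data=data2, calibrator_sample="cal"))
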