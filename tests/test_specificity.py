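import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cardiospm as c
from cardiospm.io import ExpressionMatrix

from .oracles import anova_oracle, bh_oracle


def make_matrix(arr, samples=None):
    arr = np.asarray(arr, dtype=float)
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    genes = [f"g{i}" for i in range(arr.shape[0])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), "log2")


def design_of(labels, samples=None, regions=("LA", "V", "SA")):
    samples = samples or [f"s{j}" for j in range(len(labels))]
    return c.RegionDesign(pd.Series(labels, index=samples), regions)


class TestRegionDesign:
    def test_merges_ventricles(self):
        meta = pd.DataFrame(
            {"region": ["LA", "LV", "RV", "SA"]},
            index=["a", "b", "c", "d"],
        )
        d = c.RegionDesign.from_metadata(meta)
        assert list(d.assignments) == ["LA", "V", "V", "SA"]

    def test_drops_extra_regions(self):
        meta = pd.DataFrame(
            {"region": ["LA", "V", "SA", "PA", "RA"]}, index=list("abcde")
        )
        d = c.RegionDesign.from_metadata(meta)
        assert list(d.sample_ids) == ["a", "b", "c"]

    def test_rejects_empty_region(self):
        meta = pd.DataFrame({"region": ["LA", "V"]}, index=["a", "b"])
        with pytest.raises(ValueError, match="no samples"):
            c.RegionDesign.from_metadata(meta)


class TestRegionMeans:
    def test_merged_ventricle_mean(self):
        m = make_matrix([[2, 4, 6, 8, 1, 3]])
        meta = pd.DataFrame(
            {"region": ["LV", "LV", "RV", "RV", "LA", "SA"]},
            index=[f"s{j}" for j in range(6)],
        )
        d = c.RegionDesign.from_metadata(meta)
        means = c.region_means(m, d)
        assert means.loc["g0", "V"] == pytest.approx(5.0)

    def test_single_sample_region(self):
        m = make_matrix([[1, 2, 7]])
        means = c.region_means(m, design_of(["LA", "V", "SA"]))
        assert means.loc["g0", "SA"] == 7

    def test_design_sample_missing_from_matrix(self):
        m = make_matrix([[1, 2, 3]])
        d = design_of(["LA", "V", "SA"], samples=["s0", "s1", "zzz"])
        with pytest.raises(ValueError, match="absent"):
            c.region_means(m, d)


class TestComputeSPM:
    @pytest.mark.parametrize(
        "means,expected",
        [
            ((3, 4, 0), (0.6, 0.8, 0.0)),
            ((1, 1, 1), (1 / np.sqrt(3),) * 3),
            ((0, 0, 5), (0.0, 0.0, 1.0)),
        ],
    )
    def test_known_vectors(self, means, expected):
        df = pd.DataFrame([means], index=["g"], columns=["LA", "V", "SA"])
        spm, excluded = c.compute_spm(df)
        assert np.allclose(spm.loc["g"], expected, atol=1e-12)
        assert excluded == []

    def test_unit_sum_of_squares(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.uniform(0, 10, size=(200, 3)), columns=["LA", "V", "SA"])
        spm, _ = c.compute_spm(df)
        assert np.allclose((spm**2).sum(axis=1), 1.0, atol=1e-9)
        assert ((spm >= 0) & (spm <= 1)).all().all()

    @given(
        st.lists(st.floats(0.001, 1e4), min_size=3, max_size=3),
        st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, means, scale):
        df = pd.DataFrame(
            [means, [v * scale for v in means]],
            index=["a", "b"],
            columns=["LA", "V", "SA"],
        )
        spm, _ = c.compute_spm(df)
        assert np.allclose(spm.loc["a"], spm.loc["b"], atol=1e-12)

    def test_zero_vector_excluded(self):
        df = pd.DataFrame(
            [[0, 0, 0], [1, 2, 3]], index=["z", "g"], columns=["LA", "V", "SA"]
        )
        spm, excluded = c.compute_spm(df)
        assert excluded == ["z"]
        assert list(spm.index) == ["g"]

    def test_negative_mean_rejected(self):
        df = pd.DataFrame([[1, -1, 2]], index=["g"], columns=["LA", "V", "SA"])
        with pytest.raises(ValueError, match="negative"):
            c.compute_spm(df)

    def test_monotone_in_own_region(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0.5, 5, size=3)
        df = pd.DataFrame(
            [base, base + [1.0, 0, 0]], index=["lo", "hi"], columns=["LA", "V", "SA"]
        )
        spm, _ = c.compute_spm(df)
        assert spm.loc["hi", "LA"] >= spm.loc["lo", "LA"]
        assert spm.loc["hi", "V"] <= spm.loc["lo", "V"]
        assert spm.loc["hi", "SA"] <= spm.loc["lo", "SA"]


class TestAnova:
    def test_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            sizes = rng.integers(2, 6, size=3)
            groups = [rng.normal(rng.uniform(-2, 2), 1.0, size=s) for s in sizes]
            labels = np.repeat(["LA", "V", "SA"], sizes)
            m = make_matrix([np.concatenate(groups)])
            res = c.anova_per_gene(m, design_of(labels))
            f_ref, p_ref = anova_oracle(groups)
            assert res["F"].iloc[0] == pytest.approx(f_ref, abs=1e-10, rel=1e-10)
            assert res["p"].iloc[0] == pytest.approx(p_ref, abs=1e-10, rel=1e-10)

    def test_separated_group_is_significant(self):
        m = make_matrix([[1.0, 1.1, 1.05, 0.95, 5.0, 5.1]])
        res = c.anova_per_gene(m, design_of(["LA", "LA", "V", "V", "SA", "SA"]))
        f_ref, p_ref = anova_oracle(
            [np.array([1.0, 1.1]), np.array([1.05, 0.95]), np.array([5.0, 5.1])]
        )
        assert res["p"].iloc[0] == pytest.approx(p_ref, rel=1e-10)
        assert res["p"].iloc[0] < 1e-3

    def test_equal_group_means_give_f_zero(self):
        m = make_matrix([[1.0, 3.0, 1.0, 3.0, 1.0, 3.0]])
        res = c.anova_per_gene(m, design_of(["LA", "LA", "V", "V", "SA", "SA"]))
        assert res["F"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_degenerate_constant_gene(self):
        m = make_matrix([[2.0] * 6])
        res = c.anova_per_gene(m, design_of(["LA", "LA", "V", "V", "SA", "SA"]))
        assert bool(res["degenerate"].iloc[0])
        assert res["p"].iloc[0] == 1.0

    def test_zero_within_variance_unequal_means(self):
        m = make_matrix([[1.0, 1.0, 2.0, 2.0, 3.0, 3.0]])
        res = c.anova_per_gene(m, design_of(["LA", "LA", "V", "V", "SA", "SA"]))
        assert res["p"].iloc[0] == 0.0

    def test_rejects_too_few_samples(self):
        m = make_matrix([[1.0, 2.0, 3.0]])
        with pytest.raises(ValueError):
            c.anova_per_gene(m, design_of(["LA", "V", "SA"]))


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.2], [0.2]),
            ([0.05, 1.0], [0.10, 1.0]),
        ],
    )
    def test_known_vectors(self, p, expected):
        assert np.allclose(c.bh_adjust(p), bh_oracle(np.array(p)))
        assert np.allclose(c.bh_adjust(p), expected)

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            assert np.allclose(c.bh_adjust(p), bh_oracle(p), atol=0, rtol=0)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        p = rng.uniform(0, 1, size=500)
        assert np.allclose(c.bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, size=50)
        q = c.bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            c.bh_adjust([0.5, 1.5])


class TestPermutationThreshold:
    def test_constant_genes_give_symmetric_null(self):
        m = make_matrix(np.tile([[4.0], [7.0]], (1, 6)))
        design = design_of(["LA", "LA", "V", "V", "SA", "SA"])
        null = c.permutation_null_threshold(m, design, seed=1)
        assert np.allclose(null.null_spms, 1 / np.sqrt(3), atol=1e-12)
        assert null.tau == pytest.approx(1 / np.sqrt(3))

    def test_seed_determinism(self, small_matrix, small_design):
        a = c.permutation_null_threshold(small_matrix, small_design, seed=9)
        b = c.permutation_null_threshold(small_matrix, small_design, seed=9)
        assert a.tau == b.tau
        assert np.array_equal(a.null_spms, b.null_spms)

    def test_pool_size_is_genes_times_regions(self, small_matrix, small_design):
        null = c.permutation_null_threshold(small_matrix, small_design, seed=0)
        assert null.null_spms.size == small_matrix.n_genes * 3


class TestCalls:
    def make_inputs(self, spm_value, adj_p, tau):
        spm = pd.DataFrame(
            [[spm_value, np.sqrt(max(0.0, 1 - spm_value**2)), 0.0]],
            index=["g"],
            columns=["LA", "V", "SA"],
        )
        tests = pd.DataFrame({"adj_p": [adj_p]}, index=["g"])
        null = c.NullSPMDistribution(np.array([tau]), tau, seed=0)
        return spm, tests, null

    @pytest.mark.parametrize(
        "spm_value,adj_p,tau,expected",
        [
            (0.9, 0.01, 0.8, True),
            (0.9, 0.20, 0.8, False),
            (0.7, 0.01, 0.8, False),
        ],
    )
    def test_gating_logic(self, spm_value, adj_p, tau, expected):
        spm, tests, null = self.make_inputs(spm_value, adj_p, tau)
        calls = c.call_specific_genes(spm, tests, null)
        row = calls[(calls["gene"] == "g") & (calls["region"] == "LA")].iloc[0]
        assert bool(row["is_specific"]) is expected

    def test_multi_region_reports_argmax_only(self):
        spm = pd.DataFrame(
            [[0.72, 0.69, np.sqrt(1 - 0.72**2 - 0.69**2)]],
            index=["g"],
            columns=["LA", "V", "SA"],
        )
        tests = pd.DataFrame({"adj_p": [0.001]}, index=["g"])
        null = c.NullSPMDistribution(np.array([0.6]), 0.6, seed=0)
        calls = c.call_specific_genes(spm, tests, null)
        specific = calls[calls["is_specific"]]
        assert list(specific["region"]) == ["LA"]
        assert bool(specific["multi_region"].iloc[0])

    def test_gene_missing_from_tests_rejected(self):
        spm, tests, null = self.make_inputs(0.9, 0.01, 0.8)
        with pytest.raises(ValueError):
            c.call_specific_genes(spm, tests.drop("g"), null)


class TestZscoreSPM:
    def test_symmetric_column(self):
        df = pd.DataFrame({"LA": [0.2, 0.4, 0.6]})
        z = c.zscore_spm(df)
        assert np.allclose(z["LA"], [-1, 0, 1])

    def test_constant_column_zeroed(self):
        df = pd.DataFrame({"LA": [0.5, 0.5, 0.5], "V": [0.1, 0.2, 0.9]})
        z = c.zscore_spm(df)
        assert (z["LA"] == 0).all()

    def test_columns_standardised(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.uniform(0, 1, size=(50, 3)), columns=["LA", "V", "SA"])
        z = c.zscore_spm(df)
        assert np.allclose(z.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(z.std(axis=0, ddof=1), 1, atol=1e-9)


class TestModelResults:
    def test_fit_summary_and_export(self, tmp_path, tiny_dataset):
        species = "human"
        m = tiny_dataset.matrices[species]
        meta = tiny_dataset.metadata[species]
        model = c.RegionSpecificity.from_dataframe(m.values, meta, tag=species)
        res = model.fit(seed=3)
        text = res.summary()
        assert "tau" in text and "specific genes per region" in text
        assert set(res.spm.columns) == {"LA", "V", "SA"}
        res.to_tsv(tmp_path, prefix="human_")
        assert (tmp_path / "human_spm.tsv").exists()
        assert (tmp_path / "human_calls.tsv").exists()
        assert (tmp_path / "human_null.json").exists()

    def test_specific_genes_match_calls(self, tiny_dataset):
        species = "mouse"
        model = c.RegionSpecificity.from_dataframe(
            tiny_dataset.matrices[species].values, tiny_dataset.metadata[species]
        )
        res = model.fit(seed=4)
        for region in ("LA", "V", "SA"):
            genes = res.specific_genes(region)
            table = res.specific_table()
            assert set(genes) == set(table.loc[table["region"] == region, "gene"])
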