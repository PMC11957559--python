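"""Filtering, TMM, CPM/RPKM and sex means."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from xdose.io import CountMatrix
from xdose.norm import (
    cpm,
    filter_low_expression,
    mean_by_sex,
    rpkm,
    tmm_factors,
)
from xdose.sim import simulate_annotation, simulate_counts

from conftest import study_config


def brute_force_tmm(counts: np.ndarray, trim_m=0.3, trim_a=0.05) -> np.ndarray:
    """Plain-loop evaluation of the published TMM trimming formula."""
    lib = counts.sum(axis=0).astype(float)
    q75 = np.array([np.percentile(counts[:, j], 75) for j in range(counts.shape[1])]) / lib
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = []
    for j in range(counts.shape[1]):
        m_vals, a_vals, weights = [], [], []
        for g in range(counts.shape[0]):
            o, r = counts[g, j], counts[g, ref]
            if o > 0 and r > 0:
                po, pr = o / lib[j], r / lib[ref]
                m_vals.append(np.log2(po / pr))
                a_vals.append(0.5 * np.log2(po * pr))
                weights.append(
                    (lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r)
                )
        m_vals, a_vals, weights = map(np.array, (m_vals, a_vals, weights))
        if len(m_vals) == 0 or np.max(np.abs(m_vals)) < 1e-6:
            factors.append(1.0)
            continue
        n = len(m_vals)
        rm, ra = rankdata(m_vals), rankdata(a_vals)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        f = np.sum(m_vals[keep] / weights[keep]) / np.sum(1.0 / weights[keep])
        factors.append(2.0**f)
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestFilter:
    def test_threshold_counting(self):
        # filler gene pins every library at 1e7 reads, so CPM = count / 10
        counts = pd.DataFrame(
            {
                "a": [6, 4, 0, 9_999_990],
                "b": [6, 4, 0, 9_999_990],
                "c": [4, 4, 0, 9_999_992],
                "d": [4, 4, 0, 9_999_992],
            },
            index=["kept", "low", "zero", "filler"],
        )
        cm = CountMatrix(counts)
        kept = filter_low_expression(cm, min_cpm=0.5, min_libraries=2)
        assert "kept" in kept  # CPM 0.6 in 2 of 4 libraries
        assert "low" not in kept  # CPM 0.4 everywhere
        assert "zero" not in kept

    def test_group_smaller_than_min_libraries_rejected(self, toy_counts):
        with pytest.raises(ValueError, match="at least 2"):
            filter_low_expression(toy_counts, samples=["s1"])


class TestTmm:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [5, 10, 50], "b": [5, 10, 50]})
        f = tmm_factors(CountMatrix(counts))
        assert np.allclose(f, 1.0)

    def test_pure_depth_difference_absorbed_by_library_size(self):
        counts = pd.DataFrame({"a": [10, 20, 400, 80], "b": [20, 40, 800, 160]})
        f = tmm_factors(CountMatrix(counts))
        assert np.allclose(f, 1.0)

    def test_matches_brute_force_on_toy_with_inflated_gene(self):
        rng = np.random.default_rng(42)
        counts = rng.negative_binomial(10, 0.1, size=(50, 4))
        counts[0, 0] = 5000
        cm = CountMatrix(pd.DataFrame(counts, columns=list("abcd")))
        mine = tmm_factors(cm).to_numpy()
        oracle = brute_force_tmm(counts)
        np.testing.assert_allclose(mine, oracle, rtol=1e-12)

    def test_geometric_mean_is_one(self):
        cfg = study_config(21)
        ann = simulate_annotation(cfg)
        cm, _, _ = simulate_counts(cfg, ann)
        f = tmm_factors(cm)
        assert abs(np.exp(np.mean(np.log(f))) - 1.0) < 1e-12

    def test_matches_edger_calcnormfactors(self, tmp_path):
        """Independent oracle: edgeR's calcNormFactors on the same toy matrix."""
        rng = np.random.default_rng(7)
        counts = rng.negative_binomial(5, 0.05, size=(60, 3))
        counts[1, 2] = 8000
        df = pd.DataFrame(counts, index=[f"g{i}" for i in range(60)], columns=list("abc"))
        path = tmp_path / "m.tsv"
        df.to_csv(path, sep="\t")
        script = (
            'suppressMessages(library(edgeR));'
            f'x <- as.matrix(read.delim("{path}", row.names=1));'
            'cat(sprintf("%.10f", calcNormFactors(x, method="TMM")), sep="\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        edger = np.array([float(v) for v in out.stdout.split()])
        mine = tmm_factors(CountMatrix(df)).to_numpy()
        np.testing.assert_allclose(mine, edger, atol=1e-8)


class TestCpmRpkm:
    def test_cpm_definition(self):
        counts = pd.DataFrame({"a": [500, 999_500]})
        assert cpm(CountMatrix(counts)).values.iloc[0, 0] == 500.0

    def test_cpm_scale_invariance(self, toy_counts):
        doubled = CountMatrix(toy_counts.counts * 2)
        pd.testing.assert_frame_equal(cpm(toy_counts).values, cpm(doubled).values)

    def test_norm_factor_divides(self, toy_counts):
        f2 = pd.Series([2.0, 1.0], index=toy_counts.sample_ids)
        a = cpm(toy_counts).values["s1"]
        b = cpm(toy_counts, f2).values["s1"]
        np.testing.assert_allclose(b, a / 2)

    def test_cpm_columns_sum_to_one_million(self, toy_counts):
        assert np.allclose(cpm(toy_counts).values.sum(axis=0), 1e6)

    def test_rpkm_definition_and_length_scaling(self, toy_annotation):
        counts = pd.DataFrame(
            {"s": [100, 100, 100, 100]}, index=toy_annotation.gene_ids
        )
        counts.loc["gA1", "s"] = 1_000_000 - 300
        cm = CountMatrix(counts)
        ex = rpkm(cm, toy_annotation)
        # gene gB1: 100 counts, library 1e6, length 1000 bp -> RPKM 100
        assert ex.values.at["gB1", "s"] == pytest.approx(100.0)
        # gB2 is 2000 bp: half the RPKM at equal counts
        assert ex.values.at["gB2", "s"] == pytest.approx(50.0)

    def test_rpkm_invariant_to_depth_rescaling(self, toy_counts, toy_annotation):
        scaled = CountMatrix(toy_counts.counts * 3)
        pd.testing.assert_frame_equal(
            rpkm(toy_counts, toy_annotation).values, rpkm(scaled, toy_annotation).values
        )

    def test_missing_gene_length_is_error(self, toy_annotation):
        counts = pd.DataFrame({"s": [1, 2]}, index=["gA1", "unknown"])
        with pytest.raises(ValueError, match="unknown"):
            rpkm(CountMatrix(counts), toy_annotation)

    def test_post_normalization_cpm_agrees_across_samples(self):
        cfg = study_config(31)
        ann = simulate_annotation(cfg)
        cm, _, _ = simulate_counts(cfg, ann)
        cm = CountMatrix(cm.counts, tmm_factors(cm))
        col_means = cpm(cm).values.mean(axis=0)
        assert (np.abs(col_means / col_means.mean() - 1) < 0.05).all()


class TestMeanBySex:
    def test_replicate_mean_and_order_invariance(self, toy_annotation):
        from xdose.io import SampleSheet
        from xdose.norm import ExpressionMatrix

        sheet = SampleSheet(
            pd.DataFrame(
                {"sex": ["M", "M", "F"], "tissue": ["t"] * 3, "stage": ["A"] * 3,
                 "replicate": [1, 2, 1]},
                index=pd.Index(["m1", "m2", "f1"], name="sample_id"),
            )
        )
        values = pd.DataFrame({"m1": [10.0], "m2": [20.0], "f1": [7.0]}, index=["g"])
        ex = ExpressionMatrix(values, kind="cpm")
        means = mean_by_sex(ex, sheet)
        assert means.at["g", "M"] == 15.0 and means.at["g", "F"] == 7.0
        ex2 = ExpressionMatrix(values[["f1", "m2", "m1"]], kind="cpm")
        pd.testing.assert_frame_equal(mean_by_sex(ex2, sheet), means)

    def test_absent_sex_is_error(self, toy_annotation):
        from xdose.io import SampleSheet
        from xdose.norm import ExpressionMatrix

        sheet = SampleSheet(
            pd.DataFrame(
                {"sex": ["M"], "tissue": ["t"], "stage": ["A"], "replicate": [1]},
                index=pd.Index(["m1"], name="sample_id"),
            )
        )
        ex = ExpressionMatrix(pd.DataFrame({"m1": [1.0]}, index=["g"]), kind="cpm")
        with pytest.raises(ValueError, match="sex 'F'"):
            mean_by_sex(ex, sheet)
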