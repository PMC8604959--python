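"""Count transforms, TMM / background-bin normalization, filtering,
the NB exact differential test and trajectory clustering."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from crev2g.countstats import (
    NormFactors,
    background_bin_factors,
    cluster_de_genes,
    cpm,
    differential_test,
    filter_by_median_cpm,
    fpkm,
    tmm_factors,
    tpm,
    zscore_rows,
)


def nb_counts(rng, mean, phi, size):
    n = 1 / phi
    return rng.negative_binomial(n, n / (n + np.asarray(mean, dtype=float)), size=size)


class TestTransforms:
    def test_tpm_hand_formula(self):
        counts = pd.DataFrame({"s": [100, 100]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 1000, "g2": 2000})
        t = tpm(counts, lengths)["s"]
        assert t["g1"] == pytest.approx(2 / 3 * 1e6, rel=1e-9)
        assert t["g2"] == pytest.approx(1 / 3 * 1e6, rel=1e-9)

    def test_single_gene_tpm_is_one_million(self):
        counts = pd.DataFrame({"s": [7]}, index=["g"])
        assert tpm(counts, pd.Series({"g": 500}))["s"]["g"] == pytest.approx(1e6)

    def test_tpm_and_cpm_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(1, 500, (50, 4)),
                              columns=list("abcd"))
        lengths = pd.Series(rng.integers(200, 5000, 50), index=counts.index)
        assert np.allclose(tpm(counts, lengths).sum(axis=0), 1e6, rtol=1e-6)
        assert np.allclose(cpm(counts).sum(axis=0), 1e6, rtol=1e-6)

    def test_fpkm_direct_formula(self):
        counts = pd.DataFrame({"s": [100]}, index=["r"])
        out = fpkm(counts, pd.Series({"r": 1000}), lib_sizes=pd.Series({"s": 1e6}))
        assert out["s"]["r"] == pytest.approx(100.0)

    def test_fpkm_scale_invariance(self):
        counts = pd.DataFrame({"s": [40, 60]}, index=["a", "b"])
        lengths = pd.Series({"a": 500, "b": 1500})
        lib = pd.Series({"s": 2e6})
        one = fpkm(counts, lengths, lib)
        two = fpkm(counts * 2, lengths, lib * 2)
        pd.testing.assert_frame_equal(one, two)

    def test_zero_library_size_errors(self):
        counts = pd.DataFrame({"s": [0]}, index=["g"])
        with pytest.raises(ValueError):
            cpm(counts)


def tmm_oracle(counts: pd.DataFrame, trim_m=0.30, trim_a=0.05) -> pd.Series:
    """Direct-formula TMM re-implementation used as the independent oracle."""
    X = counts.to_numpy(float)
    N = X.sum(axis=0)
    q75 = np.array([np.quantile(X[:, j][X[:, j] > 0] / N[j], 0.75)
                    for j in range(X.shape[1])])
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    fac = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        if j == ref:
            continue
        ok = (X[:, j] > 0) & (X[:, ref] > 0)
        pk, pr = X[ok, j] / N[j], X[ok, ref] / N[ref]
        M = np.log2(pk) - np.log2(pr)
        A = 0.5 * (np.log2(pk) + np.log2(pr))
        w = 1.0 / ((N[j] - X[ok, j]) / (N[j] * X[ok, j])
                   + (N[ref] - X[ok, ref]) / (N[ref] * X[ok, ref]))
        n = len(M)
        rm = pd.Series(M).rank().to_numpy()
        ra = pd.Series(A).rank().to_numpy()
        lo_m, lo_a = np.floor(n * trim_m) + 1, np.floor(n * trim_a) + 1
        keep = ((rm >= lo_m) & (rm <= n + 1 - lo_m)
                & (ra >= lo_a) & (ra <= n + 1 - lo_a))
        fac[j] = 2 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
    fac = fac / np.exp(np.mean(np.log(fac)))
    return pd.Series(fac, index=counts.columns)


@pytest.fixture
def shifted_counts():
    """200 genes, 4 samples, 10 genes 8-fold inflated in sample B."""
    rng = np.random.default_rng(7)
    base = nb_counts(rng, 200, 0.05, (200, 4)).astype(float) + 1
    counts = pd.DataFrame(base, columns=list("ABCD"))
    counts.loc[:9, "B"] *= 8
    return counts


class TestTMM:
    def test_identical_libraries_give_unit_factors(self):
        col = np.arange(1, 101)
        counts = pd.DataFrame({s: col for s in "abc"})
        f = tmm_factors(counts).factors
        assert np.allclose(f, 1.0)

    def test_pure_depth_scaling_gives_unit_factors(self):
        rng = np.random.default_rng(1)
        col = rng.integers(10, 1000, 300)
        counts = pd.DataFrame({"a": col, "b": col * 2, "c": col * 5})
        assert np.allclose(tmm_factors(counts).factors, 1.0)

    def test_composition_shift_matches_direct_oracle(self, shifted_counts):
        got = tmm_factors(shifted_counts).factors
        want = tmm_oracle(shifted_counts)
        assert np.allclose(got, want, atol=1e-6)
        # the inflated sample must be scaled down
        assert got["B"] < 1.0

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="no Rscript")
    def test_matches_edger_reference(self, shifted_counts, tmp_path):
        """Cross-check against the published implementation (edgeR)."""
        path = tmp_path / "m.tsv"
        shifted_counts.to_csv(path, sep="\t")
        script = (
            'suppressMessages(library(edgeR));'
            f'x <- read.delim("{path}", row.names=1);'
            'f <- calcNormFactors(as.matrix(x), method="TMM");'
            'cat(sprintf("%.8f ", f/exp(mean(log(f)))))'
        )
        r = subprocess.run(["Rscript", "-e", script], capture_output=True,
                           text=True, check=True)
        want = np.array([float(v) for v in r.stdout.split()])
        assert np.allclose(tmm_factors(shifted_counts).factors, want, atol=1e-5)

    def test_factors_have_geometric_mean_one(self, shifted_counts):
        f = tmm_factors(shifted_counts).factors
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)
        with pytest.raises(ValueError):
            NormFactors(pd.Series([2.0, 2.0]), method="TMM")


class TestBackgroundBins:
    def test_uniform_background_gives_unit_factors(self):
        counts = pd.DataFrame({s: np.full(100, 50) for s in "abc"})
        assert np.allclose(background_bin_factors(counts).factors, 1.0)

    def test_depth_doubling_cancels(self):
        rng = np.random.default_rng(2)
        col = rng.integers(20, 200, 500)
        counts = pd.DataFrame({"a": col, "b": col * 2})
        assert np.allclose(background_bin_factors(counts).factors, 1.0)

    def test_composition_shift_equals_tmm_on_bins(self):
        rng = np.random.default_rng(3)
        base = nb_counts(rng, 100, 0.05, (400, 3)).astype(float) + 1
        bins = pd.DataFrame(base, columns=list("xyz"))
        bins.loc[:39, "z"] *= 6
        got = background_bin_factors(bins).factors
        want = tmm_oracle(bins)
        assert np.allclose(got, want, atol=1e-6)

    def test_all_zero_bins_error(self):
        with pytest.raises(ValueError):
            background_bin_factors(pd.DataFrame({"a": [0, 0], "b": [0, 0]}))


class TestMedianCpmFilter:
    def test_boundary_below_removed_at_equal_kept(self):
        # library sizes 1e6 so CPM == counts
        lib = pd.Series({f"s{i}": 1e6 for i in range(3)})
        counts = pd.DataFrame(
            {"s0": [0.69, 1.2, 0], "s1": [0.69, 1.2, 0], "s2": [0.69, 1.2, 0]},
            index=["below", "at", "zero"],
        )
        kept = filter_by_median_cpm(counts, 1.2, lib_sizes=lib)
        assert list(kept.index) == ["at"]
        kept2 = filter_by_median_cpm(counts, 0.7, lib_sizes=lib)
        assert "below" not in kept2.index and "zero" not in kept2.index


class TestDifferentialTest:
    @staticmethod
    def groups6():
        return pd.Series({f"s{i}": ("A" if i < 3 else "B") for i in range(6)})

    def test_identical_groups_not_called(self):
        counts = pd.DataFrame(
            np.tile(np.arange(10, 100, 10)[:, None], (1, 6)),
            columns=self.groups6().index,
        )
        res = differential_test(counts, self.groups6(), dispersion=0.0)
        assert (res["call"] == "ns").all()
        assert (res["p"] > 0.9).all()

    def test_scale_invariance_of_calls(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(nb_counts(rng, 150, 0.05, (200, 6)),
                              columns=self.groups6().index)
        counts.iloc[:20, 3:] *= 5  # strong planted effect
        lib = counts.sum(axis=0).astype(float)
        res1 = differential_test(counts, self.groups6(), lib_sizes=lib)
        scaled = counts.copy()
        scaled["s5"] = scaled["s5"] * 3
        lib2 = lib.copy()
        lib2["s5"] *= 3
        res2 = differential_test(scaled, self.groups6(), lib_sizes=lib2)
        assert (res1["call"] == res2["call"]).all()

    def test_planted_fold_change_detected(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(nb_counts(rng, 200, 0.05, (100, 6)),
                              columns=self.groups6().index)
        counts.iloc[:10, 3:] = nb_counts(rng, 200 * 8, 0.05, (10, 3))
        # equal library sizes isolate the planted fold change from the
        # composition shift the planted rows themselves induce
        lib = pd.Series(200.0 * 100, index=counts.columns)
        res = differential_test(counts, self.groups6(), lib_sizes=lib)
        assert (res["call"].iloc[:10] == "up").all()
        assert res["log2fc"].iloc[:10].mean() == pytest.approx(3.0, abs=0.5)

    def test_fdr_monotone_in_p_rank(self):
        rng = np.random.default_rng(6)
        counts = pd.DataFrame(nb_counts(rng, 100, 0.1, (300, 6)),
                              columns=self.groups6().index)
        res = differential_test(counts, self.groups6()).sort_values("p")
        assert (np.diff(res["fdr"].to_numpy()) >= -1e-12).all()
        assert (res["fdr"] >= res["p"] - 1e-12).all()

    def test_filter_then_test_equals_test_then_filter_for_p(self):
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(nb_counts(rng, 80, 0.05, (150, 6)),
                              columns=self.groups6().index)
        counts.iloc[100:] = rng.integers(0, 2, (50, 6))  # low rows
        kept = filter_by_median_cpm(counts, 100.0)
        assert 0 < len(kept) < len(counts)
        # library sizes belong to the samples, not the filtered matrix
        lib = counts.sum(axis=0).astype(float)
        res_filtered = differential_test(kept, self.groups6(), lib_sizes=lib)
        res_full = differential_test(counts, self.groups6(), lib_sizes=lib,
                                     dispersion=0.05)
        res_filtered2 = differential_test(kept, self.groups6(), lib_sizes=lib,
                                          dispersion=0.05)
        # p-values depend only on the row itself given a fixed dispersion
        pd.testing.assert_series_equal(
            res_filtered2["p"], res_full.loc[kept.index, "p"], check_names=False
        )
        assert set(res_filtered.columns) == {"log2fc", "p", "fdr", "call"}

    def test_degenerate_groups_error(self):
        counts = pd.DataFrame(np.ones((5, 3)), columns=["a", "b", "c"])
        groups = pd.Series({"a": "A", "b": "A", "c": "B"})
        with pytest.raises(ValueError):
            differential_test(counts, groups)


class TestClustering:
    def test_zscore_rows_mean_zero_sd_one(self):
        rng = np.random.default_rng(9)
        mat = pd.DataFrame(rng.normal(5, 2, (20, 8)))
        z = zscore_rows(mat)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_constant_row_warns_and_zeroes(self):
        mat = pd.DataFrame([[3.0, 3.0, 3.0], [1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning):
            z = zscore_rows(mat)
        assert (z.iloc[0] == 0).all()

    def test_identical_profiles_share_a_cluster(self):
        rng = np.random.default_rng(10)
        base = rng.normal(0, 1, 8)
        rows = [base, base] + [rng.normal(0, 1, 8) for _ in range(10)]
        mat = pd.DataFrame(rows, index=[f"g{i}" for i in range(12)])
        cl = cluster_de_genes(mat, k=4)
        assert cl.assignments["g0"] == cl.assignments["g1"]

    def test_planted_archetypes_recovered(self):
        rng = np.random.default_rng(11)
        stages = ["ESC"] * 4 + ["HP"] * 4 + ["HN"] * 6
        cols = [f"s{i}" for i in range(14)]
        rows, truth = [], []
        for c, (st, sign) in enumerate(
            [("ESC", 1), ("HP", 1), ("HN", 1), ("ESC", -1), ("HP", -1), ("HN", -1)]
        ):
            for _ in range(15):
                base = np.zeros(14)
                base[[i for i, s in enumerate(stages) if s == st]] = 2.0 * sign
                rows.append(base + rng.normal(0, 0.3, 14))
                truth.append(c)
        mat = pd.DataFrame(rows, columns=cols)
        cl = cluster_de_genes(mat, k=6, stage_map=dict(zip(cols, stages)))
        # every planted group maps to exactly one recovered cluster
        df = pd.DataFrame({"truth": truth, "got": cl.assignments.to_numpy()})
        assert (df.groupby("truth")["got"].nunique() == 1).all()
        assert df["got"].nunique() == 6

    def test_too_few_genes_error(self):
        mat = pd.DataFrame(np.ones((3, 5)) + np.arange(5))
        with pytest.raises(ValueError):
            cluster_de_genes(mat, k=6)
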