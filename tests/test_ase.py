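import numpy as np
import pandas as pd
import pytest
from scipy import stats

from alleleauto import ase
from alleleauto.models import CountMatrix, SampleDesign


class TestSizeFactors:
    def test_identical_columns(self):
        counts = np.array([[10, 10], [20, 20], [5, 5]])
        assert ase.size_factors(counts) == pytest.approx([1.0, 1.0])

    def test_doubled_column_hand_toy(self):
        # 5-gene toy, column 2 = 2 x column 1: reference is the
        # geometric mean c*sqrt(2), so factors are (1/sqrt2, sqrt2)
        col = np.array([4.0, 10.0, 7.0, 3.0, 25.0])
        counts = np.column_stack([col, 2 * col])
        f = ase.size_factors(counts)
        assert f == pytest.approx([1 / np.sqrt(2), np.sqrt(2)])
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_single_sample_factor_one(self):
        assert ase.size_factors(np.array([[7], [3]])) == pytest.approx([1.0])

    def test_matches_pydeseq2(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=(200, 4)) + 1
        from pydeseq2.preprocessing import deseq2_norm

        _, expected = deseq2_norm(pd.DataFrame(counts.T))
        # DESeq2 medians log-ratios (geometric midpoint at even n);
        # we median the ratios directly, so agreement is near-exact
        assert ase.size_factors(counts) == pytest.approx(
            np.asarray(expected), rel=1e-4
        )

    def test_no_common_positive_gene(self):
        counts = np.array([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="pseudo"):
            ase.size_factors(counts)
        f = ase.size_factors(counts, allow_pseudo_reference=True)
        assert (f > 0).all()


class TestTPM:
    def test_hand_computation(self):
        tpm = ase.compute_tpm(np.array([[10.0], [20.0]]), [1000.0, 2000.0])
        assert tpm[:, 0] == pytest.approx([500000.0, 500000.0])

    def test_zero_column(self):
        tpm = ase.compute_tpm(np.zeros((3, 1)), [1000.0] * 3)
        assert (tpm == 0).all()

    def test_depth_invariance_and_column_sum(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(30, size=(50, 2)).astype(float)
        lengths = rng.uniform(500, 3000, size=50)
        tpm = ase.compute_tpm(counts, lengths)
        tpm2 = ase.compute_tpm(counts * 2, lengths)
        assert tpm == pytest.approx(tpm2)
        assert tpm.sum(axis=0) == pytest.approx([1e6, 1e6])


class TestBH:
    def test_hand_computation(self):
        assert ase.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_saturated(self):
        assert ase.bh_adjust([0.2]) == pytest.approx([0.2])
        assert ase.bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_nan_passthrough(self):
        out = ase.bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and np.isfinite(out[[0, 2]]).all()


class TestWaldTest:
    def test_identical_groups_null(self):
        a = np.array([30.0, 40.0, 50.0])
        ma, mb, lfc, p = ase.nb_wald_test(a, a, 0.1)
        assert lfc == 0.0 and p == pytest.approx(1.0)

    def test_tenfold_difference(self):
        a = np.array([100.0, 110.0, 90.0])
        b = np.array([10.0, 9.0, 11.0])
        disp = max(ase.moment_dispersion(a, b), 1e-8)
        ma, mb, lfc, p = ase.nb_wald_test(a, b, disp)
        assert 9.0 <= 2.0 ** abs(lfc) <= 10.5
        assert p < 1e-4

    @pytest.mark.parametrize("seed", range(5))
    def test_null_type_one_calibration(self, seed):
        """Null NB draws (mean 50, dispersion 0.1, 3 vs 3): the
        moderated-dispersion Wald test keeps the raw p <= 0.05
        fraction within [0.03, 0.07]."""
        rng = np.random.default_rng(100 + seed)
        n, npairs, mu, disp = 3, 10_000, 50.0, 0.1
        r = 1.0 / disp
        a = rng.negative_binomial(r, r / (r + mu), size=(npairs, n)).astype(float)
        b = rng.negative_binomial(r, r / (r + mu), size=(npairs, n)).astype(float)
        raw = np.array([
            ase.moment_dispersion(a[i], b[i]) for i in range(npairs)
        ])
        pooled = np.maximum(raw, 0.0).mean()
        alphas = np.maximum(np.maximum(raw, 1e-8), pooled)
        pvals = np.array([
            ase.nb_wald_test(a[i], b[i], alphas[i])[3] for i in range(npairs)
        ])
        frac = (pvals <= 0.05).mean()
        assert 0.03 <= frac <= 0.07


class TestClassify:
    @pytest.mark.parametrize(
        "padj, fc, zero, expected",
        [
            (0.2, 3.0, False, "Diff00"),
            (0.04, 1.5, False, "Diff0"),
            (0.04, 5.0, False, "Diff2"),
            (0.01, 10.0, False, "Diff8"),
            (np.nan, np.nan, True, "No_expression"),
            # boundaries: |FC| = 2 -> Diff0, |FC| = 8 -> Diff8
            (0.05, 2.0, False, "Diff0"),
            (0.05, 8.0, False, "Diff8"),
            (np.nan, np.nan, False, "Diff00"),  # untestable
        ],
    )
    def test_category_rules(self, padj, fc, zero, expected):
        assert ase.classify_ase(padj, fc, zero) == expected


def _toy_dataset(seed=0, npairs=60, reps=3, ase_pairs=(), silent_pairs=(),
                 mean=100.0, disp=0.05, l2fc=4.0):
    rng = np.random.default_rng(seed)
    gene_ids, rows = [], []
    r = 1.0 / disp
    for i in range(npairs):
        mu_a = mu_b = mean
        if i in silent_pairs:
            mu_a = mu_b = 0.0
        elif i in ase_pairs:
            mu_a = mean * 2.0 ** l2fc
        for g, mu in ((f"a{i}", mu_a), (f"b{i}", mu_b)):
            gene_ids.append(g)
            if mu == 0:
                rows.append([0] * reps)
            else:
                rows.append(rng.negative_binomial(r, r / (r + mu), reps).tolist())
    samples = [f"cond1_rep{j + 1}" for j in range(reps)]
    cm = CountMatrix(gene_ids, samples, np.array(rows), [1000.0] * len(gene_ids))
    design = SampleDesign({s: "cond1" for s in samples})
    pairs = pd.DataFrame({
        "gene_a": [f"a{i}" for i in range(npairs)],
        "gene_b": [f"b{i}" for i in range(npairs)],
    })
    return cm, design, pairs


class TestAnalyze:
    def test_partition_and_detection(self):
        cm, design, pairs = _toy_dataset(
            seed=1, ase_pairs={0, 1, 2}, silent_pairs={3}
        )
        res = ase.analyze(cm, design, pairs)
        assert len(res) == len(pairs)
        assert set(res["category"]) <= set(ase.CATEGORIES)
        by_pair = res.set_index("gene_a")["category"]
        assert by_pair["a3"] == "No_expression"
        assert {by_pair["a0"], by_pair["a1"], by_pair["a2"]} == {"Diff8"}
        assert res["fc_magnitude"].dropna().values == pytest.approx(
            2.0 ** res["log2fc"].dropna().abs().values
        )

    def test_swap_alleles_mirrors_results(self):
        cm, design, pairs = _toy_dataset(seed=2, ase_pairs={5})
        res = ase.analyze(cm, design, pairs)
        swapped = pairs.rename(columns={"gene_a": "gene_b", "gene_b": "gene_a"})
        res_sw = ase.analyze(cm, design, swapped)
        merged = res.merge(res_sw, left_on="gene_a", right_on="gene_b",
                           suffixes=("", "_sw"))
        assert merged["log2fc"].values == pytest.approx(
            -merged["log2fc_sw"].values, nan_ok=True
        )
        assert merged["padj"].values == pytest.approx(
            merged["padj_sw"].values, nan_ok=True
        )
        assert (merged["category"] == merged["category_sw"]).all()

    def test_untestable_with_few_replicates(self):
        cm, design, pairs = _toy_dataset(reps=2)
        res = ase.analyze(cm, design, pairs, min_replicates=3)
        assert (res["category"] == "Diff00").all()
        assert res["p"].isna().all()


class TestSummaries:
    def test_divergence_by_category_ordering(self):
        res = pd.DataFrame({
            "gene_a": [f"a{i}" for i in range(40)],
            "gene_b": [f"b{i}" for i in range(40)],
            "condition": "cond1",
            "category": ["Diff0"] * 20 + ["Diff8"] * 20,
        })
        rng = np.random.default_rng(3)
        pairs = pd.DataFrame({
            "gene_a": res["gene_a"], "gene_b": res["gene_b"],
            "ka": rng.normal(0.01, 0.001, 40),
            "ks": np.r_[rng.normal(0.02, 0.002, 20), rng.normal(0.06, 0.002, 20)],
            "ka_ks": 0.3,
        })
        summary, tests = ase.divergence_by_category(pairs, res)
        s = summary.set_index("category")
        assert s.loc["Diff8", "ks_median"] > s.loc["Diff0", "ks_median"]
        assert s.loc["Diff2", "n"] == 0 and np.isnan(s.loc["Diff2", "ks_median"])
        ks_test = tests[(tests["metric"] == "ks")
                        & (tests["category_1"] == "Diff0")
                        & (tests["category_2"] == "Diff8")]
        assert ks_test["p"].iloc[0] < 1e-6

    def test_haplotype_bias_all_one_sided(self):
        res = pd.DataFrame({
            "gene_a": ["a0", "a1"], "gene_b": ["b0", "b1"],
            "condition": "cond1", "category": "Diff8",
        })
        pair_chroms = pd.DataFrame({
            "gene_a": ["a0", "a1"], "gene_b": ["b0", "b1"],
            "chrom_a": "cA", "chrom_b": "cB",
        })
        tpm = pd.DataFrame(
            {"cond1_rep1": [10, 10, 1, 1]},
            index=["a0", "a1", "b0", "b1"],
        )
        design = SampleDesign({"cond1_rep1": "cond1"})
        bias = ase.haplotype_bias_counts(res, tpm, pair_chroms, design)
        assert bias["n_a_higher"].iloc[0] == 2
        assert bias["n_b_higher"].iloc[0] == 0

    def test_haplotype_bias_empty(self):
        bias = ase.haplotype_bias_counts(
            pd.DataFrame(columns=["gene_a", "gene_b", "condition", "category"]),
            pd.DataFrame(), pd.DataFrame(columns=["gene_a", "gene_b",
                                                  "chrom_a", "chrom_b"]),
            SampleDesign({}),
        )
        assert bias.empty

    def test_expression_gap_by_category(self):
        res = pd.DataFrame({
            "gene_a": ["a0", "a1"], "gene_b": ["b0", "b1"],
            "condition": "cond1", "category": ["Diff0", "Diff8"],
        })
        tpm = pd.DataFrame(
            {"cond1_rep1": [5.0, 100.0, 4.0, 10.0]},
            index=["a0", "a1", "b0", "b1"],
        )
        design = SampleDesign({"cond1_rep1": "cond1"})
        gap = ase.expression_gap_by_category(res, tpm, design)
        g = gap.set_index("category")
        assert g.loc["Diff0", "gap_median"] == pytest.approx(1.0)
        assert g.loc["Diff8", "gap_median"] == pytest.approx(90.0)
        assert g.loc["Diff2", "n"] == 0
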