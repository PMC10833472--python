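import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from hepaging.io_core import normalize_log1p_cp10k
from hepaging.noise import (
    balance_groups,
    bin_by_noise,
    default_target_umi,
    downsample_umi,
    noise_correlated_genes,
    noise_ratio,
    transcriptional_noise,
)

from conftest import make_count_matrix, make_meta, make_normalized


class TestDownsampleUMI:
    def test_target_above_total_drops_cell(self):
        cm = make_count_matrix([[5], [3], [2]])
        with pytest.warns(UserWarning, match="empty"):
            out = downsample_umi(cm, 11)
        assert out.n_cells == 0

    def test_target_equal_total_keeps_counts(self):
        cm = make_count_matrix([[5], [3], [2]])
        out = downsample_umi(cm, 10)
        np.testing.assert_array_equal(out.counts.toarray().ravel(), [5, 3, 2])

    def test_postcondition_sums_and_bounds(self):
        cm = make_count_matrix([[5], [3], [2]])
        out = downsample_umi(cm, 5, seed=1)
        arr = out.counts.toarray().ravel()
        assert arr.sum() == 5
        assert (arr <= [5, 3, 2]).all()

    def test_mixed_totals_keep_only_reachable_cells(self):
        cm = make_count_matrix([[5, 1], [3, 1], [2, 0]])
        out = downsample_umi(cm, 5, seed=0)
        assert out.cell_ids == ["c0"]
        assert out.total_umi().tolist() == [5]

    def test_hypergeometric_marginal_expectation(self):
        # counts (5,3,2), draw 5: E = n*K/N = (2.5, 1.5, 1.0)
        n_rep = 4000
        cm = make_count_matrix(np.tile([[5], [3], [2]], (1, n_rep)))
        out = downsample_umi(cm, 5, seed=7)
        means = out.counts.toarray().mean(axis=1)
        # binomial-ish SE per entry ~ sqrt(var/n); hypergeometric var < 1
        assert means == pytest.approx([2.5, 1.5, 1.0], abs=3 * np.sqrt(1.0 / n_rep) + 0.02)

    def test_marginal_matches_hypergeom_distribution(self):
        # the marginal of one gene under the multivariate draw is hypergeometric
        n_rep = 5000
        cm = make_count_matrix(np.tile([[6], [4], [5]], (1, n_rep)))
        out = downsample_umi(cm, 7, seed=3)
        drawn = out.counts.toarray()[0]
        support = np.arange(0, 7)
        expected = hypergeom.pmf(support, 15, 6, 7) * n_rep
        observed = np.bincount(drawn, minlength=7)[:7]
        keep = expected > 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        from scipy.stats import chi2 as chi2_dist

        p = chi2_dist.sf(chi2, df=keep.sum() - 1)
        assert p > 0.01

    def test_seed_determinism(self):
        cm = make_count_matrix([[50, 20], [30, 40], [20, 40]])
        a = downsample_umi(cm, 50, seed=9)
        b = downsample_umi(cm, 50, seed=9)
        assert (a.counts != b.counts).nnz == 0

    def test_default_target_umi_floor(self):
        cm = make_count_matrix([[500], [600]])  # total 1100
        assert default_target_umi(cm) == 1100
        cm_small = make_count_matrix([[300], [300]])
        assert default_target_umi(cm_small) == 1000


class TestBalanceGroups:
    def test_min_of_groups_selected(self):
        ids = [f"c{i}" for i in range(160)]
        meta = make_meta(ids, ["young"] * 100 + ["aged"] * 60, ["Hep"] * 160)
        chosen = balance_groups(meta, seed=0)
        sub = meta[meta["cell_id"].isin(chosen)]
        assert len(chosen) == 120
        assert (sub["group"].value_counts() == 60).all()

    def test_small_type_excluded(self):
        ids = [f"c{i}" for i in range(510)]
        meta = make_meta(ids, ["young"] * 10 + ["aged"] * 500, ["Hep"] * 510)
        with pytest.warns(UserWarning, match="excluded"):
            chosen = balance_groups(meta, seed=0, min_cells=20)
        assert chosen == []

    def test_equal_sizes_select_everything(self):
        ids = [f"c{i}" for i in range(80)]
        meta = make_meta(ids, ["young"] * 40 + ["aged"] * 40, ["Hep"] * 80)
        for seed in (0, 1, 2):
            assert sorted(balance_groups(meta, seed=seed)) == sorted(ids)


class TestTranscriptionalNoise:
    def test_identical_cells_zero_noise(self):
        arr = np.tile([[5], [3], [2]], (1, 8))
        cm = make_count_matrix(arr)
        meta = make_meta(cm.cell_ids, ["young"] * 4 + ["aged"] * 4, ["Hep"] * 8)
        nt = transcriptional_noise(cm, meta)
        np.testing.assert_allclose(nt["noise"], 0.0, atol=1e-12)

    def test_two_cell_group_half_distance(self):
        arr = np.array([[10, 2], [2, 10], [8, 8]])
        cm = make_count_matrix(arr)
        meta = make_meta(cm.cell_ids, ["young", "young"], ["Hep", "Hep"])
        nt = transcriptional_noise(cm, meta, gene_min_pct=0.0)
        nm = normalize_log1p_cp10k(cm).dense()
        expected = np.linalg.norm(nm[:, 0] - nm[:, 1]) / 2.0
        np.testing.assert_allclose(nt["noise"], expected)

    def test_three_cell_oracle_arithmetic(self):
        # independent dense recomputation of centroid distances
        rng = np.random.default_rng(0)
        arr = rng.poisson(6, size=(20, 6)) + 1
        cm = make_count_matrix(arr)
        meta = make_meta(cm.cell_ids, ["young"] * 3 + ["aged"] * 3, ["Hep"] * 6)
        nt = transcriptional_noise(cm, meta, gene_min_pct=0.0).set_index("cell_id")
        dense = normalize_log1p_cp10k(cm).dense()
        for cols, cells in [((0, 1, 2), ["c0", "c1", "c2"]), ((3, 4, 5), ["c3", "c4", "c5"])]:
            block = dense[:, list(cols)]
            centroid = block.mean(axis=1)
            for j, cid in enumerate(cells):
                expected = np.sqrt(((block[:, j] - centroid) ** 2).sum())
                assert nt.loc[cid, "noise"] == pytest.approx(expected)

    def test_gene_min_pct_filters_rare_genes(self):
        # a gene detected in 1/10 cells must not contribute at gene_min_pct=0.2
        arr = np.full((5, 10), 4)
        arr[0, :] = 0
        arr[0, 0] = 50  # rare spike would dominate distance if kept
        cm = make_count_matrix(arr)
        meta = make_meta(cm.cell_ids, ["young"] * 10, ["Hep"] * 10)
        nt_filtered = transcriptional_noise(cm, meta, gene_min_pct=0.2)
        nt_kept = transcriptional_noise(cm, meta, gene_min_pct=0.0)
        assert nt_filtered["noise"].max() < nt_kept["noise"].max()

    def test_single_cell_group_flagged(self):
        arr = np.array([[3, 5], [1, 2]])
        cm = make_count_matrix(arr)
        meta = make_meta(cm.cell_ids, ["young", "aged"], ["Hep", "Hep"])
        with pytest.warns(UserWarning, match="single cell"):
            nt = transcriptional_noise(cm, meta, gene_min_pct=0.0)
        np.testing.assert_allclose(nt["noise"], 0.0)

    def test_invariant_to_cell_order_and_gene_relabel(self):
        rng = np.random.default_rng(1)
        arr = rng.poisson(5, size=(15, 12)) + 1
        cm = make_count_matrix(arr)
        groups = ["young"] * 6 + ["aged"] * 6
        meta = make_meta(cm.cell_ids, groups, ["Hep"] * 12)
        nt1 = transcriptional_noise(cm, meta).set_index("cell_id")["noise"]
        perm = rng.permutation(12)
        cm2 = make_count_matrix(
            arr[:, perm],
            gene_ids=[f"renamed{i}" for i in range(15)],
            cell_ids=[f"c{j}" for j in perm],
        )
        meta2 = make_meta(cm2.cell_ids, [groups[j] for j in perm], ["Hep"] * 12)
        nt2 = transcriptional_noise(cm2, meta2).set_index("cell_id")["noise"]
        pd.testing.assert_series_equal(nt1.sort_index(), nt2.sort_index())


class TestNoiseRatio:
    def _table(self, young, aged, cell_type="Hep"):
        rows = [
            {"cell_id": f"y{i}", "cell_type": cell_type, "group": "young", "noise": v}
            for i, v in enumerate(young)
        ] + [
            {"cell_id": f"a{i}", "cell_type": cell_type, "group": "aged", "noise": v}
            for i, v in enumerate(aged)
        ]
        return pd.DataFrame(rows)

    def test_identical_distributions_zero_ratio(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        out = noise_ratio(self._table(vals, vals))
        assert out.iloc[0]["log2_ratio"] == 0.0

    def test_doubled_noise_ratio_one(self):
        young = [1.0, 2.0, 3.0, 4.0, 5.0]
        out = noise_ratio(self._table(young, [2 * v for v in young]))
        assert out.iloc[0]["log2_ratio"] == pytest.approx(1.0)

    def test_zero_young_median_is_na(self):
        out = noise_ratio(self._table([0.0, 0.0, 0.0], [1.0, 2.0, 3.0]))
        assert np.isnan(out.iloc[0]["log2_ratio"])
        assert "undefined" in out.iloc[0]["note"]

    def test_bh_across_cell_types(self):
        t1 = self._table([1, 1.1, 0.9, 1.2], [5, 5.2, 4.9, 5.3], "A")
        t2 = self._table([1, 1.1, 0.9, 1.2], [1.05, 1.0, 1.15, 0.95], "B")
        out = noise_ratio(pd.concat([t1, t2], ignore_index=True))
        assert len(out) == 2
        assert (out["p_adj"] >= out["p"] - 1e-12).all()


class TestNoiseCorrelatedGenes:
    def _setup(self, n_cells=40, n_genes=25, seed=0):
        rng = np.random.default_rng(seed)
        noise_vals = rng.uniform(1, 3, size=n_cells)
        values = rng.normal(1, 0.3, size=(n_genes, n_cells))
        values[0] = noise_vals + 0.5  # r = 1 by construction
        nm = make_normalized(np.abs(values))
        nt = pd.DataFrame(
            {
                "cell_id": nm.cell_ids,
                "cell_type": "Hep",
                "group": ["young"] * (n_cells // 2) + ["aged"] * (n_cells - n_cells // 2),
                "noise": noise_vals,
            }
        )
        return nm, nt

    def test_perfectly_correlated_gene(self):
        nm, nt = self._setup()
        out = noise_correlated_genes(nm, nt, "Hep").set_index("gene")
        assert out.loc["g0", "pearson_r"] == pytest.approx(1.0)
        assert out.loc["g0", "selected"]
        assert out.loc["g0", "direction"] == "positive"

    def test_constant_gene_excluded(self):
        nm, nt = self._setup()
        values = nm.dense()
        values[5] = 2.0
        nm2 = make_normalized(values)
        out = noise_correlated_genes(nm2, nt, "Hep")
        assert "g5" not in set(out["gene"])
        assert out.attrs["n_constant_excluded"] == 1

    def test_threshold_is_strict(self):
        nm, nt = self._setup()
        out = noise_correlated_genes(nm, nt, "Hep")
        some = out[(out["pearson_r"].abs() < 1) & (out["pearson_r"].abs() > 0)].iloc[0]
        strict = noise_correlated_genes(nm, nt, "Hep", r_min=abs(some["pearson_r"]))
        assert not strict.set_index("gene").loc[some["gene"], "selected"]

    def test_null_type_one_error_calibration(self):
        rng = np.random.default_rng(42)
        n_cells, n_genes = 30, 1000
        noise_vals = rng.uniform(1, 3, size=n_cells)
        values = rng.normal(1, 0.3, size=(n_genes, n_cells))
        nm = make_normalized(np.abs(values))
        nt = pd.DataFrame(
            {
                "cell_id": nm.cell_ids,
                "cell_type": "Hep",
                "group": "young",
                "noise": noise_vals,
            }
        )
        out = noise_correlated_genes(nm, nt, "Hep")
        frac = (out["p"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / n_genes) + 0.005)


class TestBinByNoise:
    def _table(self, noises, cell_type="Hep", group="young"):
        return pd.DataFrame(
            {
                "cell_id": [f"c{i:02d}" for i in range(len(noises))],
                "cell_type": cell_type,
                "group": group,
                "noise": noises,
            }
        )

    def test_one_bin_per_cell_is_rank_permutation(self):
        rng = np.random.default_rng(0)
        nt = self._table(rng.uniform(size=20))
        bins = bin_by_noise(nt, n_bins=20)
        assert sorted(bins) == list(range(20))

    def test_forty_cells_four_bins(self):
        rng = np.random.default_rng(1)
        nt = self._table(rng.uniform(size=40))
        bins = bin_by_noise(nt, n_bins=4)
        assert bins.value_counts().tolist() == [10, 10, 10, 10]

    def test_ties_broken_by_cell_id(self):
        nt = self._table([1.0, 1.0, 1.0, 1.0])
        bins = bin_by_noise(nt, n_bins=4)
        assert bins.loc["c00"] == 0 and bins.loc["c03"] == 3

    def test_too_many_bins_raises(self):
        nt = self._table([1.0, 2.0])
        with pytest.raises(ValueError):
            bin_by_noise(nt, n_bins=5)
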