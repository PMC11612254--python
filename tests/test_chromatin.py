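"""DAR selection/grouping, module scores, co-accessibility and TF activity."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from casomics.chromatin import (
    coaccessibility_links,
    dar_stats,
    group_dars,
    link_target_genes,
    module_score,
    peak_activity_pcc,
    select_dars,
    tf_activity,
    tf_activity_and_pcc,
)
from casomics.intervals import GenomicInterval
from casomics.io import CellMatrix


def matrix_from(counts, coords=None, prefix="p"):
    counts = np.asarray(counts)
    n_feat, n_cell = counts.shape
    return CellMatrix(
        counts=sp.csr_matrix(counts),
        feature_ids=[f"{prefix}{i}" for i in range(n_feat)],
        barcodes=[f"c{j}" for j in range(n_cell)],
        feature_coords=coords,
    )


class TestSelectDars:
    TOY = pd.DataFrame(
        {
            "peak": [f"p{i}" for i in range(6)],
            "log2fc": [0.4, 1.0, 0.31, 0.3, -0.5, 2.0],
            "fdr": [0.005, 0.02, 0.009, 0.001, 0.001, 0.01],
        }
    )

    def test_strict_thresholds(self):
        # selected iff fdr < 0.01 AND log2fc > 0.3, both strict
        selected = set(select_dars(self.TOY)["peak"])
        assert selected == {"p0", "p2"}

    def test_boundaries_are_exclusive(self):
        row_fdr = pd.DataFrame({"peak": ["x"], "log2fc": [1.0], "fdr": [0.01]})
        row_lfc = pd.DataFrame({"peak": ["x"], "log2fc": [0.3], "fdr": [0.001]})
        assert len(select_dars(row_fdr)) == 0
        assert len(select_dars(row_lfc)) == 0

    def test_empty_input(self):
        empty = self.TOY.iloc[:0]
        assert len(select_dars(empty)) == 0

    def test_order_invariance(self):
        shuffled = self.TOY.sample(frac=1, random_state=3)
        assert set(select_dars(shuffled)["peak"]) == set(select_dars(self.TOY)["peak"])

    def test_raw_p_values_bh_adjusted(self):
        table = pd.DataFrame(
            {"peak": ["a", "b"], "log2fc": [1.0, 1.0], "p_value": [0.001, 0.5]}
        )
        out = select_dars(table)
        assert list(out["peak"]) == ["a"]
        assert "fdr" in out.columns

    def test_missing_columns_error(self):
        with pytest.raises(ValueError, match="log2fc"):
            select_dars(pd.DataFrame({"peak": ["a"]}))


class TestGroupDars:
    def test_two_planted_archetypes_recovered_exactly(self, rng):
        arch = np.array([[2.0, 0.0, 0.0], [0.0, 0.0, 2.0]])
        truth = rng.integers(0, 2, size=60)
        profiles = pd.DataFrame(arch[truth] + rng.normal(0, 0.05, (60, 3)))
        labels, centers = group_dars(profiles, k=2, seed=0)
        assert adjusted_rand_score(truth, labels.values) == 1.0
        assert centers.shape == (2, 3)

    def test_identical_profiles_single_group(self):
        profiles = pd.DataFrame(np.ones((5, 3)))
        labels, _ = group_dars(profiles, k=1, seed=0)
        assert set(labels) == {0}

    def test_same_seed_is_deterministic(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(40, 4)))
        a, _ = group_dars(profiles, k=4, seed=9)
        b, _ = group_dars(profiles, k=4, seed=9)
        assert (a == b).all()

    def test_fewer_dars_than_k_suggests_smaller_k(self):
        with pytest.raises(ValueError, match="k <="):
            group_dars(pd.DataFrame(np.ones((3, 2))), k=10)


class TestDarStats:
    def test_planted_group_difference_detected(self, rng):
        base = rng.poisson(8, size=(30, 200)).astype(float)
        base[:5, :100] *= 4  # first 5 peaks boosted in the first 100 cells
        m = matrix_from(base)
        groups = np.array(["hot"] * 100 + ["cold"] * 100)
        stats = dar_stats(m, groups, "hot")
        dars = select_dars(stats)
        assert set(dars["peak"]) == {f"p{i}" for i in range(5)}

    def test_degenerate_grouping_rejected(self):
        m = matrix_from(np.ones((3, 4)))
        with pytest.raises(ValueError, match="non-empty"):
            dar_stats(m, ["g"] * 4, "g")


class TestModuleScore:
    def test_null_set_centered_near_zero(self, rng):
        m = matrix_from(rng.poisson(5, size=(200, 1000)))
        peaks = [f"p{i}" for i in rng.choice(200, size=20, replace=False)]
        scores = module_score(m, peaks, seed=1)
        assert abs(scores.mean()) < 0.05

    def test_mean_of_means_within_three_se_over_draws(self, rng):
        m = matrix_from(rng.poisson(5, size=(100, 300)))
        means = []
        for s in range(200):
            peaks = [f"p{i}" for i in
                     np.random.default_rng(s).choice(100, size=10, replace=False)]
            means.append(module_score(m, peaks, seed=s).mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) <= 3 * se + 1e-3

    def test_planted_cells_score_higher(self, rng):
        counts = rng.poisson(5, size=(100, 400)).astype(float)
        counts[:10, :100] *= 3  # 10 peaks open in first 100 cells
        m = matrix_from(counts)
        scores = module_score(m, [f"p{i}" for i in range(10)], seed=0)
        assert scores[:100].mean() > scores[100:].mean()

    def test_degenerate_single_cell_single_peak_scores_zero(self):
        m = matrix_from(np.array([[7]]))
        assert module_score(m, ["p0"], seed=0)[0] == 0.0

    def test_empty_set_rejected(self):
        m = matrix_from(np.ones((2, 2)))
        with pytest.raises(ValueError, match="empty"):
            module_score(m, [])


class TestCoaccessibility:
    def _coords(self, positions, chrom="chr1"):
        return [GenomicInterval(chrom, p, p + 500) for p in positions]

    def test_identical_patterns_link_with_score_one(self, rng):
        pattern = (rng.random(50) > 0.5).astype(int)
        counts = np.vstack([pattern, pattern, 1 - pattern])
        m = matrix_from(counts, coords=self._coords([0, 1000, 2000]))
        links = coaccessibility_links(m, distance_max=10_000)
        pair = links.set_index(["peak_a", "peak_b"])
        assert pair.loc[("p0", "p1"), "score"] == pytest.approx(1.0)

    def test_distance_gate_blocks_far_pairs(self, rng):
        pattern = (rng.random(50) > 0.5).astype(int)
        counts = np.vstack([pattern, pattern])
        m = matrix_from(counts, coords=self._coords([0, 10_000_000]))
        links = coaccessibility_links(m, distance_max=500_000)
        assert links.empty

    def test_independent_peaks_link_rate_matches_permutation_null(self, rng):
        n_cells = 1000
        counts = (rng.random((40, n_cells)) > 0.5).astype(int)
        m = matrix_from(counts, coords=self._coords(list(range(0, 40_000, 1000))))
        links = coaccessibility_links(m, distance_max=50_000)
        n_pairs = 40 * 39 / 2
        observed = len(links) / n_pairs
        # permutation oracle: shuffle one pattern, recompute exceedance
        null = []
        for _ in range(300):
            a = counts[int(rng.integers(40))].astype(float)
            b = rng.permutation(counts[int(rng.integers(40))]).astype(float)
            null.append(np.corrcoef(a, b)[0, 1] > 0.05)
        assert abs(observed - np.mean(null)) < 0.05

    def test_missing_coordinates_rejected(self, rng):
        m = matrix_from(rng.poisson(1, (3, 10)))
        with pytest.raises(ValueError, match="coordinates"):
            coaccessibility_links(m)

    def test_target_genes_by_upstream_overlap(self, multiomics):
        links = coaccessibility_links(multiomics.atac, distance_max=20_000)
        targets = link_target_genes(links, multiomics.atac, multiomics.genes)
        if not targets.empty:
            valid_genes = {g.gene_id for g in multiomics.genes}
            assert set(targets["gene"]) <= valid_genes


class TestTfActivity:
    def test_pcc_plus_minus_one_closed_form(self, rng):
        counts = rng.poisson(6, size=(4, 50)).astype(float)
        m = matrix_from(counts)
        x = counts[0]
        activity = pd.DataFrame(
            {bc: v for bc, v in zip(m.barcodes, np.vstack([x, -x]).T)},
        )
        activity.index = ["same", "negated"]
        pcc = peak_activity_pcc(m, activity, ["p0"])
        by = pcc.set_index("motif")["pcc"]
        assert by["same"] == pytest.approx(1.0)
        assert by["negated"] == pytest.approx(-1.0)

    def test_null_motif_activity_distribution(self, rng):
        m = matrix_from(rng.poisson(5, size=(100, 300)))
        motif = {"null": [f"p{i}" for i in rng.choice(100, 10, replace=False)]}
        act = tf_activity(m, motif, seed=2)
        z = act.loc["null"].values
        assert abs(z.mean()) < 0.6  # centered against its backgrounds

    def test_zero_peak_motif_skipped_with_warning(self, rng):
        m = matrix_from(rng.poisson(5, size=(5, 20)))
        with pytest.warns(UserWarning, match="no peaks"):
            act = tf_activity(m, {"ghost": ["nope"], "ok": ["p0", "p1"]}, seed=0)
        assert list(act.index) == ["ok"]

    def test_planted_driver_ranks_first_at_in_locus_peak(self, multiomics):
        focal = [
            pid for pid, g in multiomics.peak_to_gene.items()
            if g in multiomics.manifest.concordant_genes
        ][:2]
        _, pcc = tf_activity_and_pcc(
            multiomics.atac, multiomics.motif_peaks, focal, seed=5
        )
        for peak in focal:
            top = pcc[pcc["focal_peak"] == peak].iloc[0]
            assert top["motif"] == multiomics.manifest.driver_tf
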