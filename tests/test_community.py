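"""Tests of diversity, ordination, staging and indicator analytics."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from nitflow.community import (
    CommunityTable,
    StageAssignment,
    aggregate_taxa,
    bray_curtis,
    cluster_stages,
    dissimilarity_structure,
    indicator_taxa,
    nmds,
    rarefied_mean_table,
    rarefy_diversity,
)


def _table(counts, days=None, taxonomy=None):
    counts = pd.DataFrame(counts)
    counts.columns = [f"t{j}" for j in range(counts.shape[1])]
    days = np.arange(1.0, counts.shape[0] + 1) if days is None else days
    counts.index = days
    return CommunityTable(counts=counts, sample_days=np.asarray(days, float),
                         taxonomy=taxonomy)


class TestCommunityTable:
    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError, match="negative"):
            _table([[1, -2], [3, 4]])

    def test_rejects_non_increasing_days(self):
        with pytest.raises(ValueError, match="increasing"):
            _table([[1, 2], [3, 4]], days=[2.0, 1.0])

    def test_missing_taxonomy_filled_unclassified(self, small_table):
        t = _table([[1, 2], [3, 4]])
        assert (t.taxonomy.loc[["t0", "t1"], "genus"] == "unclassified").all()


class TestRarefyDiversity:
    def test_uniform_community(self):
        t = _table([[25, 25, 25, 25]])
        prof = rarefy_diversity(t, depth=100, reps=5, seed=0)
        assert prof["richness"].iloc[0] == 4
        assert prof["shannon"].iloc[0] == pytest.approx(np.log(4), abs=1e-9)
        assert prof["pielou"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_single_taxon(self):
        t = _table([[50, 0]])
        prof = rarefy_diversity(t, depth=50, reps=3, seed=0)
        assert prof["richness"].iloc[0] == 1
        assert prof["shannon"].iloc[0] == 0.0
        assert prof["pielou"].iloc[0] == 0.0  # defined limit for S = 1

    def test_full_depth_shannon_formula(self):
        t = _table([[6, 2]])
        prof = rarefy_diversity(t, depth=8, reps=1, seed=0)
        expected = -(0.75 * np.log(0.75) + 0.25 * np.log(0.25))
        assert prof["shannon"].iloc[0] == pytest.approx(expected, abs=1e-4)
        assert prof["shannon"].iloc[0] == pytest.approx(0.5623, abs=1e-4)

    def test_shallow_sample_rejected_by_name(self):
        t = _table([[5, 5], [100, 100]])
        with pytest.raises(ValueError, match="day 1"):
            rarefy_diversity(t, depth=50, reps=1, seed=0)

    def test_index_bounds(self, scenario_table):
        prof = rarefy_diversity(scenario_table, depth=30000, reps=3, seed=1)
        s = prof["richness"].to_numpy()
        assert (prof["pielou"].between(0, 1)).all()
        assert (prof["shannon"].to_numpy() <= np.log(s) + 1e-9).all()

    def test_rarefaction_unbiased(self):
        """Monte-Carlo: expected rarefied relative abundance equals the
        input relative abundance (3-sigma band)."""
        counts = np.array([[600, 300, 100]])
        t = _table(counts)
        reps = 400
        prof_sum = np.zeros(3)
        rng = np.random.default_rng(5)
        for _ in range(reps):
            sub = rng.multivariate_hypergeometric(counts[0], 200)
            prof_sum += sub / 200
        p_true = counts[0] / counts[0].sum()
        se = np.sqrt(p_true * (1 - p_true) / 200 / reps)
        assert np.all(np.abs(prof_sum / reps - p_true) < 3.5 * se)

    def test_rarefied_mean_table_preserves_depth(self, scenario_table):
        rt = rarefied_mean_table(scenario_table, depth=30000, reps=3, seed=0)
        np.testing.assert_allclose(rt.counts.sum(axis=1), 30000, rtol=1e-12)


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        d = bray_curtis(_table([[3, 5, 1], [3, 5, 1]]))
        assert d.data[0, 1] == 0.0

    def test_disjoint_samples_one(self):
        d = bray_curtis(_table([[5, 0], [0, 7]]))
        assert d.data[0, 1] == 1.0

    def test_hand_formula(self):
        d = bray_curtis(_table([[6, 2], [2, 2]]))
        assert d.data[0, 1] == pytest.approx(1 - 8 / 12, abs=1e-12)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            bray_curtis(_table([[0, 0], [1, 2]]))

    def test_range_and_symmetry(self, scenario_table):
        d = bray_curtis(scenario_table).data
        assert (d >= 0).all() and (d <= 1).all()
        np.testing.assert_allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)


class TestNmds:
    def test_duplicate_samples_coincide(self):
        t = _table([[5, 1, 0], [5, 1, 0], [0, 3, 3], [1, 0, 6], [2, 2, 2]])
        res = nmds(bray_curtis(t), k=2, restarts=4, seed=0)
        gap = np.linalg.norm(res.coordinates[0] - res.coordinates[1])
        assert gap <= 1e-6

    def test_embeddable_cloud_has_low_stress(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(15, 3))
        d = squareform(pdist(pts))
        res = nmds(d, k=3, restarts=8, seed=1)
        assert res.stress <= 0.01

    def test_stress_decreases_with_more_iterations(self):
        from sklearn.manifold import MDS
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(12, 4))
        d = squareform(pdist(pts))
        stresses = []
        import warnings as _w
        for it in (3, 300):
            m = MDS(n_components=2, metric=False, dissimilarity="precomputed",
                    n_init=1, random_state=0, max_iter=it,
                    normalized_stress=True)
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                m.fit(d)
            stresses.append(m.stress_)
        assert stresses[1] <= stresses[0] + 1e-12

    def test_k_too_large_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            nmds(d, k=3)

    def test_centered_configuration(self, scenario_table):
        res = nmds(bray_curtis(scenario_table), k=3, restarts=2, seed=0)
        np.testing.assert_allclose(res.coordinates.mean(axis=0), 0, atol=1e-9)


class TestClusterStages:
    def _blobs(self, sizes=(8, 8, 8), spread=0.02, seed=0):
        rng = np.random.default_rng(seed)
        centers = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        rows = []
        for c, n in zip(centers, sizes):
            for _ in range(n):
                p = np.abs(c + rng.normal(0, spread, 3))
                rows.append(1000 * p / p.sum())
        counts = np.rint(rows).astype(int)
        return _table(counts)

    def test_three_blobs_recovered_exactly(self):
        t = self._blobs()
        st = cluster_stages(bray_curtis(t), k_max=8)
        assert st.k == 3
        truth = np.repeat([1, 2, 3], 8)
        assert (st.labels == truth).all()

    def test_forced_k_one(self):
        t = self._blobs()
        st = cluster_stages(bray_curtis(t), k=1)
        assert st.k == 1
        assert (st.labels == 1).all()

    def test_k_max_clipped_with_warning(self):
        t = self._blobs(sizes=(2, 2, 2))
        with pytest.warns(UserWarning, match="clipped"):
            cluster_stages(bray_curtis(t), k_max=10)

    def test_labels_numbered_in_temporal_order(self, scenario_table):
        st = cluster_stages(bray_curtis(scenario_table), k_max=8)
        firsts = [np.flatnonzero(st.labels == lab)[0]
                  for lab in range(1, st.k + 1)]
        assert firsts == sorted(firsts)


class TestIndicatorTaxa:
    def test_single_stage_membership_perfect(self):
        t = _table([[10, 5], [10, 5], [0, 10], [0, 10]])
        stages = StageAssignment(k=2, labels=np.array([1, 1, 2, 2]),
                                 within_dispersion={})
        res = indicator_taxa(t, stages, permutations=99, seed=0)
        row = res[(res.taxon == "t0") & (res.stage == 1)].iloc[0]
        assert row.r_pb == pytest.approx(1.0, abs=1e-12)

    def test_hand_pearson_oracle(self):
        # abundance [2,0,1,0] against membership [1,0,1,0]:
        # r = 1.5 / sqrt(2.75) = 0.9045 (relative abundances equal raw
        # here because each sample is a single-taxon total of constant sum)
        x = np.array([2.0, 0.0, 1.0, 0.0])
        member = np.array([1, 0, 1, 0])
        r = np.corrcoef(x, member)[0, 1]
        assert r == pytest.approx(1.5 / np.sqrt(2.75), abs=1e-12)
        counts = pd.DataFrame({"a": [2, 1, 1, 1], "pad": [0, 1, 0, 1]})
        # normalize so taxon 'a' has relative abundance proportional to x:
        # use totals of 1 to keep proportions equal to counts
        t = _table([[20, 80], [0, 100], [10, 90], [0, 100]])
        stages = StageAssignment(k=2, labels=member + 1,
                                 within_dispersion={})
        res = indicator_taxa(t, stages, permutations=49, seed=1)
        row = res[(res.taxon == "t0") & (res.stage == 2)].iloc[0]
        assert row.r_pb == pytest.approx(0.9045, abs=1e-4)

    def test_constant_taxon_flagged(self):
        t = _table([[5, 5], [5, 5], [5, 5], [5, 5]])
        stages = StageAssignment(k=2, labels=np.array([1, 1, 2, 2]),
                                 within_dispersion={})
        res = indicator_taxa(t, stages, permutations=49, seed=0)
        assert (res.r_pb == 0).all()
        assert (res.p_value == 1).all()

    def test_needs_two_stages(self, small_table):
        stages = StageAssignment(k=1, labels=np.ones(4, int),
                                 within_dispersion={})
        with pytest.raises(ValueError):
            indicator_taxa(small_table, stages)

    def test_brute_force_oracle_random_tables(self):
        """r_pb equals the plain Pearson correlation between relative
        abundance and 0/1 membership, checked per taxon and stage on
        random 10x6 tables."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            counts = rng.integers(0, 50, size=(10, 6)) + 1
            t = _table(counts)
            labels = rng.integers(1, 4, size=10)
            while np.unique(labels).size < 2:
                labels = rng.integers(1, 4, size=10)
            stages = StageAssignment(k=3, labels=labels, within_dispersion={})
            res = indicator_taxa(t, stages, permutations=9, seed=0)
            rel = counts / counts.sum(axis=1, keepdims=True)
            for _, row in res.iterrows():
                j = int(row.taxon[1:])
                member = (labels == row.stage).astype(float)
                if np.std(rel[:, j]) == 0 or np.std(member) == 0:
                    continue
                expected = np.corrcoef(rel[:, j], member)[0, 1]
                assert row.r_pb == pytest.approx(expected, abs=1e-10)


class TestDissimilarityStructure:
    def test_identical_samples_all_gaps_zero(self):
        t = _table([[4, 4]] * 6)
        gap, _ = dissimilarity_structure(bray_curtis(t), t.sample_days)
        assert (gap["mean_dissimilarity"] == 0).all()

    def test_gap_one_pair_count(self):
        t = _table(np.random.default_rng(0).integers(1, 9, (7, 3)))
        gap, _ = dissimilarity_structure(bray_curtis(t), t.sample_days)
        assert gap.loc[gap.gap == 1.0, "n_pairs"].iloc[0] == 6

    def test_monotone_drift_gives_increasing_dissimilarity(self):
        # gradual succession: composition drifts linearly between two poles
        n = 30
        frac = np.linspace(0, 1, n)
        counts = np.column_stack([
            np.rint(1000 * (1 - frac)) + 1, np.rint(1000 * frac) + 1,
        ]).astype(int)
        t = _table(counts)
        gap, _ = dissimilarity_structure(bray_curtis(t), t.sample_days)
        rho = spearmanr(gap["gap"], gap["mean_dissimilarity"]).statistic
        assert rho > 0.8

    def test_within_stage_distributions(self, scenario_table):
        dist = bray_curtis(scenario_table)
        st = cluster_stages(dist, k_max=8)
        _, within = dissimilarity_structure(dist, scenario_table.sample_days,
                                            st)
        assert set(within) == set(range(1, st.k + 1))
        for vals in within.values():
            assert ((vals >= 0) & (vals <= 1)).all()


class TestAggregateTaxa:
    def test_same_genus_sums(self, small_table):
        out = aggregate_taxa(small_table, "genus")
        assert out.counts.loc[1.0, "GenA"] == 8  # 6 + 2
        assert out.counts.loc[1.0, "GenB"] == 0

    def test_totals_preserved(self, scenario_table):
        out = aggregate_taxa(scenario_table, "phylum")
        np.testing.assert_array_equal(out.counts.sum(axis=1),
                                      scenario_table.counts.sum(axis=1))

    def test_distinct_genera_identity(self):
        taxonomy = pd.DataFrame(
            {"genus": ["g1", "g2"], "phylum": ["p", "p"]},
            index=pd.Index(["t0", "t1"], name="taxon_id"))
        t = _table([[3, 4], [1, 2]], taxonomy=taxonomy)
        out = aggregate_taxa(t, "genus")
        np.testing.assert_array_equal(
            out.counts[["g1", "g2"]].to_numpy(),
            t.counts[["t0", "t1"]].to_numpy())

    def test_unknown_rank(self, small_table):
        with pytest.raises(ValueError, match="rank"):
            aggregate_taxa(small_table, "family")
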