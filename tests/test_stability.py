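"""Subsample stability: Jaccard, exclusive mapping, reference labels."""

import itertools

import numpy as np
import pandas as pd
import pytest

from xdec import (DECConfig, StabilityReport, clusterwise_stability,
                  derive_reference_labels, greedy_exclusive_map, jaccard,
                  make_subsets, run_stability, samplewise_stability)
from xdec.pipeline import make_pipeline_factory


def oracle_greedy_map(subset_labels, complete_labels, subset_indices):
    """Explicit sort-and-eliminate simulation of the exclusive mapping."""
    subset_indices = np.asarray(subset_indices)
    comp = np.asarray(complete_labels)[subset_indices]
    sub = np.asarray(subset_labels)
    cells = []
    for a in np.unique(sub):
        A = set(subset_indices[sub == a])
        for b in np.unique(comp):
            B = set(subset_indices[comp == b])
            cells.append((len(A & B) / len(A | B), int(a), int(b)))
    mapping = {}
    used = set()
    while cells:
        cells.sort(key=lambda t: (-t[0], t[1], t[2]))
        j, a, b = cells[0]
        mapping[a] = b
        used.add(b)
        cells = [c for c in cells if c[1] != a and c[2] != b]
    return mapping


class TestSubsetPlan:
    def test_sizes_and_uniqueness(self):
        plan = make_subsets(10, 0.9, R=5, seed=0)
        for s in plan.subsets:
            assert len(s) == 9 and len(set(s)) == 9

    def test_fraction_one_is_full_index_set(self):
        plan = make_subsets(7, 1.0, R=3, seed=0)
        for s in plan.subsets:
            assert np.array_equal(s, np.arange(7))

    def test_seed_reproducibility(self):
        a = make_subsets(50, 0.9, R=4, seed=3)
        b = make_subsets(50, 0.9, R=4, seed=3)
        c = make_subsets(50, 0.9, R=4, seed=4)
        assert all(np.array_equal(x, y) for x, y in zip(a.subsets, b.subsets))
        assert any(not np.array_equal(x, y) for x, y in zip(a.subsets, c.subsets))


class TestJaccard:
    def test_identical_sets(self):
        assert jaccard({1, 2}, {1, 2}) == 1.0

    def test_disjoint_sets(self):
        assert jaccard({1}, {2}) == 0.0

    def test_enumerated_overlap(self):
        assert jaccard({1, 2, 3}, {2, 3, 4}) == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = set(rng.integers(0, 20, size=8).tolist())
        b = set(rng.integers(0, 20, size=8).tolist())
        assert jaccard(a, b) == jaccard(b, a)
        assert 0 <= jaccard(a, b) <= 1

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError):
            jaccard(set(), set())


class TestGreedyExclusiveMap:
    def test_identity_when_labels_equal(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        m = greedy_exclusive_map(labels, labels, np.arange(6))
        assert m == {0: 0, 1: 1, 2: 2}

    def test_recovers_known_permutation(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, size=60)
        sigma = {0: 2, 1: 3, 2: 0, 3: 1}
        renamed = np.array([sigma[l] for l in labels])
        m = greedy_exclusive_map(renamed, labels, np.arange(60))
        assert m == {v: k for k, v in sigma.items()}
        # sigma is also the total-Jaccard maximiser over all permutations
        def total(perm):
            return sum(jaccard(set(np.flatnonzero(renamed == perm[c])),
                               set(np.flatnonzero(labels == c)))
                       for c in range(4))
        best = max(itertools.permutations(range(4)),
                   key=lambda p: total(dict(enumerate(p))))
        assert {v: k for k, v in enumerate(best)} == {k: v for k, v in m.items()}

    def test_tie_breaks_to_lowest_complete_index(self):
        # one subset cluster equally overlapping complete clusters 0 and 1
        subset = np.array([0, 0, 1, 1])
        complete = np.array([0, 1, 2, 2])
        m = greedy_exclusive_map(subset, complete, np.arange(4))
        assert m[1] == 2           # unambiguous best pair maps first
        assert m[0] == 0           # tie between 0 and 1 -> lowest index

    def test_leftover_subset_clusters_unmapped(self):
        subset = np.array([0, 1, 2])
        complete = np.array([0, 0, 1])
        m = greedy_exclusive_map(subset, complete, np.arange(3))
        assert len(m) == 2 and len(set(m.values())) == 2

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_sort_and_eliminate_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        k = int(rng.integers(2, 7))
        idx = np.sort(rng.choice(n * 2, size=n, replace=False))
        sub = rng.integers(0, k, size=n)
        comp = rng.integers(0, k, size=n * 2)
        assert greedy_exclusive_map(sub, comp, idx) == oracle_greedy_map(sub, comp, idx)


class TestReferenceAndStability:
    def _mapped(self, data, ids=None):
        ids = ids or [f"s{i}" for i in range(len(data))]
        return pd.DataFrame(data, index=pd.Index(ids, name="sample_id"),
                            dtype=float)

    def test_modal_reference_label(self):
        mapped = self._mapped([[3, 3, 3], [1, 1, 2], [1, 2, np.nan]])
        ref = derive_reference_labels(mapped)
        assert ref.tolist() == [3, 1, 1]  # constant; majority; tie -> lowest

    def test_uncovered_sample_needs_fallback(self):
        mapped = self._mapped([[1, 1], [np.nan, np.nan]])
        with pytest.raises(ValueError):
            derive_reference_labels(mapped)
        ref = derive_reference_labels(
            mapped, fallback=pd.Series([9, 5], index=mapped.index))
        assert ref.tolist() == [1, 5]

    def test_samplewise_fraction(self):
        # one sample present in 10 subsets, matching its reference label in 7
        row = [1] * 7 + [2] * 3
        mapped = pd.DataFrame([row], index=pd.Index(["a"], name="sample_id"),
                              dtype=float)
        ref = pd.Series([1], index=mapped.index)
        plan = make_subsets(1, 1.0, R=10, seed=0)
        frac = samplewise_stability(mapped, ref, plan)
        assert frac.loc["a"] == pytest.approx(0.7)

    def test_perfectly_stable_all_ones(self):
        plan = make_subsets(4, 1.0, R=3, seed=0)
        mapped = self._mapped([[0] * 3, [0] * 3, [1] * 3, [1] * 3])
        ref = derive_reference_labels(mapped)
        cw = clusterwise_stability(mapped, ref, plan)
        assert (cw["jaccard"] == 1.0).all()
        sw = samplewise_stability(mapped, ref, plan)
        assert (sw == 1.0).all()

    def test_single_flipping_sample_enumeration(self):
        # 4 samples, 2 clusters; sample s1 flips to cluster 1 in runs 2,3
        plan = make_subsets(4, 1.0, R=4, seed=0)
        mapped = self._mapped([[0, 0, 0, 0],
                               [0, 0, 1, 1],
                               [1, 1, 1, 1],
                               [1, 1, 1, 1]])
        ref = derive_reference_labels(mapped)
        assert ref.tolist() == [0, 0, 1, 1]
        cw = clusterwise_stability(mapped, ref, plan)
        # run 0/1: both clusters exact -> J=1; run 2/3: cluster 0 = {s0} vs
        # ref {s0,s1} -> 1/2; cluster 1 = {s1,s2,s3} vs {s2,s3} -> 2/3
        by = cw.pivot(index="subset", columns="reference_cluster", values="jaccard")
        assert np.allclose(by.loc[0], [1, 1]) and np.allclose(by.loc[1], [1, 1])
        assert np.allclose(by.loc[2], [0.5, 2 / 3])
        assert np.allclose(by.loc[3], [0.5, 2 / 3])
        sw = samplewise_stability(mapped, ref, plan)
        assert sw.tolist() == [1.0, 0.5, 1.0, 1.0]

    def test_cluster_absent_from_run_recorded_missing(self):
        plan = make_subsets(3, 1.0, R=2, seed=0)
        mapped = self._mapped([[0, 0], [0, 0], [1, 0]])
        ref = pd.Series([0, 0, 1], index=mapped.index)
        cw = clusterwise_stability(mapped, ref, plan)
        cell = cw[(cw.subset == 1) & (cw.reference_cluster == 1)]["jaccard"]
        assert cell.isna().all()


class TestRunStability:
    def test_full_subset_same_seed_gives_one(self, small_cohort, quick_train):
        ds, *_ = small_cohort
        factory = make_pipeline_factory("xdec", train_config=quick_train,
                                        dec_config=DECConfig(k=3))
        plan = make_subsets(ds.n_samples, 1.0, R=1, seed=5192)
        rep = run_stability(factory, ds, plan, run_seeds=[plan.seed])
        assert rep.overall_jaccard == pytest.approx(1.0)
        assert (rep.samplewise == 1.0).all()

    def test_separated_data_high_stability_and_report_round_trip(
            self, small_cohort, quick_train, tmp_path):
        ds, *_ = small_cohort
        factory = make_pipeline_factory("xdec", train_config=quick_train,
                                        dec_config=DECConfig(k=3))
        plan = make_subsets(ds.n_samples, 0.9, R=3, seed=5192)
        rep = run_stability(factory, ds, plan)
        assert rep.overall_jaccard >= 0.95
        assert 0 <= rep.samplewise.min() <= rep.samplewise.max() <= 1
        rep.write(tmp_path)
        back = StabilityReport.read(tmp_path)
        assert back.overall_jaccard == pytest.approx(rep.overall_jaccard)
        assert back.reference_labels.astype(int).tolist() == \
            rep.reference_labels.astype(int).tolist()
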