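"""Pseudo-bulk simulation: stratified splitting, Dirichlet fractions,
largest-remainder allocation, mixing conservation, dataset composition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nnice import pseudobulk as pb
from nnice import sc_preprocess as scp
from nnice.types import CountMatrix


@pytest.fixture(scope="module")
def pooled():
    from nnice import synthetic as syn

    cfg = syn.SyntheticConfig(n_genes=120, cells_per_type=30, seed=21)
    cells = syn.simulate_cells(syn.generate_signatures(cfg), cfg)
    return scp.pool_matrix(cells, scp.TENX_POOLING_MAP)


class TestSplitReference:
    def test_partition_is_disjoint_and_exhaustive(self, pooled):
        sel, sim = pb.split_reference(pooled, 0.3, seed=0)
        assert set(sel.column_ids) | set(sim.column_ids) == set(pooled.column_ids)
        assert set(sel.column_ids) & set(sim.column_ids) == set()

    def test_half_split_is_balanced_per_type(self, pooled):
        sel, sim = pb.split_reference(pooled, 0.5, seed=0)
        for t in set(pooled.labels):
            n_sel = sel.labels.count(t)
            n_sim = sim.labels.count(t)
            assert n_sel == n_sim

    def test_same_seed_same_split(self, pooled):
        a = pb.split_reference(pooled, 0.3, seed=7)
        b = pb.split_reference(pooled, 0.3, seed=7)
        assert a[0].column_ids == b[0].column_ids

    def test_singleton_type_cannot_stratify(self):
        m = CountMatrix(values=np.ones((3, 3), dtype=int),
                        gene_ids=["G0", "G1", "G2"],
                        column_ids=["a", "b", "c"],
                        labels=["A", "A", "B"])
        with pytest.raises(ValueError, match="'B'"):
            pb.split_reference(m, 0.5, seed=0)


class TestSampleFractions:
    def test_rows_sum_to_one(self):
        fm = pb.sample_fractions(50, list("ABCDEF"), 1.0, seed=0)
        np.testing.assert_allclose(fm.values.sum(axis=1), 1.0, atol=1e-12)

    def test_large_alpha_concentrates_at_uniform(self):
        fm = pb.sample_fractions(20, list("ABCD"), 1e6, seed=0)
        np.testing.assert_allclose(fm.values, 0.25, atol=0.01)

    def test_symmetric_dirichlet_means(self):
        """Monte-Carlo check against known Dirichlet moments: per-type mean
        of Dirichlet(1), k=6 is 1/6 with SE sqrt(var/n)."""
        n, k = 10_000, 6
        fm = pb.sample_fractions(n, list("ABCDEF"), 1.0, seed=123)
        means = fm.values.mean(axis=0)
        se = np.sqrt((1 / k) * (1 - 1 / k) / (k + 1) / n)
        assert np.all(np.abs(means - 1 / k) <= 3 * se)

    def test_k_below_two_is_error(self):
        with pytest.raises(ValueError):
            pb.sample_fractions(5, ["A"], 1.0, seed=0)


class TestAllocateCellCounts:
    def test_even_split(self):
        np.testing.assert_array_equal(
            pb.allocate_cell_counts(np.array([0.5, 0.5]), 500), [250, 250]
        )

    def test_thirds_hand_computed(self):
        counts = pb.allocate_cell_counts(np.array([1, 1, 1]) / 3, 500)
        assert counts.sum() == 500
        assert set(counts) <= {166, 167}
        # largest-remainder by hand: floor gives 166 each (498); the two
        # extra units go to the earliest types on remainder ties
        np.testing.assert_array_equal(counts, [167, 167, 166])

    def test_zero_fraction_gets_zero_cells(self):
        counts = pb.allocate_cell_counts(np.array([0.0, 0.4, 0.6]), 10)
        assert counts[0] == 0

    @settings(deadline=None, max_examples=50)
    @given(
        f=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8),
        C=st.integers(1, 2000),
    )
    def test_sums_exactly_to_C(self, f, C):
        f = np.array(f) / np.sum(f)
        counts = pb.allocate_cell_counts(f, C)
        assert counts.sum() == C
        assert (counts >= 0).all()
        # largest-remainder never deviates more than 1 from the target
        assert np.all(np.abs(counts - C * f) < 1.0)


class TestMixProfiles:
    def test_single_cell_identity(self):
        m = CountMatrix(values=np.array([[3], [0], [7]]),
                        gene_ids=["G0", "G1", "G2"], column_ids=["c0"],
                        labels=["A"])
        profile, used = pb.mix_profiles(m, {"A": 1}, seed=0)
        np.testing.assert_array_equal(profile, [3, 0, 7])
        assert used == ["c0"]

    def test_conservation(self, pooled):
        profile, used = pb.mix_profiles(pooled, {"B cell": 5, "NK cell": 3},
                                        seed=1)
        cols = [pooled.column_ids.index(c) for c in used]
        assert profile.sum() == pooled.values[:, cols].sum()

    def test_three_cell_toy_exhaustive(self):
        """counts {A:2, B:1} on a 3-cell toy: whatever the seeded draw, the
        profile equals the hand-sum of the cells reported as used, and the
        A-draw is one of the 2-subsets enumerated exhaustively."""
        vals = np.array([[1, 10, 100], [2, 20, 200]])
        m = CountMatrix(values=vals, gene_ids=["G0", "G1"],
                        column_ids=["a1", "a2", "b1"],
                        labels=["A", "A", "B"])
        profile, used = pb.mix_profiles(m, {"A": 2, "B": 1}, seed=5)
        assert sorted(used) == ["a1", "a2", "b1"]  # only one possible 2-subset
        np.testing.assert_array_equal(profile, vals.sum(axis=1))

    def test_absent_type_is_error(self, pooled):
        with pytest.raises(KeyError, match="ghost"):
            pb.mix_profiles(pooled, {"ghost": 1}, seed=0)

    def test_small_pool_falls_back_with_replacement(self):
        m = CountMatrix(values=np.array([[1, 5]]), gene_ids=["G0"],
                        column_ids=["a1", "b1"], labels=["A", "B"])
        profile, used = pb.mix_profiles(m, {"A": 4}, seed=0)
        assert len(used) == 4 and set(used) == {"a1"}
        assert profile[0] == 4


class TestSimulateDataset:
    def test_empty_dataset_valid(self, pooled):
        ds = pb.simulate_dataset(pooled, n_samples=0, seed=0)
        assert ds.n_samples == 0

    def test_conservation_all_samples(self, pooled):
        ds = pb.simulate_dataset(pooled, n_samples=10, C=60, seed=4)
        lookup = {c: i for i, c in enumerate(pooled.column_ids)}
        for i in range(ds.n_samples):
            cols = [lookup[c] for c in ds.cells_used[i]]
            assert ds.profiles[i].sum() == pooled.values[:, cols].sum()

    def test_fixed_seed_reproducible(self, pooled):
        a = pb.simulate_dataset(pooled, n_samples=5, C=30, seed=9)
        b = pb.simulate_dataset(pooled, n_samples=5, C=30, seed=9)
        assert np.array_equal(a.profiles, b.profiles)
        assert np.array_equal(a.fractions.values, b.fractions.values)
        assert a.cells_used == b.cells_used

    def test_realized_proportions_near_stored_fractions(self, pooled):
        """|realized - stored| <= K/(2C) per type under largest-remainder."""
        C, k = 200, 6
        ds = pb.simulate_dataset(pooled, n_samples=20, C=C, seed=2)
        label_of = dict(zip(pooled.column_ids, pooled.labels))
        for i in range(ds.n_samples):
            realized = np.array([
                sum(label_of[c] == t for c in ds.cells_used[i]) / C
                for t in ds.fractions.cell_type_names
            ])
            assert np.all(np.abs(realized - ds.fractions.values[i])
                          <= k / (2 * C) + 1e-12)

    def test_one_type_reference_one_hot(self):
        rng = np.random.default_rng(0)
        m = CountMatrix(values=rng.integers(0, 5, (10, 8)),
                        gene_ids=[f"G{i}" for i in range(10)],
                        column_ids=[f"c{i}" for i in range(8)],
                        labels=["A"] * 4 + ["B"] * 4)
        ds = pb.simulate_dataset(m, n_samples=6, C=10, seed=1,
                                 cell_type_names=["A", "B"])
        assert ds.fractions.values.shape == (6, 2)

    def test_write_round_trips_shapes(self, pooled, tmp_path):
        import json

        import pandas as pd

        ds = pb.simulate_dataset(pooled, n_samples=4, C=30, seed=3)
        ds.write(tmp_path)
        prof = pd.read_csv(tmp_path / "profiles.tsv", sep="\t", index_col=0)
        frac = pd.read_csv(tmp_path / "fractions.csv", index_col=0)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert prof.shape == (pooled.n_genes, 4)
        np.testing.assert_allclose(frac.to_numpy(), ds.fractions.values)
        assert manifest["C"] == 30
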