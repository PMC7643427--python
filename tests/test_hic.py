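import numpy as np
import pandas as pd
import pytest

from chromodyn import hic
from chromodyn.hic import ContactMatrix, GenomeLayout
from chromodyn.synthetic import MapRecipe, demo_layout, generate_contact_map

from conftest import dense_cm


def one_chrom_layout(n_bins=40, binsize=2000, cen_frac=0.5):
    ln = n_bins * binsize
    return GenomeLayout(("I",), (ln,), (int(ln * cen_frac),), binsize)


class TestLayout:
    def test_arm_assignment_by_midpoint(self, two_chrom_layout):
        arms = two_chrom_layout.arm_index()
        # centromere at 40 kb = bin 20 boundary; bins 0..19 left, 20..49 right
        assert np.all(arms[:20] == 0)
        assert np.all(arms[20:50] == 1)
        assert np.all(arms[50:70] == 2)

    def test_centromere_must_be_inside(self):
        with pytest.raises(ValueError):
            GenomeLayout(("I",), (1000,), (1000,), 100)

    def test_round_trip_layout_file(self, tmp_path, two_chrom_layout):
        p = tmp_path / "layout.txt"
        p.write_text("I\t100000\t40000\nII\t100000\t40000\n")
        lay = hic.read_layout(p, 2000)
        assert lay == two_chrom_layout


class TestReadContacts:
    def test_three_entries(self, tmp_path, two_chrom_layout):
        p = tmp_path / "c.txt"
        p.write_text("0\t4000\t5\n2000\t8000\t3\n100000\t102000\t2\n")
        cm = hic.read_contacts(p, two_chrom_layout)
        assert cm.matrix[0, 2] == 5
        assert cm.matrix[2, 0] == 5
        assert cm.matrix[50, 51] == 2
        assert cm.matrix.nnz == 6

    def test_duplicate_mirrored_entries_summed(self, tmp_path, two_chrom_layout):
        p = tmp_path / "c.txt"
        p.write_text("0\t4000\t5\n4000\t0\t2\n")
        cm = hic.read_contacts(p, two_chrom_layout)
        assert cm.matrix[0, 2] == 7

    def test_negative_value_errors(self, tmp_path, two_chrom_layout):
        p = tmp_path / "c.txt"
        p.write_text("0\t4000\t-1\n")
        with pytest.raises(ValueError, match="negative"):
            hic.read_contacts(p, two_chrom_layout)

    def test_out_of_range_bin_errors(self, tmp_path, two_chrom_layout):
        p = tmp_path / "c.txt"
        p.write_text("0\t900000\t1\n")
        with pytest.raises(ValueError, match="range"):
            hic.read_contacts(p, two_chrom_layout)

    def test_write_read_round_trip(self, tmp_path, two_chrom_layout):
        rng = np.random.default_rng(0)
        n = two_chrom_layout.n_bins
        a = rng.poisson(5, (n, n)).astype(float)
        cm = dense_cm(two_chrom_layout, a + a.T)
        hic.write_contacts(cm, tmp_path / "o.txt")
        back = hic.read_contacts(tmp_path / "o.txt", two_chrom_layout)
        np.testing.assert_allclose(back.toarray(), cm.toarray())


def sinkhorn_oracle(a, n_iter=5000):
    """Brute-force alternating row/column scaling."""
    m = a.copy()
    for _ in range(n_iter):
        m = m / m.sum(axis=1, keepdims=True)
        m = m / m.sum(axis=0, keepdims=True)
    return m


class TestBalancing:
    def test_kr_equal_row_sums(self, two_chrom_layout):
        rng = np.random.default_rng(5)
        n = two_chrom_layout.n_bins
        a = rng.exponential(size=(n, n))
        cm = dense_cm(two_chrom_layout, a + a.T)
        bal = hic.kr_balance(cm)
        sums = bal.toarray().sum(axis=1)
        np.testing.assert_allclose(sums, sums.mean(), rtol=1e-6)
        assert bal.normalization == "KR"

    def test_kr_matches_sinkhorn_oracle_2x2(self):
        lay = GenomeLayout(("I",), (200,), (100,), 100)
        cm = dense_cm(lay, [[2.0, 1.0], [1.0, 2.0]])
        bal = hic.kr_balance(cm).toarray()
        oracle = sinkhorn_oracle(np.array([[2.0, 1.0], [1.0, 2.0]]))
        np.testing.assert_allclose(bal / bal.sum(), oracle / oracle.sum(), rtol=1e-5)

    def test_kr_idempotent_up_to_scale(self, two_chrom_layout):
        rng = np.random.default_rng(6)
        n = two_chrom_layout.n_bins
        a = rng.exponential(size=(n, n))
        cm = dense_cm(two_chrom_layout, a + a.T)
        once = hic.kr_balance(cm)
        again = hic.kr_balance(ContactMatrix(once.layout, once.matrix))
        r = once.toarray() / np.maximum(again.toarray(), 1e-300)
        vals = r[once.toarray() > 0]
        np.testing.assert_allclose(vals, vals[0], rtol=1e-5)

    def test_kr_masks_empty_rows(self, two_chrom_layout):
        n = two_chrom_layout.n_bins
        a = np.ones((n, n))
        a[3, :] = 0
        a[:, 3] = 0
        bal = hic.kr_balance(dense_cm(two_chrom_layout, a))
        assert bal.mask[3]
        assert not bal.mask[4]

    def test_vc_sqrt_hand_computed_3x3(self):
        lay = GenomeLayout(("I",), (300,), (150,), 100)
        a = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 6.0], [4.0, 6.0, 0.0]])
        out = hic.vc_sqrt_balance(dense_cm(lay, a)).toarray()
        cov = a.sum(axis=1)
        expected = a / np.sqrt(np.outer(cov, cov))
        np.testing.assert_allclose(out, expected)

    def test_vc_sqrt_uniform_stays_uniform(self, uniform_cm):
        out = hic.vc_sqrt_balance(uniform_cm).toarray()
        assert np.allclose(out, out[0, 0])

    def test_vc_sqrt_global_scaling_equivariance(self, two_chrom_layout):
        rng = np.random.default_rng(8)
        n = two_chrom_layout.n_bins
        a = rng.poisson(10, (n, n)).astype(float)
        a = a + a.T
        o1 = hic.vc_sqrt_balance(dense_cm(two_chrom_layout, a)).toarray()
        o4 = hic.vc_sqrt_balance(dense_cm(two_chrom_layout, 4 * a)).toarray()
        np.testing.assert_allclose(o4, o1, rtol=1e-12)


class TestClassification:
    def test_single_arm_only(self, two_chrom_layout):
        n = two_chrom_layout.n_bins
        a = np.zeros((n, n))
        a[2, 5] = a[5, 2] = 10  # both bins on I left arm
        props = hic.classify_contacts(dense_cm(two_chrom_layout, a))
        assert props["intra_arm"] == pytest.approx(1.0)

    def test_hand_placed_proportions(self, two_chrom_layout):
        n = two_chrom_layout.n_bins
        a = np.zeros((n, n))
        a[2, 5] = a[5, 2] = 6        # intra-arm (I_L)
        a[2, 30] = a[30, 2] = 3      # inter-arm (I_L vs I_R)
        a[2, 55] = a[55, 2] = 1      # trans (I vs II)
        props = hic.classify_contacts(dense_cm(two_chrom_layout, a))
        assert props["intra_arm"] == pytest.approx(0.6)
        assert props["inter_arm"] == pytest.approx(0.3)
        assert props["trans"] == pytest.approx(0.1)

    def test_proportions_sum_to_one_and_scale_invariant(self, two_chrom_layout):
        rng = np.random.default_rng(9)
        n = two_chrom_layout.n_bins
        a = rng.poisson(4, (n, n)).astype(float)
        a = a + a.T
        p1 = hic.classify_contacts(dense_cm(two_chrom_layout, a))
        p9 = hic.classify_contacts(dense_cm(two_chrom_layout, 9 * a))
        assert sum(p1.values()) == pytest.approx(1.0)
        for k in p1:
            assert p1[k] == pytest.approx(p9[k], rel=1e-12)


class TestContactDecay:
    def test_single_distance_single_band(self):
        lay = one_chrom_layout(n_bins=30, cen_frac=0.99)
        n = lay.n_bins
        a = np.zeros((n, n))
        for i in range(n - 3):
            a[i, i + 3] = a[i + 3, i] = 2.0
        decay = hic.contact_decay(dense_cm(lay, a))
        nonzero = decay[decay["mean_value"] > 0]
        assert len(nonzero) == 1
        assert nonzero.iloc[0]["distance_bp"] == pytest.approx(6000, rel=0.5)

    def test_generator_decay_slope_round_trip(self):
        lay = demo_layout(n_chroms=1, chrom_length=1_000_000, binsize=2000)
        cm, _ = generate_contact_map(MapRecipe(layout=lay, decay_gamma=-1.0,
                                               depth=400.0, seed=1))
        decay = hic.contact_decay(cm)
        slope = hic.decay_exponent(decay, d_min=4000, d_max=300_000)
        assert slope == pytest.approx(-1.0, abs=0.05)

    def test_curve_length_equals_nonempty_bands(self, uniform_cm):
        decay = hic.contact_decay(uniform_cm)
        assert (decay["n_pairs"] > 0).all()


class TestZScores:
    def test_band_mean_zero_sd_one(self):
        lay = one_chrom_layout(n_bins=60, cen_frac=0.99)
        rng = np.random.default_rng(3)
        a = rng.exponential(size=(60, 60))
        a = a + a.T
        zm = hic.zscore_map(dense_cm(lay, a, normalization="vc_sqrt"))
        name, (sl, z) = next(iter(zm.arms.items()))
        for d in range(2, 45):
            band = np.diagonal(z, offset=d)
            band = band[~np.isnan(band)]
            if band.size >= 15:
                assert abs(band.mean()) < 1e-9
                assert band.std() == pytest.approx(1.0, rel=1e-9)

    def test_hand_computed_outlier(self):
        lay = one_chrom_layout(n_bins=23, cen_frac=0.99)
        n = lay.n_bins
        a = np.ones((n, n))
        a[0, 2] = a[2, 0] = 11.0  # outlier in the d=2 band (21 pairs)
        zm = hic.zscore_map(dense_cm(lay, a, normalization="vc_sqrt"))
        _, (sl, z) = next(iter(zm.arms.items()))
        band = np.array([a[i, i + 2] for i in range(n - 2)])
        expected = (11.0 - band.mean()) / band.std()
        assert z[0, 2] == pytest.approx(expected, rel=1e-12)

    def test_small_bands_masked(self):
        # 10-bin arm: d=2 band has 8 pairs < 15 -> everything masked
        lay = one_chrom_layout(n_bins=10, cen_frac=0.99)
        rng = np.random.default_rng(1)
        a = rng.exponential(size=(10, 10))
        zm = hic.zscore_map(dense_cm(lay, a + a.T, normalization="vc_sqrt"))
        for _, (sl, z) in zm.arms.items():
            assert np.all(np.isnan(z))

    def test_diagonal_and_neighbors_excluded(self):
        lay = one_chrom_layout(n_bins=60, cen_frac=0.99)
        rng = np.random.default_rng(2)
        a = rng.exponential(size=(60, 60))
        zm = hic.zscore_map(dense_cm(lay, a + a.T, normalization="vc_sqrt"))
        _, (sl, z) = next(iter(zm.arms.items()))
        assert np.all(np.isnan(np.diagonal(z)))
        assert np.all(np.isnan(np.diagonal(z, offset=1)))

    def test_zero_spread_band_warns_and_masks(self):
        lay = one_chrom_layout(n_bins=40, cen_frac=0.99)
        a = np.ones((40, 40))
        with pytest.warns(UserWarning, match="zero spread"):
            zm = hic.zscore_map(dense_cm(lay, a, normalization="vc_sqrt"))
        _, (sl, z) = next(iter(zm.arms.items()))
        assert np.all(np.isnan(z))


class TestInteractionCalling:
    def _zmap_with_outlier(self):
        lay = one_chrom_layout(n_bins=40, cen_frac=0.99)
        rng = np.random.default_rng(4)
        a = rng.normal(10, 1, (40, 40))
        a = np.abs(a + a.T) / 2
        a[0, 5] = a[5, 0] = 30.0
        return hic.zscore_map(dense_cm(lay, a, normalization="vc_sqrt"))

    def test_strict_threshold_excludes_exact_value(self):
        lay = one_chrom_layout(n_bins=23, cen_frac=0.99)
        n = lay.n_bins
        a = np.ones((n, n))
        zm = hic.zscore_map(dense_cm(lay, a, normalization="vc_sqrt"))
        # overwrite one arm's z matrix with a controlled band
        name, (sl, z) = next(iter(zm.arms.items()))
        z[:] = np.nan
        z[0, 5] = 2.0   # exactly at threshold: excluded
        z[1, 6] = 2.01  # strictly above: kept
        calls = hic.call_interactions(zm, threshold=2.0)
        assert len(calls) == 1
        assert calls.table.iloc[0]["bin1"] == sl.start + 1

    def test_outlier_called(self):
        calls = hic.call_interactions(self._zmap_with_outlier())
        assert (0, 5) in calls.pair_keys()

    def test_empty_map_empty_set(self):
        lay = one_chrom_layout(n_bins=10, cen_frac=0.99)
        zm = hic.zscore_map(dense_cm(lay, np.ones((10, 10)), normalization="vc_sqrt"))
        assert len(hic.call_interactions(zm)) == 0

    def test_bedpe_pairs_ordered(self):
        bedpe = hic.call_interactions(self._zmap_with_outlier()).to_bedpe()
        assert (bedpe["start1"] <= bedpe["start2"]).all()


class TestCompareSets:
    def _iset(self, layout, keys):
        rows = [("I_L", i, j, (j - i) * layout.binsize, 3.0) for i, j in keys]
        return hic.InteractionSet(layout, pd.DataFrame(
            rows, columns=["arm", "bin1", "bin2", "distance_bp", "z"]))

    def test_identical_all_common(self, two_chrom_layout):
        s = self._iset(two_chrom_layout, [(0, 5), (1, 7)])
        res = hic.compare_sets(s, s)
        assert res["n_common"] == 2
        assert res["n_a_specific"] == res["n_b_specific"] == 0

    def test_disjoint_no_common(self, two_chrom_layout):
        a = self._iset(two_chrom_layout, [(0, 5)])
        b = self._iset(two_chrom_layout, [(1, 7)])
        res = hic.compare_sets(a, b)
        assert res["n_common"] == 0
        assert res["n_a_specific"] == res["n_b_specific"] == 1

    def test_resolution_mismatch_errors(self, two_chrom_layout):
        other = GenomeLayout(two_chrom_layout.chroms, two_chrom_layout.lengths,
                             two_chrom_layout.centromeres, 1000)
        a = self._iset(two_chrom_layout, [(0, 5)])
        b = self._iset(other, [(0, 5)])
        with pytest.raises(ValueError, match="resolution|layout"):
            hic.compare_sets(a, b)


class TestAggregateMatrix:
    def test_flat_matrix_gives_ones(self, two_chrom_layout):
        cm = dense_cm(two_chrom_layout,
                      np.ones((two_chrom_layout.n_bins,) * 2), normalization="KR")
        iset = hic.InteractionSet(two_chrom_layout, pd.DataFrame(
            [("I_L", 8, 12, 8000, 3.0)],
            columns=["arm", "bin1", "bin2", "distance_bp", "z"]))
        agg = hic.aggregate_matrix(cm, iset)
        assert agg.shape == (9, 9)
        np.testing.assert_allclose(agg, 1.0)

    def test_two_windows_hand_mean(self):
        lay = one_chrom_layout(n_bins=40, cen_frac=0.99)
        rng = np.random.default_rng(12)
        a = rng.exponential(size=(40, 40))
        a = a + a.T
        cm = dense_cm(lay, a, normalization="KR")
        pairs = [(10, 20), (15, 30)]
        iset = hic.InteractionSet(lay, pd.DataFrame(
            [("I_L", i, j, (j - i) * 2000, 3.0) for i, j in pairs],
            columns=["arm", "bin1", "bin2", "distance_bp", "z"]))
        agg = hic.aggregate_matrix(cm, iset, half_window_bp=4000)
        subs = []
        for i, j in pairs:
            s = a[i - 2:i + 3, j - 2:j + 3]
            subs.append(s / s.mean())
        np.testing.assert_allclose(agg, np.mean(subs, axis=0), rtol=1e-12)

    def test_even_window_reading(self, two_chrom_layout):
        cm = dense_cm(two_chrom_layout,
                      np.ones((two_chrom_layout.n_bins,) * 2), normalization="KR")
        iset = hic.InteractionSet(two_chrom_layout, pd.DataFrame(
            [("I_L", 8, 12, 8000, 3.0)],
            columns=["arm", "bin1", "bin2", "distance_bp", "z"]))
        agg = hic.aggregate_matrix(cm, iset, centered=False)
        assert agg.shape == (8, 8)

    def test_edge_windows_dropped(self, two_chrom_layout):
        cm = dense_cm(two_chrom_layout,
                      np.ones((two_chrom_layout.n_bins,) * 2), normalization="KR")
        iset = hic.InteractionSet(two_chrom_layout, pd.DataFrame(
            [("I_L", 0, 5, 10000, 3.0)],  # window spills over the arm start
            columns=["arm", "bin1", "bin2", "distance_bp", "z"]))
        with pytest.raises(ValueError, match="window"):
            hic.aggregate_matrix(cm, iset)

    def test_planted_loop_center_enriched(self):
        lay = demo_layout(n_chroms=1, chrom_length=400_000, centromere_frac=0.9)
        loops = (("I", 100_000, 200_000, 8.0),)
        cm, truth = generate_contact_map(MapRecipe(layout=lay, depth=400.0,
                                                   loops=loops, seed=3))
        bal = hic.kr_balance(cm)
        i, j = next(iter(truth["loop_keys"]))
        iset = hic.InteractionSet(lay, pd.DataFrame(
            [("I_L", i, j, (j - i) * 2000, 5.0)],
            columns=["arm", "bin1", "bin2", "distance_bp", "z"]))
        agg = hic.aggregate_matrix(bal, iset)
        border = np.concatenate([agg[0, :], agg[-1, :], agg[:, 0], agg[:, -1]])
        assert agg[4, 4] > border.mean()


class TestInsulation:
    def test_uniform_matrix_constant_vectors(self):
        lay = demo_layout(n_chroms=1, chrom_length=600_000, centromere_frac=0.9)
        n = lay.n_bins
        cm = dense_cm(lay, np.ones((n, n)), normalization="KR")
        vec = hic.insulation_vectors(cm)
        for col in [c for c in vec.columns if c.startswith("offset_")]:
            vals = vec[col].dropna()
            assert len(vals) > 0
            assert np.allclose(vals, vals.iloc[0])

    def test_exactly_ten_offset_vectors(self, uniform_cm):
        vec = hic.insulation_vectors(uniform_cm)
        offs = [c for c in vec.columns if c.startswith("offset_")]
        assert len(offs) == 10
        assert offs[0] == "offset_10000" and offs[-1] == "offset_100000"

    def test_block_border_depleted_at_every_offset(self):
        lay = demo_layout(n_chroms=1, chrom_length=600_000, centromere_frac=0.9)
        n = lay.n_bins
        a = np.ones((n, n)) * 0.2
        border_bin = 150  # 300 kb
        a[:border_bin, :border_bin] = 1.0
        a[border_bin:, border_bin:] = 1.0
        cm = dense_cm(lay, a, normalization="KR")
        vec = hic.insulation_vectors(cm)
        pos = vec["position"].to_numpy()
        at_border = np.argmin(np.abs(pos - 300_000))
        for col in [c for c in vec.columns if c.startswith("offset_")]:
            v = vec[col].to_numpy()
            inside = np.nanmean(np.concatenate([v[10:20], v[40:50]]))
            assert v[at_border] < inside


class TestBorderProfile:
    def test_uniform_vectors_zero_profile(self, uniform_cm):
        vec = hic.insulation_vectors(uniform_cm)
        borders = pd.DataFrame({"chrom": ["I"], "start": [50_000], "end": [50_001]})
        with pytest.raises(ValueError):
            # +/-100 kb windows never fit inside a 100 kb chromosome
            hic.border_profile(vec, borders)

    def test_single_border_hand_profile(self):
        vec = pd.DataFrame({
            "chrom": "I",
            "position": np.arange(40) * 10_000,
            "offset_10000": np.concatenate([np.full(20, 4.0), np.full(20, 1.0)]),
        })
        borders = pd.DataFrame({"chrom": ["I"], "start": [200_000], "end": [200_001]})
        prof = hic.border_profile(vec, borders)
        win = np.concatenate([np.full(10, 4.0), np.full(11, 1.0)])
        expected = np.log2(win / win.mean())
        np.testing.assert_allclose(prof["offset_10000"], expected, rtol=1e-12)

    def test_block_joint_minimum_at_border(self):
        lay = demo_layout(n_chroms=1, chrom_length=1_000_000, centromere_frac=0.95)
        blocks = (("I", 0, 500_000, 5.0), ("I", 500_000, 1_000_000, 5.0))
        cm, truth = generate_contact_map(MapRecipe(layout=lay, depth=300.0,
                                                   blocks=blocks, seed=5))
        vec = hic.insulation_vectors(hic.kr_balance(cm))
        borders = pd.DataFrame({"chrom": ["I"], "start": [500_000], "end": [500_001]})
        prof = hic.border_profile(vec, borders)
        mean_prof = prof[[c for c in prof.columns if c.startswith("offset")]].mean(axis=1)
        center = len(prof) // 2
        assert mean_prof.idxmin() in (center - 1, center, center + 1)


class TestVirtual4C:
    def test_raw_profile_equals_matrix_row(self, two_chrom_layout):
        rng = np.random.default_rng(14)
        n = two_chrom_layout.n_bins
        a = rng.exponential(size=(n, n)) + 1
        a = a + a.T
        cm = dense_cm(two_chrom_layout, a, normalization="KR")
        prof = hic.virtual_4c(cm, "I", 30_000)
        vbin = two_chrom_layout.bin_of("I", 30_000)
        np.testing.assert_allclose(prof["raw"].to_numpy(), a[vbin, :50])

    def test_constant_profile_constant_fit_zero_band(self, two_chrom_layout):
        n = two_chrom_layout.n_bins
        cm = dense_cm(two_chrom_layout, np.full((n, n), 3.0), normalization="KR")
        prof = hic.virtual_4c(cm, "I", 30_000)
        np.testing.assert_allclose(prof["smooth"], 3.0, rtol=1e-9)
        np.testing.assert_allclose(prof["hi"] - prof["lo"], 0.0, atol=1e-9)

    def test_linear_profile_reproduced(self):
        x = np.linspace(0, 1, 80)
        y = 2.5 * x + 0.3
        sm = hic.loess(x, y, span=0.3, degree=2)
        np.testing.assert_allclose(sm["fit"], y, atol=1e-6)

    def test_masked_viewpoint_errors(self, two_chrom_layout):
        n = two_chrom_layout.n_bins
        cm = dense_cm(two_chrom_layout, np.ones((n, n)), normalization="KR")
        cm.mask[two_chrom_layout.bin_of("I", 30_000)] = True
        with pytest.raises(ValueError, match="masked"):
            hic.virtual_4c(cm, "I", 30_000)


class TestMedianInteractionDistance:
    def test_single_partner(self):
        lay = one_chrom_layout(n_bins=20, cen_frac=0.99)
        a = np.zeros((20, 20))
        a[0, 7] = a[7, 0] = 4.0
        med = hic.median_interaction_distance(dense_cm(lay, a))
        assert med.loc[0, "median_distance_bp"] == 7 * 2000

    def test_equal_weight_partners(self):
        lay = one_chrom_layout(n_bins=40, cen_frac=0.99)
        a = np.zeros((40, 40))
        for d in (5, 10, 15):  # 10, 20, 30 kb at 2 kb bins
            a[0, d] = a[d, 0] = 2.0
        med = hic.median_interaction_distance(dense_cm(lay, a))
        assert med.loc[0, "median_distance_bp"] == 20_000

    def test_empty_bin_undefined(self):
        lay = one_chrom_layout(n_bins=10, cen_frac=0.99)
        a = np.zeros((10, 10))
        a[0, 3] = a[3, 0] = 1.0
        med = hic.median_interaction_distance(dense_cm(lay, a))
        assert np.isnan(med.loc[5, "median_distance_bp"])
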