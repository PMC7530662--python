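import numpy as np
import pytest

from gravscan.errors import MetricError
from gravscan.io import Scanpath
from gravscan.metrics import (MetricParams, edit_distance, evaluate_image,
                              nss, saliency_from_fixations, scanpath_to_string,
                              sed, stde, tde)


def sp_from_xy(xy, frame=(100, 100)):
    xy = np.asarray(xy, dtype=float)
    n = xy.shape[0]
    onsets = np.arange(n) * 0.3
    durs = np.full(n, 0.25)
    return Scanpath(np.column_stack([xy, onsets, durs]), frame_size=frame)


class TestScanpathToString:
    def test_top_left_cell(self):
        sp = sp_from_xy([[10, 10]])
        assert scanpath_to_string(sp, (100, 100), 2) == ("0",)

    def test_boundary_goes_to_next_cell(self):
        sp = sp_from_xy([[50, 10]])  # x exactly on the interior boundary
        assert scanpath_to_string(sp, (100, 100), 2) == ("1",)

    def test_matches_floor_division_oracle(self, rng):
        m = 5
        xy = rng.uniform(0, 99.999, size=(20, 2))
        sp = sp_from_xy(xy)
        labels = scanpath_to_string(sp, (100, 100), m)
        alphabet = "0123456789abcdefghijklmnopqrstuvwxyz" \
                   "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        for (x, y), lab in zip(xy, labels):
            cell = min(int(y * m / 100), m - 1) * m + min(int(x * m / 100), m - 1)
            assert lab == alphabet[cell]


class TestEditDistance:
    @pytest.mark.parametrize("s1,s2,expected", [
        ("abc", "abc", 0),
        ("abc", "", 3),
        ("", "", 0),
        ("kitten", "sitting", 3),
        ("flaw", "lawn", 2),
    ])
    def test_classic_pairs(self, s1, s2, expected):
        assert edit_distance(s1, s2) == expected

    def test_metric_axioms_against_edlib_oracle(self, rng):
        edlib = pytest.importorskip("edlib")
        alphabet = "abcdefgh"
        for _ in range(30):
            s1 = "".join(rng.choice(list(alphabet), size=rng.integers(0, 10)))
            s2 = "".join(rng.choice(list(alphabet), size=rng.integers(0, 10)))
            d = edit_distance(s1, s2)
            assert d == edit_distance(s2, s1)
            if s1 and s2:
                assert d == edlib.align(s1, s2)["editDistance"]

    def test_triangle_inequality(self, rng):
        alphabet = list("abcd")
        for _ in range(20):
            a, b, c = ("".join(rng.choice(alphabet, size=rng.integers(1, 8)))
                       for _ in range(3))
            assert edit_distance(a, c) <= edit_distance(a, b) + edit_distance(b, c)


class TestSed:
    def test_identity_is_zero(self, rng):
        sp = sp_from_xy(rng.uniform(0, 99, size=(6, 2)))
        assert sed(sp, sp, (100, 100)) == 0.0

    def test_single_fixation_cases(self):
        a = sp_from_xy([[5, 5]])
        b = sp_from_xy([[95, 95]])
        c = sp_from_xy([[6, 7]])
        assert sed(a, b, (100, 100)) == 1.0
        assert sed(a, c, (100, 100)) == 0.0

    def test_symmetry(self, rng):
        a = sp_from_xy(rng.uniform(0, 99, size=(5, 2)))
        b = sp_from_xy(rng.uniform(0, 99, size=(8, 2)))
        assert sed(a, b, (100, 100)) == sed(b, a, (100, 100))

    def test_empty_scanpath_rejected(self):
        a = sp_from_xy([[5, 5]])
        empty = Scanpath(np.empty((0, 4)), frame_size=(100, 100))
        with pytest.raises(MetricError):
            sed(a, empty, (100, 100))


def brute_force_tde(human_xy, sim_xy, k):
    best_means = []
    for i in range(len(human_xy) - k + 1):
        dists = []
        for j in range(len(sim_xy) - k + 1):
            diff = np.asarray(human_xy[i:i + k]) - np.asarray(sim_xy[j:j + k])
            dists.append(np.sqrt((diff ** 2).sum()) / k)
        best_means.append(min(dists))
    return float(np.mean(best_means))


class TestTde:
    def test_identical_scanpaths_zero(self, rng):
        sp = sp_from_xy(rng.uniform(0, 99, size=(7, 2)))
        assert tde(sp, sp, 3) == 0.0

    def test_single_pair_euclidean(self):
        a = sp_from_xy([[0, 0]])
        b = sp_from_xy([[3, 4]])
        assert tde(a, b, 1) == pytest.approx(5.0)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(25):
            a = rng.uniform(0, 99, size=(rng.integers(3, 9), 2))
            b = rng.uniform(0, 99, size=(rng.integers(3, 9), 2))
            spa, spb = sp_from_xy(a), sp_from_xy(b)
            for k in (1, 2, 3):
                assert tde(spa, spb, k) == pytest.approx(
                    brute_force_tde(a, b, k), abs=1e-12)

    def test_too_short_rejected(self):
        a = sp_from_xy([[1, 1], [2, 2]])
        with pytest.raises(MetricError):
            tde(a, a, 3)


class TestStde:
    def test_identity_is_one(self, rng):
        sp = sp_from_xy(rng.uniform(0, 99, size=(6, 2)))
        assert stde(sp, sp, (100, 100), 3) == pytest.approx(1.0)

    def test_known_single_pair_value(self):
        a = sp_from_xy([[0, 0]])
        b = sp_from_xy([[30, 40]])
        assert stde(a, b, (100, 100), 1) == pytest.approx(np.exp(-0.5))

    def test_decreases_with_translation_distance(self):
        a = sp_from_xy([[10, 10], [20, 20], [30, 30]])
        vals = []
        for shift in (0, 10, 25, 50):
            b = sp_from_xy(np.asarray([[10, 10], [20, 20], [30, 30]]) + shift)
            vals.append(stde(a, b, (100, 100), 3))
        assert all(v1 > v2 for v1, v2 in zip(vals, vals[1:]))

    def test_in_unit_interval(self, rng):
        a = sp_from_xy(rng.uniform(0, 99, size=(6, 2)))
        b = sp_from_xy(rng.uniform(0, 99, size=(9, 2)))
        v = stde(a, b, (100, 100), 3)
        assert 0.0 < v <= 1.0

    def test_scale_invariance(self, rng):
        a_xy = rng.uniform(0, 99, size=(5, 2))
        b_xy = rng.uniform(0, 99, size=(7, 2))
        v1 = stde(sp_from_xy(a_xy), sp_from_xy(b_xy), (100, 100), 2)
        v2 = stde(sp_from_xy(a_xy * 4, (400, 400)),
                  sp_from_xy(b_xy * 4, (400, 400)), (400, 400), 2)
        assert v1 == pytest.approx(v2, rel=1e-12)


class TestNss:
    def test_fixation_at_max_equals_zscore_oracle(self, rng):
        s = rng.uniform(0, 1, size=(50, 50))
        y, x = np.unravel_index(np.argmax(s), s.shape)
        sp = sp_from_xy([[x, y]], frame=(50, 50))
        expected = (s.max() - s.mean()) / s.std()
        assert nss(s, sp) == pytest.approx(expected, rel=1e-12)

    def test_uniform_coverage_near_zero(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(0, 1, size=(10, 10))
        xy = [[x, y] for y in range(10) for x in range(10)]
        n = len(xy)
        sp = Scanpath(np.column_stack([xy, np.arange(n) * 0.1,
                                       np.full(n, 0.05)]), frame_size=(10, 10))
        assert abs(nss(s, sp)) < 1e-9

    def test_affine_invariance(self, rng):
        s = rng.uniform(0, 1, size=(30, 30))
        sp = sp_from_xy(rng.uniform(0, 29, size=(5, 2)), frame=(30, 30))
        assert nss(3.0 * s + 7.0, sp) == pytest.approx(nss(s, sp), rel=1e-9)

    def test_constant_map_rejected(self):
        sp = sp_from_xy([[5, 5]], frame=(20, 20))
        with pytest.raises(MetricError):
            nss(np.ones((20, 20)), sp)


class TestEvaluateImage:
    def test_identical_human_scores_perfectly(self, rng):
        sp = sp_from_xy(rng.uniform(0, 99, size=(6, 2)))
        out = evaluate_image(sp, [sp], (100, 100))
        assert out == {"sed": 0.0, "tde": 0.0, "stde": 1.0}

    def test_mean_over_observers(self, rng):
        sim = sp_from_xy(rng.uniform(0, 99, size=(6, 2)))
        h1 = sp_from_xy(rng.uniform(0, 99, size=(5, 2)))
        h2 = sp_from_xy(rng.uniform(0, 99, size=(7, 2)))
        out = evaluate_image(sim, [h1, h2], (100, 100))
        p = MetricParams()
        assert out["tde"] == pytest.approx(
            (tde(h1, sim, p.embed_k) + tde(h2, sim, p.embed_k)) / 2)
        assert out["sed"] == pytest.approx(
            (sed(sim, h1, (100, 100), p) + sed(sim, h2, (100, 100), p)) / 2)

    def test_short_observers_skipped_with_warning(self, rng):
        sim = sp_from_xy(rng.uniform(0, 99, size=(6, 2)))
        ok = sp_from_xy(rng.uniform(0, 99, size=(5, 2)))
        short = sp_from_xy([[1, 1]])
        with pytest.warns(UserWarning, match="skipping"):
            out = evaluate_image(sim, [ok, short], (100, 100))
        assert out["tde"] == pytest.approx(tde(ok, sim, 3))

    def test_all_skipped_raises(self):
        sim = sp_from_xy([[1, 1]])
        short = sp_from_xy([[2, 2]])
        with pytest.raises(MetricError):
            evaluate_image(sim, [short], (100, 100))


class TestGridSearchTune:
    def test_single_point_grid_and_tie_break(self):
        from gravscan.dynamics import SimulationParams
        from gravscan.metrics import grid_search_tune
        from gravscan.synthetic import Blob, make_blob_stimulus, make_synthetic_observers

        frame = make_blob_stimulus((32, 32), [Blob((20.0, 16.0), 3.0, amplitude=0.5)])
        humans = [make_synthetic_observers([(20.0, 16.0)] * 3, 2, (32, 32),
                                           jitter_sd=1.0, seed=0)]
        base = SimulationParams(duration=1.0, time_scale=10.0, dt=0.05,
                                pixels_per_degree=frame.pixels_per_degree)
        best, results = grid_search_tune([frame], humans, {"lam": [1.0]},
                                         base_params=base, min_fixations=1)
        assert best.lam == 1.0 and len(results) == 1
        # duplicated lattice points: argmax ties break first-in-grid,
        # so repeat runs are identical
        best2, results2 = grid_search_tune([frame], humans,
                                           {"lam": [1.0, 1.0]},
                                           base_params=base, min_fixations=1)
        assert best2 is results2[0][0]
        assert results2[0][1] == results2[1][1]

    def test_empty_grid_rejected(self):
        from gravscan.metrics import grid_search_tune
        with pytest.raises(ValueError):
            grid_search_tune([], [], {})


class TestSaliencyFromFixations:
    def test_peaks_at_fixations(self):
        sp = sp_from_xy([[10, 20]], frame=(40, 40))
        s = saliency_from_fixations(sp, (40, 40), sigma_px=2.0)
        y, x = np.unravel_index(np.argmax(s), s.shape)
        assert (x, y) == (10, 20)
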