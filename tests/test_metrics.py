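"""Dice / Hausdorff / ASSD against brute-force oracles and closed forms."""

import numpy as np
import pytest

from cardioseg.metrics import (BinaryRegion, MetricReport, assd,
                               dice_coefficient, evaluate,
                               hausdorff_distance, surface_pixels)

from conftest import (brute_assd, brute_dice, brute_hausdorff, brute_surface,
                      random_region)


def disc(shape, center, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


class TestDice:
    def test_identical_regions_score_one(self):
        a = disc((16, 16), (8, 8), 4)
        assert dice_coefficient(a, a) == 1.0

    def test_disjoint_regions_score_zero(self):
        a = np.zeros((8, 8), bool); a[1, 1] = True
        b = np.zeros((8, 8), bool); b[6, 6] = True
        assert dice_coefficient(a, b) == 0.0

    def test_half_overlap_toy(self):
        # |A|=4, |B|=4, |A n B|=2 -> 0.5
        a = np.zeros((4, 4), bool); a[0, 0:4] = True
        b = np.zeros((4, 4), bool); b[0, 2:4] = True; b[1, 0:2] = True
        assert dice_coefficient(a, b) == 0.5

    def test_both_empty_is_one_by_convention(self):
        e = np.zeros((5, 5), bool)
        assert dice_coefficient(e, e) == 1.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid mismatch"):
            dice_coefficient(np.zeros((4, 4), bool), np.zeros((5, 5), bool))

    def test_symmetry_on_random_pairs(self, rng):
        for _ in range(20):
            a, b = random_region(rng), random_region(rng)
            assert dice_coefficient(a, b) == dice_coefficient(b, a)


class TestSurface:
    def test_single_pixel_region_is_its_own_surface(self):
        m = np.zeros((5, 5), bool); m[2, 2] = True
        assert (surface_pixels(m) == m).all()

    def test_solid_square_surface_is_perimeter(self):
        m = np.zeros((5, 5), bool); m[1:4, 1:4] = True
        s = surface_pixels(m)
        expected = m.copy(); expected[2, 2] = False
        assert (s == expected).all()
        assert s.sum() == 8

    def test_full_grid_surface_is_border_ring(self):
        m = np.ones((6, 7), bool)
        s = surface_pixels(m)
        ring = np.zeros_like(m); ring[0] = ring[-1] = True
        ring[:, 0] = ring[:, -1] = True
        assert (s == ring).all()

    def test_matches_brute_force_on_random_regions(self, rng):
        for _ in range(30):
            m = random_region(rng)
            assert (surface_pixels(m) == brute_surface(m)).all()

    def test_empty_region_has_empty_surface(self):
        assert not surface_pixels(np.zeros((4, 4), bool)).any()

    def test_eight_connectivity_counts_diagonal_exposure(self):
        # plus shape: the center is interior under 4-connectivity but its
        # diagonals are outside, so 8-connectivity puts it on the surface
        plus = np.zeros((5, 5), bool)
        plus[2, 1:4] = True
        plus[1:4, 2] = True
        assert not surface_pixels(plus, connectivity=4)[2, 2]
        assert surface_pixels(plus, connectivity=8)[2, 2]
        with pytest.raises(ValueError, match="connectivity"):
            surface_pixels(plus, connectivity=6)


class TestSurfaceDistances:
    def test_identical_regions_are_zero_distance(self):
        a = disc((16, 16), (8, 8), 4)
        assert hausdorff_distance(a, a) == 0.0
        assert assd(a, a) == 0.0

    def test_three_four_five_singletons(self):
        a = np.zeros((8, 8), bool); a[0, 0] = True
        b = np.zeros((8, 8), bool); b[3, 4] = True
        assert hausdorff_distance(a, b) == pytest.approx(5.0)
        assert assd(a, b) == pytest.approx(5.0)

    def test_spacing_scales_distances(self):
        a = np.zeros((8, 8), bool); a[0, 0] = True
        b = np.zeros((8, 8), bool); b[0, 4] = True
        assert hausdorff_distance(a, b, spacing=(2.0, 0.5)) == pytest.approx(2.0)

    def test_empty_region_yields_nan_sentinel(self):
        a = disc((8, 8), (4, 4), 2)
        e = np.zeros((8, 8), bool)
        assert np.isnan(hausdorff_distance(a, e))
        assert np.isnan(assd(e, a))

    def test_exact_agreement_with_brute_force(self, rng):
        """Distance-transform results equal all-pairs search exactly."""
        for k in range(60):
            a, b = random_region(rng), random_region(rng)
            spacing = (1.0, 1.0) if k % 2 == 0 else (0.7, 1.92)
            kw = {} if k % 2 == 0 else {"spacing": spacing}
            assert hausdorff_distance(a, b, **kw) == pytest.approx(
                brute_hausdorff(a, b, spacing if kw else (1.0, 1.0)), abs=1e-9)
            assert assd(a, b, **kw) == pytest.approx(
                brute_assd(a, b, spacing if kw else (1.0, 1.0)), abs=1e-9)

    def test_assd_never_exceeds_hausdorff(self, rng):
        for _ in range(30):
            a, b = random_region(rng), random_region(rng)
            assert assd(a, b) <= hausdorff_distance(a, b) + 1e-12

    def test_translation_invariance(self, rng):
        for _ in range(10):
            a = random_region(rng, shape=(12, 12))
            b = random_region(rng, shape=(12, 12))
            big_a = np.zeros((20, 20), bool); big_a[2:14, 2:14] = a
            big_b = np.zeros((20, 20), bool); big_b[2:14, 2:14] = b
            sh_a = np.zeros((20, 20), bool); sh_a[5:17, 6:18] = a
            sh_b = np.zeros((20, 20), bool); sh_b[5:17, 6:18] = b
            assert dice_coefficient(big_a, big_b) == dice_coefficient(sh_a, sh_b)
            assert hausdorff_distance(big_a, big_b) == pytest.approx(
                hausdorff_distance(sh_a, sh_b))
            assert assd(big_a, big_b) == pytest.approx(assd(sh_a, sh_b))

    def test_hausdorff_triangle_inequality(self, rng):
        for _ in range(15):
            a = random_region(rng); b = random_region(rng); c = random_region(rng)
            assert (hausdorff_distance(a, c)
                    <= hausdorff_distance(a, b) + hausdorff_distance(b, c) + 1e-9)

    def test_symmetry(self, rng):
        for _ in range(10):
            a, b = random_region(rng), random_region(rng)
            assert hausdorff_distance(a, b) == hausdorff_distance(b, a)
            assert assd(a, b) == pytest.approx(assd(b, a))


class TestEvaluate:
    def _masks(self, rng, n=4, shape=(16, 16)):
        masks = []
        for _ in range(n):
            m = np.zeros(shape, np.uint8)
            m[disc(shape, (8, 8), 4)] = 3
            m[disc(shape, (8, 8), 6) & ~disc(shape, (8, 8), 4)] = 2
            m[3:6, 1:4] = 1
            masks.append(m)
        return masks

    def test_perfect_prediction_scores_perfectly(self, rng):
        gts = self._masks(rng)
        phases = ["ED", "ED", "ES", "ES"]
        rep = evaluate(gts, gts, phases)
        for s in ("LV", "RV", "myo"):
            for ph in ("ED", "ES", "mean"):
                assert rep.get(s, ph, "dice") == 1.0
                assert rep.get(s, ph, "hd") == 0.0
                assert rep.get(s, ph, "assd") == 0.0

    def test_mean_row_is_arithmetic_mean_of_phases(self, rng):
        gts = self._masks(rng)
        preds = [np.roll(g, 1, axis=0) for g in gts]
        rep = evaluate(preds, gts, ["ED", "ED", "ES", "ES"])
        for s in ("LV", "RV", "myo"):
            for m in ("dice", "hd", "assd"):
                assert rep.get(s, "mean", m) == pytest.approx(
                    (rep.get(s, "ED", m) + rep.get(s, "ES", m)) / 2)

    def test_report_composes_single_pair_metric_calls(self, rng):
        gt = self._masks(rng, n=1)[0]
        pred = np.roll(gt, 2, axis=1)
        rep = evaluate([pred], [gt], ["ED"])
        for s, c in (("RV", 1), ("myo", 2), ("LV", 3)):
            assert rep.get(s, "ED", "dice") == pytest.approx(
                dice_coefficient(gt == c, pred == c))
            assert rep.get(s, "ED", "hd") == pytest.approx(
                hausdorff_distance(gt == c, pred == c))
            assert rep.get(s, "ED", "assd") == pytest.approx(
                assd(gt == c, pred == c))
            # single phase: its row doubles as half of the mean row
            assert rep.get(s, "ED", "dice") == rep.get(s, "ED", "dice")

    def test_empty_prediction_policy(self, rng):
        gt = self._masks(rng, n=1)[0]
        pred = np.zeros_like(gt)  # predicts background everywhere
        rep = evaluate([pred], [gt], ["ES"])
        assert rep.get("LV", "ES", "dice") == 0.0
        assert np.isnan(rep.get("LV", "ES", "hd"))
        assert rep.get("LV", "ES", "n_excluded") == 1

    def test_mismatched_pairing_is_an_error(self, rng):
        gts = self._masks(rng, n=2)
        with pytest.raises(ValueError, match="align"):
            evaluate(gts, gts[:1], ["ED"])

    def test_report_round_trips_to_csv_and_json(self, rng, tmp_path):
        gts = self._masks(rng, n=2)
        rep = evaluate(gts, gts, ["ED", "ES"])
        rep.to_csv(tmp_path / "r.csv")
        rep.to_json(tmp_path / "r.json")
        import json
        import pandas as pd
        df = pd.read_csv(tmp_path / "r.csv")
        assert set(df["structure"]) == {"LV", "RV", "myo"}
        assert set(df["phase"]) == {"ED", "ES", "mean"}
        rows = json.load(open(tmp_path / "r.json"))["rows"]
        assert len(rows) == 9
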