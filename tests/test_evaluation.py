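"""Dice, confusion matrices, Cohen's kappa and bootstrap CIs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdluquant import classes as C
from tdluquant.annotations import LabelMap
from tdluquant.evaluation import (
    bootstrap_ci,
    cohens_kappa,
    confusion_matrix,
    dice,
    dice_report,
)


def _lm(arr):
    return LabelMap(np.asarray(arr, dtype=np.uint8))


class TestDice:
    def test_identical_maps_score_one(self, ring_map):
        for code in (C.EPITHELIUM, C.LUMEN, C.INTRALOBULAR_STROMA):
            assert dice(ring_map, ring_map, code) == 1.0

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((10, 10), np.uint8)
        b = np.zeros((10, 10), np.uint8)
        a[:5] = C.LUMEN
        b[5:] = C.LUMEN
        assert dice(_lm(a), _lm(b), C.LUMEN) == 0.0

    def test_half_overlap_hand_case(self):
        # |S| = 4, |G| = 4, overlap 2 -> 2*2 / 8 = 0.5
        s = np.zeros((4, 4), np.uint8)
        g = np.zeros((4, 4), np.uint8)
        s[0, 0:4] = C.VESSEL
        g[0, 2:4] = C.VESSEL
        g[1, 0:2] = C.VESSEL
        assert dice(_lm(s), _lm(g), C.VESSEL) == 0.5

    def test_empty_empty_is_one_single_empty_is_zero(self):
        empty = _lm(np.zeros((5, 5)))
        some = _lm(np.full((5, 5), C.ADIPOSE))
        assert dice(empty, empty, C.ADIPOSE) == 1.0
        assert dice(empty, some, C.ADIPOSE) == 0.0

    def test_extent_mismatch(self):
        with pytest.raises(ValueError, match="extent"):
            dice(_lm(np.zeros((4, 4))), _lm(np.zeros((5, 5))), 1)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = _lm(rng.integers(0, 8, (12, 12)))
        b = _lm(rng.integers(0, 8, (12, 12)))
        for code in (1, 4, 6):
            assert dice(a, b, code) == dice(b, a, code)

    def test_brute_force_formula_oracle(self):
        rng = np.random.default_rng(7)
        s = rng.integers(0, 8, (10, 10))
        g = rng.integers(0, 8, (10, 10))
        for code in range(1, 7):
            inter = sum(
                1
                for y in range(10)
                for x in range(10)
                if s[y, x] == code and g[y, x] == code
            )
            size = (s == code).sum() + (g == code).sum()
            expected = 1.0 if size == 0 else 2 * inter / size
            assert dice(_lm(s), _lm(g), code) == pytest.approx(expected)


class TestDiceReport:
    def test_identical_pair_all_ones(self, ring_map):
        report = dice_report([(ring_map, ring_map)], n_boot=50, seed=0)
        present = {k: v for k, v in report.per_class.items() if not np.isnan(v)}
        assert all(v == 1.0 for v in present.values())
        assert report.weighted_mean == 1.0
        assert report.weighted_mean_ci95 == (1.0, 1.0)

    def test_pooling_is_global_sum_not_mean_of_pairs(self):
        # pair 1: perfect agreement on 4 lumen px; pair 2: complete miss on
        # 12 lumen px. Pooled: 2*4 / (4 + 16 + 12) != mean of (1.0, 0.0)
        a1 = np.zeros((4, 4), np.uint8)
        a1[0, :4] = C.LUMEN
        b2g = np.zeros((4, 4), np.uint8)
        b2g[0:3, :4] = C.LUMEN
        b2s = np.zeros((4, 4), np.uint8)
        pooled = dice_report(
            [(_lm(a1), _lm(a1)), (_lm(b2s), _lm(b2g))], n_boot=10, seed=0
        )
        expected = 2 * 4 / (4 + 4 + 12)
        assert pooled.per_class["lumen"] == pytest.approx(expected)
        assert pooled.per_class["lumen"] != pytest.approx(0.5)

    def test_weighted_mean_uses_ground_truth_pixel_counts(self):
        s = np.full((10, 10), C.ADIPOSE, np.uint8)
        g = np.full((10, 10), C.ADIPOSE, np.uint8)
        g[0, :5] = C.VESSEL  # 5 of 100 px vessel, all missed
        report = dice_report([(_lm(s), _lm(g))], n_boot=10, seed=0)
        d_adipose = 2 * 95 / (100 + 95)
        expected = (95 * d_adipose + 5 * 0.0) / 100
        assert report.weighted_mean == pytest.approx(expected)

    def test_bootstrap_of_identical_pairs_zero_width(self, ring_map):
        report = dice_report([(ring_map, ring_map)] * 3, n_boot=100, seed=1)
        low, high = report.weighted_mean_ci95
        assert low == high == 1.0


class TestConfusionMatrix:
    def test_identity_on_equal_maps(self, ring_map):
        cm = confusion_matrix(ring_map, ring_map)
        for name in cm.index:
            row = cm.loc[name]
            if row.sum() > 0:
                assert row[name] == 1.0

    def test_half_half_row(self):
        g = np.full((10, 10), C.LUMEN, np.uint8)
        s = np.full((10, 10), C.LUMEN, np.uint8)
        s[:5] = C.EPITHELIUM
        cm = confusion_matrix(_lm(s), _lm(g))
        assert cm.loc["lumen", "lumen"] == 0.5
        assert cm.loc["lumen", "epithelium"] == 0.5

    def test_heatmap_rendered_to_file(self, ring_map, tmp_path):
        from tdluquant.evaluation import plot_confusion_heatmap

        cm = confusion_matrix(ring_map, ring_map)
        out = tmp_path / "confusion.png"
        plot_confusion_heatmap(cm, out)
        assert out.stat().st_size > 0

    def test_rows_sum_to_one_or_zero(self):
        rng = np.random.default_rng(3)
        s = _lm(rng.integers(1, 7, (20, 20)))
        g = _lm(rng.integers(1, 5, (20, 20)))
        cm = confusion_matrix(s, g)
        sums = cm.sum(axis=1)
        for name in cm.index:
            assert sums[name] == pytest.approx(1.0, abs=1e-9) or sums[name] == 0.0
        assert (cm.loc["adipose"] == 0).all()  # absent from ground truth


class TestCohensKappa:
    def test_perfect_agreement(self):
        a = [0, 1, 2, 3, 4, 5] * 4
        for weighting in ("linear", "unweighted"):
            assert cohens_kappa(a, a, weighting).kappa == 1.0

    def test_two_category_hand_case(self):
        # O = [[20, 5], [10, 15]]: p_o = 0.7, p_e = 0.5, kappa = 0.4
        a = [0] * 25 + [1] * 25
        b = [0] * 20 + [1] * 5 + [0] * 10 + [1] * 15
        assert cohens_kappa(a, b, "unweighted").kappa == pytest.approx(0.40)

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(12)
        a = rng.integers(0, 6, 10_000)
        b = rng.integers(0, 6, 10_000)
        for weighting in ("linear", "unweighted"):
            assert abs(cohens_kappa(a, b, weighting).kappa) < 0.05

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=15, deadline=None)
    def test_matches_reference_implementation(self, seed):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(seed)
        a = rng.integers(0, 6, 60)
        b = np.clip(a + rng.integers(-2, 3, 60), 0, 5)
        cats = np.arange(6)
        assert cohens_kappa(a, b, "unweighted", cats).kappa == pytest.approx(
            cohen_kappa_score(a, b, labels=cats)
        )
        assert cohens_kappa(a, b, "linear", cats).kappa == pytest.approx(
            cohen_kappa_score(a, b, weights="linear", labels=cats)
        )

    def test_input_validation(self):
        with pytest.raises(ValueError):
            cohens_kappa([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            cohens_kappa([1], [1])


class TestBootstrap:
    def test_constant_statistic_zero_width(self):
        low, high = bootstrap_ci([3.0] * 20, lambda xs: float(np.mean(xs)), 500, 0)
        assert low == high == 3.0

    def test_mean_ci_matches_analytic(self):
        rng = np.random.default_rng(5)
        data = list(rng.normal(0, 1, 1000))
        low, high = bootstrap_ci(data, lambda xs: float(np.mean(xs)), 2000, 5)
        half_width = 1.96 / np.sqrt(1000)
        assert low == pytest.approx(np.mean(data) - half_width, abs=0.02)
        assert high == pytest.approx(np.mean(data) + half_width, abs=0.02)
        assert low < 0.0 < high

    def test_deterministic_given_seed(self):
        data = list(np.random.default_rng(1).normal(size=50))
        ci1 = bootstrap_ci(data, lambda xs: float(np.mean(xs)), 300, 42)
        ci2 = bootstrap_ci(data, lambda xs: float(np.mean(xs)), 300, 42)
        assert ci1 == ci2

    def test_coverage_of_mean_ci(self):
        # ~95% of percentile CIs over replicate experiments should cover the
        # true mean (within a few points at this replicate count)
        rng = np.random.default_rng(10)
        covered = 0
        n_rep = 300
        for rep in range(n_rep):
            data = list(rng.normal(0.0, 1.0, 80))
            low, high = bootstrap_ci(
                data, lambda xs: float(np.mean(xs)), n_boot=400, seed=rep
            )
            covered += low <= 0.0 <= high
        assert abs(covered / n_rep - 0.95) <= 0.035
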