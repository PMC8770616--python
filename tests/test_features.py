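"""Morphometric feature extraction from TDLU label maps."""

import numpy as np
import pandas as pd
import pytest

from tdluquant import classes as C
from tdluquant.annotations import LabelMap, build_border_class
from tdluquant.features import (
    compute_features,
    features_um2,
    find_acini,
    merge_border,
    summarize_subjects,
)

from conftest import draw_disc, make_map


class TestMergeBorder:
    def test_conservation(self, ring_map):
        bordered = build_border_class(ring_map, 3)
        n_border = int((bordered.codes == C.BORDER).sum())
        n_intra = int((bordered.codes == C.INTRALOBULAR_STROMA).sum())
        merged = merge_border(bordered)
        assert int((merged.codes == C.BORDER).sum()) == 0
        assert int((merged.codes == C.INTRALOBULAR_STROMA).sum()) == n_intra + n_border

    def test_identity_without_border(self, ring_map):
        assert np.array_equal(merge_border(ring_map).codes, ring_map.codes)

    def test_idempotent(self, ring_map):
        bordered = build_border_class(ring_map, 3)
        once = merge_border(bordered)
        assert np.array_equal(merge_border(once).codes, once.codes)


def _blob_map(areas, gap=4):
    """Horizontal strip of square epithelial blobs with the given areas."""
    side = max(int(np.ceil(np.sqrt(a))) for a in areas)
    codes = np.zeros((side + 20, (side + gap) * len(areas) + 20), np.uint8)
    x = 10
    for a in areas:
        s = int(np.floor(np.sqrt(a)))
        rem = a - s * s
        codes[10 : 10 + s, x : x + s] = C.EPITHELIUM
        if rem:  # spill the remainder into an attached partial row
            codes[10 + s, x : x + rem] = C.EPITHELIUM
        x += side + gap
    return LabelMap(codes)


class TestFindAcini:
    def test_area_threshold_is_strict(self):
        lm = _blob_map([900, 850, 500])
        acini = find_acini(lm, min_area_px=800)
        assert len(acini) == 2
        assert sorted(a.pixel_area for a in acini) == [850, 900]
        # exactly 800 px does not count ("larger than 800 pixels")
        assert find_acini(_blob_map([800]), min_area_px=800) == []
        assert len(find_acini(_blob_map([801]), min_area_px=800)) == 1

    def test_connectivity_choice_on_diagonal_touch(self):
        codes = np.zeros((80, 80), np.uint8)
        codes[10:40, 10:40] = C.EPITHELIUM  # 900 px
        codes[40:70, 40:70] = C.EPITHELIUM  # 900 px, touching at one corner
        lm = LabelMap(codes)
        assert len(find_acini(lm, connectivity=4)) == 2
        assert len(find_acini(lm, connectivity=8)) == 1

    def test_connectivity_matches_brute_force_flood_fill(self):
        rng = np.random.default_rng(0)
        codes = np.where(rng.uniform(size=(30, 30)) < 0.4, C.EPITHELIUM, 0).astype(
            np.uint8
        )
        for connectivity in (4, 8):
            # brute-force flood fill oracle
            mask = codes == C.EPITHELIUM
            seen = np.zeros_like(mask)
            comps = []
            steps4 = [(1, 0), (-1, 0), (0, 1), (0, -1)]
            steps = steps4 + ([(1, 1), (1, -1), (-1, 1), (-1, -1)] if connectivity == 8 else [])
            for y, x in zip(*np.where(mask)):
                if seen[y, x]:
                    continue
                stack, size = [(y, x)], 0
                seen[y, x] = True
                while stack:
                    cy, cx = stack.pop()
                    size += 1
                    for dy, dx in steps:
                        ny, nx = cy + dy, cx + dx
                        if 0 <= ny < 30 and 0 <= nx < 30 and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                comps.append(size)
            expected = sorted(s for s in comps if s > 5)
            got = sorted(
                a.pixel_area for a in find_acini(LabelMap(codes), 5, connectivity)
            )
            assert got == expected

    def test_border_must_be_merged_first(self, ring_map):
        bordered = build_border_class(ring_map, 3)
        with pytest.raises(ValueError, match="merge_border"):
            find_acini(bordered)

    def test_contained_lumen_area(self, ring_map):
        acini = find_acini(ring_map, min_area_px=100)
        assert len(acini) == 1
        assert acini[0].contained_lumen_area == int(
            (ring_map.codes == C.LUMEN).sum()
        )


class TestComputeFeatures:
    def test_tdlu_area_is_sum_of_compartments(self):
        codes = np.zeros((200, 200), np.uint8)
        codes[:25, :200] = C.EPITHELIUM  # 5000 px
        codes[30:36, :200] = C.LUMEN  # 1200 px
        codes[50:90, :200] = C.INTRALOBULAR_STROMA  # 8000 px
        feats = compute_features(LabelMap(codes))
        assert feats["tdlu_area"] == 14200.0
        assert feats["epithelial_area"] == 5000.0
        assert feats["epithelial_to_stromal_ratio"] == pytest.approx(5000 / 8000)

    def test_empty_tdlu_all_zero_ratio_missing(self):
        lm = LabelMap(make_map((50, 50), C.EXTRALOBULAR_STROMA))
        feats = compute_features(lm)
        assert np.isnan(feats["epithelial_to_stromal_ratio"])
        for name in ("tdlu_area", "acini_count", "epithelial_area", "vessel_count",
                     "mean_acinar_size", "large_lumen_acini_count"):
            assert feats[name] == 0.0

    def test_vessels_counted_without_area_filter(self):
        codes = make_map((100, 100), C.EXTRALOBULAR_STROMA)
        draw_disc(codes, (20, 20), 5, C.VESSEL)
        draw_disc(codes, (70, 70), 2, C.VESSEL)  # tiny vessel still counts
        feats = compute_features(LabelMap(codes))
        assert feats["vessel_count"] == 2.0
        assert feats["vessel_area"] == float((codes == C.VESSEL).sum())

    def test_area_conservation(self, ring_map):
        counts = merge_border(ring_map).class_pixel_counts()
        assert sum(counts.values()) == ring_map.codes.size

    def test_um2_conversion(self, ring_map):
        feats = compute_features(ring_map)
        um = features_um2(feats, resolution=0.495)
        assert um["tdlu_area"] == pytest.approx(feats["tdlu_area"] * 0.495**2)
        assert um["acini_count"] == feats["acini_count"]


class TestSceneRecovery:
    def test_counts_exact_and_areas_match_truth(self):
        from dataclasses import replace

        from tdluquant.synthetic import SceneParams, generate_scene

        base = SceneParams()
        for level, seed in [(0, 3), (2, 4), (4, 5), (5, 6)]:
            _, truth = generate_scene(replace(base, involution_level=level, seed=seed))
            feats = compute_features(truth.label_map)
            tf = truth.true_features
            for name in ("acini_count", "vessel_count", "large_lumen_acini_count"):
                assert feats[name] == tf[name]
            for name in ("tdlu_area", "epithelial_area", "vessel_area", "adipose_area"):
                if tf[name] > 0:
                    assert abs(feats[name] - tf[name]) / tf[name] < 0.01

    def test_mean_acini_count_decreases_along_involution_axis(self):
        from dataclasses import replace

        from tdluquant.synthetic import SceneParams, generate_scene

        base = SceneParams()
        bin_means = []
        for levels in [(0,), (1, 2), (3, 4), (5,)]:
            counts = [
                generate_scene(
                    replace(base, involution_level=lv, seed=700 + 10 * lv + r)
                )[1].true_features["acini_count"]
                for lv in levels
                for r in range(3)
            ]
            bin_means.append(np.mean(counts))
        assert bin_means[0] > bin_means[1] > bin_means[2] > bin_means[3]


class TestSummarize:
    def test_mean_and_pairwise_missing(self):
        df = pd.DataFrame(
            {
                "subject_id": ["s1", "s1", "s2"],
                "acini_count": [10.0, 20.0, 7.0],
                "epithelial_to_stromal_ratio": [2.0, np.nan, 0.5],
            }
        )
        out = summarize_subjects(df).set_index("subject_id")
        assert out.loc["s1", "acini_count"] == 15.0
        assert out.loc["s1", "epithelial_to_stromal_ratio"] == 2.0
        assert out.loc["s2", "acini_count"] == 7.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_subjects(pd.DataFrame(columns=["subject_id", "acini_count"]))
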