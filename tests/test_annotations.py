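"""Annotation reading, rasterization, border construction and label-map I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage
from skimage.draw import disk

from tdluquant import classes as C
from tdluquant.annotations import (
    AnnotationPolygon,
    LabelMap,
    border_width_um,
    build_border_class,
    rasterize,
    read_annotations,
    read_label_map,
    write_label_map,
)

ASAP_XML = """<?xml version="1.0"?>
<ASAP_Annotations>
 <Annotations>
  <Annotation Name="epithelium" Type="Polygon" PartOfGroup="None">
   <Coordinates>
    <Coordinate Order="0" X="1" Y="1"/><Coordinate Order="1" X="9" Y="1"/>
    <Coordinate Order="2" X="9" Y="9"/><Coordinate Order="3" X="1" Y="9"/>
   </Coordinates>
  </Annotation>
  <Annotation Name="Epithelium" Type="Polygon" PartOfGroup="None">
   <Coordinates>
    <Coordinate Order="0" X="12" Y="1"/><Coordinate Order="1" X="18" Y="1"/>
    <Coordinate Order="2" X="18" Y="9"/>
   </Coordinates>
  </Annotation>
  <Annotation Name="epithelium" Type="Polygon" PartOfGroup="None">
   <Coordinates>
    <Coordinate Order="0" X="1" Y="12"/><Coordinate Order="1" X="9" Y="12"/>
    <Coordinate Order="2" X="9" Y="18"/><Coordinate Order="3" X="1" Y="18"/>
   </Coordinates>
  </Annotation>
  <Annotation Name="Lumen" Type="Polygon" PartOfGroup="None">
   <Coordinates>
    <Coordinate Order="0" X="3" Y="3"/><Coordinate Order="1" X="6" Y="3"/>
    <Coordinate Order="2" X="6" Y="6"/><Coordinate Order="3" X="3" Y="6"/>
   </Coordinates>
  </Annotation>
 </Annotations>
</ASAP_Annotations>
"""


class TestReadAnnotations:
    def test_counts_and_classes_preserved(self, tmp_path):
        path = tmp_path / "ann.xml"
        path.write_text(ASAP_XML)
        polys = read_annotations(path)
        assert len(polys) == 4
        assert [p.class_name for p in polys].count("epithelium") == 3
        assert polys[-1].class_name == "lumen"

    def test_alias_table(self, tmp_path):
        xml = ASAP_XML.replace('Name="Lumen"', 'Name="Capillary"')
        path = tmp_path / "ann.xml"
        path.write_text(xml)
        polys = read_annotations(path, aliases={"Capillary": "vessel"})
        assert polys[-1].class_name == "vessel"

    def test_unknown_class_names_offender(self, tmp_path):
        xml = ASAP_XML.replace('Name="Lumen"', 'Name="mystery"')
        path = tmp_path / "ann.xml"
        path.write_text(xml)
        with pytest.raises(ValueError, match="mystery"):
            read_annotations(path)

    def test_empty_document(self, tmp_path):
        path = tmp_path / "empty.xml"
        path.write_text("<ASAP_Annotations><Annotations/></ASAP_Annotations>")
        assert read_annotations(path) == []

    def test_malformed_coordinate(self, tmp_path):
        xml = ASAP_XML.replace('X="3"', 'X="oops"', 1)
        path = tmp_path / "bad.xml"
        path.write_text(xml)
        with pytest.raises(ValueError, match="annotation element"):
            read_annotations(path)

    def test_too_few_vertices(self):
        with pytest.raises(ValueError, match="3 vertices"):
            AnnotationPolygon("lumen", ((0, 0), (1, 1)))


class TestRasterize:
    def test_axis_aligned_square_exact_area(self):
        poly = AnnotationPolygon(
            "epithelium", ((0, 0), (10, 0), (10, 10), (0, 10))
        )
        lm = rasterize([poly], (100, 100))
        assert int((lm.codes == C.EPITHELIUM).sum()) == 100

    @given(
        w=st.integers(1, 30),
        h=st.integers(1, 30),
        x0=st.integers(0, 50),
        y0=st.integers(0, 50),
    )
    @settings(max_examples=25, deadline=None)
    def test_rectangle_area_property(self, w, h, x0, y0):
        poly = AnnotationPolygon(
            "adipose", ((x0, y0), (x0 + w, y0), (x0 + w, y0 + h), (x0, y0 + h))
        )
        lm = rasterize([poly], (90, 90))
        assert int((lm.codes == C.ADIPOSE).sum()) == w * h

    def test_lumen_overrides_epithelium_regardless_of_order(self):
        ring = AnnotationPolygon("epithelium", ((0, 0), (20, 0), (20, 20), (0, 20)))
        lumen = AnnotationPolygon("lumen", ((9, 9), (11, 9), (11, 11), (9, 11)))
        for order in ([lumen, ring], [ring, lumen]):
            lm = rasterize(order, (30, 30))
            assert int((lm.codes == C.LUMEN).sum()) == 4

    def test_epithelium_overrides_stroma(self):
        stroma = AnnotationPolygon(
            "intralobular_stroma", ((0, 0), (30, 0), (30, 30), (0, 30))
        )
        epi = AnnotationPolygon("epithelium", ((5, 5), (15, 5), (15, 15), (5, 15)))
        lm = rasterize([epi, stroma], (30, 30))
        assert int((lm.codes == C.EPITHELIUM).sum()) == 100

    def test_no_polygons_all_zero(self):
        lm = rasterize([], (20, 20))
        assert not lm.codes.any()

    def test_out_of_extent_clipped_with_warning(self, caplog):
        poly = AnnotationPolygon("vessel", ((-5, -5), (5, -5), (5, 5), (-5, 5)))
        with caplog.at_level("WARNING"):
            lm = rasterize([poly], (20, 20))
        assert "clipping" in caplog.text
        assert int((lm.codes == C.VESSEL).sum()) == 25


class TestBorderClass:
    def test_physical_width(self):
        assert round(border_width_um(3, 0.495), 1) == 1.5

    def test_disc_border_matches_erosion_oracle(self):
        codes = np.zeros((60, 60), np.uint8)
        rr, cc = disk((30, 30), 10)
        codes[rr, cc] = C.EPITHELIUM
        lm = build_border_class(LabelMap(codes), 3)
        # brute-force oracle: repeated single-step 4-neighbour peeling
        mask = codes == C.EPITHELIUM
        for _ in range(3):
            keep = mask.copy()
            ys, xs = np.where(mask)
            for y, x in zip(ys, xs):
                for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < 60 and 0 <= xx < 60 and not mask[yy, xx]:
                        keep[y, x] = False
                        break
            mask = keep
        expected_border = int((codes == C.EPITHELIUM).sum() - mask.sum())
        assert int((lm.codes == C.BORDER).sum()) == expected_border

    def test_conservation(self, ring_map):
        before = int((ring_map.codes == C.EPITHELIUM).sum())
        lm = build_border_class(ring_map, 3)
        after = int((lm.codes == C.EPITHELIUM).sum()) + int((lm.codes == C.BORDER).sum())
        assert after == before
        # no other class modified
        for code in (C.INTRALOBULAR_STROMA, C.LUMEN):
            assert (lm.codes == code).sum() == (ring_map.codes == code).sum()

    def test_idempotent(self, ring_map):
        once = build_border_class(ring_map, 3)
        twice = build_border_class(once, 3)
        assert np.array_equal(once.codes, twice.codes)

    def test_thin_component_becomes_all_border(self):
        codes = np.zeros((20, 40), np.uint8)
        codes[8:10, 5:35] = C.EPITHELIUM  # 2 px thick < 3 px depth
        lm = build_border_class(LabelMap(codes), 3)
        assert int((lm.codes == C.EPITHELIUM).sum()) == 0
        assert int((lm.codes == C.BORDER).sum()) == 60

    def test_width_validation(self, ring_map):
        with pytest.raises(ValueError):
            build_border_class(ring_map, 0)

    def test_requires_epithelium(self):
        with pytest.raises(ValueError, match="no epithelium"):
            build_border_class(LabelMap(np.zeros((10, 10), np.uint8)), 3)


class TestLabelMapIO:
    @pytest.mark.parametrize("suffix", [".png", ".tif"])
    def test_lossless_round_trip(self, tmp_path, ring_map, suffix):
        path = tmp_path / f"labels{suffix}"
        write_label_map(ring_map, path)
        back = read_label_map(path)
        assert np.array_equal(back.codes, ring_map.codes)
        assert back.resolution == ring_map.resolution

    def test_out_of_table_code_rejected(self, tmp_path):
        from PIL import Image

        bad = np.full((8, 8), 9, dtype=np.uint8)
        path = tmp_path / "bad.png"
        Image.fromarray(bad, mode="L").save(path)
        with pytest.raises(ValueError, match="9"):
            read_label_map(path)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.png"
        path.touch()
        with pytest.raises(ValueError, match="empty"):
            read_label_map(path)

    def test_label_map_validation(self):
        with pytest.raises(ValueError, match="resolution"):
            LabelMap(np.zeros((4, 4), np.uint8), resolution=0.0)
        with pytest.raises(ValueError, match="class table"):
            LabelMap(np.full((4, 4), 11, np.uint8))
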