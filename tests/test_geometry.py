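"""Edge-to-edge distance geometry and ring assignment."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from shapely.geometry import Polygon, box

from nichemap import geometry, simulate
from nichemap.io import CellRecord
from nichemap.studies import brute_force_edge_distance


def _cell(cell_id, poly, fov="F1", cell_type="other"):
    return CellRecord(
        cell_id=cell_id, fov_id=fov, sample_id="S", patient_id="P",
        timepoint="baseline", response="responder", cell_type=cell_type,
        polygon=poly,
    )


class TestEdgeDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (box(0, 0, 1, 1), box(1, 0, 2, 1), 0.0),  # shared edge
            (box(0, 0, 1, 1), box(2, 0, 3, 1), 1.0),  # unit gap
            (box(0, 0, 10, 10), box(4, 4, 6, 6), 0.0),  # containment
            (box(0, 0, 1, 1), box(2, 2, 3, 3), np.sqrt(2)),  # corner gap
        ],
    )
    def test_known_configurations(self, a, b, expected):
        assert geometry.edge_distance(a, b) == pytest.approx(expected)
        assert geometry.edge_distance(b, a) == pytest.approx(expected)

    def test_self_distance_zero(self):
        p = box(0, 0, 3, 2)
        assert geometry.edge_distance(p, p) == 0.0

    def test_degenerate_polygon_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            geometry.edge_distance(Polygon([(0, 0), (1, 1), (2, 2)]), box(0, 0, 1, 1))

    @given(
        dx=st.floats(-30, 30), dy=st.floats(-30, 30),
        sx=st.floats(0.5, 4), sy=st.floats(0.5, 4),
    )
    def test_symmetry_and_translation_property(self, dx, dy, sx, sy):
        a = box(0, 0, 2, 2)
        b = box(dx, dy, dx + sx, dy + sy)
        d1 = geometry.edge_distance(a, b)
        d2 = geometry.edge_distance(b, a)
        assert d1 == pytest.approx(d2)
        shift = 7.5
        b2 = box(dx + shift, dy, dx + sx + shift, dy + sy)
        a2 = box(shift, 0, 2 + shift, 2)
        assert geometry.edge_distance(a2, b2) == pytest.approx(d1, abs=1e-9)


class TestDistanceTable:
    def test_far_apart_cells_give_empty_table(self):
        cells = [_cell("a", box(0, 0, 1, 1)), _cell("b", box(100, 100, 101, 101))]
        assert len(geometry.build_distance_table(cells, 45.0).pairs) == 0

    def test_infinite_cutoff_counts_all_pairs(self, small_fov):
        _, cells, _, _, _ = small_fov
        n = len(cells)
        table = geometry.build_distance_table(cells, np.inf)
        assert len(table.pairs) == n * (n - 1) // 2

    def test_matches_brute_force_oracle(self):
        params = simulate.TissueParams(
            fov_width=90, fov_height=60, n_cells=30, n_genes=5, seed=21
        )
        cells, _, _, _ = simulate.simulate_fov(params, emit_transcripts=False)
        table = geometry.build_distance_table(cells, 45.0)
        got = {
            tuple(sorted((a, b))): d for a, b, d in table.pairs.itertuples(index=False)
        }
        want = {}
        for ca, cb in itertools.combinations(cells, 2):
            d = brute_force_edge_distance(ca.polygon, cb.polygon)
            if d <= 45.0:
                want[tuple(sorted((ca.cell_id, cb.cell_id)))] = d
        assert got.keys() == want.keys()
        assert all(abs(got[k] - want[k]) < 1e-9 for k in want)

    def test_mixed_fovs_rejected(self):
        cells = [_cell("a", box(0, 0, 1, 1)), _cell("b", box(3, 0, 4, 1), fov="F2")]
        with pytest.raises(ValueError, match="FOV"):
            geometry.build_distance_table(cells, 45.0)

    def test_edge_distance_bounded_by_centroid_distance(self, small_fov):
        _, cells, _, _, _ = small_fov
        table = geometry.build_distance_table(cells, 45.0)
        cent = {c.cell_id: np.array(c.centroid) for c in cells}
        for a, b, d in table.pairs.itertuples(index=False):
            assert d <= np.linalg.norm(cent[a] - cent[b]) + 1e-12


class TestTouchingNeighbors:
    def test_isolated_cell_and_mode(self):
        cells = [
            _cell("a", box(0, 0, 1, 1)),
            _cell("b", box(1, 0, 2, 1)),
            _cell("c", box(50, 50, 51, 51)),
        ]
        table = geometry.build_distance_table(cells, 45.0)
        counts, mode = geometry.touching_neighbors(table, 0.0)
        assert counts == {"a": 1, "b": 1}
        assert "c" not in counts
        assert mode == 1

    def test_three_equidistant_touching_neighbors(self):
        """A central square with three flush neighbors reports exactly 3
        directly touching cells, with no proximity ranking among them."""
        cells = [
            _cell("center", box(0, 0, 2, 2)),
            _cell("left", box(-2, 0, 0, 2)),
            _cell("right", box(2, 0, 4, 2)),
            _cell("top", box(0, 2, 2, 4)),
        ]
        table = geometry.build_distance_table(cells, 45.0)
        counts, _ = geometry.touching_neighbors(table, 0.0)
        assert counts["center"] == 3

    def test_honeycomb_interior_cells_touch_six(self):
        cells = []
        # hexagonal lattice of touching hexagons (gap 0)
        r = 1.0
        w = np.sqrt(3) * r
        for row in range(5):
            for col in range(5):
                cx = col * w + (row % 2) * w / 2
                cy = row * 1.5 * r
                hexagon = Polygon(
                    [
                        (cx + r * np.sin(a), cy + r * np.cos(a))
                        for a in np.linspace(0, 2 * np.pi, 7)[:-1]
                    ]
                )
                cells.append(_cell(f"h{row}{col}", hexagon))
        table = geometry.build_distance_table(cells, 10.0)
        counts, mode = geometry.touching_neighbors(table, 1e-9)
        assert counts["h22"] == 6  # interior cell
        assert mode == 6


class TestAssignRings:
    def _cells_at_gaps(self, gaps):
        cells = [_cell("leuk", box(0, 0, 10, 100), cell_type="leukemia")]
        for i, g in enumerate(gaps):
            cells.append(_cell(f"n{i}", box(10 + g, i * 12, 11 + g, i * 12 + 1)))
        return cells

    def test_half_open_ring_convention(self):
        cells = self._cells_at_gaps([3.0, 5.0, 44.999, 45.0])
        ra = geometry.assign_rings(cells, ["leuk"], [0, 5, 15, 25, 35, 45])
        got = dict(zip(ra["other_cell_id"], ra["ring_index"]))
        assert got["n0"] == 0  # 3 μm -> [0, 5)
        assert got["n1"] == 1  # exactly 5 μm -> [5, 15)
        assert got["n2"] == 4  # just inside the last ring
        assert "n3" not in got  # exactly 45 μm -> omitted

    def test_neighbors_may_serve_multiple_leukemia_cells(self):
        cells = [
            _cell("L1", box(0, 0, 2, 2), cell_type="leukemia"),
            _cell("L2", box(8, 0, 10, 2), cell_type="leukemia"),
            _cell("t", box(4, 0, 6, 2), cell_type="T cell"),
        ]
        ra = geometry.assign_rings(cells, ["L1", "L2"], [0, 5, 15, 25, 35, 45])
        t_rows = ra[ra["other_cell_id"] == "t"]
        assert set(t_rows["leukemia_cell_id"]) == {"L1", "L2"}

    def test_ring_index_consistent_with_distance(self, small_fov):
        _, cells, _, _, truth = small_fov
        edges = np.array([0, 5, 15, 25, 35, 45.0])
        ra = geometry.assign_rings(cells, truth.leukemia_ids, edges)
        assert len(ra) > 0
        for d, r in zip(ra["distance"], ra["ring_index"]):
            assert edges[r] <= d < edges[r + 1]
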