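"""QC, reference selection, and Poisson-likelihood type assignment."""

import numpy as np
import pytest
from scipy.stats import poisson

from nichemap import celltyping, studies
from nichemap.celltyping import (
    assign_types, build_reference_profile, select_reference_cells,
)
from nichemap.io import CountMatrix


def _counts(genes, cells, mat, negctrl=()):
    return CountMatrix(list(genes), list(cells), np.asarray(mat), set(negctrl))


MARKERS = {"T cell": ["CD3E", "CD3D"], "B cell": ["CD19", "CD79A"]}
GENES = ["CD3E", "CD3D", "CD19", "CD79A", "OTHER"]


class TestQC:
    def test_boundary_thresholds(self):
        res = studies.qc_threshold_study()
        assert res["kept_fovs"] == ["FOV_A"]
        assert res["n_kept"] == 300
        assert not res["low_count_cell_kept"]
        assert res["log"]["cells_removed_low_count"] == 1
        assert res["log"]["fovs_removed"] == ["FOV_B"]

    def test_all_pass_is_identity(self, small_fov):
        _, cells, _, cm, _ = small_fov
        kept, log = celltyping.qc_filter(cells, cm, 0, 0)
        assert len(kept) == len(cells)
        assert log["cells_removed_low_count"] == 0


class TestReferenceSelection:
    def test_single_positive_marker_type(self):
        cm = _counts(GENES, ["c1", "c2", "c3"], [
            [8, 0, 0],   # CD3E
            [4, 0, 0],   # CD3D
            [0, 6, 3],   # CD19
            [0, 4, 0],   # CD79A
            [1, 1, 40],  # OTHER dominates c3
        ])
        refs = select_reference_cells(cm, MARKERS)
        assert refs["T cell"] == ["c1"]
        assert refs["B cell"] == ["c2"]

    def test_double_positive_cell_is_not_a_reference(self):
        cm = _counts(GENES, ["c1"], [[5], [5], [5], [5], [0]])
        refs = select_reference_cells(cm, MARKERS)
        assert refs == {}

    def test_pure_high_depth_cells_become_references(self):
        cm, truth = studies.simulate_typing_counts(400, depth_median=1000, seed=3)
        _, _, markers = studies._typing_panel()
        refs = select_reference_cells(cm, markers)
        correct = total = 0
        truth_map = dict(zip(cm.cells, truth))
        for t, ids in refs.items():
            for cid in ids:
                total += 1
                correct += truth_map[cid] == t
        assert total / len(cm.cells) >= 0.9  # most cells usable as references
        assert correct / total >= 0.99


class TestReferenceProfile:
    def test_single_reference_equals_its_counts(self):
        cm = _counts(GENES, ["c1", "c2"], [[8, 0], [4, 0], [0, 6], [0, 4], [1, 1]])
        prof = build_reference_profile(cm, {"T cell": ["c1"], "B cell": ["c2"]})
        assert np.array_equal(prof.profile[:, prof.cell_types.index("T cell")],
                              [8, 4, 0, 0, 1])

    def test_zero_negative_probes_give_zero_background(self):
        cm = _counts(GENES + ["NegPrb01"], ["c1"], [[8], [4], [0], [0], [1], [0]],
                     negctrl=["NegPrb01"])
        prof = build_reference_profile(cm, {"T cell": ["c1"], "B cell": ["c1"]})
        assert prof.negctrl_mean == 0.0

    def test_profile_recovers_generator_rates(self):
        """Per-type mean profile matches the generating rate vector within
        10% relative error on marker genes at 200 reference cells/type."""
        genes, profiles, markers = studies._typing_panel()
        rng = np.random.default_rng(8)
        ref_cells = {}
        cols, ids = [], []
        for t in studies.TYPING_TYPES:
            p = profiles[t] / profiles[t].sum()
            for k in range(200):
                cid = f"{t}_{k}"
                cols.append(rng.poisson(400 * p))
                ids.append(cid)
            ref_cells[t] = [f"{t}_{k}" for k in range(200)]
        cm = _counts(genes, ids, np.column_stack(cols))
        prof = build_reference_profile(cm, ref_cells)
        for t in studies.TYPING_TYPES:
            est = prof.profile[:, prof.cell_types.index(t)]
            expect = 400 * profiles[t] / profiles[t].sum()
            sel = expect > 5  # marker genes
            assert np.all(np.abs(est[sel] - expect[sel]) / expect[sel] < 0.10)


class TestAssignTypes:
    def _two_type_profile(self):
        genes = ["g1", "g2", "g3", "g4"]
        profile = np.array([[10.0, 0.1], [5.0, 0.1], [0.1, 10.0], [0.1, 5.0]])
        from nichemap.celltyping import ReferenceProfile

        return ReferenceProfile(genes, ["A", "B"], profile, 0.05, {"A": 1, "B": 1})

    def test_high_depth_cell_concentrates_posterior(self):
        """A cell sampled from type A's normalized profile at depth 1e4 is
        assigned to A with posterior > 0.99; the in-package likelihood
        matches a brute-force Poisson log-pmf computation."""
        ref = self._two_type_profile()
        rng = np.random.default_rng(0)
        adj = ref.profile + ref.negctrl_mean
        p = adj / adj.sum(axis=0)
        y = rng.poisson(1e4 * p[:, 0])
        cm = _counts(ref.genes, ["c"], y[:, None])
        res = assign_types(cm, ref)
        assert res.assignments.loc[0, "broad_type"] == "A"
        assert res.posterior[0, res.cell_types.index("A")] > 0.99
        # independent oracle: sum of Poisson log-pmfs at each type's rates
        total = y.sum()
        ll = np.array([
            poisson.logpmf(y, total * p[:, t]).sum() for t in range(2)
        ])
        want = np.exp(ll - ll.max())
        want = want / want.sum()
        assert np.allclose(res.posterior[0], want, atol=1e-12)

    def test_identical_profiles_split_posterior(self):
        from nichemap.celltyping import ReferenceProfile

        profile = np.array([[3.0, 3.0], [1.0, 1.0]])
        ref = ReferenceProfile(["g1", "g2"], ["A", "B"], profile, 0.0, {"A": 1, "B": 1})
        cm = _counts(["g1", "g2"], ["c"], np.array([[7], [2]]))
        res = assign_types(cm, ref)
        assert np.allclose(res.posterior[0], [0.5, 0.5])

    def test_posterior_invariant_to_profile_scaling(self):
        ref = self._two_type_profile()
        cm = _counts(ref.genes, ["c"], np.array([[6], [3], [1], [0]]))
        res1 = assign_types(cm, ref)
        import dataclasses

        # scale profile AND background: rates are defined up to a constant
        ref2 = dataclasses.replace(
            ref, profile=ref.profile * 37.0, negctrl_mean=ref.negctrl_mean * 37.0
        )
        res2 = assign_types(cm, ref2)
        assert np.allclose(res1.posterior, res2.posterior)

    def test_zero_count_cell_raises(self):
        ref = self._two_type_profile()
        cm = _counts(ref.genes, ["c"], np.zeros((4, 1), dtype=int))
        with pytest.raises(ValueError, match="zero total"):
            assign_types(cm, ref)

    def test_round2_refines_but_never_changes_broad_class(self):
        rng = np.random.default_rng(5)
        genes = ["CD3E", "CD3D", "CD4", "CD8A", "CD19", "CD79A"]
        sub_markers = {"T cell": {"CD4 T": ["CD4"], "CD8 T": ["CD8A"]}}
        cols, ids = [], []
        for k in range(60):
            y = rng.poisson([20, 10, 15, 0.1, 0.1, 0.1])
            cols.append(y)
            ids.append(f"t4_{k}")
        for k in range(60):
            y = rng.poisson([20, 10, 0.1, 15, 0.1, 0.1])
            cols.append(y)
            ids.append(f"t8_{k}")
        for k in range(60):
            y = rng.poisson([0.1, 0.1, 0.1, 0.1, 20, 12])
            cols.append(y)
            ids.append(f"b_{k}")
        cm = _counts(genes, ids, np.column_stack(cols))
        refs = select_reference_cells(cm, {"T cell": ["CD3E", "CD3D"],
                                           "B cell": ["CD19", "CD79A"]})
        prof = build_reference_profile(cm, refs)
        res = assign_types(cm, prof, round2_panel=sub_markers)
        a = res.assignments
        t_rows = a[a["broad_type"] == "T cell"]
        assert set(t_rows["subtype"]) <= {"CD4 T", "CD8 T"}
        b_rows = a[a["broad_type"] == "B cell"]
        assert (b_rows["subtype"] == "B cell").all()
        cd4 = a[a["cell_id"].str.startswith("t4")]
        assert (cd4["subtype"] == "CD4 T").mean() > 0.9


class TestValidateBySize:
    def test_fraction_matches_confusion_oracle(self, small_fov):
        _, cells, _, _, _ = small_fov
        import pandas as pd

        calls = pd.DataFrame({
            "cell_id": [c.cell_id for c in cells],
            "broad_type": ["megakaryocyte" if i % 3 else "T cell"
                           for i in range(len(cells))],
            "subtype": "x", "posterior_max": 1.0,
        })
        from nichemap.celltyping import TypingResult

        typing = TypingResult([c.cell_id for c in cells], ["x"],
                              np.ones((len(cells), 1)), calls)
        thresh = float(np.median([c.area for c in cells]))
        frac = celltyping.validate_by_size(cells, typing, thresh, "megakaryocyte")
        large = [c for c in cells if c.area > thresh]
        want = np.mean([
            calls.set_index("cell_id").loc[c.cell_id, "broad_type"] == "megakaryocyte"
            for c in large
        ])
        assert frac == pytest.approx(want)

    def test_no_large_cells_returns_none(self, small_fov):
        _, cells, _, _, _ = small_fov
        import pandas as pd

        from nichemap.celltyping import TypingResult

        calls = pd.DataFrame({"cell_id": [c.cell_id for c in cells],
                              "broad_type": "T cell", "subtype": "x",
                              "posterior_max": 1.0})
        typing = TypingResult([c.cell_id for c in cells], ["x"],
                              np.ones((len(cells), 1)), calls)
        assert celltyping.validate_by_size(cells, typing, 1e9, "megakaryocyte") is None
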