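"""Ring count construction and the Poisson mixed count model."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from nichemap import geometry, glmm, simulate
from nichemap.io import CellRecord


def _cell(cell_id, poly, cell_type, fov="F1"):
    return CellRecord(
        cell_id=cell_id, fov_id=fov, sample_id="S", patient_id="P1",
        timepoint="baseline", response="responder", cell_type=cell_type,
        polygon=poly,
    )


class TestBuildRingCounts:
    def _fixture(self):
        cells = [
            _cell("L", box(0, 0, 4, 4), "leukemia"),
            # ring [5, 15): three T cells and two monocytes
            _cell("t1", box(10, 0, 12, 2), "T cell"),
            _cell("t2", box(0, 10, 2, 12), "T cell"),
            _cell("t3", box(11, 3, 13, 5), "T cell"),
            _cell("m1", box(12, 0, 14, 2), "CD14 monocyte"),
            _cell("m2", box(0, 12, 2, 14), "CD14 monocyte"),
            # an RBC in the same ring: excluded from totals
            _cell("r1", box(3, 12, 5, 14), "RBC"),
        ]
        ra = geometry.assign_rings(cells, ["L"], [0, 5, 15, 25, 35, 45])
        return cells, ra

    def test_counts_and_shared_totals(self):
        cells, ra = self._fixture()
        rec = glmm.build_ring_counts(ra, cells)
        ring1 = rec[rec["ring_index"] == 1].set_index("focal_type")
        assert ring1.loc["T cell", "count"] == 3
        assert ring1.loc["CD14 monocyte", "count"] == 2
        assert (ring1["total"] == 5).all()  # RBC not counted

    def test_empty_rings_emit_no_records(self):
        cells, ra = self._fixture()
        rec = glmm.build_ring_counts(ra, cells)
        assert set(rec["ring_index"]) == {1}

    def test_totals_equal_sum_over_focal_types(self, small_fov):
        _, cells, _, _, truth = small_fov
        ra = geometry.assign_rings(cells, truth.leukemia_ids, [0, 5, 15, 25, 35, 45])
        rec = glmm.build_ring_counts(ra, cells)
        focal = sorted(rec["focal_type"].unique())
        for (leuk, ring), grp in rec.groupby(["leukemia_cell_id", "ring_index"]):
            # totals include leukemia neighbors, counts cover non-leukemia types
            meta = {c.cell_id: c.cell_type for c in cells}
            n_leuk_neighbors = sum(
                1 for _, row in ra.iterrows()
                if row["leukemia_cell_id"] == leuk and row["ring_index"] == ring
                and meta[row["other_cell_id"]] == "leukemia"
            )
            assert grp["count"].sum() + n_leuk_neighbors == grp["total"].iloc[0]
            assert set(grp["focal_type"]) == set(focal)


class TestPoissonGLMM:
    def test_offset_identity(self):
        """Doubling every total shifts only the intercept, by -log 2."""
        rec = simulate.simulate_ring_records(rr_post_responder=2.0, seed=2)
        res1 = glmm.fit_niche_model(rec)
        rec2 = rec.assign(total=rec["total"] * 2)
        res2 = glmm.fit_niche_model(rec2)
        b1 = res1.coefficients.set_index("term")["estimate"]
        b2 = res2.coefficients.set_index("term")["estimate"]
        assert b2["Intercept"] - b1["Intercept"] == pytest.approx(-np.log(2), abs=1e-4)
        others = [t for t in b1.index if t != "Intercept"]
        assert np.allclose(b1[others], b2[others], atol=1e-4)

    def test_fixed_effects_invariant_to_fov_relabeling(self):
        rec = simulate.simulate_ring_records(rr_post_responder=1.5, seed=4)
        res1 = glmm.fit_niche_model(rec)
        relabeled = rec.assign(fov_id="x_" + rec["fov_id"])
        res2 = glmm.fit_niche_model(relabeled)
        assert np.allclose(
            res1.coefficients["estimate"], res2.coefficients["estimate"], atol=1e-6
        )
        assert res1.sigma2 == pytest.approx(res2.sigma2, rel=1e-4)

    def test_variance_component_recovered(self):
        rec = simulate.simulate_ring_records(
            rr_post_responder=1.0, fov_sd=0.5, n_fovs_per_patient=40, seed=6
        )
        res = glmm.fit_niche_model(rec)
        assert 0.5**2 * 0.5 < res.sigma2 < 0.5**2 * 2.0

    def test_missing_factor_levels_rejected(self):
        rec = simulate.simulate_ring_records(seed=0)
        only_baseline = rec[rec["timepoint"] == "baseline"]
        with pytest.raises(ValueError, match="levels"):
            glmm.fit_niche_model(only_baseline)

    def test_agrees_with_lme4_glmer(self, tmp_path):
        """Independent oracle: lme4's Laplace glmer fit on the same records
        reproduces our per-condition fixed-effect predictions and variance."""
        rec = simulate.simulate_ring_records(
            n_patients=4, n_fovs_per_patient=8, rr_post_responder=2.0, seed=9
        )
        res = glmm.fit_niche_model(rec)
        data_path = tmp_path / "rec.csv"
        rec.to_csv(data_path, index=False)
        out_path = tmp_path / "out.csv"
        rscript = tmp_path / "fit.R"
        rscript.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{data_path}")
            d$response <- factor(d$response, levels=c("nonresponder","responder"))
            d$timepoint <- factor(d$timepoint, levels=c("baseline","post_ici"))
            d$ring <- factor(d$ring_index)
            m <- glmer(count ~ response*timepoint*ring + (1|fov_id),
                       offset=log(total), family=poisson, data=d)
            grid <- unique(d[, c("response","timepoint","ring")])
            grid$eta <- predict(m, newdata=grid, re.form=NA)
            grid$sigma2 <- as.numeric(VarCorr(m)$fov_id[1])
            write.csv(grid, "{out_path}", row.names=FALSE)
        """))
        subprocess.run(["Rscript", str(rscript)], check=True, capture_output=True)
        ref = pd.read_csv(out_path)
        beta = res.coefficients["estimate"].to_numpy()
        for _, row in ref.iterrows():
            eta_ours = res.design.row(
                row["response"], row["timepoint"], int(row["ring"])
            ) @ beta
            assert eta_ours == pytest.approx(row["eta"], abs=2e-2)
        assert res.sigma2 == pytest.approx(ref["sigma2"].iloc[0], rel=0.2, abs=0.02)

    def test_fixed_fov_glm_cross_checks_ring_effects(self):
        rec = simulate.simulate_ring_records(rr_post_responder=1.0, seed=13)
        res = glmm.fit_niche_model(rec)
        glm = glmm.fit_fixed_fov_glm(rec).set_index("term")
        beta = res.coefficients.set_index("term")["estimate"]
        for r in (1, 2, 3, 4):
            assert glm.loc[f"ring_{r}", "estimate"] == pytest.approx(
                beta[f"ring[{r}]"], abs=0.08
            )


class TestContrasts:
    def test_single_contrast_adjusted_equals_raw(self):
        rec = simulate.simulate_ring_records(rr_post_responder=2.0, seed=3)
        res = glmm.fit_niche_model(rec)
        spec = [("only", ("responder", "post_ici", 0), ("responder", "baseline", 0))]
        table = glmm.niche_contrasts([res], spec)
        assert len(table) == 1
        assert table.loc[0, "p_adjusted"] == table.loc[0, "p_raw"]

    def test_bonferroni_arithmetic(self):
        rec = simulate.simulate_ring_records(rr_post_responder=2.0, seed=3)
        res = glmm.fit_niche_model(rec)
        table = glmm.niche_contrasts([res])
        m = len(table)
        for _, row in table.iterrows():
            assert row["p_adjusted"] == pytest.approx(min(1.0, row["p_raw"] * m))
        assert (table["p_adjusted"] >= table["p_raw"] - 1e-15).all()
        # hand check of the published arithmetic: m tests at p=0.004
        assert min(1.0, 20 * 0.004) == pytest.approx(0.08)

    def test_absent_level_raises(self):
        rec = simulate.simulate_ring_records(rr_post_responder=2.0, seed=3)
        res = glmm.fit_niche_model(rec)
        spec = [("bad", ("responder", "eoc2", 0), ("responder", "baseline", 0))]
        with pytest.raises(ValueError, match="absent"):
            glmm.niche_contrasts([res], spec)

    def test_rr_equals_exp_log_rr(self):
        rec = simulate.simulate_ring_records(rr_post_responder=2.0, seed=3)
        res = glmm.fit_niche_model(rec)
        table = glmm.niche_contrasts([res])
        assert np.allclose(table["rr"], np.exp(table["log_rr"]))
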