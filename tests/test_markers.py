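"""Genotype-matrix preprocessing, association, LD blocks and marker models."""

import json

import numpy as np
import pandas as pd
import pytest

from headcast.markers import (
    GenotypeMatrix,
    MarkerLinearModel,
    associate,
    backward_eliminate,
    impute,
    ld_blocks,
    load_bundled_model,
    major_gene_model,
    mask_rare,
    pfc_filter,
    predict_parameter,
)


def matrix_from(cols: dict, index=None) -> GenotypeMatrix:
    n = len(next(iter(cols.values())))
    idx = index or [f"G{i}" for i in range(n)]
    return GenotypeMatrix.from_calls(pd.DataFrame(cols, index=idx, dtype=object))


class TestMaskRare:
    def test_class_below_threshold_masked(self):
        mat = matrix_from({"A": ["11"] * 96 + ["22"] * 4})
        out = mask_rare(mat, min_freq=0.05)
        assert out.calls["A"].isna().sum() == 4  # 4% < 5%
        assert (out.calls["A"].dropna() == "11").all()

    def test_balanced_marker_untouched(self):
        mat = matrix_from({"A": ["11"] * 50 + ["22"] * 50})
        assert mask_rare(mat).calls.equals(mat.calls)

    def test_zero_threshold_is_identity(self):
        mat = matrix_from({"A": ["11"] * 99 + ["22"]})
        assert mask_rare(mat, min_freq=0.0).calls.equals(mat.calls)

    def test_frequencies_among_nonmissing_calls(self):
        # 3 of 50 non-missing = 6% -> kept even with 50 extra missing rows
        col = ["11"] * 47 + ["22"] * 3 + [np.nan] * 50
        mat = matrix_from({"A": col})
        assert mask_rare(mat).calls["A"].notna().sum() == 50


class TestImpute:
    def test_planted_copy_recovered_with_zero_pfc(self):
        rng = np.random.default_rng(1)
        n = 80
        a = np.where(rng.random(n) < 0.5, "11", "22")
        b = a.astype(object).copy()
        masked_rows = rng.choice(n, 16, replace=False)
        b[masked_rows] = np.nan
        mat = matrix_from({"A": list(a), "B": list(b), "C": list(
            np.where(rng.random(n) < 0.5, "11", "22"))})
        out, report = impute(mat, seed=0, n_trees=60)
        assert not out.calls.isna().any().any()
        recovered = out.calls["B"].iloc[masked_rows] == pd.Series(a).iloc[masked_rows].values
        assert recovered.all()
        assert report.pfc["B"] < 0.05

    def test_independent_marker_pfc_near_mode_baseline(self):
        rng = np.random.default_rng(2)
        n = 150
        cols = {
            f"M{j}": list(np.where(rng.random(n) < 0.5, "11", "22")) for j in range(4)
        }
        target = np.where(rng.random(n) < 0.3, "ins", "del").astype(object)
        target[rng.choice(n, 20, replace=False)] = np.nan
        cols["T"] = list(target)
        mat = matrix_from(cols)
        _, report = impute(mat, seed=0, n_trees=60)
        # best achievable for an unlinked marker ~ always guess the mode
        assert report.pfc["T"] == pytest.approx(0.3, abs=0.12)

    def test_complete_matrix_is_identity(self):
        mat = matrix_from({"A": ["11", "22"] * 10, "B": ["ins", "del"] * 10})
        out, report = impute(mat, seed=0)
        assert out.calls.equals(mat.calls)
        assert report.pfc == {}

    def test_fully_missing_marker_rejected(self):
        mat = matrix_from({"A": ["11", "22"] * 5, "B": [np.nan] * 10})
        with pytest.raises(ValueError, match="missing in every genotype"):
            impute(mat, seed=0)


class TestPfcFilter:
    def test_boundary_strictly_greater(self):
        mat = matrix_from({"A": ["11", "22"] * 5, "B": ["11", "22"] * 5})
        from headcast.markers import ImputationReport

        report = ImputationReport(pfc={"A": 0.2, "B": 0.21})
        out = pfc_filter(mat, report, max_pfc=0.2)
        assert out.marker_ids == ["A"]  # 0.2 retained, 0.21 dropped
        assert "n_missing_raw" in out.meta.columns

    def test_empty_report_is_identity(self):
        mat = matrix_from({"A": ["11", "22"] * 5})
        from headcast.markers import ImputationReport

        assert pfc_filter(mat, ImputationReport()).marker_ids == ["A"]


@pytest.fixture(scope="module")
def null_scan():
    """200 unlinked markers, 120 genotypes, trait driven by structure only."""
    rng = np.random.default_rng(5)
    n, m = 120, 200
    freqs = rng.uniform(0.2, 0.8, m)
    calls = pd.DataFrame(
        np.where(rng.random((n, m)) < freqs, "11", "22"),
        index=[f"G{i}" for i in range(n)],
        columns=[f"mk{j}" for j in range(m)],
        dtype=object,
    )
    mat = GenotypeMatrix.from_calls(calls)
    structure = pd.DataFrame(
        rng.dirichlet([1.0] * 4, n), index=calls.index, columns=["g1", "g2", "g3", "g4"]
    )
    trait = pd.Series(
        structure.values @ np.array([10.0, 20.0, 5.0, 0.0]) + rng.normal(0, 3, n),
        index=calls.index,
    )
    return mat, structure, trait


class TestAssociate:
    def test_null_type_one_error_calibrated(self, null_scan):
        mat, structure, trait = null_scan
        recs = associate(trait, mat, structure, B=0, seed=0)
        raw = np.array([r.raw_p for r in recs])
        frac = (raw < 0.05).mean()
        # binomial 99% band around 0.05 over 200 markers
        half = 2.576 * np.sqrt(0.05 * 0.95 / len(raw))
        assert abs(frac - 0.05) <= half
        from scipy import stats

        assert stats.kstest(raw, "uniform").pvalue > 0.01

    def test_permutation_adjustment_reproducible_and_bounded(self, null_scan):
        mat, structure, trait = null_scan
        sub = GenotypeMatrix(mat.calls.iloc[:, :40].copy(), mat.meta.iloc[:40].copy())
        a = associate(trait, sub, structure, B=200, seed=11)
        b = associate(trait, sub, structure, B=200, seed=11)
        assert [r.adjusted_p for r in a] == [r.adjusted_p for r in b]
        for r in a:
            assert 1 / 201 <= r.adjusted_p <= 1.0
            assert 0.0 <= r.r2 <= 1.0

    def test_planted_effect_has_smallest_adjusted_p(self, null_scan):
        mat, structure, trait = null_scan
        sub = GenotypeMatrix(mat.calls.iloc[:, :30].copy(), mat.meta.iloc[:30].copy())
        planted = sub.marker_ids[3]
        y = trait + 40.0 * (sub.calls[planted] == "22")
        recs = associate(y, sub, structure, B=100, seed=2)
        best = min(recs, key=lambda r: (r.adjusted_p, r.raw_p))
        assert best.marker_id == planted

    def test_monomorphic_marker_skipped_with_notice(self, null_scan):
        _, structure, trait = null_scan
        mat = matrix_from(
            {"mono": ["11"] * 120, "ok": ["11", "22"] * 60},
            index=list(structure.index),
        )
        with pytest.warns(UserWarning, match="monomorphic"):
            recs = associate(trait, mat, structure, B=0)
        assert [r.marker_id for r in recs] == ["ok"]

    def test_b_zero_gives_raw_only(self, null_scan):
        mat, structure, trait = null_scan
        sub = GenotypeMatrix(mat.calls.iloc[:, :5].copy(), mat.meta.iloc[:5].copy())
        recs = associate(trait, sub, structure, B=0)
        assert all(r.adjusted_p is None for r in recs)


class TestLdBlocks:
    def test_duplicate_pair_blocks_and_representative(self):
        rng = np.random.default_rng(3)
        a = list(np.where(rng.random(100) < 0.5, "11", "22"))
        b = list(a)
        b[0] = np.nan  # B has more raw missing than A
        mat = matrix_from({"A": a, "B": b})
        blocks, reps = ld_blocks(mat)
        assert blocks == [["A", "B"]]
        assert reps == ["A"]

    def test_independent_markers_are_singletons(self):
        rng = np.random.default_rng(4)
        cols = {
            f"M{j}": list(np.where(rng.random(200) < 0.5, "11", "22"))
            for j in range(6)
        }
        blocks, reps = ld_blocks(matrix_from(cols))
        assert all(len(b) == 1 for b in blocks)
        assert reps == [f"M{j}" for j in range(6)]

    def test_chain_closure_groups_three_markers(self):
        rng = np.random.default_rng(6)
        n = 200
        base = np.where(rng.random(n) < 0.5, "11", "22").astype(object)
        m2 = base.copy()
        f2 = rng.choice(n, 8, replace=False)
        m2[f2] = np.where(m2[f2] == "11", "22", "11")
        m3 = m2.copy()
        f3 = rng.choice(n, 8, replace=False)
        m3[f3] = np.where(m3[f3] == "11", "22", "11")
        mat = matrix_from({"M1": list(base), "M2": list(m2), "M3": list(m3)})
        blocks, _ = ld_blocks(mat, r_threshold=0.8)
        assert blocks == [["M1", "M2", "M3"]]  # connected component closure


@pytest.fixture(scope="module")
def elimination_panel():
    rng = np.random.default_rng(8)
    n = 120
    cols = {
        f"N{j}": list(np.where(rng.random(n) < 0.5, "11", "22")) for j in range(5)
    }
    planted = np.where(rng.random(n) < 0.4, "22", "11")
    cols["Q"] = list(planted)
    mat = matrix_from(cols)
    y = pd.Series(
        20.0 + 18.0 * (planted == "22") + rng.normal(0, 2.0, n),
        index=mat.calls.index,
    )
    return mat, y


class TestBackwardElimination:
    def test_planted_marker_survives_noise_candidates(self, elimination_panel):
        mat, y = elimination_panel
        model = backward_eliminate(y, mat.marker_ids, mat, trait="v_sat")
        assert "Q" in model.markers()
        assert model.r2_fit > 0.5

    def test_pure_noise_candidate_gives_intercept_only(self, elimination_panel):
        mat, y = elimination_panel
        rng = np.random.default_rng(9)
        z = pd.Series(rng.normal(0, 1, len(y)), index=y.index)
        model = backward_eliminate(z, ["N0"], mat)
        assert model.terms == []
        assert model.intercept == pytest.approx(float(z.mean()))

    def test_alpha_one_retains_every_candidate(self, elimination_panel):
        mat, y = elimination_panel
        model = backward_eliminate(y, mat.marker_ids, mat, alpha=1.0)
        assert set(model.markers()) == set(mat.marker_ids)

    def test_rank_deficiency_reported(self):
        rng = np.random.default_rng(10)
        n = 5
        cols = {
            f"M{j}": list(np.where(rng.random(n) < 0.5, "11", "22"))
            for j in range(8)
        }
        mat = matrix_from(cols)
        y = pd.Series(rng.normal(size=n), index=mat.calls.index)
        with pytest.raises(ValueError, match="rank deficiency"):
            backward_eliminate(y, mat.marker_ids, mat)

    def test_residual_mean_zero_on_fitting_data(self, elimination_panel):
        mat, y = elimination_panel
        model = backward_eliminate(y, mat.marker_ids, mat)
        preds = [
            predict_parameter(model, mat.calls.loc[g].to_dict())
            for g in mat.genotype_ids
        ]
        assert float(np.mean(y.to_numpy() - np.array(preds))) == pytest.approx(
            0.0, abs=1e-8
        )

    def test_major_gene_restriction(self, elimination_panel):
        mat, y = elimination_panel
        only_q = major_gene_model(y, mat, ["Q"])
        assert only_q.markers() == ["Q"]
        empty = major_gene_model(y, mat, [])
        assert empty.terms == []
        full = major_gene_model(y, mat, mat.marker_ids)
        assert full.terms == backward_eliminate(y, mat.marker_ids, mat).terms


class TestBundledModels:
    def ref_calls(self, model):
        return {t["marker"]: t["reference"] for t in model.terms}

    def test_reference_genotype_predicts_intercepts(self):
        mv = load_bundled_model("v_sat")
        mp = load_bundled_model("p_base")
        assert predict_parameter(mv, self.ref_calls(mv)) == pytest.approx(53.9)
        assert predict_parameter(mp, self.ref_calls(mp)) == pytest.approx(4.85)

    @pytest.mark.parametrize(
        "trait,marker,allele,delta",
        [
            ("p_base", "PpdD1.PromDel", "2", -1.5),
            ("v_sat", "Vrn.A1ex7", "12", -24.7),
            ("v_sat", "Vrn.A1ex7", "22", -28.3),
            ("v_sat", "vern.5B.Sins.8761", "ins", 13.3),
            ("v_sat", "Vrn.A1pr", "44", 36.6),
            ("p_base", "gpw1107", "171", 0.7),
        ],
    )
    def test_single_allele_contrasts(self, trait, marker, allele, delta):
        model = load_bundled_model(trait)
        ref = self.ref_calls(model)
        alt = dict(ref)
        alt[marker] = allele
        got = predict_parameter(model, alt) - predict_parameter(model, ref)
        assert got == pytest.approx(delta)

    def test_unknown_or_missing_call_is_an_error(self):
        model = load_bundled_model("v_sat")
        calls = self.ref_calls(model)
        bad = dict(calls)
        bad["Vrn.A1ex7"] = "99"
        with pytest.raises(ValueError, match="unknown allele"):
            predict_parameter(model, bad)
        gone = dict(calls)
        del gone["Vrn.A1ex7"]
        with pytest.raises(KeyError):
            predict_parameter(model, gone)
        nan = dict(calls)
        nan["Vrn.A1ex7"] = float("nan")
        with pytest.raises(ValueError, match="missing call"):
            predict_parameter(model, nan)

    def test_empty_model_predicts_intercept(self):
        m = MarkerLinearModel("v_sat", 12.5, [])
        assert predict_parameter(m, {}) == 12.5

    def test_json_round_trip(self, tmp_path):
        m = load_bundled_model("p_base")
        path = tmp_path / "m.json"
        m.to_json(path)
        back = MarkerLinearModel.from_json(path)
        assert back.trait == m.trait
        assert back.intercept == m.intercept
        assert back.terms == m.terms
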