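"""Grid construction, the RMSEP objective, and brute-force calibration."""

import datetime as dt

import numpy as np
import pytest

from headcast.calibrate import (
    GridSpec,
    HeadingModel,
    PanelEngine,
    UnfilterableGenotypeError,
    build_grid,
    filter_winter_vectors,
    optimize_genotype,
    resample_robustness,
    rmsep,
    select_representative,
)
from headcast.io import HeadingObservation
from headcast.phenology import GenotypeParameters, simulate


def doy(d):
    return dt.date(2001, 1, 1) + dt.timedelta(days=d - 1)


class TestGrid:
    def test_two_parameter_grid_cardinality(self):
        grid = build_grid(GridSpec(strategy="2p"))
        assert len(grid) == 13231  # 101 x 131
        assert all(g.tt_emhe == 500.0 for g in grid)

    def test_three_parameter_grid_cardinality(self):
        spec = GridSpec(strategy="3p")
        assert spec.n_vectors == 542471  # 101 x 131 x 41
        assert spec.v_sat_axis().size == 131
        assert spec.p_base_axis().size == 101
        assert spec.tt_emhe_axis().size == 41

    def test_degenerate_grid_is_single_vector(self):
        spec = GridSpec(
            strategy="3p",
            v_sat_range=(10.0, 10.0),
            p_base_range=(2.0, 2.0),
            tt_emhe_range=(500.0, 500.0),
        )
        assert build_grid(spec) == [GenotypeParameters(10.0, 2.0, 500.0)]

    def test_grid_order_v_sat_outer(self):
        spec = GridSpec(
            v_sat_range=(0.0, 1.0), p_base_range=(0.0, 0.2), p_base_step=0.1
        )
        got = [(g.v_sat, g.p_base) for g in build_grid(spec)]
        assert got == [(0, 0), (0, 0.1), (0, 0.2), (1, 0), (1, 0.1), (1, 0.2)]


class TestRmsep:
    def test_zero_for_perfect_prediction(self):
        dates = [doy(100), doy(120)]
        assert rmsep(dates, dates) == 0.0

    def test_hand_arithmetic(self):
        assert rmsep([doy(100), doy(110)], [doy(103), doy(106)]) == pytest.approx(
            np.sqrt((9 + 16) / 2)
        )

    def test_single_pair(self):
        assert rmsep([doy(100)], [doy(107)]) == 7.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmsep([], [])

    def test_not_reached_uses_penalty_date(self):
        got = rmsep([doy(100)], [None], nr_penalty=[doy(150)])
        assert got == 50.0
        with pytest.raises(ValueError, match="penalty"):
            rmsep([doy(100)], [None])


@pytest.fixture(scope="module")
def tiny_engine(request):
    """Engine over the recovery dataset's experiments with a 5x5 grid."""
    data = request.getfixturevalue("recovery_dataset")
    spec = GridSpec(
        v_sat_range=(0.0, 40.0),
        v_sat_step=10.0,
        p_base_range=(0.0, 4.0),
        p_base_step=1.0,
    )
    return data, spec, PanelEngine(
        data["experiments"], data["sites"], data["weather"], spec
    )


class TestOracleEquivalence:
    def test_grid_rmsep_bit_identical_to_naive_resimulation(self, tiny_engine):
        """The vectorized grid path must agree bit-for-bit with running the
        scalar day-step simulator once per vector."""
        data, spec, eng = tiny_engine
        gid = data["truth"].index[0]
        obs_by_exp = {
            o.experiment_id: o.heading
            for o in data["observations"]
            if o.genotype_id == gid and o.heading is not None
        }
        fast = eng.rmsep_over(obs_by_exp)
        grid = build_grid(spec)
        for i, p in enumerate(grid):
            diffs = []
            for exp_id, obs in obs_by_exp.items():
                exp = data["experiments"][exp_id]
                site = data["sites"][exp.site]
                wx = [
                    w
                    for w in data["weather"][exp.site]
                    if w.date <= exp.sowing_date + dt.timedelta(days=exp.horizon_days)
                ]
                tr = simulate(exp.sowing_date, wx, site, p)
                pred = tr.heading_date or (wx[-1].date + dt.timedelta(days=1))
                diffs.append((pred - obs).days)
            naive = float(np.sqrt(np.mean(np.asarray(diffs, dtype=float) ** 2)))
            assert fast[i] == naive  # exact, not approx


class TestOptimize:
    def test_forward_simulated_genotype_attains_zero_rmsep(self, recovery_dataset):
        data = recovery_dataset
        gid = data["truth"].index[0]
        truth = data["truth"].loc[gid]
        res = optimize_genotype(
            gid,
            data["observations"],
            data["experiments"],
            data["sites"],
            data["weather"],
        )
        assert res.min_rmsep == 0.0
        assert any(
            v.v_sat == truth["v_sat"] and v.p_base == truth["p_base"]
            for v in res.minimizing_vectors
        )
        assert res.selected in res.minimizing_vectors

    def test_autumn_only_observation_is_ambiguous(self, recovery_dataset):
        data = recovery_dataset
        gid = data["truth"].index[0]
        one_autumn = [
            o
            for o in data["observations"]
            if o.genotype_id == gid and o.experiment_id == "aut2000CF"
        ]
        res = optimize_genotype(
            gid, one_autumn, data["experiments"], data["sites"], data["weather"]
        )
        assert len(res.minimizing_vectors) > 1  # v_sat not identifiable

    def test_all_not_headed_rejected(self, recovery_dataset):
        data = recovery_dataset
        obs = [HeadingObservation("GX", "aut2000CF", None)]
        with pytest.raises(ValueError, match="no usable"):
            optimize_genotype(
                "GX", obs, data["experiments"], data["sites"], data["weather"]
            )

    def test_removing_experiment_never_raises_total_squared_error(self, tiny_engine):
        # each vector's subset sum of squared errors is bounded by its full
        # sum, so the attainable minimum total squared error cannot grow
        data, spec, eng = tiny_engine
        for gid in data["truth"].index[:5]:
            obs_by_exp = {
                o.experiment_id: o.heading
                for o in data["observations"]
                if o.genotype_id == gid and o.heading is not None
            }
            n = len(obs_by_exp)
            full = (eng.rmsep_over(obs_by_exp) ** 2 * n).min()
            for drop in obs_by_exp:
                sub = {e: d for e, d in obs_by_exp.items() if e != drop}
                sub_min = (eng.rmsep_over(sub) ** 2 * len(sub)).min()
                assert sub_min <= full + 1e-9


class TestRepresentative:
    def test_single_vector(self):
        v = [GenotypeParameters(10, 2)]
        assert select_representative(v, GridSpec()) == v[0]

    def test_median_member(self):
        vs = [GenotypeParameters(v, 2.0) for v in (10.0, 20.0, 30.0)]
        assert select_representative(vs, GridSpec()) == GenotypeParameters(20.0, 2.0)

    def test_tie_breaks_to_lowest_v_sat(self):
        vs = [GenotypeParameters(10.0, 2.0), GenotypeParameters(30.0, 2.0)]
        assert select_representative(vs, GridSpec()) == GenotypeParameters(10.0, 2.0)

    def test_axes_scaled_by_grid_step(self):
        # 1 day of v_sat counts like 0.1 h of p_base after scaling
        vs = [GenotypeParameters(10.0, 0.0), GenotypeParameters(12.0, 0.1)]
        med_scaled = select_representative(
            vs + [GenotypeParameters(10.0, 0.1)], GridSpec()
        )
        assert med_scaled == GenotypeParameters(10.0, 0.1)


class TestWinterFilter:
    def test_margin_semantics(self, small_dataset):
        data = small_dataset
        spec = GridSpec()
        eng = PanelEngine(data["experiments"], data["sites"], data["weather"], spec)
        spring_exp = "spr2001LM"
        winter_gid = data["truth"].index[data["truth"]["is_winter"]][0]
        res = optimize_genotype(
            winter_gid,
            [
                o
                for o in data["observations"]
                if o.genotype_id == winter_gid and o.heading is not None
            ],
            data["experiments"],
            data["sites"],
            data["weather"],
            eng=eng,
        )
        # a low-v_sat vector heads early in spring: removed with margin 10
        early = GenotypeParameters(0.0, 0.0, 500.0)
        pred_early = eng.predicted_date(spring_exp, eng.index_of(early))
        assert pred_early is not None
        fake = res.__class__(
            genotype_id=winter_gid,
            minimizing_vectors=[early, GenotypeParameters(130.0, 0.0, 500.0)],
            min_rmsep=res.min_rmsep,
            selected=early,
            n_experiments_used=res.n_experiments_used,
        )
        last = {spring_exp: pred_early}  # latest observed == early prediction
        # margin 0: prediction equal to the last observed heading is retained
        kept = filter_winter_vectors(fake, last, eng, margin_days=0)
        assert early in kept.minimizing_vectors
        # margin 10: the same vector now predicts too early and is removed;
        # the NOT_REACHED vector always survives
        kept10 = filter_winter_vectors(fake, last, eng, margin_days=10)
        assert early not in kept10.minimizing_vectors
        assert GenotypeParameters(130.0, 0.0, 500.0) in kept10.minimizing_vectors
        assert kept10.filtered

    def test_all_vectors_removed_is_an_error(self, small_dataset):
        data = small_dataset
        eng = PanelEngine(
            data["experiments"], data["sites"], data["weather"], GridSpec()
        )
        early = GenotypeParameters(0.0, 0.0, 500.0)
        pred = eng.predicted_date("spr2001LM", eng.index_of(early))
        from headcast.calibrate import CalibrationResult

        fake = CalibrationResult("g", [early], 0.0, early, 1)
        far_future = {"spr2001LM": pred + dt.timedelta(days=100)}
        with pytest.raises(UnfilterableGenotypeError):
            filter_winter_vectors(fake, far_future, eng, margin_days=10)


class TestRobustness:
    def test_fixed_seed_reproducible(self, recovery_dataset):
        data = recovery_dataset
        gid = data["truth"].index[1]
        kw = dict(
            observations=data["observations"],
            experiments=data["experiments"],
            sites=data["sites"],
            weather=data["weather"],
            n_repeats=5,
            seed=42,
        )
        a = resample_robustness(gid, **kw)
        b = resample_robustness(gid, **kw)
        assert a.equals(b)

    def test_noiseless_selection_is_stable(self, recovery_dataset):
        """Without observation noise the re-optimized parameters stay within
        the grid-tie width of each other across experiment subsets."""
        data = recovery_dataset
        gid = data["truth"].index[1]
        df = resample_robustness(
            gid,
            data["observations"],
            data["experiments"],
            data["sites"],
            data["weather"],
            n_repeats=8,
            seed=1,
        )
        assert df.attrs["sd_v_sat"] <= 6.0
        assert df.attrs["sd_p_base"] <= 0.5

    def test_requires_two_experiments_in_a_season(self, recovery_dataset):
        data = recovery_dataset
        gid = data["truth"].index[0]
        one = [
            o
            for o in data["observations"]
            if o.genotype_id == gid and o.experiment_id == "aut2000CF"
        ]
        with pytest.raises(ValueError, match=">=2"):
            resample_robustness(
                gid, one, data["experiments"], data["sites"], data["weather"]
            )


class TestHeadingModel:
    def test_fit_classes_and_summary(self, small_dataset):
        data = small_dataset
        model = HeadingModel(
            data["observations"],
            data["experiments"],
            data["sites"],
            data["weather"],
        )
        fit = model.fit()
        p = fit.params
        winter_ids = set(data["truth"].index[data["truth"]["is_winter"]])
        assert set(p.index) == set(data["truth"].index)
        for gid in winter_ids:
            assert model.is_winter(gid)
            assert p.loc[gid, "filtered"]
        # winter genotypes calibrate on autumn experiments only
        assert (p.loc[sorted(winter_ids), "n_experiments"] <= 3).all()
        text = fit.summary()
        assert "genotypes calibrated : 20" in text
        # predictions exist for every calibrated genotype x experiment
        preds = fit.predict()
        assert len(preds) == len(p) * len(data["experiments"])
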