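"""Brute-force grid calibration of genotype parameters.

For every genotype, the day-step model is run for every vector of a
parameter grid (``V_sat`` 0..130 d step 1; ``P_base`` 0..10 h step 0.1;
optionally ``TT_emhe`` 400..800 step 10) in every experiment where the
genotype headed, and the vectors minimizing the root-mean-square error of
prediction (RMSEP, in days) across experiments are retained.  Winter
genotypes — those that never headed in any spring sowing — are calibrated
on autumn sowings only, and their minimizing vectors are then filtered
using the spring information: a vector predicting heading earlier than the
last recorded heading plus a safety margin (default 10 days) in any
spring-sown experiment is discarded.  When several vectors tie, the
representative is the one closest (in grid-step units) to the
component-wise median of the tied set.

Exposed both as plain functions (``optimize_genotype``,
``filter_winter_vectors``, ``select_representative``,
``resample_robustness``) and as the :class:`HeadingModel` /
:class:`CalibrationResults` pair, which calibrates a whole panel at once.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import engine
from .engine import NOT_REACHED_IDX, ExperimentSeries, build_series
from .io import DailyWeather, Experiment, HeadingObservation, Site
from .phenology import DEFAULT_CONSTANTS, NOT_REACHED, GenotypeParameters, ModelConstants

__all__ = [
    "GridSpec",
    "CalibrationResult",
    "build_grid",
    "rmsep",
    "optimize_genotype",
    "filter_winter_vectors",
    "select_representative",
    "resample_robustness",
    "HeadingModel",
    "CalibrationResults",
    "UnfilterableGenotypeError",
]

#: RMSEP values within this of the minimum count as ties.
TIE_TOL = 1e-9


class UnfilterableGenotypeError(ValueError):
    """Every minimizing vector was rejected by the winter-genotype filter."""


def _axis(lo: float, hi: float, step: float, decimals: int) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    return np.round(lo + step * np.arange(n), decimals)


@dataclass(frozen=True)
class GridSpec:
    """Parameter grid for brute-force calibration.

    The default ``2p`` grid spans 101 ``p_base`` x 131 ``v_sat`` = 13 231
    vectors with ``tt_emhe`` pinned at its default; the ``3p`` grid adds 41
    ``tt_emhe`` values for 542 471 vectors.  Bounds are inclusive.
    """

    strategy: str = "2p"
    v_sat_range: tuple[float, float] = (0.0, 130.0)
    v_sat_step: float = 1.0
    p_base_range: tuple[float, float] = (0.0, 10.0)
    p_base_step: float = 0.1
    tt_emhe_range: tuple[float, float] = (400.0, 800.0)
    tt_emhe_step: float = 10.0
    tt_emhe_default: float = 500.0

    def __post_init__(self):
        if self.strategy not in ("2p", "3p"):
            raise ValueError(f"strategy must be '2p' or '3p', got {self.strategy!r}")

    def v_sat_axis(self) -> np.ndarray:
        return _axis(*self.v_sat_range, self.v_sat_step, 6)

    def p_base_axis(self) -> np.ndarray:
        return _axis(*self.p_base_range, self.p_base_step, 6)

    def tt_emhe_axis(self) -> np.ndarray:
        if self.strategy == "2p":
            return np.array([self.tt_emhe_default])
        return _axis(*self.tt_emhe_range, self.tt_emhe_step, 6)

    @property
    def n_vectors(self) -> int:
        return (
            self.v_sat_axis().size * self.p_base_axis().size * self.tt_emhe_axis().size
        )

    def thinned(
        self, v_sat_step: float = 13.0, p_base_step: float = 0.7, tt_emhe_step: float = 100.0
    ) -> "GridSpec":
        """Coarser grid for sensitivity work and tests (ratio statistics such
        as the standardized regression coefficients are stable under
        thinning)."""
        return replace(
            self,
            v_sat_step=v_sat_step,
            p_base_step=p_base_step,
            tt_emhe_step=tt_emhe_step,
        )


def build_grid(spec: GridSpec) -> list[GenotypeParameters]:
    """All grid vectors, ``v_sat`` outermost, then ``p_base``, then
    ``tt_emhe``."""
    out = []
    for v in spec.v_sat_axis():
        for p in spec.p_base_axis():
            for t in spec.tt_emhe_axis():
                out.append(GenotypeParameters(float(v), float(p), float(t)))
    return out


def rmsep(obs, pred, nr_penalty=None):
    """Root-mean-square error of prediction between two date sequences, in
    days.

    ``pred`` entries may be the NOT_REACHED sentinel (``None``); these are
    replaced by the corresponding entry of ``nr_penalty`` (one past the end
    of the weather record), which keeps the objective finite and ordered.
    """
    if len(obs) != len(pred):
        raise ValueError("obs and pred must have equal length")
    if len(obs) == 0:
        raise ValueError("rmsep of an empty set is undefined")
    diffs = []
    for i, (o, pr) in enumerate(zip(obs, pred)):
        if pr is NOT_REACHED:
            if nr_penalty is None:
                raise ValueError(
                    "prediction NOT_REACHED but no penalty date provided"
                )
            pr = nr_penalty[i]
        diffs.append((o - pr).days)
    return float(np.sqrt(np.mean(np.asarray(diffs, dtype=float) ** 2)))


@dataclass
class CalibrationResult:
    """Outcome of grid calibration for one genotype."""

    genotype_id: str
    minimizing_vectors: list[GenotypeParameters]
    min_rmsep: float
    selected: GenotypeParameters
    n_experiments_used: int
    filtered: bool = False
    experiment_ids: tuple[str, ...] = ()


# --------------------------------------------------------------- engine


class PanelEngine:
    """Per-experiment grid predictions, computed once and reused.

    ``pred_ord[exp_id]`` is a flat int array over the grid (v_sat outer,
    p_base inner, tt_emhe innermost) of predicted heading dates as
    proleptic-Gregorian ordinals; never-reached vectors carry the
    experiment's penalty ordinal (last weather day + 1), kept alongside in
    ``penalty_ord`` so they can be told apart.
    """

    def __init__(
        self,
        experiments: dict[str, Experiment],
        sites: dict[str, Site],
        weather: dict[str, list[DailyWeather]],
        spec: GridSpec,
        k: ModelConstants = DEFAULT_CONSTANTS,
    ):
        self.spec = spec
        self.k = k
        self.experiments = experiments
        self.series: dict[str, ExperimentSeries] = {}
        self.pred_ord: dict[str, np.ndarray] = {}
        self.penalty_ord: dict[str, int] = {}
        va, pa, ta = spec.v_sat_axis(), spec.p_base_axis(), spec.tt_emhe_axis()
        self._axes = (va, pa, ta)
        for exp_id, exp in experiments.items():
            site = sites[exp.site]
            series = build_series(exp, weather[exp.site], site, k)
            self.series[exp_id] = series
            offs = engine.heading_offsets(series, va, pa, ta, k).reshape(-1)
            penalty = series.penalty_date.toordinal()
            base = series.sowing_date.toordinal() + 1
            ords = np.where(offs == NOT_REACHED_IDX, penalty, base + offs)
            self.pred_ord[exp_id] = ords
            self.penalty_ord[exp_id] = penalty

    def grid_params(self) -> list[GenotypeParameters]:
        return build_grid(self.spec)

    def vector_at(self, flat_idx: int) -> GenotypeParameters:
        va, pa, ta = self._axes
        iv, rem = divmod(flat_idx, pa.size * ta.size)
        ip, it = divmod(rem, ta.size)
        return GenotypeParameters(float(va[iv]), float(pa[ip]), float(ta[it]))

    def index_of(self, params: GenotypeParameters) -> int:
        va, pa, ta = self._axes
        iv = int(np.argmin(np.abs(va - params.v_sat)))
        ip = int(np.argmin(np.abs(pa - params.p_base)))
        it = int(np.argmin(np.abs(ta - params.tt_emhe)))
        return (iv * pa.size + ip) * ta.size + it

    def rmsep_over(self, obs_by_exp: dict[str, _dt.date]) -> np.ndarray:
        """RMSEP of every grid vector against one genotype's observations."""
        if not obs_by_exp:
            raise ValueError("no usable observations")
        sq = None
        for exp_id, obs in obs_by_exp.items():
            d = self.pred_ord[exp_id].astype(float) - obs.toordinal()
            sq = d * d if sq is None else sq + d * d
        return np.sqrt(sq / len(obs_by_exp))

    def predicted_date(self, exp_id: str, flat_idx: int) -> _dt.date | None:
        o = int(self.pred_ord[exp_id][flat_idx])
        if o == self.penalty_ord[exp_id]:
            return NOT_REACHED
        return _dt.date.fromordinal(o)


# --------------------------------------------------- per-genotype pieces


def _minimize(
    eng: PanelEngine, genotype_id: str, obs_by_exp: dict[str, _dt.date]
) -> tuple[list[int], float]:
    r = eng.rmsep_over(obs_by_exp)
    mn = float(r.min())
    idx = np.nonzero(r <= mn + TIE_TOL)[0]
    return list(map(int, idx)), mn


def select_representative(
    vectors: list[GenotypeParameters], spec: GridSpec
) -> GenotypeParameters:
    """The vector closest (scaled by grid steps) to the component-wise
    median of the tied set; ties broken by lowest v_sat, p_base, tt_emhe."""
    if not vectors:
        raise ValueError("no vectors to select from")
    scale = np.array([spec.v_sat_step, spec.p_base_step, spec.tt_emhe_step])
    pts = np.array([[v.v_sat, v.p_base, v.tt_emhe] for v in vectors]) / scale
    med = np.median(pts, axis=0)
    d2 = np.sum((pts - med) ** 2, axis=1)
    order = sorted(
        range(len(vectors)),
        key=lambda i: (d2[i], pts[i, 0], pts[i, 1], pts[i, 2]),
    )
    return vectors[order[0]]


def _finish(
    eng: PanelEngine,
    genotype_id: str,
    idx: list[int],
    mn: float,
    n_exp: int,
    exp_ids: tuple[str, ...],
    filtered: bool = False,
) -> CalibrationResult:
    vectors = [eng.vector_at(i) for i in idx]
    selected = select_representative(vectors, eng.spec)
    return CalibrationResult(
        genotype_id, vectors, mn, selected, n_exp, filtered, exp_ids
    )


def optimize_genotype(
    genotype_id: str,
    observations: list[HeadingObservation],
    experiments: dict[str, Experiment],
    sites: dict[str, Site],
    weather: dict[str, list[DailyWeather]],
    spec: GridSpec = GridSpec(),
    k: ModelConstants = DEFAULT_CONSTANTS,
    eng: PanelEngine | None = None,
) -> CalibrationResult:
    """Grid-calibrate one genotype on the experiments where it headed."""
    obs_by_exp = {
        o.experiment_id: o.heading
        for o in observations
        if o.genotype_id == genotype_id and o.heading is not None
    }
    if not obs_by_exp:
        raise ValueError(f"genotype {genotype_id!r} has no usable observations")
    if eng is None:
        used = {e: experiments[e] for e in obs_by_exp}
        eng = PanelEngine(used, sites, weather, spec, k)
    idx, mn = _minimize(eng, genotype_id, obs_by_exp)
    return _finish(
        eng, genotype_id, idx, mn, len(obs_by_exp), tuple(sorted(obs_by_exp))
    )


def filter_winter_vectors(
    result: CalibrationResult,
    spring_last_heading: dict[str, _dt.date],
    eng: PanelEngine,
    margin_days: int = 10,
) -> CalibrationResult:
    """Apply the spring-sowing filter to a winter genotype's tied vectors.

    A vector is removed if, in any spring experiment, it predicts a heading
    date strictly earlier than that experiment's last recorded heading plus
    ``margin_days``; vectors predicting no heading always pass.
    """
    survivors: list[int] = []
    for v in result.minimizing_vectors:
        flat = eng.index_of(v)
        ok = True
        for exp_id, last_obs in spring_last_heading.items():
            pred = eng.predicted_date(exp_id, flat)
            if pred is NOT_REACHED:
                continue
            if pred < last_obs + _dt.timedelta(days=margin_days):
                ok = False
                break
        if ok:
            survivors.append(flat)
    if not survivors:
        raise UnfilterableGenotypeError(
            f"genotype {result.genotype_id!r}: every minimizing vector predicts "
            "heading too early in a spring-sown experiment"
        )
    vectors = [eng.vector_at(i) for i in survivors]
    selected = select_representative(vectors, eng.spec)
    return CalibrationResult(
        result.genotype_id,
        vectors,
        result.min_rmsep,
        selected,
        result.n_experiments_used,
        filtered=True,
        experiment_ids=result.experiment_ids,
    )


def grid_filter_mask(
    eng: PanelEngine,
    spring_last_heading: dict[str, _dt.date],
    margin_days: int = 10,
) -> np.ndarray:
    """Boolean mask over the whole grid of vectors passing the spring-sowing
    rule (predict NOT_REACHED, or heading at/after last observed + margin)
    in every spring experiment."""
    ok = None
    for exp_id, last_obs in spring_last_heading.items():
        cutoff = (last_obs + _dt.timedelta(days=margin_days)).toordinal()
        ords = eng.pred_ord[exp_id]
        passes = (ords == eng.penalty_ord[exp_id]) | (ords >= cutoff)
        ok = passes if ok is None else (ok & passes)
    return ok if ok is not None else np.ones(eng.spec.n_vectors, dtype=bool)


def resample_robustness(
    genotype_id: str,
    observations: list[HeadingObservation],
    experiments: dict[str, Experiment],
    sites: dict[str, Site],
    weather: dict[str, list[DailyWeather]],
    spec: GridSpec = GridSpec(),
    k: ModelConstants = DEFAULT_CONSTANTS,
    n_repeats: int = 10,
    seed: int = 0,
    eng: PanelEngine | None = None,
) -> pd.DataFrame:
    """Repeat calibration on jackknife-like subsets of the experiments.

    Each repeat drops one spring and one autumn experiment at random
    (sampling ``n_spring - 1`` and ``n_autumn - 1`` without replacement)
    and re-optimizes.  Returns one row per repeat with the selected
    vector; the ``v_sat``/``p_base`` standard deviations across repeats
    measure how robust the calibration is to the choice of experiments.
    """
    obs_by_exp = {
        o.experiment_id: o.heading
        for o in observations
        if o.genotype_id == genotype_id and o.heading is not None
    }
    if not obs_by_exp:
        raise ValueError(f"genotype {genotype_id!r} has no usable observations")
    by_season = {"autumn": [], "spring": []}
    for exp_id in sorted(obs_by_exp):
        by_season[experiments[exp_id].season_class].append(exp_id)
    if max(len(v) for v in by_season.values()) < 2:
        raise ValueError(
            f"genotype {genotype_id!r}: robustness resampling needs >=2 "
            "experiments in at least one season class"
        )
    if eng is None:
        used = {e: experiments[e] for e in obs_by_exp}
        eng = PanelEngine(used, sites, weather, spec, k)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_repeats):
        subset: list[str] = []
        for season in ("spring", "autumn"):
            pool = by_season[season]
            take = max(len(pool) - 1, 0)
            if take:
                subset.extend(rng.choice(pool, size=take, replace=False))
        if not subset:
            raise ValueError("resampled experiment subset is empty")
        sub_obs = {e: obs_by_exp[e] for e in subset}
        idx, mn = _minimize(eng, genotype_id, sub_obs)
        sel = select_representative([eng.vector_at(i) for i in idx], eng.spec)
        rows.append(
            {
                "repeat": rep,
                "v_sat": sel.v_sat,
                "p_base": sel.p_base,
                "tt_emhe": sel.tt_emhe,
                "min_rmsep": mn,
                "n_experiments": len(subset),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["sd_v_sat"] = float(df["v_sat"].std(ddof=1))
    df.attrs["sd_p_base"] = float(df["p_base"].std(ddof=1))
    return df


# ----------------------------------------------------- model front-end


class HeadingModel:
    """Panel-level calibration model.

    Built from the raw tables (observations, experiments, sites, weather);
    :meth:`fit` runs the grid calibration for every genotype and returns a
    :class:`CalibrationResults`.  Winter genotypes (observed in >=1 spring
    sowing and headed in none) are calibrated on autumn sowings and
    filtered with the spring-sowing rule; spring genotypes use all
    experiments where they headed.
    """

    def __init__(
        self,
        observations: list[HeadingObservation],
        experiments: dict[str, Experiment],
        sites: dict[str, Site],
        weather: dict[str, list[DailyWeather]],
        grid: GridSpec = GridSpec(),
        constants: ModelConstants = DEFAULT_CONSTANTS,
    ):
        self.observations = observations
        self.experiments = experiments
        self.sites = sites
        self.weather = weather
        self.grid = grid
        self.constants = constants
        self._engine: PanelEngine | None = None

    @property
    def engine(self) -> PanelEngine:
        if self._engine is None:
            self._engine = PanelEngine(
                self.experiments, self.sites, self.weather, self.grid, self.constants
            )
        return self._engine

    def genotype_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for o in self.observations:
            seen.setdefault(o.genotype_id, None)
        return list(seen)

    def is_winter(self, genotype_id: str) -> bool:
        """Winter type: observed in >=1 spring sowing and headed in none."""
        spring = [
            o
            for o in self.observations
            if o.genotype_id == genotype_id
            and self.experiments[o.experiment_id].season_class == "spring"
        ]
        return bool(spring) and all(o.heading is None for o in spring)

    def spring_last_heading(self) -> dict[str, _dt.date]:
        """Latest recorded heading per spring-sown experiment, panel-wide."""
        out: dict[str, _dt.date] = {}
        for o in self.observations:
            if o.heading is None:
                continue
            if self.experiments[o.experiment_id].season_class != "spring":
                continue
            cur = out.get(o.experiment_id)
            if cur is None or o.heading > cur:
                out[o.experiment_id] = o.heading
        return out

    def fit(self, margin_days: int = 10) -> "CalibrationResults":
        eng = self.engine
        spring_last = self.spring_last_heading()
        results: dict[str, CalibrationResult] = {}
        failures: dict[str, str] = {}
        for gid in self.genotype_ids():
            obs_by_exp = {
                o.experiment_id: o.heading
                for o in self.observations
                if o.genotype_id == gid and o.heading is not None
            }
            winter = self.is_winter(gid)
            if winter:
                obs_by_exp = {
                    e: d
                    for e, d in obs_by_exp.items()
                    if self.experiments[e].season_class == "autumn"
                }
            if not obs_by_exp:
                failures[gid] = "no experiments with a heading date"
                continue
            idx, mn = _minimize(eng, gid, obs_by_exp)
            res = _finish(
                eng, gid, idx, mn, len(obs_by_exp), tuple(sorted(obs_by_exp))
            )
            if winter and spring_last:
                try:
                    res = filter_winter_vectors(res, spring_last, eng, margin_days)
                except UnfilterableGenotypeError:
                    # every tied vector contradicts the spring NH record
                    # (observation noise pulled the autumn-only tie set to
                    # low v_sat): re-minimize over the filter-passing
                    # subset of the whole grid instead
                    mask = grid_filter_mask(eng, spring_last, margin_days)
                    if mask.any():
                        r_all = eng.rmsep_over(obs_by_exp)
                        r_all = np.where(mask, r_all, np.inf)
                        mn2 = float(r_all.min())
                        idx2 = list(
                            map(int, np.nonzero(r_all <= mn2 + TIE_TOL)[0])
                        )
                        res = _finish(
                            eng, gid, idx2, mn2, len(obs_by_exp),
                            tuple(sorted(obs_by_exp)), filtered=True,
                        )
                    else:
                        failures[gid] = "no grid vector satisfies the spring filter"
            results[gid] = res
        return CalibrationResults(self, results, failures)


class CalibrationResults:
    """Fitted parameters and diagnostics for a calibrated panel."""

    def __init__(
        self,
        model: HeadingModel,
        results: dict[str, CalibrationResult],
        failures: dict[str, str],
    ):
        self.model = model
        self.results = results
        self.failures = failures

    @property
    def params(self) -> pd.DataFrame:
        rows = []
        for gid, r in self.results.items():
            rows.append(
                {
                    "genotype_id": gid,
                    "v_sat": r.selected.v_sat,
                    "p_base": r.selected.p_base,
                    "tt_emhe": r.selected.tt_emhe,
                    "min_rmsep": r.min_rmsep,
                    "n_vectors": len(r.minimizing_vectors),
                    "n_experiments": r.n_experiments_used,
                    "filtered": r.filtered,
                }
            )
        return pd.DataFrame(rows).set_index("genotype_id")

    def selected(self, genotype_id: str) -> GenotypeParameters:
        return self.results[genotype_id].selected

    def predict(
        self, experiments: dict[str, Experiment] | None = None
    ) -> list[HeadingObservation]:
        """Heading predictions for every calibrated genotype in the given
        experiments (default: the calibration experiments)."""
        from .pipeline import predict_headings

        experiments = experiments or self.model.experiments
        params = {g: r.selected for g, r in self.results.items()}
        return predict_headings(
            params, experiments, self.model.sites, self.model.weather,
            self.model.constants,
        )

    def resample_robustness(
        self, genotype_id: str, n_repeats: int = 10, seed: int = 0
    ) -> pd.DataFrame:
        return resample_robustness(
            genotype_id,
            self.model.observations,
            self.model.experiments,
            self.model.sites,
            self.model.weather,
            self.model.grid,
            self.model.constants,
            n_repeats=n_repeats,
            seed=seed,
            eng=self.model.engine,
        )

    def summary(self) -> str:
        p = self.params
        lines = [
            "Grid calibration of genotype parameters",
            f"  genotypes calibrated : {len(p)}",
            f"  grid strategy        : {self.model.grid.strategy} "
            f"({self.model.grid.n_vectors} vectors)",
            f"  experiments          : {len(self.model.experiments)}",
            f"  median min RMSEP     : {p['min_rmsep'].median():.2f} d"
            if len(p)
            else "  (no genotypes)",
            f"  winter-filtered      : {int(p['filtered'].sum())}" if len(p) else "",
            "",
            p.to_string(),
        ]
        if self.failures:
            lines.append("")
            lines.append("Failures:")
            for g, msg in self.failures.items():
                lines.append(f"  {g}: {msg}")
        return "\n".join(line for line in lines if line is not None)
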