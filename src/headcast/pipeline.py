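"""End-to-end orchestration and evaluation.

Chains the stages — calibrate a panel, fit marker models to the calibrated
parameters, predict parameters for unseen genotypes from their marker
calls, simulate their heading dates, and score predictions against
observations with RMSEP (days) and R^2 (squared Pearson correlation of
observed vs predicted dates).  Dates are compared as calendar dates
throughout; day-of-year is a display format only, so autumn sowings that
head the following year evaluate correctly.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import engine
from .calibrate import GridSpec, HeadingModel
from .io import DailyWeather, Experiment, HeadingObservation, Site
from .markers import (
    GenotypeMatrix,
    MarkerLinearModel,
    associate,
    backward_eliminate,
    impute,
    ld_blocks,
    mask_rare,
    pfc_filter,
    predict_parameter,
)
from .phenology import DEFAULT_CONSTANTS, GenotypeParameters, ModelConstants

__all__ = [
    "predict_headings",
    "evaluate",
    "EvaluationReport",
    "fit_marker_models",
    "predict_parameters",
    "run_round_trip",
]

log = logging.getLogger("headcast")


def predict_headings(
    params: dict[str, GenotypeParameters],
    experiments: dict[str, Experiment],
    sites: dict[str, Site],
    weather: dict[str, list[DailyWeather]],
    k: ModelConstants = DEFAULT_CONSTANTS,
) -> list[HeadingObservation]:
    """Simulated heading dates for each genotype x experiment; NOT_REACHED
    becomes a None heading."""
    out: list[HeadingObservation] = []
    for exp_id, exp in experiments.items():
        series = engine.build_series(exp, weather[exp.site], sites[exp.site], k)
        for gid, p in params.items():
            off = engine.heading_offsets(
                series,
                np.array([p.v_sat]),
                np.array([p.p_base]),
                np.array([p.tt_emhe]),
                k,
            )[0, 0, 0]
            date = None if off == engine.NOT_REACHED_IDX else series.date_of(int(off))
            out.append(HeadingObservation(gid, exp_id, date))
    return out


@dataclass
class EvaluationReport:
    """Scoped prediction-quality table.

    One row per group with the pair count ``n``, mean/min/max observed
    heading (day of year), RMSEP in days and R^2; pairs where either side
    is NH / not reached are counted in ``n_excluded`` rather than scored.
    """

    table: pd.DataFrame

    def __str__(self) -> str:
        return self.table.to_string(index=False)


def _pairs(
    observations: list[HeadingObservation], predictions: list[HeadingObservation]
) -> pd.DataFrame:
    obs = {(o.genotype_id, o.experiment_id): o.heading for o in observations}
    pred = {(p.genotype_id, p.experiment_id): p.heading for p in predictions}
    rows = []
    for key in obs.keys() & pred.keys():
        rows.append(
            {
                "genotype_id": key[0],
                "experiment_id": key[1],
                "obs": obs[key],
                "pred": pred[key],
            }
        )
    return pd.DataFrame(rows)


def _score(group: pd.DataFrame) -> dict:
    ok = group[group["obs"].notna() & group["pred"].notna()]
    n_excl = len(group) - len(ok)
    if len(ok) == 0:
        return {
            "n": 0, "n_excluded": n_excl, "mean": np.nan, "min": np.nan,
            "max": np.nan, "rmsep": np.nan, "r2": np.nan,
        }
    o = np.array([d.toordinal() for d in ok["obs"]], dtype=float)
    p = np.array([d.toordinal() for d in ok["pred"]], dtype=float)
    doy = np.array([d.timetuple().tm_yday for d in ok["obs"]], dtype=float)
    rm = float(np.sqrt(np.mean((o - p) ** 2)))
    if len(ok) >= 2 and np.std(o) > 0 and np.std(p) > 0:
        r2 = float(np.corrcoef(o, p)[0, 1] ** 2)
    else:
        r2 = np.nan
    return {
        "n": len(ok),
        "n_excluded": n_excl,
        "mean": float(doy.mean()),
        "min": float(doy.min()),
        "max": float(doy.max()),
        "rmsep": rm,
        "r2": r2,
    }


def evaluate(
    observations: list[HeadingObservation],
    predictions: list[HeadingObservation],
    grouping: str = "pooled",
    experiments: dict[str, Experiment] | None = None,
    genotype_class: dict[str, str] | None = None,
) -> EvaluationReport:
    """Score predictions against observations.

    ``grouping`` is one of ``pooled``, ``per-experiment``, ``per-season``
    (needs ``experiments``) or ``per-genotype-class`` (needs
    ``genotype_class``).  A pooled row is always included.
    """
    pairs = _pairs(observations, predictions)
    if pairs.empty:
        raise ValueError("no genotype x experiment pairs in common")
    rows = [{"scope": "pooled", "group": "all", **_score(pairs)}]
    if grouping == "per-experiment":
        for exp_id, g in pairs.groupby("experiment_id", sort=True):
            rows.append({"scope": "experiment", "group": exp_id, **_score(g)})
    elif grouping == "per-season":
        if experiments is None:
            raise ValueError("per-season grouping needs the experiments table")
        season = pairs["experiment_id"].map(lambda e: experiments[e].season_class)
        for s, g in pairs.groupby(season, sort=True):
            rows.append({"scope": "season", "group": s, **_score(g)})
    elif grouping == "per-genotype-class":
        if genotype_class is None:
            raise ValueError("per-genotype-class grouping needs a class mapping")
        cls = pairs["genotype_id"].map(genotype_class)
        for c, g in pairs.groupby(cls, sort=True):
            rows.append({"scope": "genotype_class", "group": c, **_score(g)})
    elif grouping != "pooled":
        raise ValueError(f"unknown grouping {grouping!r}")
    report = EvaluationReport(pd.DataFrame(rows))
    report.table.attrs["r2_definition"] = "squared Pearson correlation obs~pred"
    return report


# ---------------------------------------------------------- marker stage


def fit_marker_models(
    calibrated: pd.DataFrame,
    matrix: GenotypeMatrix,
    structure: pd.DataFrame,
    traits: tuple[str, ...] = ("v_sat", "p_base"),
    B: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    min_freq: float = 0.05,
    max_pfc: float = 0.2,
    r_threshold: float = 0.8,
    impute_kwargs: dict | None = None,
    cleaned: GenotypeMatrix | None = None,
) -> dict[str, MarkerLinearModel]:
    """Calibrated parameters -> marker models, via the full genetic chain:
    rare-class masking, imputation, PFC filter, association scan,
    LD-blocking of the significant markers, backward elimination.

    ``cleaned`` may supply an already masked/imputed/filtered matrix (e.g.
    when the same matrix serves several model fits); otherwise the chain
    runs here.
    """
    if cleaned is None:
        cleaned = mask_rare(matrix, min_freq)
        cleaned, report = impute(cleaned, seed=seed, **(impute_kwargs or {}))
        cleaned = pfc_filter(cleaned, report, max_pfc)
    log.info("marker stage: %d markers after PFC filter", len(cleaned.marker_ids))
    models: dict[str, MarkerLinearModel] = {}
    for trait in traits:
        values = calibrated[trait]
        records = associate(values, cleaned, structure, trait=trait, B=B, seed=seed)
        hits = [r.marker_id for r in records if r.raw_p < alpha]
        if hits:
            sub = GenotypeMatrix(
                cleaned.calls[hits].copy(), cleaned.meta.loc[hits].copy()
            )
            _, reps = ld_blocks(sub, r_threshold)
            models[trait] = backward_eliminate(values, reps, cleaned, trait, alpha)
        else:
            models[trait] = backward_eliminate(values, [], cleaned, trait, alpha)
        log.info(
            "trait %s: %d associated, model keeps %d markers (R2=%.2f)",
            trait, len(hits), len(models[trait].terms), models[trait].r2_fit or 0.0,
        )
    return models


def predict_parameters(
    models: dict[str, MarkerLinearModel],
    matrix: GenotypeMatrix,
    genotype_ids: list[str] | None = None,
    tt_emhe_default: float = 500.0,
    clip_to_grid: bool = True,
) -> tuple[dict[str, GenotypeParameters], dict[str, str]]:
    """Marker calls -> predicted model parameters per genotype.

    Genotypes lacking a known call at any model marker are listed in the
    returned exclusions mapping instead of being silently dropped.
    Predictions are clipped to the physical parameter ranges (v_sat >= 0,
    0 <= p_base < 20) unless ``clip_to_grid`` is off.
    """
    gids = genotype_ids or matrix.genotype_ids
    out: dict[str, GenotypeParameters] = {}
    excluded: dict[str, str] = {}
    for gid in gids:
        calls = matrix.calls.loc[gid].to_dict()
        try:
            v = predict_parameter(models["v_sat"], calls) if "v_sat" in models else 0.0
            p = predict_parameter(models["p_base"], calls) if "p_base" in models else 0.0
            t = (
                predict_parameter(models["tt_emhe"], calls)
                if "tt_emhe" in models
                else tt_emhe_default
            )
        except (KeyError, ValueError) as exc:
            excluded[gid] = str(exc)
            continue
        if clip_to_grid:
            v = float(np.clip(v, 0.0, None))
            p = float(np.clip(p, 0.0, 19.9))
            t = float(np.clip(t, 1.0, None))
        out[gid] = GenotypeParameters(v, p, t)
    return out, excluded


def run_round_trip(
    data: dict,
    n_holdout_genotypes: int = 30,
    holdout_experiments: tuple[str, ...] = (),
    grid: GridSpec = GridSpec(),
    B: int = 200,
    seed: int = 0,
    n_trees: int = 30,
    k: ModelConstants = DEFAULT_CONSTANTS,
) -> dict:
    """Full synthetic round-trip on a generated dataset bundle.

    Splits the genotypes into a calibration panel and a hold-out set,
    calibrates the panel on the non-held-out experiments, fits marker
    models to the calibrated parameters, predicts parameters for the
    hold-out genotypes from their markers alone, simulates their heading
    dates in the held-out experiments, and evaluates both routes.
    """
    rng = np.random.default_rng(seed)
    truth = data["truth"]
    gids = list(truth.index)
    holdout = set(rng.choice(gids, size=n_holdout_genotypes, replace=False))
    panel = [g for g in gids if g not in holdout]
    cal_exps = {
        e: x for e, x in data["experiments"].items() if e not in holdout_experiments
    }
    held_exps = {
        e: x for e, x in data["experiments"].items() if e in holdout_experiments
    }
    panel_obs = [
        o
        for o in data["observations"]
        if o.genotype_id in panel and o.experiment_id in cal_exps
    ]

    model = HeadingModel(
        panel_obs, cal_exps, data["sites"], data["weather"], grid, k
    )
    fit = model.fit()

    # clean/impute/filter the full matrix once; the model fit uses the
    # panel rows, prediction the hold-out rows
    cleaned = mask_rare(data["matrix"])
    filled, report = impute(cleaned, seed=seed, n_trees=n_trees)
    filled = pfc_filter(filled, report)
    panel_view = GenotypeMatrix(filled.calls.loc[panel].copy(), filled.meta.copy())
    models = fit_marker_models(
        fit.params, panel_view, data["structure"], B=B, seed=seed, cleaned=panel_view
    )

    # marker-only route for hold-out genotypes in held-out environments
    pred_params, excluded = predict_parameters(models, filled, sorted(holdout))
    target_exps = held_exps or data["experiments"]
    marker_preds = predict_headings(
        pred_params, target_exps, data["sites"], data["weather"], k
    )
    holdout_obs = [
        o
        for o in data["observations"]
        if o.genotype_id in holdout and o.experiment_id in target_exps
    ]
    marker_eval = evaluate(holdout_obs, marker_preds, "per-experiment")

    # both routes on the calibration panel itself
    opt_preds = fit.predict(cal_exps)
    panel_params, _ = predict_parameters(models, filled, panel)
    panel_marker_preds = predict_headings(
        panel_params, cal_exps, data["sites"], data["weather"], k
    )
    panel_cal_obs = [o for o in panel_obs if o.experiment_id in cal_exps]
    opt_eval = evaluate(panel_cal_obs, opt_preds, "pooled")
    panel_marker_eval = evaluate(panel_cal_obs, panel_marker_preds, "pooled")

    return {
        "calibration": fit,
        "marker_models": models,
        "predicted_params": pred_params,
        "excluded": excluded,
        "holdout_eval": marker_eval,
        "panel_optimized_eval": opt_eval,
        "panel_marker_eval": panel_marker_eval,
    }


def load_bundle(config: dict) -> dict:
    """Load every table a config references into one bundle dict."""
    from . import io as hio
    from .markers import read_genotypes

    sites = hio.read_sites(config["sites"])
    weather = {
        name: hio.read_weather(path)
        for name, path in (config.get("weather") or {}).items()
    }
    experiments = hio.read_experiments(config["experiments"], sites)
    out = {"sites": sites, "weather": weather, "experiments": experiments}
    if config.get("phenotypes"):
        out["observations"] = hio.read_phenotypes(config["phenotypes"], experiments)
    if config.get("genotypes"):
        out["matrix"] = read_genotypes(config["genotypes"])
    if config.get("structure"):
        out["structure"] = hio.read_structure(config["structure"])
    return out


def run_calibration(config: dict):
    """Config -> fitted :class:`~headcast.calibrate.CalibrationResults`;
    writes the parameter table when the config names an output."""
    b = load_bundle(config)
    grid = GridSpec(**(config.get("grid") or {}))
    log.info("calibration config %s", config_hash(config))
    model = HeadingModel(
        b["observations"], b["experiments"], b["sites"], b["weather"], grid
    )
    fit = model.fit(margin_days=int(config.get("margin_days", 10)))
    if config.get("out"):
        fit.params.to_csv(config["out"])
    return fit


def run_marker_fit(config: dict) -> dict[str, MarkerLinearModel]:
    """Config (+ calibrated parameter table) -> marker-model JSONs."""
    import pathlib

    b = load_bundle(config)
    params = pd.read_csv(config["params"], index_col=0)
    params.index = params.index.astype(str)
    models = fit_marker_models(
        params, b["matrix"], b["structure"],
        traits=tuple(config.get("traits", ("v_sat", "p_base"))),
        B=int(config.get("permutations", 200)),
        seed=int(config.get("seed", 0)),
    )
    if config.get("outdir"):
        outp = pathlib.Path(config["outdir"])
        outp.mkdir(parents=True, exist_ok=True)
        for t, m in models.items():
            m.to_json(outp / f"{t}_marker_model.json")
    return models


def run_prediction(config: dict):
    """Config (+ marker models) -> predicted parameters and heading dates."""
    from . import io as hio
    from .markers import MarkerLinearModel as MLM
    from .markers import load_bundled_model

    b = load_bundle(config)
    if config.get("models"):
        models = {}
        for p in config["models"]:
            m = MLM.from_json(p)
            models[m.trait] = m
    else:
        models = {t: load_bundled_model(t) for t in ("v_sat", "p_base")}
    params, excluded = predict_parameters(models, b["matrix"])
    preds = predict_headings(params, b["experiments"], b["sites"], b["weather"])
    if config.get("out"):
        hio.write_phenotypes(preds, config["out"])
    return params, preds, excluded


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
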