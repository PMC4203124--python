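"""Standardized-regression-coefficient (SRC) sensitivity analysis.

Heading date is simulated for every vector of a three-parameter grid in a
given experiment and regressed (ordinary least squares, with intercept) on
``V_sat``, ``P_base`` and ``TT_emhe``.  The share of simulated-output
variance attributed to parameter ``i`` is

    SRC_i = beta_i^2 V(X_i) / V(Y),    V(Y) = sum_i beta_i^2 V(X_i)

so the SRCs sum to one by construction whenever V(Y) > 0.  Vectors whose
heading the weather record never reaches are excluded from the fit (a
penalty date would manufacture spurious linearity); the excluded fraction
is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import engine
from .calibrate import GridSpec
from .engine import NOT_REACHED_IDX, build_series
from .io import DailyWeather, Experiment, Site
from .phenology import DEFAULT_CONSTANTS, ModelConstants

__all__ = ["SrcResult", "src_analysis", "src_from_samples", "aggregate_src"]

PARAMS = ("v_sat", "p_base", "tt_emhe")


@dataclass
class SrcResult:
    experiment_id: str
    season_class: str
    beta0: float
    beta: dict[str, float]
    var_x: dict[str, float]
    var_y: float
    src: dict[str, float]  # NaN where undefined (constant axis or V(Y)=0)
    frac_excluded: float
    n_used: int

    def as_row(self) -> dict:
        return {
            "experiment_id": self.experiment_id,
            "season_class": self.season_class,
            "src_vsat": self.src["v_sat"],
            "src_pbase": self.src["p_base"],
            "src_ttemhe": self.src["tt_emhe"],
            "frac_excluded": self.frac_excluded,
        }


def src_from_samples(X: np.ndarray, y: np.ndarray, names=PARAMS) -> tuple[
    float, dict, dict, float, dict
]:
    """OLS of ``y`` on columns of ``X`` (intercept added) and the SRC
    decomposition.  Columns with zero variance are dropped from the fit and
    get an undefined (NaN) SRC."""
    names = list(names)
    y = np.asarray(y, dtype=float)
    degenerate_y = len(y) == 0 or np.var(y) < 1e-12
    var_x = {nm: float(np.var(X[:, j])) for j, nm in enumerate(names)}
    active = [j for j, nm in enumerate(names) if var_x[nm] > 0]
    beta = {nm: np.nan for nm in names}
    if active and len(y) > len(active):
        A = np.column_stack([np.ones(len(y)), X[:, active]])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        beta0 = float(coef[0])
        for j, col in enumerate(active):
            beta[names[col]] = float(coef[1 + j])
    else:
        beta0 = float(np.mean(y)) if len(y) else np.nan
    var_y = float(
        np.nansum([beta[nm] ** 2 * var_x[nm] for nm in names if not np.isnan(beta[nm])])
    )
    src = {}
    for nm in names:
        if np.isnan(beta[nm]) or var_y <= 0 or degenerate_y:
            src[nm] = np.nan
        else:
            src[nm] = beta[nm] ** 2 * var_x[nm] / var_y
    return beta0, beta, var_x, var_y, src


def src_analysis(
    experiment: Experiment,
    weather: dict[str, list[DailyWeather]] | list[DailyWeather],
    sites: dict[str, Site] | Site,
    spec: GridSpec | None = None,
    k: ModelConstants = DEFAULT_CONSTANTS,
) -> SrcResult:
    """SRC decomposition of simulated heading date for one experiment.

    ``spec`` should be a ``3p`` grid; the full 542 471-vector grid is
    supported, a thinned one (``GridSpec(strategy="3p").thinned()``) runs
    in well under a second.
    """
    spec = spec or GridSpec(strategy="3p").thinned()
    site = sites if isinstance(sites, Site) else sites[experiment.site]
    wx = weather if isinstance(weather, list) else weather[experiment.site]
    series = build_series(experiment, wx, site, k)
    va, pa, ta = spec.v_sat_axis(), spec.p_base_axis(), spec.tt_emhe_axis()
    offs = engine.heading_offsets(series, va, pa, ta, k)
    V, P, T = np.meshgrid(va, pa, ta, indexing="ij")
    reached = offs != NOT_REACHED_IDX
    n_total = offs.size
    y = offs[reached].astype(float)  # days after sowing; SRC is shift-invariant
    X = np.column_stack([V[reached], P[reached], T[reached]])
    beta0, beta, var_x, var_y, src = src_from_samples(X, y)
    return SrcResult(
        experiment_id=experiment.id,
        season_class=experiment.season_class,
        beta0=beta0,
        beta=beta,
        var_x=var_x,
        var_y=var_y,
        src=src,
        frac_excluded=1.0 - float(reached.sum()) / n_total,
        n_used=int(reached.sum()),
    )


def aggregate_src(results: list[SrcResult]) -> pd.DataFrame:
    """Min/median/max of each parameter's SRC within each season class."""
    rows = []
    for season in ("autumn", "spring"):
        group = [r for r in results if r.season_class == season]
        if not group:
            continue
        for nm in PARAMS:
            vals = np.array([r.src[nm] for r in group], dtype=float)
            rows.append(
                {
                    "season_class": season,
                    "parameter": nm,
                    "n": len(group),
                    "min": np.nanmin(vals) if not np.all(np.isnan(vals)) else np.nan,
                    "median": np.nanmedian(vals) if not np.all(np.isnan(vals)) else np.nan,
                    "max": np.nanmax(vals) if not np.all(np.isnan(vals)) else np.nan,
                }
            )
    return pd.DataFrame(rows)
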