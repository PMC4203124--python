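"""Vectorized grid evaluation of the phenology model.

Brute-force calibration evaluates the day-step model for every vector of a
parameter grid (13 231 vectors for the two-parameter grid, 542 471 for the
three-parameter one) in every experiment.  Predicted heading dates depend
only on the environment and the parameter vector — not on the genotype —
so the daily series (TM, Tt, Veff, VDD, Ph) and the emergence date are
computed once per experiment and the whole grid is evaluated against them
with array arithmetic.  The per-day arithmetic mirrors
:func:`headcast.phenology.simulate` operation-for-operation so that batch
and scalar paths agree bit-for-bit.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np

from .io import DailyWeather, Experiment, Site
from .phenology import (
    DEFAULT_CONSTANTS,
    ModelConstants,
    daily_thermal_time,
    mean_temperature,
    vernalization_efficiency,
)
from .solar import day_of_year, photoperiod

__all__ = ["ExperimentSeries", "build_series", "heading_offsets", "NOT_REACHED_IDX"]

#: Offset value marking a vector whose heading the weather record never reached.
NOT_REACHED_IDX = -1


@dataclass
class ExperimentSeries:
    """Parameter-independent daily series of one experiment.

    Day ``i`` of the arrays is ``sowing_date + (i + 1)`` days: accumulation
    starts the day after sowing.  ``emergence_idx`` is the index of the
    emergence day (first day on which plain thermal time reaches the
    sowing-to-emergence threshold) or ``None`` if never reached.
    """

    experiment: Experiment
    site: Site
    sowing_date: _dt.date
    tt: np.ndarray  # daily thermal time, degree-days
    vdd: np.ndarray  # cumulative vernalizing days (includes current day)
    ph: np.ndarray  # day length, hours
    emergence_idx: int | None

    @property
    def n_days(self) -> int:
        return len(self.tt)

    def date_of(self, idx: int) -> _dt.date:
        return self.sowing_date + _dt.timedelta(days=int(idx) + 1)

    @property
    def last_date(self) -> _dt.date:
        return self.date_of(self.n_days - 1)

    @property
    def penalty_date(self) -> _dt.date:
        """Finite stand-in date for a never-reached heading (last day + 1)."""
        return self.last_date + _dt.timedelta(days=1)


def build_series(
    experiment: Experiment,
    weather: list[DailyWeather],
    site: Site,
    k: ModelConstants = DEFAULT_CONSTANTS,
) -> ExperimentSeries:
    """Precompute the daily series of one experiment from its sowing date."""
    sowing = experiment.sowing_date
    by_date = {w.date: w for w in weather}
    if sowing not in by_date:
        raise ValueError(
            f"weather for site {site.name!r} does not contain sowing date {sowing}"
        )
    days = []
    d = sowing + _dt.timedelta(days=1)
    limit = (
        sowing + _dt.timedelta(days=experiment.horizon_days)
        if experiment.horizon_days is not None
        else None
    )
    while d in by_date and (limit is None or d <= limit):
        days.append(by_date[d])
        d += _dt.timedelta(days=1)
    tm = np.array([mean_temperature(w.tmin, w.tmax) for w in days])
    tt = daily_thermal_time(tm, k)
    vdd = np.cumsum(vernalization_efficiency(tm, k))
    doy = np.array([day_of_year(w.date) for w in days])
    ph = photoperiod(doy, site.latitude, k.sun_angle)
    cum_tt = np.cumsum(tt)
    reached = np.nonzero(cum_tt >= k.tt_sow_em)[0]
    em_idx = int(reached[0]) if reached.size else None
    return ExperimentSeries(experiment, site, sowing, tt, vdd, ph, em_idx)


def heading_offsets(
    series: ExperimentSeries,
    v_sat: np.ndarray,
    p_base: np.ndarray,
    tt_emhe: np.ndarray,
    k: ModelConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Heading-day indices for the Cartesian grid of parameter values.

    Returns an int array of shape ``(len(v_sat), len(p_base),
    len(tt_emhe))`` holding the day index (into the series) on which the
    post-emergence modified-thermal-time accumulator first reaches the
    threshold, or :data:`NOT_REACHED_IDX`.  The date of index ``i`` is
    ``series.date_of(i)``.
    """
    v_sat = np.asarray(v_sat, dtype=float)
    p_base = np.asarray(p_base, dtype=float)
    tt_emhe = np.asarray(tt_emhe, dtype=float)
    shape = (v_sat.size, p_base.size, tt_emhe.size)
    out = np.full(shape, NOT_REACHED_IDX, dtype=np.int64)
    if series.emergence_idx is None:
        return out
    s = slice(series.emergence_idx + 1, None)
    tt = series.tt[s]
    if tt.size == 0:
        return out
    vdd = series.vdd[s]
    ph = series.ph[s]

    # FV rows: clip(VDD / v_sat); fully spring (v_sat <= v_base) -> 1
    with np.errstate(divide="ignore", invalid="ignore"):
        fv = np.clip((vdd[None, :] - k.v_base) / (v_sat[:, None] - k.v_base), 0.0, 1.0)
    fv[v_sat <= k.v_base, :] = 1.0
    if np.any(p_base >= k.p_opt):
        raise ValueError("p_base values must be below p_opt")
    fp = np.clip(
        (ph[None, :] - p_base[:, None]) / (k.p_opt - p_base[:, None]), 0.0, 1.0
    )
    # same multiplication order as the scalar path: (tt * fv) * fp
    pv = (tt[None, :] * fv)[:, None, :] * fp[None, :, :]
    cum = np.cumsum(pv, axis=-1)
    n_days = tt.size
    for iv in range(v_sat.size):
        for ip in range(p_base.size):
            idx = np.searchsorted(cum[iv, ip], tt_emhe, side="left")
            row = np.where(idx < n_days, idx + series.emergence_idx + 1, NOT_REACHED_IDX)
            out[iv, ip] = row
    return out
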