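"""Day-step wheat phenology: thermal time modified by vernalization and
photoperiod.

The model accumulates a daily development increment from sowing to heading.
Each day, the mean temperature ``TM = (Tmin + Tmax)/2`` is turned into a
temperature factor ``FT`` (bilinear between a base, an optimum and a
ceiling temperature) and a daily thermal time ``Tt = FT * T_opt`` in
degree-days.  From emergence onward the increment is further reduced by a
vernalization factor ``FV`` — driven by the running count of vernalizing
days ``VDD`` relative to the genotype's requirement ``V_sat`` — and a
photoperiod factor ``FP`` — driven by the day length relative to the
genotype's base photoperiod ``P_base``:

    PVTt = Tt * FV * FP        (modified thermal time, em -> heading)

Sowing to emergence requires 148 (unmodified) degree-days; emergence to
heading requires ``TT_emhe`` modified degree-days (default 500).  A stage
is assigned to the first day on which its accumulator reaches or exceeds
the threshold, and the accumulator resets at the stage change (surplus is
discarded).  Accumulation starts the day after the reference event: the
first increment toward emergence falls on the day after sowing, and the
first modified increment on the day after emergence.  ``VDD`` likewise
starts counting the day after sowing.

``V_sat``, ``P_base`` and (optionally) ``TT_emhe`` are the genotype-specific
"genetic" parameters; everything else is a species-level constant.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DailyWeather, Site
from .solar import day_of_year, photoperiod

__all__ = [
    "NOT_REACHED",
    "ModelConstants",
    "GenotypeParameters",
    "SimulationTrace",
    "mean_temperature",
    "thermal_factor",
    "daily_thermal_time",
    "vernalization_efficiency",
    "vernalization_factor",
    "photoperiod_factor",
    "simulate",
]

#: Sentinel for a stage the weather record never reaches.
NOT_REACHED = None


@dataclass(frozen=True)
class ModelConstants:
    """Species-level constants of the day-step model.

    Cardinal temperatures of the development response are 1/26/37 °C; the
    vernalizing-efficiency trapezoid runs -4..3..10..17 °C; day length
    counts light down to 6° solar depression; phase durations are 148
    degree-days (sowing to emergence) and 500 modified degree-days
    (emergence to heading) unless the genotype's ``tt_emhe`` overrides the
    latter.  ``t_card_max`` is the cardinal ceiling temperature (distinct
    from the daily maximum temperature of a weather record).
    """

    t_base: float = 1.0
    t_opt: float = 26.0
    t_card_max: float = 37.0
    v_t1: float = -4.0
    v_t2: float = 3.0
    v_t3: float = 10.0
    v_t4: float = 17.0
    v_base: float = 0.0
    p_opt: float = 20.0
    tt_sow_em: float = 148.0
    tt_emhe_default: float = 500.0
    sun_angle: float = 6.0

    def __post_init__(self):
        if not self.t_base < self.t_opt < self.t_card_max:
            raise ValueError("require t_base < t_opt < t_card_max")
        if not self.v_t1 <= self.v_t2 <= self.v_t3 <= self.v_t4:
            raise ValueError("vernalization cardinal temperatures must be ordered")
        if self.tt_sow_em <= 0:
            raise ValueError("tt_sow_em must be positive")


DEFAULT_CONSTANTS = ModelConstants()


@dataclass(frozen=True)
class GenotypeParameters:
    """Genotype-specific response parameters.

    v_sat : vernalizing days required for full vernalization (FV = 1)
    p_base : base photoperiod in hours below which development stops (FP = 0)
    tt_emhe : modified degree-days from emergence to heading
    """

    v_sat: float
    p_base: float
    tt_emhe: float = 500.0

    def __post_init__(self):
        if self.v_sat < 0:
            raise ValueError(f"v_sat must be >= 0, got {self.v_sat}")
        if self.p_base < 0:
            raise ValueError(f"p_base must be >= 0, got {self.p_base}")
        if self.tt_emhe <= 0:
            raise ValueError(f"tt_emhe must be > 0, got {self.tt_emhe}")


def mean_temperature(tmin: float, tmax: float) -> float:
    """Daily mean temperature, the arithmetic midpoint of Tmin and Tmax."""
    if tmin > tmax:
        raise ValueError(f"tmin ({tmin}) > tmax ({tmax})")
    return (tmin + tmax) / 2.0


def thermal_factor(tm, k: ModelConstants = DEFAULT_CONSTANTS):
    """Temperature factor FT in [0, 1].

    Zero at or below ``t_base`` and at or above ``t_card_max``, one at
    ``t_opt``, linear in between (bilinear response).
    """
    tm = np.asarray(tm, dtype=float)
    up = (tm - k.t_base) / (k.t_opt - k.t_base)
    down = (k.t_card_max - tm) / (k.t_card_max - k.t_opt)
    ft = np.where(tm <= k.t_opt, up, down)
    ft = np.clip(ft, 0.0, 1.0)
    # open interval: FT = 0 exactly at the cardinal bounds
    ft = np.where((tm <= k.t_base) | (tm >= k.t_card_max), 0.0, ft)
    return float(ft) if ft.ndim == 0 else ft


def daily_thermal_time(tm, k: ModelConstants = DEFAULT_CONSTANTS):
    """Daily thermal time Tt = FT * t_opt, in degree-days, in [0, t_opt]."""
    ft = thermal_factor(tm, k)
    return ft * k.t_opt


def vernalization_efficiency(tm, k: ModelConstants = DEFAULT_CONSTANTS):
    """Vernalizing efficiency of one day at mean temperature ``tm``.

    Trapezoid on the cardinal temperatures T1..T4: zero outside [T1, T4],
    one on the plateau [T2, T3], linear on the flanks.
    """
    tm = np.asarray(tm, dtype=float)
    up = np.divide(
        tm - k.v_t1, k.v_t2 - k.v_t1, out=np.ones_like(tm), where=k.v_t2 > k.v_t1
    )
    down = np.divide(
        k.v_t4 - tm, k.v_t4 - k.v_t3, out=np.ones_like(tm), where=k.v_t4 > k.v_t3
    )
    veff = np.clip(np.minimum(up, down), 0.0, 1.0)
    veff = np.where((tm < k.v_t1) | (tm > k.v_t4), 0.0, veff)
    return float(veff) if veff.ndim == 0 else veff


def vernalization_factor(
    vdd, p: GenotypeParameters, k: ModelConstants = DEFAULT_CONSTANTS
):
    """Vernalization factor FV = (VDD - V_base)/(V_sat - V_base), clamped to
    [0, 1].  A genotype with ``v_sat <= v_base`` is fully spring: FV = 1."""
    vdd = np.asarray(vdd, dtype=float)
    if p.v_sat <= k.v_base:
        fv = np.ones_like(vdd)
    else:
        fv = np.clip((vdd - k.v_base) / (p.v_sat - k.v_base), 0.0, 1.0)
    return float(fv) if fv.ndim == 0 else fv


def photoperiod_factor(
    ph, p: GenotypeParameters, k: ModelConstants = DEFAULT_CONSTANTS
):
    """Photoperiod factor FP = (Ph - P_base)/(P_opt - P_base), clamped to
    [0, 1]."""
    ph = np.asarray(ph, dtype=float)
    if p.p_base >= k.p_opt:
        raise ValueError(f"p_base ({p.p_base}) must be below p_opt ({k.p_opt})")
    fp = np.clip((ph - p.p_base) / (k.p_opt - p.p_base), 0.0, 1.0)
    return float(fp) if fp.ndim == 0 else fp


@dataclass
class SimulationTrace:
    """Per-day factors and accumulators of one simulation, plus stage dates."""

    days: pd.DataFrame
    emergence_date: _dt.date | None = NOT_REACHED
    heading_date: _dt.date | None = NOT_REACHED
    params: GenotypeParameters | None = None
    site: Site | None = None
    sowing_date: _dt.date | None = None


def simulate(
    sowing_date: _dt.date,
    weather: list[DailyWeather],
    site: Site,
    p: GenotypeParameters,
    k: ModelConstants = DEFAULT_CONSTANTS,
) -> SimulationTrace:
    """Run the day-step model from sowing until heading or end of weather.

    The returned trace has one row per simulated day (starting the day
    after sowing) with TM, FT, Tt, Veff, cumulative VDD, FV, Ph, FP, the
    daily modified thermal time PVTt and the phase label.  Stage dates are
    the first day whose accumulator meets its threshold; ``NOT_REACHED``
    if the weather record ends first.
    """
    dates = {w.date: w for w in weather}
    if sowing_date not in dates:
        raise ValueError(f"weather record does not contain sowing date {sowing_date}")
    last = max(dates)

    rows = []
    emergence = NOT_REACHED
    heading = NOT_REACHED
    acc = 0.0  # phase accumulator, reset at emergence
    vdd = 0.0
    day = sowing_date
    while heading is NOT_REACHED:
        day = day + _dt.timedelta(days=1)
        if day > last:
            break
        if day not in dates:
            raise ValueError(f"gap in weather record at {day}")
        w = dates[day]
        tm = mean_temperature(w.tmin, w.tmax)
        ft = thermal_factor(tm, k)
        tt = ft * k.t_opt
        veff = vernalization_efficiency(tm, k)
        vdd += veff
        fv = vernalization_factor(vdd, p, k)
        ph = photoperiod(day_of_year(day), site.latitude, k.sun_angle)
        fp = photoperiod_factor(ph, p, k)
        if emergence is NOT_REACHED:
            phase = "sow_em"
            pvtt = tt  # pre-emergence: unmodified thermal time (FV = FP = 1)
            acc += tt
            if acc >= k.tt_sow_em:
                emergence = day
                acc = 0.0
        else:
            phase = "em_he"
            pvtt = tt * fv * fp
            acc += pvtt
            if acc >= p.tt_emhe:
                heading = day
                phase = "done"
        rows.append(
            {
                "date": day,
                "TM": tm,
                "FT": ft,
                "Tt": tt,
                "Veff": veff,
                "VDD": vdd,
                "FV": fv,
                "Ph": ph,
                "FP": fp,
                "PVTt": pvtt,
                "phase": phase,
            }
        )
    return SimulationTrace(
        days=pd.DataFrame(rows),
        emergence_date=emergence,
        heading_date=heading,
        params=p,
        site=site,
        sowing_date=sowing_date,
    )
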