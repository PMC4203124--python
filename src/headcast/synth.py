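"""Seeded synthetic data: weather, trials, genotype panels, phenotypes.

The generator emulates the structure of a temperate multi-environment
wheat trial network at desk scale: sinusoidal annual temperature cycles
with autocorrelated daily noise at two mid-latitude sites, a mix of autumn
and spring sowings scored up to a harvest horizon, and a panel mixing
spring genotypes with obligate-winter ones whose vernalization requirement
(``V_sat``) and photoperiod sensitivity (``P_base``) are driven by a small
number of planted marker effects plus a residual polygenic deviation.
Phenotypes are forward-simulated with the day-step model and observation
noise; a genotype whose simulated heading falls past an experiment's
scoring horizon is recorded NH, which is how obligate-winter genotypes
fail to head in spring sowings.

Everything is deterministic in the seed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine
from .calibrate import GridSpec
from .io import DailyWeather, Experiment, HeadingObservation, Site
from .markers import GenotypeMatrix
from .phenology import DEFAULT_CONSTANTS, GenotypeParameters, ModelConstants

__all__ = ["SynthConfig", "gen_weather", "gen_experiments", "gen_panel",
           "gen_phenotypes", "gen_dataset", "write_fixtures"]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the synthetic trial network.

    Defaults echo the real design at desk scale: 60 genotypes, 300
    markers, 3 autumn + 2 spring sowings at two sites, 1.5-day observation
    noise.  Effect markers are disjoint between traits.  ``v_sat`` effects
    are in days and include one major "winter" allele large enough to make
    its carriers obligate-winter; ``p_base`` effects are in hours.
    """

    seed: int = 0
    n_genotypes: int = 60
    n_markers: int = 300
    winter_fraction: float = 0.25
    noise_sd_days: float = 1.5
    # missingness is concentrated on a minority of markers, as in real
    # panels where a few assays are unreliable while major-gene diagnostic
    # markers are scored completely; planted markers stay complete
    missing_rate: float = 0.1
    missing_marker_fraction: float = 0.1
    # (carrier allele frequency, additive effect) per planted marker
    v_sat_effects: tuple = ((0.35, 15.0), (0.30, 6.0))
    p_base_effects: tuple = ((0.40, 3.0), (0.30, 1.0))
    winter_effect: float = 100.0  # v_sat shift of the major winter allele
    v_sat_base: float = 5.0
    p_base_base: float = 1.0
    param_noise_v: float = 1.0  # polygenic deviation SD, days
    param_noise_p: float = 0.15  # hours
    sites: tuple = (("CF", 45.8), ("LM", 48.7))
    weather_start: _dt.date = _dt.date(2000, 1, 1)
    weather_years: int = 5
    autumn_sowings: tuple = (("CF", 2000), ("LM", 2001), ("CF", 2002))
    spring_sowings: tuple = (("LM", 2001), ("CF", 2002))
    autumn_horizon: int = 280
    spring_horizon: int = 130

    def __post_init__(self):
        for r in (self.winter_fraction, self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")


# ---------------------------------------------------------------- weather


def gen_weather(
    site: Site,
    start: _dt.date,
    years: int,
    seed: int = 0,
) -> list[DailyWeather]:
    """Daily Tmin/Tmax over ``years`` years from ``start``.

    Mean temperature follows a sinusoidal annual cycle (coldest mid
    January) whose level and amplitude depend on latitude, plus AR(1)
    noise; the diurnal range is positive by construction so tmin <= tmax
    always.  Winters at mid latitudes sit in the vernalizing 3..10 C
    plateau for weeks at a time.
    """
    rng = np.random.default_rng([seed, int(abs(site.latitude) * 1000)])
    n = (start.replace(year=start.year + years) - start).days
    dates = [start + _dt.timedelta(days=i) for i in range(n)]
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
    mean = 24.0 - 0.27 * abs(site.latitude)
    amp = 4.0 + 0.1 * abs(site.latitude)
    cycle = mean - amp * np.cos(2.0 * np.pi * (doy - 15.0) / 365.25)
    phi, sd = 0.7, 2.5
    eps = rng.normal(0.0, sd * np.sqrt(1 - phi**2), size=n)
    noise = np.empty(n)
    acc = 0.0
    for i in range(n):
        acc = phi * acc + eps[i]
        noise[i] = acc
    tm = cycle + noise
    dr = np.maximum(rng.normal(8.0, 1.5, size=n), 1.0)
    return [
        DailyWeather(d, float(t - r / 2.0), float(t + r / 2.0))
        for d, t, r in zip(dates, tm, dr)
    ]


def gen_experiments(cfg: SynthConfig) -> dict[str, Experiment]:
    out: dict[str, Experiment] = {}
    for site, year in cfg.autumn_sowings:
        eid = f"aut{year}{site}"
        out[eid] = Experiment(
            eid, site, _dt.date(year, 10, 20), "autumn", cfg.autumn_horizon
        )
    for site, year in cfg.spring_sowings:
        eid = f"spr{year}{site}"
        out[eid] = Experiment(
            eid, site, _dt.date(year, 4, 5), "spring", cfg.spring_horizon
        )
    return out


# ------------------------------------------------------------------ panel


def _snap(values: np.ndarray, lo: float, hi: float, step: float) -> np.ndarray:
    return np.clip(np.round(values / step) * step, lo, hi).round(6)


def gen_panel(
    cfg: SynthConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Genotype matrix, structure table and true parameters.

    True ``v_sat``/``p_base`` are an intercept plus the planted allelic
    effects plus a small normal deviation, snapped to the calibration grid
    (``v_sat`` whole days in 0..130, ``p_base`` tenths of an hour in
    0..9).  Carriers of the major winter allele get a ``v_sat`` far above
    what a spring sowing can vernalize, making them obligate-winter.
    Structure proportions come from a seeded Dirichlet; missing calls are
    injected completely at random at ``missing_rate``.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    gids = [f"G{i:03d}" for i in range(cfg.n_genotypes)]

    n_effect = 1 + len(cfg.v_sat_effects) + len(cfg.p_base_effects)
    if cfg.n_markers < n_effect:
        raise ValueError("n_markers smaller than the number of planted markers")
    mids = [f"mk{i:04d}" for i in range(cfg.n_markers)]
    effect_ids = list(rng.choice(cfg.n_markers, size=n_effect, replace=False))
    winter_marker = mids[effect_ids[0]]
    v_markers = [mids[i] for i in effect_ids[1 : 1 + len(cfg.v_sat_effects)]]
    p_markers = [mids[i] for i in effect_ids[1 + len(cfg.v_sat_effects) :]]

    calls = pd.DataFrame(index=gids, columns=mids, dtype=object)
    freqs = rng.uniform(0.1, 0.9, size=cfg.n_markers)
    planted_freq = {winter_marker: cfg.winter_fraction}
    planted_eff = {winter_marker: ("v_sat", cfg.winter_effect)}
    for m, (f, e) in zip(v_markers, cfg.v_sat_effects):
        planted_freq[m] = f
        planted_eff[m] = ("v_sat", e)
    for m, (f, e) in zip(p_markers, cfg.p_base_effects):
        planted_freq[m] = f
        planted_eff[m] = ("p_base", e)
    for j, m in enumerate(mids):
        f = planted_freq.get(m, freqs[j])
        carrier = rng.random(cfg.n_genotypes) < f
        calls[m] = np.where(carrier, "22", "11")

    v_sat = np.full(cfg.n_genotypes, cfg.v_sat_base)
    p_base = np.full(cfg.n_genotypes, cfg.p_base_base)
    for m, (trait, eff) in planted_eff.items():
        carrier = (calls[m] == "22").to_numpy()
        if trait == "v_sat":
            v_sat = v_sat + eff * carrier
        else:
            p_base = p_base + eff * carrier
    v_sat = v_sat + rng.normal(0.0, cfg.param_noise_v, cfg.n_genotypes)
    p_base = p_base + rng.normal(0.0, cfg.param_noise_p, cfg.n_genotypes)
    v_sat = _snap(v_sat, 0.0, 130.0, 1.0)
    p_base = _snap(p_base, 0.0, 9.0, 0.1)
    is_winter = (calls[winter_marker] == "22").to_numpy()

    truth = pd.DataFrame(
        {
            "v_sat": v_sat,
            "p_base": p_base,
            "tt_emhe": 500.0,
            "is_winter": is_winter,
        },
        index=pd.Index(gids, name="genotype_id"),
    )
    truth.attrs["winter_marker"] = winter_marker
    truth.attrs["v_sat_markers"] = [winter_marker] + v_markers
    truth.attrs["p_base_markers"] = p_markers
    truth.attrs["effects"] = {m: planted_eff[m][1] for m in planted_eff}

    if cfg.missing_rate > 0 and cfg.missing_marker_fraction > 0:
        planted = set(planted_freq)
        candidates = [m for m in mids if m not in planted]
        n_aff = int(round(cfg.missing_marker_fraction * cfg.n_markers))
        affected = rng.choice(candidates, size=min(n_aff, len(candidates)), replace=False)
        for m in affected:
            hole = rng.random(cfg.n_genotypes) < cfg.missing_rate
            calls.loc[hole, m] = np.nan

    structure = pd.DataFrame(
        rng.dirichlet(np.full(4, 0.8), size=cfg.n_genotypes),
        index=pd.Index(gids, name="genotype_id"),
        columns=["g1", "g2", "g3", "g4"],
    )
    return GenotypeMatrix.from_calls(calls), structure, truth


# ------------------------------------------------------------- phenotypes


def gen_phenotypes(
    truth: pd.DataFrame,
    experiments: dict[str, Experiment],
    sites: dict[str, Site],
    weather: dict[str, list[DailyWeather]],
    noise_sd_days: float = 1.5,
    seed: int = 0,
    k: ModelConstants = DEFAULT_CONSTANTS,
) -> list[HeadingObservation]:
    """Forward-simulated heading observations with rounded normal noise;
    a heading past the scoring horizon becomes an NH observation."""
    rng = np.random.default_rng([seed, 2])
    obs: list[HeadingObservation] = []
    for exp_id in experiments:
        exp = experiments[exp_id]
        series = engine.build_series(exp, weather[exp.site], sites[exp.site], k)
        for gid, row in truth.iterrows():
            off = engine.heading_offsets(
                series,
                np.array([row["v_sat"]]),
                np.array([row["p_base"]]),
                np.array([row["tt_emhe"]]),
                k,
            )[0, 0, 0]
            if off == engine.NOT_REACHED_IDX:
                obs.append(HeadingObservation(gid, exp_id, None))
                continue
            date = series.date_of(int(off))
            if noise_sd_days > 0:
                date = date + _dt.timedelta(
                    days=int(round(rng.normal(0.0, noise_sd_days)))
                )
            obs.append(HeadingObservation(gid, exp_id, date))
    return obs


def gen_dataset(cfg: SynthConfig):
    """Generate the full bundle: sites, weather, experiments, panel,
    structure, truth and observations."""
    sites = {name: Site(name, lat) for name, lat in cfg.sites}
    weather = {
        name: gen_weather(site, cfg.weather_start, cfg.weather_years, cfg.seed)
        for name, site in sites.items()
    }
    experiments = gen_experiments(cfg)
    matrix, structure, truth = gen_panel(cfg)
    observations = gen_phenotypes(
        truth, experiments, sites, weather, cfg.noise_sd_days, cfg.seed
    )
    return {
        "sites": sites,
        "weather": weather,
        "experiments": experiments,
        "matrix": matrix,
        "structure": structure,
        "truth": truth,
        "observations": observations,
    }


def write_fixtures(cfg: SynthConfig, outdir) -> None:
    """Write the generated bundle as CSVs in the package's table dialects,
    plus a truth.csv with the planted parameters."""
    import pathlib

    from . import io as hio
    from .markers import write_genotypes

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    data = gen_dataset(cfg)
    hio.write_sites(data["sites"], out / "sites.csv")
    for name, wx in data["weather"].items():
        hio.write_weather(wx, out / f"weather_{name}.csv")
    hio.write_experiments(data["experiments"], out / "experiments.csv")
    hio.write_phenotypes(data["observations"], out / "phenotypes.csv")
    write_genotypes(data["matrix"], out / "genotypes.csv")
    hio.write_structure(data["structure"], out / "structure.csv")
    data["truth"].to_csv(out / "truth.csv")
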