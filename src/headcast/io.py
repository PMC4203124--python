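"""Tables and containers for weather, trials, phenotypes and structure.

All tables are plain CSV:

* weather:     ``date (ISO-8601), tmin, tmax`` — one row per day per file
* sites:       ``name, latitude, longitude, elevation``
* experiments: ``id, site, sowing_date, season_class`` (autumn|spring)
* phenotypes:  ``genotype_id, experiment_id, heading_date`` with the literal
  token ``NH`` for genotypes that never headed in that experiment
* structure:   ``genotype_id, g1, g2, g3, g4`` — ancestral-group contributions

Weather records must be gap-free: daily thermal-time accumulation over a
silently interpolated hole would bias every downstream date, so a missing
day is an error, never patched.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "NOT_HEADED",
    "Site",
    "DailyWeather",
    "Experiment",
    "HeadingObservation",
    "DataError",
    "read_weather",
    "write_weather",
    "read_sites",
    "write_sites",
    "read_experiments",
    "write_experiments",
    "read_phenotypes",
    "write_phenotypes",
    "read_structure",
    "write_structure",
]

#: Sentinel for an observation where the genotype never headed (spring-sown
#: winter wheats with an unmet vernalization requirement).
NOT_HEADED = None

_NH_TOKEN = "NH"


class DataError(ValueError):
    """A malformed or inconsistent input table."""


@dataclass(frozen=True)
class Site:
    name: str
    latitude: float
    longitude: float | None = None
    elevation: float | None = None

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise DataError(
                f"site {self.name!r}: latitude {self.latitude} outside [-90, 90]"
            )


class DailyWeather(NamedTuple):
    date: _dt.date
    tmin: float
    tmax: float


@dataclass(frozen=True)
class Experiment:
    """One location x sowing-date combination.

    ``horizon_days`` bounds the scoring window: field trials are observed
    until harvest, so a genotype whose simulated heading falls past the
    horizon counts as not reached, exactly as a real one is recorded NH.
    ``None`` means the full weather record is used.
    """

    id: str
    site: str
    sowing_date: _dt.date
    season_class: str  # "autumn" | "spring", declared, never inferred
    horizon_days: int | None = None

    def __post_init__(self):
        if self.season_class not in ("autumn", "spring"):
            raise DataError(
                f"experiment {self.id!r}: season_class must be autumn|spring, "
                f"got {self.season_class!r}"
            )


class HeadingObservation(NamedTuple):
    genotype_id: str
    experiment_id: str
    heading: _dt.date | None  # None == NOT_HEADED


def _parse_date(text: str, context: str) -> _dt.date:
    try:
        return _dt.date.fromisoformat(str(text).strip())
    except ValueError as exc:
        raise DataError(f"{context}: bad date {text!r}") from exc


# ---------------------------------------------------------------- weather


def read_weather(path) -> list[DailyWeather]:
    """Read a daily weather table; dates must be unique and consecutive."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"date", "tmin", "tmax"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing weather columns {sorted(missing)}")
    records: list[DailyWeather] = []
    for row in df.itertuples(index=False):
        date = _parse_date(row.date, f"{path}")
        tmin, tmax = float(row.tmin), float(row.tmax)
        if not np.isfinite(tmin) or not np.isfinite(tmax):
            raise DataError(f"{path}: non-finite temperature on {date}")
        if tmin > tmax:
            raise DataError(f"{path}: tmin > tmax on {date} ({tmin} > {tmax})")
        records.append(DailyWeather(date, tmin, tmax))
    for prev, cur in zip(records, records[1:]):
        delta = (cur.date - prev.date).days
        if delta == 0:
            raise DataError(f"{path}: duplicate date {cur.date}")
        if delta != 1:
            raise DataError(
                f"{path}: gap in weather record between {prev.date} and {cur.date}"
            )
    return records


def write_weather(records: list[DailyWeather], path) -> None:
    # shortest round-tripping float representation so read(write(x)) == x
    pd.DataFrame(
        {
            "date": [r.date.isoformat() for r in records],
            "tmin": [repr(r.tmin) for r in records],
            "tmax": [repr(r.tmax) for r in records],
        }
    ).to_csv(path, index=False)


# ------------------------------------------------------------------ sites


def read_sites(path) -> dict[str, Site]:
    df = pd.read_csv(path)
    sites: dict[str, Site] = {}
    for row in df.itertuples(index=False):
        name = str(row.name)
        if name in sites:
            raise DataError(f"{path}: duplicate site {name!r}")
        lon = float(row.longitude) if "longitude" in df.columns and pd.notna(row.longitude) else None
        elev = float(row.elevation) if "elevation" in df.columns and pd.notna(row.elevation) else None
        sites[name] = Site(name, float(row.latitude), lon, elev)
    return sites


def write_sites(sites: dict[str, Site], path) -> None:
    pd.DataFrame(
        [
            {
                "name": s.name,
                "latitude": s.latitude,
                "longitude": s.longitude,
                "elevation": s.elevation,
            }
            for s in sites.values()
        ]
    ).to_csv(path, index=False)


# ------------------------------------------------------------ experiments


def read_experiments(path, sites: dict[str, Site] | None = None) -> dict[str, Experiment]:
    df = pd.read_csv(path)
    out: dict[str, Experiment] = {}
    for row in df.itertuples(index=False):
        exp_id = str(row.id)
        if exp_id in out:
            raise DataError(f"{path}: duplicate experiment id {exp_id!r}")
        site = str(row.site)
        if sites is not None and site not in sites:
            raise DataError(f"{path}: experiment {exp_id!r} references unknown site {site!r}")
        horizon = None
        if "horizon_days" in df.columns and pd.notna(row.horizon_days):
            horizon = int(row.horizon_days)
        out[exp_id] = Experiment(
            exp_id, site, _parse_date(row.sowing_date, f"{path}:{exp_id}"),
            str(row.season_class), horizon,
        )
    return out


def write_experiments(experiments: dict[str, Experiment], path) -> None:
    pd.DataFrame(
        [
            {
                "id": e.id,
                "site": e.site,
                "sowing_date": e.sowing_date.isoformat(),
                "season_class": e.season_class,
                "horizon_days": e.horizon_days,
            }
            for e in experiments.values()
        ]
    ).to_csv(path, index=False)


# ------------------------------------------------------------- phenotypes


def read_phenotypes(
    path, experiments: dict[str, Experiment] | None = None
) -> list[HeadingObservation]:
    """Read heading observations; ``NH`` parses to the NOT_HEADED sentinel."""
    df = pd.read_csv(path, dtype=str)
    missing = {"genotype_id", "experiment_id", "heading_date"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing phenotype columns {sorted(missing)}")
    seen: set[tuple[str, str]] = set()
    obs: list[HeadingObservation] = []
    for row in df.itertuples(index=False):
        key = (str(row.genotype_id), str(row.experiment_id))
        if key in seen:
            raise DataError(f"{path}: duplicate observation for {key}")
        seen.add(key)
        if experiments is not None and key[1] not in experiments:
            raise DataError(f"{path}: unknown experiment reference {key[1]!r}")
        token = str(row.heading_date).strip()
        if token == _NH_TOKEN:
            heading = NOT_HEADED
        else:
            heading = _parse_date(token, f"{path}:{key}")
            if experiments is not None and heading < experiments[key[1]].sowing_date:
                raise DataError(
                    f"{path}: heading {heading} before sowing of {key[1]!r}"
                )
        obs.append(HeadingObservation(key[0], key[1], heading))
    return obs


def write_phenotypes(obs: list[HeadingObservation], path) -> None:
    pd.DataFrame(
        {
            "genotype_id": [o.genotype_id for o in obs],
            "experiment_id": [o.experiment_id for o in obs],
            "heading_date": [
                _NH_TOKEN if o.heading is NOT_HEADED else o.heading.isoformat()
                for o in obs
            ],
        }
    ).to_csv(path, index=False)


# -------------------------------------------------------------- structure


def read_genotypes(path):
    """Genotype CSV (rows = genotypes, columns = markers, empty = missing);
    see :class:`headcast.markers.GenotypeMatrix`."""
    from .markers import read_genotypes as _rg

    return _rg(path)


def read_structure(path) -> pd.DataFrame:
    """Ancestral-group contributions, indexed by genotype_id, columns g1..g4."""
    df = pd.read_csv(path, dtype={"genotype_id": str})
    missing = {"genotype_id", "g1", "g2", "g3", "g4"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing structure columns {sorted(missing)}")
    if df["genotype_id"].duplicated().any():
        dup = df.loc[df["genotype_id"].duplicated(), "genotype_id"].iloc[0]
        raise DataError(f"{path}: duplicate genotype {dup!r} in structure table")
    out = df.set_index("genotype_id")[["g1", "g2", "g3", "g4"]].astype(float)
    return out


def write_structure(structure: pd.DataFrame, path) -> None:
    structure.rename_axis("genotype_id").reset_index().to_csv(path, index=False)
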