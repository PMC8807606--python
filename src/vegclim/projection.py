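"""Scenario projection of vegetation-driven temperature change.

Applies a fitted sensitivity model to per-model, per-scenario trajectories
of leaf area and its climate drivers, factors the resulting signal into
LAI-only / climate-change / per-driver terms, adds the carbon-stock
(biochemical) term, and aggregates across zones, seasons and the model
ensemble.

Sign convention: negative temperature change is cooling, everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid_core import (
    AreaWeights,
    ClimateZoneMap,
    EmptyDomainError,
    GridError,
    GridField,
    VEGETATED_ZONES,
    ZONE_CODES,
)
from .sensitivity import SensitivityModel, eval_surface

log = logging.getLogger(__name__)

#: degC of land warming per Tt of carbon added to the atmosphere
CARBON_WARMING_PER_TTC = 2.2


class ProjectionError(ValueError):
    pass


@dataclass
class ScenarioRun:
    """One model x one scenario bundle of annual driver/LAI trajectories.

    Each GridField carries a monthly climatology for every year (time axis
    of length nyears*12, year-major). ``carbon`` is the global vegetation
    carbon stock (Tt C) per year; ``warming`` is the scenario's global land
    warming (degC relative to the baseline year) per year.
    """

    model: str
    scenario: str
    lai: GridField
    sc: GridField
    sw: GridField
    e: GridField
    carbon: np.ndarray
    warming: np.ndarray
    baseline_year: int

    def __post_init__(self) -> None:
        geo = self.lai.geometry
        for f in (self.sc, self.sw, self.e):
            if f.geometry != geo:
                raise GridError("scenario fields must share one geometry")
        self.carbon = np.asarray(self.carbon, dtype=float)
        self.warming = np.asarray(self.warming, dtype=float)
        if np.any(self.carbon < 0):
            raise ProjectionError("vegetation carbon must be nonnegative")

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.lai.time[:, 0])

    def monthly_stack(self, name: str, year: int) -> np.ndarray:
        """(12, nlat, nlon) float64 stack for one year of one field."""
        f: GridField = getattr(self, name)
        out = np.empty((12, *f.geometry.shape))
        for m in range(1, 13):
            out[m - 1] = np.asarray(f.sel(year, m), dtype=float)
        return out


def _delta_T_monthly(
    model: SensitivityModel,
    sc: np.ndarray,
    sw: np.ndarray,
    e: np.ndarray,
    lai_t: np.ndarray,
    lai_base: np.ndarray,
) -> np.ndarray:
    """Regime-split temperature change for one (12, nlat, nlon) stack."""
    snow = sc >= model.snow_threshold
    s_snow = eval_surface(model.snow_surface, sc, sw, warn_out_of_range=False)
    s_free = eval_surface(model.snowfree_surface, e, sw, warn_out_of_range=False)
    with np.errstate(invalid="ignore", divide="ignore"):
        dln = np.log(lai_t) - np.log(lai_base)
    bad_free = (~snow) & ~((lai_t > 0) & (lai_base > 0))
    out = np.where(snow, s_snow * (lai_t - lai_base), s_free * dln)
    out = np.where(bad_free, np.nan, out)
    return out


def biophysical_delta_T(
    model: SensitivityModel, run: ScenarioRun, year: int
) -> GridField:
    """Monthly vegetation-driven temperature change of ``year`` relative to
    the run's baseline year (12 monthly slices; average them for the annual
    value).

    The regime is picked per cell-month from the year's own snow cover: the
    snow surface scales the absolute LAI change, the snow-free surface the
    log LAI change.
    """
    sc = run.monthly_stack("sc", year)
    sw = run.monthly_stack("sw", year)
    e = run.monthly_stack("e", year)
    lai_t = run.monthly_stack("lai", year)
    lai_b = run.monthly_stack("lai", run.baseline_year)
    vals = _delta_T_monthly(model, sc, sw, e, lai_t, lai_b)
    n_bad = int(np.count_nonzero(np.isnan(vals) & np.isfinite(sc)))
    if n_bad:
        log.info("biophysical_delta_T: %d cell-months with nonpositive LAI", n_bad)
    time = np.column_stack([np.full(12, year), np.arange(1, 13)])
    return GridField(
        geometry=run.lai.geometry, time=time, values=vals, units="degC",
        name="biophysical dT",
    )


def biophysical_series(
    model: SensitivityModel, run: ScenarioRun
) -> tuple[np.ndarray, np.ndarray]:
    """(years, values) with values of shape (nyears, 12, nlat, nlon)."""
    years = run.years
    out = np.empty((years.size, 12, *run.lai.geometry.shape))
    for i, y in enumerate(years):
        out[i] = biophysical_delta_T(model, run, int(y)).values
    return years, out


@dataclass
class AttributionResult:
    """Factorial decomposition of the projected signal.

    All arrays have shape (nyears, 12, nlat, nlon). ``climate_effect`` is
    exactly ``all_effects - lai_effect``; the hold-one-at-baseline driver
    terms do not add up exactly to it, and the shortfall is surfaced as
    ``closure_residual`` rather than hidden.
    """

    years: np.ndarray
    geometry: object
    all_effects: np.ndarray
    lai_effect: np.ndarray
    climate_effect: np.ndarray
    driver_terms: dict[str, np.ndarray]
    closure_residual: np.ndarray


def factorial_attribution(
    model: SensitivityModel,
    run: ScenarioRun,
    baseline_year: int | None = None,
) -> AttributionResult:
    """Split the projected signal into LAI-only, climate-change and
    per-driver contributions.

    ``lai_effect`` evaluates the surfaces at baseline drivers with future
    LAI; ``all_effects`` uses future drivers; each driver term is
    ``all_effects`` minus the variant with that one driver held at its
    baseline climatology.
    """
    by = run.baseline_year if baseline_year is None else baseline_year
    try:
        base = {name: run.monthly_stack(name, by) for name in ("sc", "sw", "e", "lai")}
    except KeyError as exc:
        raise ProjectionError(f"baseline year {by} missing from run") from exc
    years = run.years
    shape = (years.size, 12, *run.lai.geometry.shape)
    all_eff = np.empty(shape)
    lai_eff = np.empty(shape)
    terms = {d: np.empty(shape) for d in ("snow", "evap", "solar")}
    driver_of = {"snow": "sc", "evap": "e", "solar": "sw"}
    for i, y in enumerate(years):
        cur = {name: run.monthly_stack(name, int(y)) for name in ("sc", "sw", "e", "lai")}
        all_eff[i] = _delta_T_monthly(
            model, cur["sc"], cur["sw"], cur["e"], cur["lai"], base["lai"]
        )
        lai_eff[i] = _delta_T_monthly(
            model, base["sc"], base["sw"], base["e"], cur["lai"], base["lai"]
        )
        for term, dname in driver_of.items():
            held = dict(cur)
            held[dname] = base[dname]
            variant = _delta_T_monthly(
                model, held["sc"], held["sw"], held["e"], cur["lai"], base["lai"]
            )
            terms[term][i] = all_eff[i] - variant
    climate = all_eff - lai_eff
    residual = climate - (terms["snow"] + terms["evap"] + terms["solar"])
    return AttributionResult(
        years=years,
        geometry=run.lai.geometry,
        all_effects=all_eff,
        lai_effect=lai_eff,
        climate_effect=climate,
        driver_terms=terms,
        closure_residual=residual,
    )


def linear_lai_run(run: ScenarioRun) -> ScenarioRun:
    """Variant of a run whose LAI follows its per-cell-month linear trend
    (slope x elapsed years from the baseline) instead of the raw
    trajectory; feeding this to any projection operation gives the
    slope-based flavour of the "sensitivity times LAI trend" product.
    For an exactly linear trajectory it is the identity."""
    years = run.years.astype(float)
    geo = run.lai.geometry
    vals = np.asarray(run.lai.values, dtype=float).reshape(
        years.size, 12, *geo.shape
    )
    ym = years.mean()
    dy = years - ym
    slope = np.tensordot(dy, vals - vals.mean(axis=0), axes=(0, 0)) / (dy @ dy)
    base = vals.mean(axis=0) + slope * (run.baseline_year - ym)
    fitted = base[None] + slope[None] * (years - run.baseline_year)[:, None, None, None]
    lai = GridField(
        geometry=geo, time=run.lai.time.copy(),
        values=fitted.reshape(-1, *geo.shape), units=run.lai.units,
        name=run.lai.name,
    )
    return ScenarioRun(
        model=run.model, scenario=run.scenario, lai=lai, sc=run.sc, sw=run.sw,
        e=run.e, carbon=run.carbon, warming=run.warming,
        baseline_year=run.baseline_year,
    )


def biochemical_delta_T(dB):
    """Temperature change from moving ``dB`` Tt C from the atmosphere into
    vegetation: a cooling (negative) of magnitude 2.2 degC per Tt C."""
    dB = np.asarray(dB, dtype=float)
    out = -CARBON_WARMING_PER_TTC * dB
    if out.ndim == 0:
        return float(out)
    return out


def linear_trend(values: np.ndarray, years, per: float = 1.0) -> np.ndarray:
    """Per-cell OLS slope of annual values against year, scaled to
    units per ``per`` years (e.g. per=10 for decadal trends).

    ``values`` has shape (nyears, ...); all-missing cells come back NaN.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if years.size < 3:
        raise ProjectionError("need >= 3 time points for a trend")
    flat = values.reshape(years.size, -1)
    ok = np.isfinite(flat)
    n = ok.sum(axis=0)
    t = years[:, None]
    tm = np.where(ok, t, 0.0).sum(axis=0) / np.maximum(n, 1)
    vm = np.where(ok, flat, 0.0).sum(axis=0) / np.maximum(n, 1)
    dt = np.where(ok, t - tm, 0.0)
    dv = np.where(ok, flat - vm, 0.0)
    num = (dt * dv).sum(axis=0)
    den = (dt * dt).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where((n >= 3) & (den > 0), num / den, np.nan)
    return (slope * per).reshape(values.shape[1:])


def ensemble_stats(members: list[np.ndarray]) -> dict[str, np.ndarray]:
    """Element-wise ensemble order statistics; quartiles use linear
    interpolation between order statistics (fixed, deterministic rule)."""
    if len(members) < 2:
        raise ProjectionError("ensemble statistics need >= 2 members")
    stack = np.stack([np.asarray(m, dtype=float) for m in members])
    return {
        "median": np.nanmedian(stack, axis=0),
        "q1": np.nanquantile(stack, 0.25, axis=0),
        "q3": np.nanquantile(stack, 0.75, axis=0),
        "min": np.nanmin(stack, axis=0),
        "max": np.nanmax(stack, axis=0),
    }


def climate_zone_aggregate(
    values: np.ndarray,
    years,
    zones: ClimateZoneMap,
    weights: AreaWeights,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-zone annual series and mean seasonal cycle.

    ``values`` has shape (nyears, 12, nlat, nlon). Southern-hemisphere cells
    have their monthly cycle rotated by 6 months before zone averaging so
    seasonality lines up with the northern solar cycle. Polar and non-land
    cells are excluded. Returns (annual, seasonal) frames indexed by zone
    name: annual has one column per year, seasonal one per month.
    """
    values = np.asarray(values, dtype=float)
    years = np.asarray(years)
    if values.shape[1] != 12 or values.shape[2:] != zones.geometry.shape:
        raise GridError("values must be (nyears, 12, nlat, nlon) on the zone grid")
    south = zones.geometry.lat < 0.0
    aligned = values.copy()
    aligned[:, :, south, :] = np.roll(values[:, :, south, :], 6, axis=1)
    w = weights.w
    annual_rows, seasonal_rows, index = [], [], []
    for code in VEGETATED_ZONES:
        zmask = zones.mask(code)
        if not zmask.any():
            continue
        index.append(ZONE_CODES[code])
        sel = aligned[:, :, zmask]  # (nyears, 12, ncells)
        wsel = w[zmask]
        valid = np.isfinite(sel)
        wz = np.where(valid, wsel, 0.0)
        den = wz.sum(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            num = (np.where(valid, sel, 0.0) * wsel).sum(axis=-1)
            zone_monthly = np.where(den > 0, num / den, np.nan)
        if np.isnan(zone_monthly).all():
            log.info("climate_zone_aggregate: zone %s has no valid cells", ZONE_CODES[code])
        annual_rows.append(np.nanmean(zone_monthly, axis=1))
        seasonal_rows.append(np.nanmean(zone_monthly, axis=0))
    annual = pd.DataFrame(annual_rows, index=index, columns=years)
    seasonal = pd.DataFrame(seasonal_rows, index=index, columns=range(1, 13))
    return annual, seasonal


def relative_mitigation(mitigation_cooling: float, scenario_warming: float) -> float:
    """Mitigation as a percentage of the absolute scenario warming."""
    if scenario_warming == 0:
        raise ProjectionError("relative mitigation undefined for zero warming")
    return 100.0 * mitigation_cooling / abs(scenario_warming)


def _end_of_century(values: np.ndarray, n_last: int = 5) -> np.ndarray:
    return np.asarray(values)[-n_last:].mean(axis=0)


def mitigation_summary(
    model: SensitivityModel,
    runs: list[ScenarioRun],
    weights: AreaWeights,
    n_last: int = 5,
) -> pd.DataFrame:
    """Per-scenario ensemble statistics of end-of-century global land
    temperature effects.

    Columns: biophysical and biochemical temperature change (degC, negative
    = cooling), total scenario land warming (degC), and relative mitigation
    (%, cooling magnitudes over the absolute warming). Rows: one per
    scenario x statistic (median/q1/q3/min/max).
    """
    per_scen: dict[str, dict[str, list[float]]] = {}
    for run in runs:
        years, vals = biophysical_series(model, run)
        annual = np.nanmean(vals, axis=1)  # (nyears, nlat, nlon)
        glob = np.array(
            [
                np.nansum(a * weights.w) / np.nansum(np.where(np.isfinite(a), weights.w, 0.0))
                for a in annual
            ]
        )
        biophys = float(_end_of_century(glob, n_last))
        biochem = float(biochemical_delta_T(run.carbon[-1] - run.carbon[0]))
        warming = float(_end_of_century(run.warming, n_last))
        rel = relative_mitigation(-(biophys + biochem), warming)
        d = per_scen.setdefault(
            run.scenario,
            {"biophysical": [], "biochemical": [], "warming": [], "relative_pct": []},
        )
        d["biophysical"].append(biophys)
        d["biochemical"].append(biochem)
        d["warming"].append(warming)
        d["relative_pct"].append(rel)
    rows = []
    for scen, cols in per_scen.items():
        for stat, fn in (
            ("median", np.median),
            ("q1", lambda a: np.quantile(a, 0.25)),
            ("q3", lambda a: np.quantile(a, 0.75)),
            ("min", np.min),
            ("max", np.max),
        ):
            rows.append(
                {
                    "scenario": scen,
                    "stat": stat,
                    **{k: float(fn(np.asarray(v))) for k, v in cols.items()},
                }
            )
    return pd.DataFrame(rows)
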