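"""Synthetic observation grids and scenario ensembles with known ground truth.

The baseline generator builds monthly LAI / temperature / snow / radiation /
evaporation fields in which a known sensitivity model is injected on top of
a large-scale temperature anomaly shared by neighbouring cells, so the
decomposition and surface fitting can be validated end to end. The scenario
generator emits CMIP6-like multi-model driver trajectories whose ensemble
ordering and carbon coupling are known by construction.

Temperature construction, per cell, month and year:

    T = T_clim + A(year, month) + L + noise

where A is the shared anomaly and L the injected vegetation term: the snow
surface times the LAI excursion from its reference value in snowy
cell-months, the snow-free surface times the ln-LAI excursion elsewhere.
By default A is spatially uniform per (year, month) -- an infinite
correlation length -- so inverse-distance weighting over stable neighbours
recovers it exactly; a finite ``anomaly_correlation_cells`` adds smooth
spatial modes to stress-test that assumption.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .grid_core import GridField, GridGeometry, great_circle_distance_km
from .local_signal import NeighborGraph
from .projection import ScenarioRun
from .sensitivity import SensitivityModel, published_surfaces

DEG_KM = 111.194926644559


class GenerationError(RuntimeError):
    """The requested configuration cannot satisfy its own contracts."""


def default_baseline_geometry() -> GridGeometry:
    """60 x 120 grid spanning 60S-80N, global in longitude."""
    dlat = 140.0 / 60.0
    lat = -60.0 + dlat / 2.0 + dlat * np.arange(60)
    lon = -180.0 + 1.5 + 3.0 * np.arange(120)
    return GridGeometry(lat=lat, lon=lon)


def default_scenario_geometry() -> GridGeometry:
    """2-degree grid over a 57 x 20 lat/lon window reaching into the snow zone."""
    lat = -44.0 + 2.0 * np.arange(57)  # -44 .. 68
    lon = 1.0 + 2.0 * np.arange(20)
    return GridGeometry(lat=lat, lon=lon)


def auto_radius_km(geometry: GridGeometry) -> float:
    """Neighbour-search radius guaranteeing every cell at least its 4-cell
    neighbourhood: 1.45x the larger of the lat step and the equatorial lon
    step."""
    dlat_km = geometry.dlat() * DEG_KM
    dlon_km = geometry.dlon() * DEG_KM
    return 1.45 * max(dlat_km, dlon_km)


# ---------------------------------------------------------------------------
# deterministic latitude-month driver templates


def _declination(month: np.ndarray) -> np.ndarray:
    return 23.44 * np.cos(2.0 * np.pi * (month - 6) / 12.0)


def driver_templates(geometry: GridGeometry) -> dict[str, np.ndarray]:
    """Deterministic (12, nlat, nlon) climatologies of SW, SC, E, LAI and T.

    Snow cover declines toward low latitudes and summer months; radiation
    follows a latitude/season insolation curve; evaporation rises with leaf
    area and radiation; every field stays within physical ranges.
    """
    months = np.arange(1, 13)
    lat = geometry.lat
    la = lat[None, :]  # (1, nlat)
    m = months[:, None]  # (12, 1)

    decl = _declination(m)
    sw = 430.0 * np.clip(np.cos(np.deg2rad(la - decl)), 0.0, None) ** 1.2

    w_north = 0.5 * (1.0 + np.cos(2.0 * np.pi * (m - 1) / 12.0))
    w_south = 0.5 * (1.0 + np.cos(2.0 * np.pi * (m - 7) / 12.0))
    s_north = np.clip((la - 40.0) / 25.0, 0.0, 1.0)
    s_south = np.clip((-la - 40.0) / 25.0, 0.0, 1.0)
    sc = 95.0 * (s_north * w_north + s_south * w_south)
    sc = np.where(sc < 2.0, 0.0, np.clip(sc, 0.0, 100.0))

    base = 0.4 + 4.0 * np.exp(-(((la - 10.0) / 35.0) ** 2))
    grow_n = 0.5 * (1.0 - np.cos(2.0 * np.pi * (m - 1) / 12.0))
    grow_s = 0.5 * (1.0 - np.cos(2.0 * np.pi * (m - 7) / 12.0))
    grow = np.where(la >= 0, grow_n, grow_s)
    seasonality = np.clip((np.abs(la) - 20.0) / 30.0, 0.0, 1.0)
    lai = base * (1.0 - 0.4 * seasonality * (1.0 - grow))

    e = 0.15 + 0.5 * lai + 1.8 * (sw / 430.0)

    t = 30.0 * np.cos(np.deg2rad(la)) - 8.0 + 10.0 * (sw / 430.0 - 0.5)

    out = {}
    for key, arr in (("sw", sw), ("sc", sc), ("e", e), ("lai", lai), ("t", t)):
        out[key] = np.broadcast_to(
            arr[:, :, None], (12, geometry.nlat, geometry.nlon)
        ).copy()
    return out


# ---------------------------------------------------------------------------
# baseline observations


@dataclass(frozen=True)
class BaselineSyntheticConfig:
    geometry: GridGeometry = field(default_factory=default_baseline_geometry)
    years: tuple[int, ...] = tuple(range(2003, 2015))
    true_model: SensitivityModel = field(default_factory=published_surfaces)
    anomaly_sd: float = 1.0  # degC, inter-annual large-scale anomaly
    anomaly_correlation_cells: float | None = None  # None = spatially uniform
    obs_noise_sd: float = 0.0  # degC, independent observation noise
    stable_fraction: float = 0.4
    change_rel_range: tuple[float, float] = (0.35, 0.65)  # fractional LAI shift
    min_change_abs: float = 0.4  # m2/m2 floor on the shift
    browning_fraction: float = 0.15
    driver_heterogeneity: float = 0.35  # per-cell spread of SC/SW/E templates
    radius_km: float | None = None  # None = auto from geometry
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.stable_fraction < 1.0:
            raise ValueError("stable_fraction must lie in (0, 1)")
        if self.obs_noise_sd < 0 or self.anomaly_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        if len(self.years) < 2:
            raise ValueError("need at least 2 years")

    def resolved_radius_km(self) -> float:
        return self.radius_km if self.radius_km is not None else auto_radius_km(self.geometry)


@dataclass
class BaselineTruth:
    """Everything needed to predict the injected signal exactly."""

    model: SensitivityModel
    stable_mask: np.ndarray  # (nlat, nlon) bool
    amplitude: np.ndarray  # (nlat, nlon), m2/m2 change over the full window
    lai_climatology: np.ndarray  # (12, nlat, nlon) reference-year LAI
    drivers: dict[str, np.ndarray]  # sc/sw/e climatologies (12, nlat, nlon)
    snow_regime: np.ndarray  # (12, nlat, nlon) bool
    surface_value: np.ndarray  # (12, nlat, nlon) regime-native sensitivity
    anomaly: np.ndarray  # (nt, nlat, nlon) degC
    radius_km: float

    def expected_response(self, cell: np.ndarray, month: np.ndarray) -> np.ndarray:
        """Injected regime-native sensitivity for flat cell indices."""
        return self.surface_value.reshape(12, -1)[
            np.asarray(month, int) - 1, np.asarray(cell, int)
        ]


def _anomaly_field(
    rng: np.random.Generator, config: BaselineSyntheticConfig, nt: int
) -> np.ndarray:
    nlat, nlon = config.geometry.shape
    if config.anomaly_sd == 0:
        return np.zeros((nt, nlat, nlon))
    uniform = rng.normal(0.0, config.anomaly_sd, size=nt)
    out = np.broadcast_to(uniform[:, None, None], (nt, nlat, nlon)).copy()
    lc = config.anomaly_correlation_cells
    if lc is not None:
        # a few smooth plane-wave modes of wavelength ~lc cells
        ii, jj = np.meshgrid(np.arange(nlat), np.arange(nlon), indexing="ij")
        n_modes = 3
        for _ in range(n_modes):
            theta = rng.uniform(0.0, 2.0 * np.pi)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            pattern = np.cos(
                2.0 * np.pi * (np.cos(theta) * ii + np.sin(theta) * jj) / lc + phase
            )
            amp = rng.normal(0.0, config.anomaly_sd / np.sqrt(n_modes), size=nt)
            out += amp[:, None, None] * pattern[None, :, :]
    return out


def _assign_cell_classes(
    rng: np.random.Generator,
    config: BaselineSyntheticConfig,
    lai0: np.ndarray,
    graph: NeighborGraph,
) -> tuple[np.ndarray, np.ndarray]:
    """Stable mask and signed change amplitude, repaired so every changing
    cell keeps at least one stable neighbour within the search radius."""
    geometry = config.geometry
    n = geometry.ncell
    stable = rng.random(n) < config.stable_fraction
    lo, hi = config.change_rel_range
    rel = rng.uniform(lo, hi, size=n)
    min_lai = lai0.reshape(12, -1).min(axis=0)
    mag = np.maximum(config.min_change_abs, rel * min_lai)
    sign = np.ones(n)
    can_brown = min_lai - mag >= 0.15
    sign[(rng.random(n) < config.browning_fraction) & can_brown] = -1.0
    amp = np.where(stable, 0.0, mag * sign)

    counts = graph.neighbor_count()
    if np.any((counts < 1) & ~stable):
        raise GenerationError(
            "search radius leaves cells with no neighbours at all; "
            "increase radius_km"
        )
    adjacency = graph.adjacency
    for _ in range(20):
        has_ref = (adjacency @ stable.astype(float)) >= 1.0
        orphans = np.flatnonzero(~stable & ~has_ref)
        if orphans.size == 0:
            break
        for o in orphans:
            nbrs = adjacency.indices[adjacency.indptr[o] : adjacency.indptr[o + 1]]
            pick = int(nbrs[0])
            stable[pick] = True
            amp[pick] = 0.0
    else:
        raise GenerationError("could not satisfy stable-neighbour coverage")
    return stable.reshape(geometry.shape), amp.reshape(geometry.shape)


def generate_baseline_obs(
    config: BaselineSyntheticConfig,
) -> tuple[dict[str, GridField], BaselineTruth]:
    """Generate the observation bundle {lai, t, sc, sw, e} plus ground truth.

    Same config (including seed) always yields bit-identical fields.
    """
    rng = np.random.default_rng(config.seed)
    geometry = config.geometry
    years = np.asarray(config.years, dtype=int)
    ny = years.size
    nt = ny * 12
    templates = driver_templates(geometry)
    radius = config.resolved_radius_km()
    graph = NeighborGraph(geometry, radius_km=radius)

    # per-cell, year-independent heterogeneity (cloudiness, snow shading,
    # aridity) so the two predictors of each regime fill a 2-d region
    # instead of tracing a latitude-month curve
    h = config.driver_heterogeneity
    u_sw, u_sc, u_e = (rng.random(geometry.shape) for _ in range(3))
    templates = dict(templates)
    templates["sw"] = templates["sw"] * (1.0 - 0.6 * h * u_sw)
    sc_mod = templates["sc"] * (1.0 - 1.2 * h * u_sc)
    templates["sc"] = np.where(sc_mod < 1.5, 0.0, sc_mod)
    templates["e"] = templates["e"] * (1.0 + h * (2.0 * u_e - 1.0))

    stable, amp = _assign_cell_classes(rng, config, templates["lai"], graph)
    anomaly = _anomaly_field(rng, config, nt)
    noise = (
        rng.normal(0.0, config.obs_noise_sd, size=(nt, *geometry.shape))
        if config.obs_noise_sd > 0
        else np.zeros((nt, *geometry.shape))
    )

    model = config.true_model
    snow = templates["sc"] >= model.snow_threshold
    sv_snow = _eval_quadratic(model.snow_surface.coeffs, templates["sc"], templates["sw"])
    sv_free = _eval_quadratic(model.snowfree_surface.coeffs, templates["e"], templates["sw"])
    surface_value = np.where(snow, sv_snow, sv_free)

    time = np.array([(int(y), m) for y in years for m in range(1, 13)], dtype=int)
    shape = (nt, *geometry.shape)
    lai_vals = np.empty(shape)
    t_vals = np.empty(shape)
    # two-level trajectory: first half of the window at the reference LAI,
    # second half shifted by the full cell amplitude. Within-half pairs then
    # carry exactly zero LAI change (clean references), cross-half pairs the
    # full shift, always above the retention threshold.
    ramp = (np.arange(ny) >= ny // 2).astype(float)
    for iy, y in enumerate(years):
        for m in range(12):
            it = iy * 12 + m
            lai0 = templates["lai"][m]
            lai_y = lai0 + amp * ramp[iy]
            lai_vals[it] = lai_y
            with np.errstate(invalid="ignore", divide="ignore"):
                local = np.where(
                    snow[m],
                    surface_value[m] * (lai_y - lai0),
                    surface_value[m] * (np.log(lai_y) - np.log(lai0)),
                )
            t_vals[it] = templates["t"][m] + anomaly[it] + local + noise[it]
    if np.any(lai_vals <= 0):
        raise GenerationError("generated LAI fell to zero; reduce change amplitude")

    def _field(name: str, vals: np.ndarray, units: str) -> GridField:
        return GridField(geometry=geometry, time=time.copy(), values=vals, units=units, name=name)

    clim = {
        k: np.tile(templates[k], (ny, 1, 1)) for k in ("sc", "sw", "e")
    }
    fields = {
        "lai": _field("leaf area index", lai_vals, "m2/m2"),
        "t": _field("air temperature", t_vals, "degC"),
        "sc": _field("snow cover fraction", clim["sc"], "%"),
        "sw": _field("downwelling shortwave radiation", clim["sw"], "W/m2"),
        "e": _field("land evaporation", clim["e"], "mm/day"),
    }
    truth = BaselineTruth(
        model=model,
        stable_mask=stable,
        amplitude=amp,
        lai_climatology=templates["lai"].copy(),
        drivers={k: templates[k].copy() for k in ("sc", "sw", "e")},
        snow_regime=snow,
        surface_value=surface_value,
        anomaly=anomaly,
        radius_km=radius,
    )
    return fields, truth


def _eval_quadratic(coeffs, x, y):
    # kept deliberately separate from sensitivity.eval_surface: this is the
    # oracle's own arithmetic (same canonical term order)
    a_xx, a_yy, a_xy, b_x, b_y, c = coeffs
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return a_xx * x * x + a_yy * y * y + a_xy * x * y + b_x * x + b_y * y + c


# ---------------------------------------------------------------------------
# scenario ensembles


@dataclass(frozen=True)
class ScenarioSyntheticConfig:
    geometry: GridGeometry = field(default_factory=default_scenario_geometry)
    n_models: int = 6
    scenarios: tuple[tuple[str, float], ...] = (
        ("ssp126", 0.25),
        ("ssp245", 0.5),
        ("ssp370", 0.75),
        ("ssp585", 1.0),
    )
    years: tuple[int, ...] = tuple(range(2015, 2101))
    perturbation_sd: float = 0.15
    carbon_per_lai: float = 0.5  # Tt C per unit global-mean LAI increase
    carbon_base: float = 0.45  # Tt C initial vegetation stock
    warming_at_strength_1: float = 5.0  # degC land warming by 2100
    lai_gain: float = 0.5  # fractional LAI increase at strength 1 by 2100
    arid_band: tuple[float, float] = (15.0, 32.0)  # |lat| range with flat E
    true_model: SensitivityModel = field(default_factory=published_surfaces)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 2:
            raise ValueError("need at least 2 models")
        strengths = [s for _, s in self.scenarios]
        if any(b <= a for a, b in zip(strengths, strengths[1:])):
            raise ValueError("scenario strengths must be strictly increasing")


@dataclass
class ScenarioTruth:
    """Ground truth for projection tests: the surfaces used to build the
    runs, plus the ensemble-shared greening pattern and model factors."""

    model: SensitivityModel
    greening_pattern: np.ndarray  # (nlat, nlon) in (0, 1]
    model_factors: np.ndarray  # (n_models,)


def generate_scenario_ensemble(
    config: ScenarioSyntheticConfig,
) -> tuple[list[ScenarioRun], ScenarioTruth]:
    """CMIP6-like runs: ensemble-mean LAI rises at a rate proportional to
    scenario strength, snow cover declines, evaporation rises outside the
    arid band, vegetation carbon tracks global LAI; per-model spread is
    controlled by ``perturbation_sd``.

    Model perturbation factors are drawn once per model and shared across
    scenarios, so the ensemble-mean scenario ordering holds for every seed.
    """
    rng = np.random.default_rng(config.seed)
    geometry = config.geometry
    templates = driver_templates(geometry)
    years = np.asarray(config.years, dtype=int)
    ny = years.size
    ramp = (years - years[0]) / max(years[-1] - years[0], 1)

    pattern = (0.3 + 0.7 * rng.random(geometry.shape)).astype(float)
    factors = np.clip(1.0 + rng.normal(0.0, config.perturbation_sd, config.n_models), 0.3, None)
    carbon_noise = rng.normal(0.0, config.perturbation_sd, config.n_models)
    warm_noise = rng.normal(0.0, config.perturbation_sd, config.n_models)

    from .grid_core import cell_area_weights

    w = cell_area_weights(geometry).w
    wn = w / w.sum()
    arid_lo, arid_hi = config.arid_band
    arid = (np.abs(geometry.lat)[:, None] >= arid_lo) & (
        np.abs(geometry.lat)[:, None] < arid_hi
    )
    arid = np.broadcast_to(arid, geometry.shape)

    time = np.array([(int(y), m) for y in years for m in range(1, 13)], dtype=int)
    runs: list[ScenarioRun] = []
    for im in range(config.n_models):
        f = float(factors[im])
        for scen, strength in config.scenarios:
            lai = np.empty((ny * 12, *geometry.shape), dtype=np.float32)
            sc = np.empty_like(lai)
            sw = np.empty_like(lai)
            e = np.empty_like(lai)
            for iy in range(ny):
                r = float(ramp[iy])
                lai_gain = 1.0 + config.lai_gain * strength * f * r * pattern
                sc_gain = 1.0 - 0.6 * strength * r
                e_gain = np.where(
                    arid,
                    1.0 - 0.05 * strength * r,
                    1.0 + 0.25 * strength * r * pattern,
                )
                sw_gain = 1.0 - 0.03 * strength * r
                sl = slice(iy * 12, iy * 12 + 12)
                lai[sl] = templates["lai"] * lai_gain
                sc[sl] = templates["sc"] * sc_gain
                e[sl] = templates["e"] * e_gain
                sw[sl] = templates["sw"] * sw_gain
            annual_lai = lai.reshape(ny, 12, -1).mean(axis=1, dtype=np.float64)
            global_lai = annual_lai @ wn.ravel()
            carbon = config.carbon_base + config.carbon_per_lai * (
                global_lai - global_lai[0]
            ) * (1.0 + 0.3 * np.tanh(carbon_noise[im]))
            warming = (
                config.warming_at_strength_1
                * strength
                * ramp
                * (1.0 + 0.2 * np.tanh(warm_noise[im]))
            )

            def _f(name, vals, units):
                return GridField(
                    geometry=geometry, time=time.copy(), values=vals, units=units,
                    name=name,
                )

            runs.append(
                ScenarioRun(
                    model=f"model{im:02d}",
                    scenario=scen,
                    lai=_f("lai", lai, "m2/m2"),
                    sc=_f("snow cover", sc, "%"),
                    sw=_f("shortwave", sw, "W/m2"),
                    e=_f("evaporation", e, "mm/day"),
                    carbon=carbon,
                    warming=warming,
                    baseline_year=int(years[0]),
                )
            )
    truth = ScenarioTruth(
        model=config.true_model, greening_pattern=pattern, model_factors=factors
    )
    return runs, truth


def ground_truth_delta_T(truth: ScenarioTruth, run: ScenarioRun, year: int) -> GridField:
    """Exact vegetation-driven temperature change implied by the stored true
    surfaces and the run's drivers, for one year relative to the run's
    baseline year (independent oracle for the projection path)."""
    geo = run.lai.geometry
    if truth.greening_pattern.shape != geo.shape:
        raise ValueError("truth and run geometries differ")
    model = truth.model
    out = np.empty((12, *geo.shape))
    for m in range(1, 13):
        sc = np.asarray(run.sc.sel(year, m), dtype=float)
        sw = np.asarray(run.sw.sel(year, m), dtype=float)
        e = np.asarray(run.e.sel(year, m), dtype=float)
        lai_t = np.asarray(run.lai.sel(year, m), dtype=float)
        lai_b = np.asarray(run.lai.sel(run.baseline_year, m), dtype=float)
        snow = sc >= model.snow_threshold
        s_snow = _eval_quadratic(model.snow_surface.coeffs, sc, sw)
        s_free = _eval_quadratic(model.snowfree_surface.coeffs, e, sw)
        with np.errstate(invalid="ignore", divide="ignore"):
            dln = np.log(lai_t) - np.log(lai_b)
        bad_free = (~snow) & ~((lai_t > 0) & (lai_b > 0))
        vals = np.where(snow, s_snow * (lai_t - lai_b), s_free * dln)
        out[m - 1] = np.where(bad_free, np.nan, vals)
    time = np.column_stack([np.full(12, year), np.arange(1, 13)])
    return GridField(geometry=geo, time=time, values=out, units="degC", name="true dT")


def latitudinal_zone_map(geometry: GridGeometry):
    """Simple latitude-band stand-in for the merged climate-zone raster:
    Equatorial <15, Arid 15-30, Temperate 30-50, Boreal 50-66, Polar >=66."""
    from .grid_core import ClimateZoneMap

    alat = np.abs(geometry.lat)
    codes_1d = np.select(
        [alat < 15.0, alat < 30.0, alat < 50.0, alat < 66.0],
        [1, 2, 3, 4],
        default=5,
    )
    zone = np.broadcast_to(codes_1d[:, None], geometry.shape).copy()
    return ClimateZoneMap(geometry=geometry, zone=zone)


def write_manifest(path, config, extra: dict | None = None) -> None:
    """Record the generating configuration + seed alongside any outputs."""
    d = {"config_class": type(config).__name__, "seed": config.seed}
    for k, v in vars(config).items():
        if k in ("geometry", "true_model"):
            continue
        if isinstance(v, tuple):
            v = list(v)
        d[k] = v
    d["geometry"] = {
        "lat_first": float(config.geometry.lat[0]),
        "lat_step": config.geometry.dlat(),
        "nlat": config.geometry.nlat,
        "lon_first": float(config.geometry.lon[0]),
        "lon_step": config.geometry.dlon(),
        "nlon": config.geometry.nlon,
    }
    if extra:
        d.update(extra)
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2, default=str)
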