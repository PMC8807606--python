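"""Space-for-time decomposition of the vegetation-driven temperature signal.

For every pair of years and every calendar month, the observed between-year
temperature change at a cell whose leaf area changed is split into a
large-scale climate component -- estimated by inverse-distance weighting of
the change observed at nearby stable-LAI reference cells -- and the residual
local component attributed to the LAI change. Per-record sensitivities are
then formed per regime, filtered, and aggregated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .grid_core import (
    AreaWeights,
    GridError,
    GridField,
    GridGeometry,
    great_circle_distance_km,
)

log = logging.getLogger(__name__)

DEFAULT_RADIUS_KM = 50.0
DEFAULT_STABILITY = 0.1  # m2/m2
DEFAULT_CHANGE = 0.1  # m2/m2, retention threshold on |dLAI|
DEFAULT_SNOW_THRESHOLD = 1.0  # % snow cover
DEFAULT_SD_FILTER = 0.2
DEFAULT_DLNLAI_FLOOR = 0.05


class DecompositionError(ValueError):
    pass


@dataclass(frozen=True)
class YearPair:
    y1: int
    y2: int
    month: int

    def __post_init__(self) -> None:
        if self.y2 <= self.y1:
            raise ValueError("year pairs are oriented y2 > y1")
        if not 1 <= self.month <= 12:
            raise ValueError("month must lie in 1..12")


def enumerate_year_pairs(years) -> list[tuple[int, int]]:
    """All unordered pairs of distinct years, oriented (earlier, later)."""
    ys = sorted(set(int(y) for y in years))
    if len(ys) < 2:
        raise ValueError("need at least 2 distinct years to form pairs")
    return [(ys[i], ys[j]) for i in range(len(ys)) for j in range(i + 1, len(ys))]


# ---------------------------------------------------------------------------
# neighbourhood machinery


class NeighborGraph:
    """Precomputed within-radius neighbour structure on a fixed geometry.

    Holds a sparse matrix of inverse great-circle distances between each
    cell (row) and its neighbours (columns), excluding the cell itself, so
    that per-pair IDW residuals reduce to two sparse matrix-vector products.
    """

    def __init__(self, geometry: GridGeometry, radius_km: float = DEFAULT_RADIUS_KM):
        if radius_km <= 0:
            raise ValueError("radius must be positive")
        self.geometry = geometry
        self.radius_km = float(radius_km)
        lat_f, lon_f = geometry.flat_coords()
        nlat, nlon = geometry.shape
        dlat = geometry.dlat()
        dlon = geometry.dlon()
        deg_km = 111.194926644559  # one degree of latitude on the 6371 km sphere
        max_dj_lat = int(np.floor(radius_km / (dlat * deg_km))) + 1
        rows, cols, invd = [], [], []
        cos_min = np.cos(np.deg2rad(np.minimum(np.abs(geometry.lat), 90.0)))
        for i in range(nlat):
            # candidate latitude rows within reach
            j_lo = max(0, i - max_dj_lat)
            j_hi = min(nlat - 1, i + max_dj_lat)
            for j in range(j_lo, j_hi + 1):
                # candidate longitude offsets within reach at the wider row
                c = max(min(cos_min[i], cos_min[j]), 1e-12)
                max_dk = int(np.floor(radius_km / (dlon * deg_km * c))) + 1
                max_dk = min(max_dk, nlon - 1)
                for dk in range(-max_dk, max_dk + 1):
                    if j == i and dk == 0:
                        continue
                    d = great_circle_distance_km(
                        geometry.lat[i], 0.0, geometry.lat[j], dk * dlon
                    )
                    if d <= radius_km and d > 0:
                        k = np.arange(nlon)
                        kk = k + dk
                        ok = (kk >= 0) & (kk < nlon)
                        r = i * nlon + k[ok]
                        cidx = j * nlon + kk[ok]
                        rows.append(r)
                        cols.append(cidx)
                        invd.append(np.full(r.size, 1.0 / d))
        if rows:
            rows = np.concatenate(rows)
            cols = np.concatenate(cols)
            invd = np.concatenate(invd)
        else:
            rows = np.empty(0, int)
            cols = np.empty(0, int)
            invd = np.empty(0, float)
        n = geometry.ncell
        self.inv_dist = sparse.csr_matrix((invd, (rows, cols)), shape=(n, n))
        self.adjacency = sparse.csr_matrix(
            (np.ones_like(invd), (rows, cols)), shape=(n, n)
        )
        self._lat_f = lat_f
        self._lon_f = lon_f

    def neighbor_count(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def idw_residual_field(
        self, delta: np.ndarray, stable: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """IDW estimate of ``delta`` at every cell from its stable
        neighbours; returns (residual, n_refs), NaN where no reference."""
        flat = np.asarray(delta, dtype=float).ravel()
        ok = np.asarray(stable, dtype=bool).ravel() & np.isfinite(flat)
        vals = np.where(ok, flat, 0.0)
        sel = ok.astype(float)
        num = self.inv_dist @ (vals * sel)
        den = self.inv_dist @ sel
        nref = (self.adjacency @ sel).astype(int)
        with np.errstate(invalid="ignore", divide="ignore"):
            res = np.where(den > 0, num / den, np.nan)
        return res.reshape(delta.shape), nref.reshape(delta.shape)


def find_reference_cells(
    dlai: np.ndarray,
    geometry: GridGeometry,
    target: tuple[int, int],
    radius_km: float = DEFAULT_RADIUS_KM,
    stability_threshold: float = DEFAULT_STABILITY,
) -> list[tuple[tuple[int, int], float]]:
    """Stable-LAI cells within ``radius_km`` of the target cell center.

    Returns (cell index, distance km) pairs; an empty list is a legal
    result -- the caller decides what to do with orphan targets.
    """
    dlai = np.asarray(dlai, dtype=float)
    if dlai.shape != geometry.shape:
        raise GridError("dLAI slice does not match geometry")
    ti, tj = target
    tlat, tlon = geometry.lat[ti], geometry.lon[tj]
    la, lo = geometry.mesh()
    dist = great_circle_distance_km(tlat, tlon, la, lo)
    ok = (
        (dist <= radius_km)
        & np.isfinite(dlai)
        & (np.abs(dlai) < stability_threshold)
    )
    ok[ti, tj] = False
    out = []
    for i, j in zip(*np.nonzero(ok)):
        out.append(((int(i), int(j)), float(dist[i, j])))
    out.sort(key=lambda item: item[1])
    return out


def idw_residual(ref_dT, distances) -> float:
    """Inverse-distance-weighted mean of reference temperature changes."""
    v = np.asarray(ref_dT, dtype=float)
    d = np.asarray(distances, dtype=float)
    if v.size == 0:
        raise DecompositionError("IDW needs at least one reference cell")
    if v.shape != d.shape:
        raise DecompositionError("values and distances differ in length")
    if np.any(d <= 0):
        raise DecompositionError("reference distance must be positive")
    w = 1.0 / d
    return float(np.sum(v * w) / np.sum(w))


def local_delta(dT: float, dT_res: float) -> float:
    """Vegetation-attributed temperature change: observed minus residual."""
    return dT - dT_res


def pair_driver_means(
    sc: GridField, sw: GridField, e: GridField, pair: YearPair
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-year mean of each driver for one (month, year-pair)."""
    out = []
    for f in (sc, sw, e):
        a = f.sel(pair.y1, pair.month)
        b = f.sel(pair.y2, pair.month)
        out.append(0.5 * (np.asarray(a, float) + np.asarray(b, float)))
    return tuple(out)


RECORD_COLUMNS = [
    "cell", "lat", "lon", "month", "y1", "y2", "dT", "dT_res", "dT_lai",
    "dLAI", "dlnLAI", "lai1", "lai2", "SC_mean", "SW_mean", "E_mean", "n_refs",
]


def decompose(
    obs: dict[str, GridField],
    radius_km: float = DEFAULT_RADIUS_KM,
    stability_threshold: float = DEFAULT_STABILITY,
    change_threshold: float = DEFAULT_CHANGE,
    graph: NeighborGraph | None = None,
) -> pd.DataFrame:
    """Run the full per-pair, per-month decomposition over an observation
    bundle ``{"lai", "t", "sc", "sw", "e"}``.

    Stability of a reference cell is assessed per year-pair on that month's
    dLAI field. Records are retained where |dLAI| > ``change_threshold`` and
    at least one reference cell exists.
    """
    for key in ("lai", "t", "sc", "sw", "e"):
        if key not in obs:
            raise DecompositionError(f"observation bundle lacks field {key!r}")
    lai, t = obs["lai"], obs["t"]
    geo = lai.geometry
    if graph is None:
        graph = NeighborGraph(geo, radius_km=radius_km)
    elif graph.geometry != geo:
        raise DecompositionError("neighbour graph geometry mismatch")
    years = lai.years()
    pairs = enumerate_year_pairs(years)
    lat_f, lon_f = geo.flat_coords()
    cells = np.arange(geo.ncell)

    chunks: list[dict[str, np.ndarray]] = []
    n_orphans = 0
    for month in range(1, 13):
        # index time steps once per month
        try:
            idx = {int(y): lai.time_index(int(y), month) for y in years}
        except KeyError:
            continue
        for y1, y2 in pairs:
            l1 = np.asarray(lai.values[idx[y1]], float)
            l2 = np.asarray(lai.values[idx[y2]], float)
            dlai = l2 - l1
            dT = np.asarray(t.values[idx[y2]], float) - np.asarray(
                t.values[idx[y1]], float
            )
            stable = np.isfinite(dlai) & (np.abs(dlai) < stability_threshold)
            res, nref = graph.idw_residual_field(dT, stable)
            target = (
                np.isfinite(dlai)
                & np.isfinite(dT)
                & (np.abs(dlai) > change_threshold)
            )
            n_orphans += int(np.count_nonzero(target & (nref < 1)))
            keep = target & (nref >= 1) & np.isfinite(res)
            if not np.any(keep):
                continue
            k = keep.ravel()
            sc_m = 0.5 * (
                np.asarray(obs["sc"].values[idx[y1]], float)
                + np.asarray(obs["sc"].values[idx[y2]], float)
            )
            sw_m = 0.5 * (
                np.asarray(obs["sw"].values[idx[y1]], float)
                + np.asarray(obs["sw"].values[idx[y2]], float)
            )
            e_m = 0.5 * (
                np.asarray(obs["e"].values[idx[y1]], float)
                + np.asarray(obs["e"].values[idx[y2]], float)
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                dln = np.where(
                    (l1 > 0) & (l2 > 0), np.log(l2) - np.log(l1), np.nan
                )
            dT_f = dT.ravel()[k]
            res_f = res.ravel()[k]
            chunks.append(
                {
                    "cell": cells[k],
                    "lat": lat_f[k],
                    "lon": lon_f[k],
                    "month": np.full(k.sum(), month, dtype=int),
                    "y1": np.full(k.sum(), y1, dtype=int),
                    "y2": np.full(k.sum(), y2, dtype=int),
                    "dT": dT_f,
                    "dT_res": res_f,
                    "dT_lai": dT_f - res_f,
                    "dLAI": dlai.ravel()[k],
                    "dlnLAI": dln.ravel()[k],
                    "lai1": l1.ravel()[k],
                    "lai2": l2.ravel()[k],
                    "SC_mean": sc_m.ravel()[k],
                    "SW_mean": sw_m.ravel()[k],
                    "E_mean": e_m.ravel()[k],
                    "n_refs": nref.ravel()[k],
                }
            )
    if n_orphans:
        log.info("decompose: %d target cell-pairs had no reference cell", n_orphans)
    if not chunks:
        return pd.DataFrame({c: [] for c in RECORD_COLUMNS})
    out = pd.DataFrame(
        {c: np.concatenate([ch[c] for ch in chunks]) for c in RECORD_COLUMNS}
    )
    return out


def build_sensitivity_samples(
    records: pd.DataFrame,
    snow_threshold: float = DEFAULT_SNOW_THRESHOLD,
    dlnlai_floor: float = DEFAULT_DLNLAI_FLOOR,
) -> pd.DataFrame:
    """Per-record sensitivity samples split by snow regime.

    Snow regime (SC_mean >= threshold): response = dT_lai / dLAI with
    predictors (SC_mean, SW_mean). Snow-free: response = dT_lai / dlnLAI
    with predictors (E_mean, SW_mean); records with nonpositive LAI or
    |dlnLAI| < ``dlnlai_floor`` are dropped.
    """
    snow = records["SC_mean"].to_numpy() >= snow_threshold
    dlai = records["dLAI"].to_numpy()
    dln = records["dlnLAI"].to_numpy()
    dT_lai = records["dT_lai"].to_numpy()
    keep_snow = snow & (dlai != 0)
    keep_free = (~snow) & np.isfinite(dln) & (np.abs(dln) >= dlnlai_floor)
    n_bad_lai = int(np.count_nonzero(~snow & ~np.isfinite(dln)))
    if n_bad_lai:
        log.info(
            "build_sensitivity_samples: %d snow-free records rejected "
            "(nonpositive LAI)", n_bad_lai,
        )
    keep = keep_snow | keep_free
    with np.errstate(invalid="ignore", divide="ignore"):
        response = np.where(snow, dT_lai / dlai, dT_lai / dln)
    x = np.where(snow, records["SC_mean"].to_numpy(), records["E_mean"].to_numpy())
    out = pd.DataFrame(
        {
            "cell": records["cell"].to_numpy()[keep],
            "lat": records["lat"].to_numpy()[keep],
            "lon": records["lon"].to_numpy()[keep],
            "month": records["month"].to_numpy()[keep],
            "y1": records["y1"].to_numpy()[keep],
            "y2": records["y2"].to_numpy()[keep],
            "regime": np.where(snow[keep], "snow", "snow_free"),
            "response": response[keep],
            "x": x[keep],
            "y": records["SW_mean"].to_numpy()[keep],
        }
    )
    bad = ~np.isfinite(out["response"].to_numpy())
    if bad.any():
        out = out.loc[~bad].reset_index(drop=True)
    return out


def stddev_filter(
    samples: pd.DataFrame, max_sd: float = DEFAULT_SD_FILTER
) -> pd.DataFrame:
    """Drop (cell, month) groups whose sample standard deviation of the
    response exceeds ``max_sd``, or which hold fewer than 2 samples."""
    if samples.empty:
        return samples.copy()
    grp = samples.groupby(["cell", "month"])["response"]
    sd = grp.transform("std", ddof=1)
    n = grp.transform("size")
    keep = (n >= 2) & (sd <= max_sd)
    n_small = int(((n < 2)).sum())
    n_noisy = int(((n >= 2) & (sd > max_sd)).sum())
    log.info(
        "stddev_filter: dropped %d samples in groups with <2 members, "
        "%d in groups with sd > %.3g", n_small, n_noisy, max_sd,
    )
    return samples.loc[keep.to_numpy()].reset_index(drop=True)


@dataclass(frozen=True)
class TransitionBinMatrix:
    """Area-weighted mean vegetation-attributed temperature change binned by
    the (earlier-year, later-year) LAI combination."""

    edges1: np.ndarray
    edges2: np.ndarray
    mean_dT_lai: np.ndarray
    total_area: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.mean_dT_lai.shape


def lai_transition_bins(
    records: pd.DataFrame,
    weights: AreaWeights,
    bin_percent: float = 1.0,
) -> TransitionBinMatrix:
    """Bin records on (LAI year1, LAI year2) axes with bins spanning
    ``bin_percent`` of the observed LAI range, area-weighting dT_lai."""
    if records.empty:
        raise DecompositionError("no records to bin")
    l1 = records["lai1"].to_numpy(float)
    l2 = records["lai2"].to_numpy(float)
    lo = float(min(l1.min(), l2.min()))
    hi = float(max(l1.max(), l2.max()))
    if hi <= lo:
        raise DecompositionError("degenerate LAI range: max == min")
    nbins = int(round(100.0 / bin_percent))
    edges = np.linspace(lo, hi, nbins + 1)
    i1 = np.clip(np.searchsorted(edges, l1, side="right") - 1, 0, nbins - 1)
    i2 = np.clip(np.searchsorted(edges, l2, side="right") - 1, 0, nbins - 1)
    cell = records["cell"].to_numpy(int)
    a = weights.w.ravel()[cell]
    val = records["dT_lai"].to_numpy(float)
    flat = i1 * nbins + i2
    num = np.bincount(flat, weights=a * val, minlength=nbins * nbins)
    den = np.bincount(flat, weights=a, minlength=nbins * nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(den > 0, num / den, np.nan)
    return TransitionBinMatrix(
        edges1=edges,
        edges2=edges.copy(),
        mean_dT_lai=mean.reshape(nbins, nbins),
        total_area=den.reshape(nbins, nbins),
    )


def mean_annual_sensitivity_map(
    samples: pd.DataFrame,
    lai_climatology: np.ndarray,
    geometry: GridGeometry,
    conversion: str = "finite",
) -> np.ndarray:
    """Per-cell mean annual sensitivity (degC per 1 m2/m2 LAI change).

    Snow-regime responses are already per m2/m2; snow-free (per-ln-LAI)
    responses are converted at the cell's monthly LAI climatology. Months
    are averaged with equal weight over months that carry samples.

    ``lai_climatology`` has shape (12, nlat, nlon), index 0 = January.
    """
    from .sensitivity import ln_conversion_factor

    lai_climatology = np.asarray(lai_climatology, dtype=float)
    if lai_climatology.shape != (12, *geometry.shape):
        raise GridError("LAI climatology must have shape (12, nlat, nlon)")
    out = np.full(geometry.shape, np.nan)
    if samples.empty:
        return out
    df = samples.copy()
    cell = df["cell"].to_numpy(int)
    month = df["month"].to_numpy(int)
    resp = df["response"].to_numpy(float).copy()
    free = (df["regime"] == "snow_free").to_numpy()
    factor = ln_conversion_factor(
        lai_climatology.reshape(12, -1)[month - 1, cell], conversion
    )
    resp[free] = resp[free] * factor[free]
    ok = np.isfinite(resp)
    df = pd.DataFrame({"cell": cell[ok], "month": month[ok], "v": resp[ok]})
    per_cm = df.groupby(["cell", "month"])["v"].mean()
    per_cell = per_cm.groupby(level="cell").mean()
    out.ravel()[per_cell.index.to_numpy(int)] = per_cell.to_numpy()
    return out


def zonal_sensitivity_quartiles(
    samples: pd.DataFrame,
    lai_climatology: np.ndarray,
    geometry: GridGeometry,
    conversion: str = "finite",
) -> pd.DataFrame:
    """Median and quartiles of the zonal-mean annual sensitivity across the
    year-pair ensemble (one zonal profile per pair, statistics over pairs)."""
    from .sensitivity import ln_conversion_factor

    if samples.empty:
        return pd.DataFrame(columns=["lat", "median", "q1", "q3"])
    df = samples.copy()
    cell = df["cell"].to_numpy(int)
    month = df["month"].to_numpy(int)
    resp = df["response"].to_numpy(float).copy()
    free = (df["regime"] == "snow_free").to_numpy()
    factor = ln_conversion_factor(
        np.asarray(lai_climatology).reshape(12, -1)[month - 1, cell], conversion
    )
    resp[free] = resp[free] * factor[free]
    df["v"] = resp
    df["row"] = cell // geometry.nlon
    df = df.loc[np.isfinite(resp)]
    zonal = (
        df.groupby(["y1", "y2", "row"])["v"].mean().reset_index()
    )
    stats = zonal.groupby("row")["v"].agg(
        median="median",
        q1=lambda s: s.quantile(0.25),
        q3=lambda s: s.quantile(0.75),
    )
    stats.insert(0, "lat", geometry.lat[stats.index.to_numpy(int)])
    return stats.reset_index(drop=True)
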