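"""Regime-specific bivariate quadratic sensitivity surfaces.

Two surfaces describe how near-surface air temperature responds to leaf-area
change as a function of background climate: a snow regime driven by snow
cover (%) and downwelling shortwave radiation (W/m2), responding per unit
LAI (m2/m2); and a snow-free regime driven by land evaporation (mm/day) and
shortwave radiation, responding per unit ln(LAI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import yaml

from .grid_core import AreaWeights, GridError, GridField

COEFF_NAMES = ("a_xx", "a_yy", "a_xy", "b_x", "b_y", "c")

SNOW = "snow"
SNOW_FREE = "snow_free"
PER_LAI = "per_lai"
PER_LN_LAI = "per_ln_lai"

#: plausibility envelopes used only for out-of-range warnings
PREDICTOR_RANGES = {
    "SC": (0.0, 100.0),
    "SW": (0.0, 450.0),
    "E": (0.0, 10.0),
}


class FitError(ValueError):
    """The quadratic design is unusable (too few samples or rank deficient)."""


@dataclass(frozen=True)
class QuadraticSurface:
    """Six-coefficient bivariate quadratic response surface.

    response = a_xx*x^2 + a_yy*y^2 + a_xy*x*y + b_x*x + b_y*y + c
    """

    coeffs: tuple[float, float, float, float, float, float]
    predictors: tuple[str, str]
    regime: str
    response_scale: str

    def __post_init__(self) -> None:
        if len(self.coeffs) != 6:
            raise ValueError("a quadratic surface has exactly 6 coefficients")
        object.__setattr__(self, "coeffs", tuple(float(v) for v in self.coeffs))
        if self.regime not in (SNOW, SNOW_FREE):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.response_scale not in (PER_LAI, PER_LN_LAI):
            raise ValueError(f"unknown response scale {self.response_scale!r}")

    def to_dict(self) -> dict:
        return {
            "coeffs": dict(zip(COEFF_NAMES, self.coeffs)),
            "predictors": list(self.predictors),
            "regime": self.regime,
            "response_scale": self.response_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticSurface":
        return cls(
            coeffs=tuple(d["coeffs"][k] for k in COEFF_NAMES),
            predictors=tuple(d["predictors"]),
            regime=d["regime"],
            response_scale=d["response_scale"],
        )


def eval_surface(surface: QuadraticSurface, x, y, warn_out_of_range: bool = True):
    """Evaluate a surface at predictor values (scalars or arrays).

    Values outside the physical plausibility envelope trigger a warning,
    never a failure.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if warn_out_of_range:
        for name, vals in zip(surface.predictors, (x, y)):
            lo, hi = PREDICTOR_RANGES.get(name, (-np.inf, np.inf))
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < lo or finite.max() > hi):
                warnings.warn(
                    f"predictor {name} outside plausible range [{lo}, {hi}]",
                    stacklevel=2,
                )
    a_xx, a_yy, a_xy, b_x, b_y, c = surface.coeffs
    out = a_xx * x * x + a_yy * y * y + a_xy * x * y + b_x * x + b_y * y + c
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class SensitivityModel:
    """The pair of regime surfaces plus the snow-cover threshold (%) that
    selects between them."""

    snow_surface: QuadraticSurface
    snowfree_surface: QuadraticSurface
    snow_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.snow_surface.regime != SNOW or self.snow_surface.response_scale != PER_LAI:
            raise ValueError("snow_surface must be regime=snow, per-LAI scale")
        if (
            self.snowfree_surface.regime != SNOW_FREE
            or self.snowfree_surface.response_scale != PER_LN_LAI
        ):
            raise ValueError("snowfree_surface must be regime=snow_free, per-ln-LAI scale")
        if self.snow_threshold <= 0:
            raise ValueError("snow threshold must be positive")

    def to_dict(self) -> dict:
        return {
            "snow_threshold_percent": self.snow_threshold,
            "snow_surface": self.snow_surface.to_dict(),
            "snowfree_surface": self.snowfree_surface.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensitivityModel":
        return cls(
            snow_surface=QuadraticSurface.from_dict(d["snow_surface"]),
            snowfree_surface=QuadraticSurface.from_dict(d["snowfree_surface"]),
            snow_threshold=float(d["snow_threshold_percent"]),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SensitivityModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def published_surfaces() -> SensitivityModel:
    """The reference coefficient sets fitted from 2003-2014 Earth
    observations (snow regime on snow cover + shortwave; snow-free regime on
    evaporation + shortwave, per unit ln LAI)."""
    snow = QuadraticSurface(
        coeffs=(-1.66e-5, -2.14e-7, 1.56e-5, 2.9e-3, -8.23e-4, -0.011),
        predictors=("SC", "SW"),
        regime=SNOW,
        response_scale=PER_LAI,
    )
    snowfree = QuadraticSurface(
        coeffs=(3.64e-3, 1.17e-5, -5.80e-5, 8.51e-2, -6.74e-3, 0.42),
        predictors=("E", "SW"),
        regime=SNOW_FREE,
        response_scale=PER_LN_LAI,
    )
    return SensitivityModel(snow_surface=snow, snowfree_surface=snowfree, snow_threshold=1.0)


@dataclass(frozen=True)
class FitDiagnostics:
    n: int
    residual_sd: float
    r_squared: float
    coeff_cov: np.ndarray


def _design(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.column_stack([x * x, y * y, x * y, x, y, np.ones_like(x)])


def fit_quadratic_surface(
    x,
    y,
    response,
    predictors: tuple[str, str],
    regime: str,
    response_scale: str,
    weights=None,
) -> tuple[QuadraticSurface, FitDiagnostics]:
    """Ordinary (optionally weighted) least squares on the quadratic design
    (x^2, y^2, xy, x, y, 1)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    z = np.asarray(response, dtype=float).ravel()
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    x, y, z = x[ok], y[ok], z[ok]
    if x.size < 6:
        raise FitError(f"need >= 6 samples to fit a quadratic surface, got {x.size}")
    X = _design(x, y)
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float).ravel()[ok])
        X = X * w[:, None]
        z = z * w
    rank = np.linalg.matrix_rank(X)
    if rank < 6:
        raise FitError(
            f"rank-deficient quadratic design (rank {rank} < 6): predictors are collinear"
        )
    beta, _, _, _ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ beta
    dof = max(x.size - 6, 1)
    sigma2 = float(resid @ resid) / dof
    ss_tot = float(np.sum((z - z.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    cov = sigma2 * np.linalg.inv(X.T @ X)
    surface = QuadraticSurface(
        coeffs=tuple(beta), predictors=predictors, regime=regime,
        response_scale=response_scale,
    )
    diag = FitDiagnostics(
        n=int(x.size), residual_sd=float(np.sqrt(sigma2)), r_squared=r2, coeff_cov=cov
    )
    return surface, diag


def fit_surfaces_per_zone(
    samples,
    zones,
    regime: str,
    predictors: tuple[str, str],
    response_scale: str,
) -> dict[str, tuple[QuadraticSurface, FitDiagnostics]]:
    """Optional per-climate-zone fits (the default remains one global fit
    per regime). ``samples`` is a sample table with cell/x/y/response
    columns; zones with fewer than 6 samples are skipped."""
    from .grid_core import VEGETATED_ZONES, ZONE_CODES

    zone_of_cell = zones.zone.ravel()
    out: dict[str, tuple[QuadraticSurface, FitDiagnostics]] = {}
    sub = samples[samples["regime"] == regime]
    codes = zone_of_cell[sub["cell"].to_numpy(int)]
    for code in VEGETATED_ZONES:
        part = sub[codes == code]
        if len(part) < 6:
            continue
        out[ZONE_CODES[code]] = fit_quadratic_surface(
            part["x"], part["y"], part["response"],
            predictors=predictors, regime=regime, response_scale=response_scale,
        )
    return out


def ln_conversion_factor(lai, mode: str = "finite"):
    """Factor turning a per-ln-LAI response into a per-1-m2/m2 response.

    ``finite``: ln(LAI+1) - ln(LAI), a literal unit-LAI step.
    ``infinitesimal``: 1/LAI, the derivative d(lnLAI)/dLAI.
    """
    lai = np.asarray(lai, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if mode == "finite":
            out = np.where(lai > 0, np.log(lai + 1.0) - np.log(lai), np.nan)
        elif mode == "infinitesimal":
            out = np.where(lai > 0, 1.0 / lai, np.nan)
        else:
            raise ValueError(f"unknown ln-conversion mode {mode!r}")
    if out.ndim == 0:
        return float(out)
    return out


def sensitivity_map(
    model: SensitivityModel,
    sc: GridField,
    sw: GridField,
    e: GridField,
    lai: GridField,
    conversion: str = "finite",
) -> np.ndarray:
    """Annual-mean sensitivity map (degC per m2/m2) from driver fields.

    Every cell-month is evaluated by exactly one surface: the snow surface
    where SC >= threshold, else the snow-free surface converted to a per-LAI
    scale at the cell's LAI. The annual map is the mean over time steps.
    Snow-free cells with nonpositive LAI come back missing.
    """
    for f in (sw, e, lai):
        if f.geometry != sc.geometry or f.nt != sc.nt:
            raise GridError("driver fields must be co-registered")
    monthly = np.full((sc.nt, *sc.geometry.shape), np.nan)
    for it in range(sc.nt):
        scv = np.asarray(sc.values[it], dtype=float)
        swv = np.asarray(sw.values[it], dtype=float)
        ev = np.asarray(e.values[it], dtype=float)
        lv = np.asarray(lai.values[it], dtype=float)
        snow = scv >= model.snow_threshold
        s_snow = eval_surface(model.snow_surface, scv, swv, warn_out_of_range=False)
        s_free = eval_surface(model.snowfree_surface, ev, swv, warn_out_of_range=False)
        s_free = s_free * ln_conversion_factor(lv, conversion)
        vals = np.where(snow, s_snow, s_free)
        vals = np.where(
            np.isfinite(scv) & np.isfinite(swv), vals, np.nan
        )
        monthly[it] = vals
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(monthly, axis=0)


def compare_maps(
    a: np.ndarray, b: np.ndarray, weights: AreaWeights
) -> tuple[float, float]:
    """Area-weighted Pearson correlation and RMSE over jointly valid cells."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != weights.geometry.shape or b.shape != weights.geometry.shape:
        raise GridError("maps and weights are not co-registered")
    ok = np.isfinite(a) & np.isfinite(b)
    if np.count_nonzero(ok) < 2:
        raise EmptyComparisonError("need >= 2 jointly valid cells")
    w = weights.w[ok]
    w = w / w.sum()
    av, bv = a[ok], b[ok]
    am = float(np.sum(w * av))
    bm = float(np.sum(w * bv))
    cov = float(np.sum(w * (av - am) * (bv - bm)))
    va = float(np.sum(w * (av - am) ** 2))
    vb = float(np.sum(w * (bv - bm) ** 2))
    if va <= 0 or vb <= 0:
        raise EmptyComparisonError("constant field: correlation undefined")
    r = cov / np.sqrt(va * vb)
    rmse = float(np.sqrt(np.sum(w * (av - bv) ** 2)))
    return float(r), rmse


class EmptyComparisonError(GridError):
    """Too few jointly valid cells (or zero variance) for a comparison."""
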