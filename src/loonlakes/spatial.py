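"""Great-circle geometry and semivariogram estimation.

Nearby lakes tend to share water chemistry, so a similarity-based habitat
preference test can be confounded by spatial autocorrelation.  This module
quantifies that structure: empirical (optionally directional)
semivariograms, weighted least-squares fits of exponential/spherical
variogram models, and the practical autocorrelation range that gates the
spatially constrained randomization test.

All distances are great-circle (haversine, Earth radius 6371 km) for
consistency across the package; pair bearings are folded modulo 180 degrees
because variograms are orientation-symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .lakes import Lake

EARTH_RADIUS_KM = 6371.0


def _check_coords(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any((lat < -90.0) | (lat > 90.0)):
        raise ValueError("latitude out of [-90, 90]")
    if np.any((lon < -180.0) | (lon > 180.0)):
        raise ValueError("longitude out of [-180, 180]")


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km; accepts scalars or numpy arrays."""
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    phi1, lam1, phi2, lam2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


def bearing_deg(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing, degrees clockwise from north in [0, 360).

    Raises on coincident scalar points (the bearing is undefined there).
    """
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    scalar = all(np.ndim(x) == 0 for x in (lat1, lon1, lat2, lon2))
    if scalar and lat1 == lat2 and lon1 == lon2:
        raise ValueError("bearing undefined for coincident points")
    phi1, lam1, phi2, lam2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlam = lam2 - lam1
    y = np.sin(dlam) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    theta = np.where(theta >= 360.0, 0.0, theta)  # guard fp fold of -0 epsilon
    return float(theta) if np.ndim(theta) == 0 else theta


@dataclass
class Variogram:
    """Binned semivariance vs lag distance.

    ``semivariances`` is NaN for empty bins (``pair_counts`` 0); lags are
    bin centres in km.  ``direction_deg``/``tolerance_deg`` record an
    optional directional filter (pair bearing folded mod 180).
    """

    trait: str
    lag_bin_centers: np.ndarray
    semivariances: np.ndarray
    pair_counts: np.ndarray
    bin_width_km: float
    max_lag_km: float
    direction_deg: Optional[float] = None
    tolerance_deg: float = 22.5

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "lag_bin_centers_km": [float(x) for x in self.lag_bin_centers],
            "semivariances": [None if not np.isfinite(g) else float(g)
                              for g in self.semivariances],
            "pair_counts": [int(c) for c in self.pair_counts],
            "bin_width_km": self.bin_width_km,
            "max_lag_km": self.max_lag_km,
            "direction_deg": self.direction_deg,
            "tolerance_deg": self.tolerance_deg,
        }


@dataclass
class VariogramModelFit:
    """Weighted least-squares fit of a variogram model.

    ``practical_range_km`` is the lag at which the model reaches ~95% of its
    sill: 3x the range parameter for the exponential model, the range
    parameter itself for the spherical.  ``no_structure`` flags fits where
    the partial sill is (numerically) zero — a flat variogram carries no
    usable autocorrelation range.
    """

    model: str
    nugget: float
    sill: float
    range_param: float
    practical_range_km: float
    fit_loss: float
    no_structure: bool = False

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "nugget": self.nugget,
            "sill": self.sill,
            "range_param_km": self.range_param,
            "practical_range_km": self.practical_range_km,
            "fit_loss": self.fit_loss,
            "no_structure": self.no_structure,
        }


def _pairwise_geometry(lakes: Sequence[Lake], trait: str):
    vals = [(lake.lat, lake.lon, lake.get_trait(trait)) for lake in lakes]
    vals = [(la, lo, z) for la, lo, z in vals if z is not None]
    if len(vals) < 2:
        raise ValueError(
            f"need >= 2 lakes with trait {trait!r} present, got {len(vals)}"
        )
    lat = np.array([v[0] for v in vals])
    lon = np.array([v[1] for v in vals])
    z = np.array([v[2] for v in vals], dtype=float)
    i, j = np.triu_indices(len(z), k=1)
    d = haversine_km(lat[i], lon[i], lat[j], lon[j])
    sqdiff = (z[i] - z[j]) ** 2
    # orientation-symmetric pair bearing; coincident pairs get bearing 0
    with np.errstate(invalid="ignore"):
        brg = np.where(
            d > 0,
            bearing_deg(lat[i], lon[i], lat[j], lon[j]),
            0.0,
        ) % 180.0
    return d, sqdiff, brg


def _direction_mask(bearings_mod180: np.ndarray, direction_deg: float,
                    tolerance_deg: float) -> np.ndarray:
    # half-open window [-tol, tol) so that default windows partition [0, 180)
    delta = (bearings_mod180 - direction_deg + 90.0) % 180.0 - 90.0
    return (delta >= -tolerance_deg) & (delta < tolerance_deg)


def empirical_semivariogram(
    lakes: Sequence[Lake],
    trait: str,
    bin_width_km: float = 2.0,
    max_lag_km: Optional[float] = None,
    direction_deg: Optional[float] = None,
    tolerance_deg: float = 22.5,
) -> Variogram:
    """Method-of-moments semivariogram: per lag bin,
    gamma(h) = (1 / 2 N_h) * sum (z_i - z_j)^2 over pairs in the bin.

    ``max_lag_km`` defaults to half the maximum pairwise distance.  With
    ``direction_deg`` only pairs whose folded bearing lies within
    +-``tolerance_deg`` of the direction contribute.
    """
    if bin_width_km <= 0:
        raise ValueError("bin_width_km must be > 0")
    d, sqdiff, brg = _pairwise_geometry(lakes, trait)
    if max_lag_km is None:
        max_lag_km = float(d.max()) / 2.0
        if max_lag_km <= 0:  # all lakes coincident
            max_lag_km = bin_width_km
    mask = d < max_lag_km
    if direction_deg is not None:
        mask &= _direction_mask(brg, direction_deg % 180.0, tolerance_deg)
    d, sqdiff = d[mask], sqdiff[mask]
    n_bins = int(np.ceil(max_lag_km / bin_width_km))
    idx = np.minimum((d / bin_width_km).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=sqdiff, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / (2.0 * np.maximum(counts, 1)), np.nan)
    centers = (np.arange(n_bins) + 0.5) * bin_width_km
    return Variogram(
        trait=trait,
        lag_bin_centers=centers,
        semivariances=gamma,
        pair_counts=counts,
        bin_width_km=bin_width_km,
        max_lag_km=float(max_lag_km),
        direction_deg=direction_deg,
        tolerance_deg=tolerance_deg,
    )


def _model_gamma(model: str, h: np.ndarray, nugget: float, psill: float,
                 a: float) -> np.ndarray:
    if model == "exponential":
        return nugget + psill * (1.0 - np.exp(-h / a))
    if model == "spherical":
        r = np.minimum(h / a, 1.0)
        return nugget + psill * (1.5 * r - 0.5 * r ** 3)
    raise ValueError(f"unknown variogram model {model!r}")


def fit_variogram_model(v: Variogram, model: str = "exponential") -> VariogramModelFit:
    """Fit nugget/sill/range by least squares weighted by pair counts.

    Multi-start over the range parameter guards against local minima.  A
    variogram that is flat at zero (constant trait) is returned as a
    degenerate sill-equals-nugget fit flagged ``no_structure``.
    """
    ok = (v.pair_counts > 0) & np.isfinite(v.semivariances)
    h = np.asarray(v.lag_bin_centers, dtype=float)[ok]
    g = np.asarray(v.semivariances, dtype=float)[ok]
    w = np.sqrt(np.asarray(v.pair_counts, dtype=float)[ok])
    if len(h) < 4:
        raise ValueError(f"need >= 4 non-empty bins to fit, got {len(h)}")
    if np.allclose(g, 0.0):
        return VariogramModelFit(model, 0.0, 0.0, float("nan"), float("nan"),
                                 0.0, no_structure=True)

    gmax = float(g.max())
    nugget0 = max(float(g[0]), 1e-12 * gmax)
    psill0 = max(gmax - nugget0, 1e-6 * gmax)
    hmax = float(h.max())

    def resid(p):
        nug, psill, a = p
        return w * (_model_gamma(model, h, nug, psill, a) - g)

    best = None
    for a0 in (hmax / 10.0, hmax / 3.0, hmax):
        res = least_squares(
            resid,
            x0=[nugget0, psill0, a0],
            bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, 100.0 * hmax]),
            method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        if best is None or res.cost < best.cost:
            best = res
    nugget, psill, a = (float(x) for x in best.x)
    sill = nugget + psill
    practical = 3.0 * a if model == "exponential" else a
    no_structure = psill <= max(1e-12, 1e-6 * sill)
    if no_structure:
        practical = float("nan")
    return VariogramModelFit(
        model=model, nugget=nugget, sill=sill, range_param=a,
        practical_range_km=practical, fit_loss=float(2.0 * best.cost),
        no_structure=no_structure,
    )


@dataclass
class AnisotropyScan:
    """Directional variograms per bearing plus the direction of maximal
    fitted sill (``None`` when no direction could be fitted)."""

    variograms: dict[float, Variogram]
    fits: dict[float, Optional[VariogramModelFit]]
    max_sill_direction_deg: Optional[float] = None


def anisotropy_scan(
    lakes: Sequence[Lake],
    trait: str,
    directions: Sequence[float] = (0.0, 45.0, 90.0, 135.0),
    bin_width_km: float = 2.0,
    max_lag_km: Optional[float] = None,
    tolerance_deg: float = 22.5,
    model: str = "exponential",
) -> AnisotropyScan:
    """Directional variograms along each bearing (+- tolerance window).

    With the default four bearings and 22.5 degree tolerance the windows
    partition the pair set.  Directions whose variogram has too few
    non-empty bins to fit get a ``None`` fit.
    """
    variograms: dict[float, Variogram] = {}
    fits: dict[float, Optional[VariogramModelFit]] = {}
    for direction in directions:
        vg = empirical_semivariogram(
            lakes, trait, bin_width_km=bin_width_km, max_lag_km=max_lag_km,
            direction_deg=float(direction), tolerance_deg=tolerance_deg,
        )
        variograms[float(direction)] = vg
        try:
            fits[float(direction)] = fit_variogram_model(vg, model=model)
        except ValueError:
            fits[float(direction)] = None
    best_dir = None
    best_sill = -np.inf
    for direction, fit in fits.items():
        if fit is not None and not fit.no_structure and fit.sill > best_sill:
            best_sill = fit.sill
            best_dir = direction
    return AnisotropyScan(variograms=variograms, fits=fits,
                          max_sill_direction_deg=best_dir)
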