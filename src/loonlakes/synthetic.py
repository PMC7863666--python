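"""Synthetic lake landscapes and juvenile visit simulation.

The generator emulates a northern-Wisconsin-style study region: ~120 glacial
lakes scattered over a ~60 x 60 km extent, with pH spatially autocorrelated
(practical range ~20 km) and optionally carrying a SW-NE linear gradient,
while the other basic traits (area, depth, shape, clarity) are spatially
unstructured.  Juvenile lake choice is a softmax over candidate lakes within
a travel radius, with tunable attraction to natal-like pH, to large lakes,
and to trophically complex lakes — the knobs the inference modules are
exercised against.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from datetime import date as Date, timedelta
from typing import Optional, Sequence

import numpy as np

from .lakes import (
    COMPLEX_CODES,
    LAKE_TROPHIC_CODES,
    Lake,
    VisitRecord,
    compute_shape_index,
)

#: Reference origin of the local tangent plane (study-region latitude band);
#: km offsets are converted to lat/lon about this point so that haversine
#: distances agree with planar km coordinates to well under 1%.
REF_LAT = 45.7
REF_LON = -89.5
_KM_PER_DEG_LAT = math.pi / 180.0 * 6371.0  # ~111.19 km


def km_to_latlon(x_km, y_km):
    """Convert east/north km offsets (tangent plane) to WGS84 degrees."""
    lat = REF_LAT + np.asarray(y_km, dtype=float) / _KM_PER_DEG_LAT
    lon = REF_LON + np.asarray(x_km, dtype=float) / (
        _KM_PER_DEG_LAT * math.cos(math.radians(REF_LAT))
    )
    return lat, lon


#: Printed study-region trait ranges used as generator defaults.
DEFAULT_TRAIT_BOUNDS: dict[str, tuple[float, float]] = {
    "ph": (4.7, 9.4),
    "area_ha": (8.0, 1400.0),
    "max_depth": (3.0, 117.0),
    "shape_index": (0.35, 3.9),
    "secchi": (0.75, 6.9),
}

#: Default class mix over the nine natural-lake trophic codes.
DEFAULT_TROPHIC_MIX: dict[str, float] = {
    "CCC": 0.18, "CCD": 0.12, "CWC": 0.10, "CWD": 0.08,
    "SCC": 0.14, "SCD": 0.12, "SWC": 0.08, "SWD": 0.10, "TS": 0.08,
}


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic lake landscape.

    pH variance components (``ph_sill``, ``ph_nugget``) are specified on the
    latent field; the field is affinely rescaled into ``trait_bounds['ph']``,
    so they act as relative (structured : unstructured) controls while the
    realized spread follows from the bounds.  ``ph_range_km`` is the
    practical range (95% of sill) of the exponential covariance.
    ``anisotropy_gradient`` adds a linear trend (latent units per km) along
    ``anisotropy_direction_deg`` (bearing clockwise from north; 45 = SW-NE).
    """

    n_lakes: int = 120
    extent_km: float = 60.0
    ph_field: str = "autocorrelated"  # or "iid"
    ph_range_km: float = 20.0
    ph_sill: float = 1.0
    ph_nugget: float = 0.05
    anisotropy_direction_deg: float = 45.0
    anisotropy_gradient: float = 0.03
    trait_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_BOUNDS))
    trophic_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TROPHIC_MIX))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lakes < 2:
            raise ValueError("n_lakes must be >= 2")
        if self.extent_km <= 0:
            raise ValueError("extent_km must be > 0")
        if self.ph_field not in ("autocorrelated", "iid"):
            raise ValueError("ph_field must be 'autocorrelated' or 'iid'")
        if self.ph_range_km <= 0 or self.ph_sill < 0 or self.ph_nugget < 0:
            raise ValueError("invalid pH field variance/range parameters")
        for trait, (lo, hi) in self.trait_bounds.items():
            if not lo < hi:
                raise ValueError(f"trait_bounds[{trait!r}]: min must be < max")
        total = sum(self.trophic_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"trophic_mix proportions sum to {total}, not 1")
        for code in self.trophic_mix:
            if code not in LAKE_TROPHIC_CODES:
                raise ValueError(f"trophic_mix: unknown lake code {code!r}")


def _rescale_to_bounds(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    xmin, xmax = float(x.min()), float(x.max())
    if xmax == xmin:
        return np.full_like(x, 0.5 * (lo + hi))
    return lo + (x - xmin) * (hi - lo) / (xmax - xmin)


def _simulate_ph_field(xy: np.ndarray, config: LandscapeConfig,
                       rng: np.random.Generator) -> np.ndarray:
    n = len(xy)
    if config.ph_field == "iid":
        z = rng.normal(0.0, math.sqrt(config.ph_sill + config.ph_nugget), size=n)
    else:
        # exponential covariance with range parameter a = practical_range / 3
        d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
        cov = config.ph_sill * np.exp(-3.0 * d / config.ph_range_km)
        cov[np.diag_indices(n)] += config.ph_nugget + 1e-10
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(
                "pH covariance matrix could not be factorized; "
                "increase ph_nugget"
            ) from exc
        z = chol @ rng.standard_normal(n)
    if config.anisotropy_gradient:
        theta = math.radians(config.anisotropy_direction_deg)
        axis = np.array([math.sin(theta), math.cos(theta)])  # (east, north)
        proj = (xy - xy.mean(axis=0)) @ axis
        z = z + config.anisotropy_gradient * proj
    return z


def _assign_trophic_classes(areas: np.ndarray, mix: dict[str, float],
                            rng: np.random.Generator) -> list[str]:
    """Draw class counts from the mix, assigning Complex classes
    preferentially to large lakes (area-weighted sampling without
    replacement), mimicking the empirical size-complexity association."""
    n = len(areas)
    codes = list(mix.keys())
    counts = rng.multinomial(n, [mix[c] for c in codes])
    assigned = [""] * n
    available = np.arange(n)
    order = sorted(range(len(codes)),
                   key=lambda k: codes[k] not in COMPLEX_CODES)  # Complex first
    for k in order:
        cnt = int(counts[k])
        if cnt == 0 or len(available) == 0:
            continue
        cnt = min(cnt, len(available))
        if codes[k] in COMPLEX_CODES:
            w = areas[available]
        else:
            w = np.ones(len(available))
        w = w / w.sum()
        chosen = rng.choice(len(available), size=cnt, replace=False, p=w)
        for idx in available[chosen]:
            assigned[idx] = codes[k]
        available = np.delete(available, chosen)
    return assigned


def generate_landscape(config: LandscapeConfig) -> list[Lake]:
    """Generate a reproducible synthetic lake landscape.

    Coordinates are uniform over the square extent; pH comes from a Gaussian
    random field with exponential covariance (or iid noise), optionally plus
    a linear gradient, rescaled into the pH bounds; area and depth are
    log-uniform, clarity and shape uniform, within their bounds; trophic
    classes follow the configured mix with Complex classes skewed toward
    large lakes.  Suitability is area >= 10 ha (all generated classes are
    natural lakes).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_lakes
    xy = rng.uniform(0.0, config.extent_km, size=(n, 2))
    ph_latent = _simulate_ph_field(xy, config, rng)
    ph = _rescale_to_bounds(ph_latent, *config.trait_bounds["ph"])

    lo, hi = config.trait_bounds["area_ha"]
    area = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    lo, hi = config.trait_bounds["max_depth"]
    depth = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    secchi = rng.uniform(*config.trait_bounds["secchi"], size=n)
    shape = rng.uniform(*config.trait_bounds["shape_index"], size=n)
    perimeter = shape * np.sqrt(area)

    codes = _assign_trophic_classes(area, config.trophic_mix, rng)
    lat, lon = km_to_latlon(xy[:, 0], xy[:, 1])

    lakes = []
    for i in range(n):
        lakes.append(Lake(
            lake_id=f"L{i:03d}",
            name=f"Lake {i:03d}",
            lat=float(lat[i]),
            lon=float(lon[i]),
            area_ha=float(area[i]),
            perimeter_km=float(perimeter[i]),
            shape_index=float(compute_shape_index(float(perimeter[i]),
                                                  float(area[i]))),
            max_depth=float(depth[i]),
            secchi=float(secchi[i]),
            ph=float(ph[i]),
            trophic_class=codes[i],
            loon_suitable=bool(area[i] >= 10.0),
        ))
    return lakes


@dataclass
class PreferenceModel:
    """Destination-choice model for simulated juveniles.

    Each visit's destination is drawn from suitable non-natal lakes within
    ``max_travel_km`` of the natal lake with probability proportional to
    ``exp(-w_ph * |pH_natal - pH_dest| + w_size * log(area_dest)
    + w_complex * 1[dest is Complex])``.  All-zero weights give uniform
    choice.  Weights are simulation knobs, not biological estimates.
    """

    w_ph: float = 0.0
    w_size: float = 0.0
    w_complex: float = 0.0
    max_travel_km: float = 30.0
    n_juveniles: int = 43
    visits_per_juvenile: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_travel_km <= 0:
            raise ValueError("max_travel_km must be > 0")
        for w in (self.w_ph, self.w_size, self.w_complex):
            if not math.isfinite(w):
                raise ValueError("preference weights must be finite")
        if self.n_juveniles < 1 or self.visits_per_juvenile < 1:
            raise ValueError("need at least one juvenile and one visit each")


def simulate_visits(lakes: Sequence[Lake], pref: PreferenceModel) -> list[VisitRecord]:
    """Simulate juvenile lake visits under the preference model.

    Natal lakes are sampled uniformly (with replacement) among suitable
    lakes; juveniles whose natal lake has no suitable neighbour within the
    travel radius are skipped with a warning.  Dates fall in the
    September-October fledging window.  Reproducible from ``pref.seed``.
    """
    rng = np.random.default_rng(pref.seed)
    suitable = [lake for lake in lakes if lake.loon_suitable]
    if len(suitable) < 2:
        raise ValueError("need >= 2 suitable lakes to simulate visits")
    for lake in suitable:
        if lake.ph is None or lake.area_ha is None:
            raise ValueError(f"lake {lake.lake_id}: pH and area required")

    lat = np.array([lake.lat for lake in suitable])
    lon = np.array([lake.lon for lake in suitable])
    ph = np.array([lake.ph for lake in suitable])
    log_area = np.log(np.array([lake.area_ha for lake in suitable]))
    is_complex = np.array(
        [lake.trophic_class in COMPLEX_CODES for lake in suitable], dtype=float)

    from .spatial import haversine_km  # local import avoids cycle at module load

    visits: list[VisitRecord] = []
    season_start = Date(2014, 9, 1)
    for j in range(pref.n_juveniles):
        natal_idx = int(rng.integers(len(suitable)))
        natal = suitable[natal_idx]
        d = haversine_km(natal.lat, natal.lon, lat, lon)
        pool = np.flatnonzero((d <= pref.max_travel_km)
                              & (np.arange(len(suitable)) != natal_idx))
        if len(pool) == 0:
            warnings.warn(
                f"juvenile J{j:03d}: natal lake {natal.lake_id} has no suitable "
                f"lake within {pref.max_travel_km} km; skipped",
                stacklevel=2,
            )
            continue
        utility = (-pref.w_ph * np.abs(ph[pool] - natal.ph)
                   + pref.w_size * log_area[pool]
                   + pref.w_complex * is_complex[pool])
        utility -= utility.max()
        p = np.exp(utility)
        p /= p.sum()
        for _ in range(pref.visits_per_juvenile):
            dest_idx = int(pool[rng.choice(len(pool), p=p)])
            day = int(rng.integers(0, 61))  # Sep 1 .. Oct 31
            visits.append(VisitRecord(
                juvenile_id=f"J{j:03d}",
                natal_lake_id=natal.lake_id,
                destination_lake_id=suitable[dest_idx].lake_id,
                date=season_start + timedelta(days=day),
            ))
    return visits
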