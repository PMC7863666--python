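"""Trophic-class selection: goodness-of-fit against windowed availability.

Are some lake classes visited out of proportion to their availability?  The
expected distribution is the class composition of suitable lakes lying
within a radius (default 40 km) of at least one natal lake — availability
as the juveniles experience it, not the whole map.  Observed destination
class counts are then compared with a chi-square goodness-of-fit test,
overall and separately per natal class; the per-natal-class results also
report the "own class" observed vs expected proportion, the descriptive
reading of natal-class fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import chi2

from .lakes import (
    DEFAULT_EXCLUDED_CLASSES,
    Lake,
    VisitRecord,
    filter_loon_suitable,
    lakes_by_id,
)
from .spatial import haversine_km


@dataclass
class ClassGofResult:
    """Chi-square goodness-of-fit of visit counts vs expected proportions."""

    grouping: str  # "all" or a natal class code
    observed_counts: dict[str, int]
    expected_proportions: dict[str, float]
    chi_square: float
    df: int
    p_value: float
    low_expected_warning: bool = False
    own_class_observed_prop: Optional[float] = None
    own_class_expected_prop: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "grouping": self.grouping,
            "observed_counts": dict(self.observed_counts),
            "expected_proportions": dict(self.expected_proportions),
            "chi_square": self.chi_square,
            "df": self.df,
            "p_value": self.p_value,
            "low_expected_warning": self.low_expected_warning,
            "own_class_observed_prop": self.own_class_observed_prop,
            "own_class_expected_prop": self.own_class_expected_prop,
        }


def expected_class_distribution(
    natal_lakes: Sequence[Lake],
    all_lakes: Sequence[Lake],
    radius_km: float = 40.0,
    min_area_ha: float = 10.0,
    excluded_classes: frozenset[str] | set[str] = DEFAULT_EXCLUDED_CLASSES,
    window: str = "union",
) -> dict[str, float]:
    """Expected trophic-class proportions from windowed availability.

    Candidates are suitable lakes (area and class filters applied) with a
    known class lying within ``radius_km`` of at least one natal lake
    (``window="union"``; ``"intersection"`` requires being within range of
    every natal lake, usually empty and kept only for completeness).
    """
    if not natal_lakes:
        raise ValueError("natal_lakes must be non-empty")
    if window not in ("union", "intersection"):
        raise ValueError("window must be 'union' or 'intersection'")
    candidates = [
        lake for lake in filter_loon_suitable(
            all_lakes, min_area_ha=min_area_ha, excluded_classes=excluded_classes)
        if lake.trophic_class is not None
    ]
    nlat = np.array([l.lat for l in natal_lakes])
    nlon = np.array([l.lon for l in natal_lakes])
    counts: dict[str, int] = {}
    total = 0
    for lake in candidates:
        d = haversine_km(lake.lat, lake.lon, nlat, nlon)
        d = np.atleast_1d(d)
        inside = bool(np.any(d <= radius_km)) if window == "union" \
            else bool(np.all(d <= radius_km))
        if inside:
            counts[lake.trophic_class] = counts.get(lake.trophic_class, 0) + 1
            total += 1
    if total == 0:
        raise ValueError(
            f"no suitable candidate lakes within {radius_km} km of the natal lakes"
        )
    return {code: n / total for code, n in sorted(counts.items())}


def gof_test(
    observed_counts: Mapping[str, int],
    expected_proportions: Mapping[str, float],
    grouping: str = "all",
) -> ClassGofResult:
    """Chi-square goodness of fit of observed class counts.

    The statistic is the direct summation ``sum (O_k - n p_k)^2 / (n p_k)``
    over classes with positive expected proportion; df is that class count
    minus one; the p-value is the upper tail of the chi-square law.  An
    observation in a class with zero expected proportion is an error (the
    availability model cannot explain it); any expected count below 5 sets
    the small-sample warning flag.
    """
    psum = float(sum(expected_proportions.values()))
    if abs(psum - 1.0) > 1e-9:
        raise ValueError(f"expected proportions sum to {psum}, not 1")
    n = int(sum(observed_counts.values()))
    if n <= 0:
        raise ValueError("total observed count must be > 0")
    for code, obs in observed_counts.items():
        if obs > 0 and expected_proportions.get(code, 0.0) <= 0.0:
            raise ValueError(
                f"observed count in class {code!r} with zero expected proportion"
            )
    classes = [c for c, p in expected_proportions.items() if p > 0.0]
    chi_sq = 0.0
    low_expected = False
    for code in classes:
        expected = n * expected_proportions[code]
        obs = observed_counts.get(code, 0)
        chi_sq += (obs - expected) ** 2 / expected
        if expected < 5.0:
            low_expected = True
    df = len(classes) - 1
    p_value = float(chi2.sf(chi_sq, df)) if df > 0 else 1.0
    return ClassGofResult(
        grouping=grouping,
        observed_counts={c: int(observed_counts.get(c, 0)) for c in classes},
        expected_proportions={c: float(expected_proportions[c]) for c in classes},
        chi_square=float(chi_sq),
        df=df,
        p_value=p_value,
        low_expected_warning=low_expected,
    )


def destination_class_counts(
    visits: Sequence[VisitRecord], lakes: Sequence[Lake]
) -> dict[str, int]:
    """Visit counts by destination trophic class."""
    by_id = lakes_by_id(lakes)
    counts: dict[str, int] = {}
    for v in visits:
        code = by_id[v.destination_lake_id].trophic_class
        if code is None:
            raise ValueError(
                f"destination lake {v.destination_lake_id} has no trophic class"
            )
        counts[code] = counts.get(code, 0) + 1
    return counts


def per_natal_class_tests(
    visits: Sequence[VisitRecord],
    lakes: Sequence[Lake],
    expected_proportions: Mapping[str, float],
) -> tuple[dict[str, ClassGofResult], list[str]]:
    """Goodness-of-fit test per natal class.

    Visits are grouped by natal-lake class; each group's destination-class
    counts are tested against the shared expected distribution.  Groups
    with no visits are omitted with a note.  Each result carries the
    own-class observed and expected proportions (does a juvenile from class
    X visit class X more than availability predicts?).
    """
    by_id = lakes_by_id(lakes)
    groups: dict[str, list[VisitRecord]] = {}
    for v in visits:
        code = by_id[v.natal_lake_id].trophic_class
        if code is None:
            raise ValueError(f"natal lake {v.natal_lake_id} has no trophic class")
        groups.setdefault(code, []).append(v)

    results: dict[str, ClassGofResult] = {}
    notes: list[str] = []
    for code in sorted(set(expected_proportions) | set(groups)):
        group = groups.get(code, [])
        if not group:
            notes.append(f"natal class {code}: no visits, omitted")
            continue
        counts = destination_class_counts(group, lakes)
        res = gof_test(counts, expected_proportions, grouping=code)
        n = sum(counts.values())
        res.own_class_observed_prop = counts.get(code, 0) / n
        res.own_class_expected_prop = float(expected_proportions.get(code, 0.0))
        results[code] = res
    return results, notes
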