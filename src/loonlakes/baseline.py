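"""Auxiliary statistics: Welch t comparisons and travel summaries.

Complements the randomization tests with (a) lake-level Welch two-sample
t tests comparing the natal lake set against the destination lake set per
trait, at a Bonferroni-adjusted alpha, and (b) per-visit travel distance
and bearing summaries for polar/frequency plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lakes import BASIC_TRAITS, Lake, VisitRecord, lakes_by_id
from .spatial import bearing_deg, haversine_km


@dataclass
class WelchResult:
    """Unequal-variance two-sample t test (Welch-Satterthwaite df)."""

    mean_a: float
    mean_b: float
    t_statistic: float
    df: float
    p_value: float
    significant_at: Optional[float] = None
    significant: Optional[bool] = None


def welch_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> WelchResult:
    """Welch two-sample t test, two-sided.

    Requires at least two values per sample and positive variance in at
    least one of them.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise ValueError("both samples have zero variance; t is undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
    )


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-test alpha under Bonferroni correction: family_alpha / m."""
    if not 0.0 < family_alpha < 1.0:
        raise ValueError("family_alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return family_alpha / m


def natal_destination_welch_table(
    visits: Sequence[VisitRecord],
    lakes: Sequence[Lake],
    traits: Sequence[str] = BASIC_TRAITS,
    alpha_family: float = 0.05,
) -> pd.DataFrame:
    """Trait-by-trait Welch comparison of natal vs destination lake sets.

    Lake-level: each lake enters its set once however many visits reference
    it.  Returns a tidy table (trait, natal mean, destination mean, df, t,
    p, significance at the Bonferroni-adjusted alpha).
    """
    by_id = lakes_by_id(lakes)
    natal_ids = sorted({v.natal_lake_id for v in visits})
    dest_ids = sorted({v.destination_lake_id for v in visits})
    alpha = bonferroni_alpha(alpha_family, len(traits))
    rows = []
    for trait in traits:
        a = [by_id[i].get_trait(trait) for i in natal_ids]
        b = [by_id[i].get_trait(trait) for i in dest_ids]
        a = [x for x in a if x is not None]
        b = [x for x in b if x is not None]
        res = welch_t_test(a, b)
        rows.append({
            "trait": trait,
            "natal_mean": res.mean_a,
            "destination_mean": res.mean_b,
            "df": res.df,
            "t": res.t_statistic,
            "p_value": res.p_value,
            "alpha": alpha,
            "significant": res.p_value <= alpha,
        })
    return pd.DataFrame(rows)


@dataclass
class TravelSummary:
    """Per-visit travel distances/bearings plus summary statistics."""

    distances_km: np.ndarray
    bearings_deg: np.ndarray
    mean_km: float
    max_km: float
    bearing_bin_deg: float
    bearing_bin_edges: np.ndarray
    bearing_counts: np.ndarray

    def to_dict(self) -> dict:
        return {
            "n_visits": int(len(self.distances_km)),
            "mean_km": self.mean_km,
            "max_km": self.max_km,
            "distances_km": [float(d) for d in self.distances_km],
            "bearings_deg": [float(b) for b in self.bearings_deg],
            "bearing_bin_deg": self.bearing_bin_deg,
            "bearing_bin_edges": [float(e) for e in self.bearing_bin_edges],
            "bearing_counts": [int(c) for c in self.bearing_counts],
        }


def travel_summary(
    visits: Sequence[VisitRecord],
    lakes: Sequence[Lake],
    bearing_bin_deg: float = 30.0,
) -> TravelSummary:
    """Haversine distance and initial bearing of every natal-to-destination
    movement, with mean/max and a bearing histogram for polar plots."""
    if not visits:
        raise ValueError("empty visit set")
    if not (0.0 < bearing_bin_deg <= 360.0) or 360.0 % bearing_bin_deg != 0:
        raise ValueError("bearing_bin_deg must divide 360")
    by_id = lakes_by_id(lakes)
    distances = []
    bearings = []
    for v in visits:
        a, b = by_id[v.natal_lake_id], by_id[v.destination_lake_id]
        distances.append(haversine_km(a.lat, a.lon, b.lat, b.lon))
        bearings.append(bearing_deg(a.lat, a.lon, b.lat, b.lon))
    distances = np.asarray(distances)
    bearings = np.asarray(bearings)
    edges = np.arange(0.0, 360.0 + bearing_bin_deg, bearing_bin_deg)
    counts, _ = np.histogram(bearings, bins=edges)
    return TravelSummary(
        distances_km=distances,
        bearings_deg=bearings,
        mean_km=float(distances.mean()),
        max_km=float(distances.max()),
        bearing_bin_deg=float(bearing_bin_deg),
        bearing_bin_edges=edges,
        bearing_counts=counts,
    )
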