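"""Monte Carlo randomization tests of natal-destination trait similarity.

The question: do juveniles visit lakes more similar to their natal lake in
a given trait than random lake choice from the study area would predict?
The observed statistic is the mean absolute natal-destination trait
difference over all visit records (repeat visits count once per record).
The null distribution is built by replacing every visit's destination with
a uniform draw, with replacement, from that visit's candidate pool —
suitable lakes excluding the natal lake — and recomputing the mean, 10,000
times by default.  The p-value is lower-tail (similarity means smaller
differences than the null) with an add-one correction so finite resampling
never yields p = 0.

Spatial autocorrelation confounds the unconstrained test: nearby lakes are
alike, and juveniles do not travel far.  Two conservative variants guard
against it: ``pool_radius_km`` restricts each null pool to lakes within a
radius of the natal lake (the autocorrelation threshold), and
``subset_radius_km`` instead restricts the observations to visits shorter
than the radius.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .lakes import Lake, VisitRecord, lakes_by_id
from .spatial import haversine_km


@dataclass
class TraitDifferenceResult:
    """Outcome of one randomization test for one trait."""

    trait: str
    n_obs: int
    observed_mean_abs_diff: float
    null_mean: float
    null_q025: float
    null_q975: float
    n_iterations: int
    p_value: float
    pool_radius_km: Optional[float] = None
    subset_radius_km: Optional[float] = None
    seed: Optional[int] = None
    alpha: Optional[float] = None
    significant: Optional[bool] = None
    null_means: Optional[np.ndarray] = None  # full null distribution

    def to_dict(self, include_null_histogram: bool = True) -> dict:
        out = {
            "trait": self.trait,
            "n_obs": self.n_obs,
            "observed_mean_abs_diff": self.observed_mean_abs_diff,
            "null_mean": self.null_mean,
            "null_q025": self.null_q025,
            "null_q975": self.null_q975,
            "n_iterations": self.n_iterations,
            "p_value": self.p_value,
            "pool_radius_km": self.pool_radius_km,
            "subset_radius_km": self.subset_radius_km,
            "seed": self.seed,
            "alpha": self.alpha,
            "significant": self.significant,
        }
        if include_null_histogram and self.null_means is not None:
            counts, edges = np.histogram(self.null_means, bins=50)
            out["null_histogram"] = {
                "bin_edges": [float(e) for e in edges],
                "counts": [int(c) for c in counts],
            }
        return out


def observed_mean_difference(
    visits: Sequence[VisitRecord], lakes: Sequence[Lake], trait: str
) -> float:
    """Mean absolute natal-destination trait difference over all records.

    Every visit record counts once, including repeat visits by the same
    individual to the same lake.
    """
    if len(visits) == 0:
        raise ValueError("empty visit set")
    by_id = lakes_by_id(lakes)
    diffs = []
    for v in visits:
        zn = by_id[v.natal_lake_id].get_trait(trait)
        zd = by_id[v.destination_lake_id].get_trait(trait)
        if zn is None or zd is None:
            raise ValueError(
                f"trait {trait!r} missing on lake pair "
                f"({v.natal_lake_id}, {v.destination_lake_id})"
            )
        diffs.append(abs(zn - zd))
    return float(np.mean(diffs))


def build_resampling_pool(
    natal: Lake,
    lakes: Sequence[Lake],
    radius_km: Optional[float] = None,
) -> list[Lake]:
    """Candidate destination lakes for the null: suitable lakes excluding
    the natal lake, optionally restricted to within ``radius_km`` of it.
    The actual destination lake stays eligible — a random chooser could
    pick it."""
    pool = [
        lake for lake in lakes
        if lake.loon_suitable and lake.lake_id != natal.lake_id
    ]
    if radius_km is not None:
        pool = [
            lake for lake in pool
            if haversine_km(natal.lat, natal.lon, lake.lat, lake.lon) <= radius_km
        ]
    if not pool:
        where = f" within {radius_km} km" if radius_km is not None else ""
        raise ValueError(
            f"empty resampling pool for natal lake {natal.lake_id}{where}"
        )
    return pool


def randomization_test(
    visits: Sequence[VisitRecord],
    lakes: Sequence[Lake],
    trait: str,
    n_iterations: int = 10_000,
    pool_radius_km: Optional[float] = None,
    subset_radius_km: Optional[float] = None,
    seed: Optional[int] = None,
) -> TraitDifferenceResult:
    """Monte Carlo randomization test for one trait.

    Each iteration redraws every visit's destination uniformly, with
    replacement, from that visit's natal pool and records the mean absolute
    difference; ``p = (#{null <= observed} + 1) / (n_iterations + 1)``
    (lower tail).  The 2.5/97.5% empirical quantiles of the null are
    reported for interval plots.  Deterministic given ``seed``.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    by_id = lakes_by_id(lakes)
    if subset_radius_km is not None:
        kept = []
        for v in visits:
            a, b = by_id[v.natal_lake_id], by_id[v.destination_lake_id]
            if haversine_km(a.lat, a.lon, b.lat, b.lon) <= subset_radius_km:
                kept.append(v)
        visits = kept
    if len(visits) == 0:
        raise ValueError("no visits left to test (after optional subsetting)")

    observed = observed_mean_difference(visits, lakes, trait)

    rng = np.random.default_rng(seed)
    # per-visit arrays of |z_pool - z_natal|; pools shared across visits
    # from the same natal lake (cached by natal id + radius)
    pool_diffs_cache: dict[str, np.ndarray] = {}
    null_sum = np.zeros(n_iterations)
    for v in visits:
        natal = by_id[v.natal_lake_id]
        diffs = pool_diffs_cache.get(natal.lake_id)
        if diffs is None:
            pool = build_resampling_pool(natal, lakes, radius_km=pool_radius_km)
            zs = [lake.get_trait(trait) for lake in pool]
            if any(z is None for z in zs) or natal.get_trait(trait) is None:
                raise ValueError(
                    f"trait {trait!r} missing in pool of natal lake {natal.lake_id}"
                )
            diffs = np.abs(np.asarray(zs, dtype=float) - natal.get_trait(trait))
            pool_diffs_cache[natal.lake_id] = diffs
        idx = rng.integers(0, len(diffs), size=n_iterations)
        null_sum += diffs[idx]
    null_means = null_sum / len(visits)

    p_value = (int(np.count_nonzero(null_means <= observed)) + 1) / (n_iterations + 1)
    q025, q975 = np.quantile(null_means, [0.025, 0.975])
    return TraitDifferenceResult(
        trait=trait,
        n_obs=len(visits),
        observed_mean_abs_diff=observed,
        null_mean=float(null_means.mean()),
        null_q025=float(q025),
        null_q975=float(q975),
        n_iterations=n_iterations,
        p_value=float(p_value),
        pool_radius_km=pool_radius_km,
        subset_radius_km=subset_radius_km,
        seed=seed,
        null_means=null_means,
    )


DEFAULT_TRAITS: tuple[str, ...] = ("area_ha", "max_depth", "shape_index",
                                   "secchi", "ph")


def run_all_traits(
    visits: Sequence[VisitRecord],
    lakes: Sequence[Lake],
    traits: Sequence[str] = DEFAULT_TRAITS,
    alpha_family: float = 0.05,
    n_iterations: int = 10_000,
    pool_radius_km: Optional[float] = None,
    subset_radius_km: Optional[float] = None,
    seed: Optional[int] = 0,
) -> list[TraitDifferenceResult]:
    """One randomization test per trait with Bonferroni-adjusted decisions.

    Each trait gets an independent sub-seed derived from ``seed``; the
    per-test alpha is ``alpha_family / len(traits)`` and each result's
    ``significant`` flag is set at that level.
    """
    if not traits:
        raise ValueError("need at least one trait")
    alpha = alpha_family / len(traits)
    sub_seeds = np.random.SeedSequence(seed).generate_state(len(traits)) % (2 ** 31)
    results = []
    for trait, s in zip(traits, sub_seeds):
        res = randomization_test(
            visits, lakes, trait,
            n_iterations=n_iterations,
            pool_radius_km=pool_radius_km,
            subset_radius_km=subset_radius_km,
            seed=int(s),
        )
        res.alpha = alpha
        res.significant = res.p_value <= alpha
        results.append(res)
    return results
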