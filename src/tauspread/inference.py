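"""Bootstrap inference and seed-specificity null models.

Model fits and beta weights carry mouse-level sampling uncertainty, so
distributions are built by resampling mice with replacement within each
genotype x treatment group and recomputing the statistic on the resampled
regional means.  Two bootstrap distributions are compared with a two-tailed
non-parametric sign test on their difference; p-value vectors from such
panels are adjusted with Benjamini-Hochberg FDR.

Seed specificity is assessed against a spatially matched null: many random
region sets of the same cardinality as the experimental seed, whose mean
pairwise centroid distance matches the experimental set's within a
tolerance, are each used to re-fit the diffusion model, and the experimental
fit is located within that null distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .atlas import Connectome, RegionAtlas
from .diffusion import DEFAULT_T_MONTHS, Propagator, SeedSpec, fit_rate
from .errors import UnfittableError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapDistribution:
    statistic_name: str
    values: np.ndarray
    B: int
    rng_seed: int
    group: str
    n_failed: int = 0

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (self.B,):
            raise ValidationError(
                f"distribution holds {vals.shape} values, expected B={self.B}"
            )


@dataclass(frozen=True)
class NullSeedEnsemble:
    true_fit: float
    null_fits: np.ndarray
    sets: list[tuple[str, ...]]
    n_sets: int
    matching_tolerance: float
    percentile_of_true: float
    true_c: float = float("nan")

    def __post_init__(self):
        nf = np.asarray(self.null_fits, dtype=float)
        object.__setattr__(self, "null_fits", nf)
        if nf.shape != (self.n_sets,):
            raise ValidationError("null_fits length != n_sets")
        if not (0.0 <= self.percentile_of_true <= 1.0):
            raise ValidationError("percentile outside [0, 1]")


def bootstrap_statistics(
    cohort: pd.DataFrame,
    group: tuple[str, str],
    stat_fn: Callable[[pd.DataFrame], Mapping[str, float]],
    B: int = 1000,
    rng_seed: int = 0,
) -> dict[str, BootstrapDistribution]:
    """Bootstrap one or more cohort-level statistics on shared mouse resamples.

    Mice of the requested genotype x treatment group are drawn with
    replacement (ids disambiguated so per-mouse rows stay unique) and
    ``stat_fn`` recomputes its statistics on each resampled cohort, returning
    a name -> value mapping.  Resamples where ``stat_fn`` raises are excluded
    and logged, never imputed.  Bit-for-bit reproducible under a fixed
    ``rng_seed``.
    """
    genotype, treatment = group
    sub = cohort.loc[
        (cohort["genotype"] == genotype) & (cohort["treatment"] == treatment)
    ]
    mice = sorted(sub["mouse_id"].unique())
    if len(mice) < 3:
        raise ValidationError(f"group {group} has {len(mice)} mice (need >= 3)")
    by_mouse = {m: df for m, df in sub.groupby("mouse_id", observed=True)}
    rng = np.random.default_rng(rng_seed)
    records: list[Mapping[str, float]] = []
    n_failed = 0
    while len(records) < B:
        draw = rng.choice(mice, size=len(mice), replace=True)
        parts = []
        for k, m in enumerate(draw):
            part = by_mouse[m].copy()
            part["mouse_id"] = f"{m}#{k}"
            parts.append(part)
        resampled = pd.concat(parts, ignore_index=True)
        try:
            records.append(dict(stat_fn(resampled)))
        except (UnfittableError, ValidationError) as exc:
            n_failed += 1
            if n_failed > 50 * B:
                raise UnfittableError(
                    f"bootstrap: statistic failed on {n_failed} resamples"
                ) from exc
            continue
    if n_failed:
        logger.info("bootstrap(%s-%s): %d failed resample(s) excluded",
                    genotype, treatment, n_failed)
    names = records[0].keys()
    return {
        name: BootstrapDistribution(
            statistic_name=name,
            values=np.array([rec[name] for rec in records], dtype=float),
            B=B,
            rng_seed=rng_seed,
            group=f"{genotype}-{treatment}",
            n_failed=n_failed,
        )
        for name in names
    }


def bootstrap_statistic(
    cohort: pd.DataFrame,
    group: tuple[str, str],
    stat_fn: Callable[[pd.DataFrame], float],
    B: int = 1000,
    rng_seed: int = 0,
    statistic_name: str = "statistic",
) -> BootstrapDistribution:
    """Bootstrap a single scalar statistic (see :func:`bootstrap_statistics`)."""
    dists = bootstrap_statistics(
        cohort, group, lambda df: {statistic_name: float(stat_fn(df))},
        B=B, rng_seed=rng_seed,
    )
    return dists[statistic_name]


def compare_distributions(
    d1: BootstrapDistribution | np.ndarray,
    d2: BootstrapDistribution | np.ndarray,
    pairing: str = "matched",
) -> float:
    """Two-tailed non-parametric comparison of two bootstrap distributions.

    Forms differences Delta between draws of d1 and d2 (index-matched by
    default, or all pairs) and returns

        p = 2 * min( P̂(Delta <= 0), P̂(Delta >= 0) ),   capped at 1,

    with a +1/(n+1) continuity correction so complete separation yields the
    minimum attainable p of 2/(n+1) rather than 0.  Symmetric in its
    arguments.
    """
    v1 = d1.values if isinstance(d1, BootstrapDistribution) else np.asarray(d1, float)
    v2 = d2.values if isinstance(d2, BootstrapDistribution) else np.asarray(d2, float)
    if v1.size == 0 or v2.size == 0:
        raise ValidationError("empty distribution")
    if pairing == "matched":
        if v1.size != v2.size:
            raise ValidationError("matched pairing needs equal-size distributions")
        delta = v1 - v2
    elif pairing == "all_pairs":
        delta = (v1[:, None] - v2[None, :]).ravel()
    else:
        raise ValidationError(f"unknown pairing {pairing!r}")
    n = delta.size
    p_low = (np.count_nonzero(delta <= 0) + 1) / (n + 1)
    p_high = (np.count_nonzero(delta >= 0) + 1) / (n + 1)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def fdr_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _mean_pairwise(cents: np.ndarray) -> float:
    if cents.shape[0] < 2:
        return 0.0
    return float(pdist(cents).mean())


def _max_pairwise(cents: np.ndarray) -> float:
    if cents.shape[0] < 2:
        return 0.0
    return float(pdist(cents).max())

_MATCH_STATS = {"mean_pairwise": _mean_pairwise, "max_pairwise": _max_pairwise}


def sample_matched_seed_sets(
    atlas: RegionAtlas,
    regions: Sequence[str],
    reference_sites: Sequence[str],
    n_sets: int,
    tolerance: float = 0.2,
    rng: np.random.Generator | int = 0,
    *,
    match_stat: str = "mean_pairwise",
    max_proposals: int = 10 ** 6,
    exclude: Sequence[Sequence[str]] = (),
) -> list[tuple[str, ...]]:
    """Draw distinct random region sets spatially matched to a reference set.

    Sets have the same cardinality as ``reference_sites`` and a matching
    statistic (mean pairwise centroid distance by default) within
    ``+-tolerance`` (relative) of the reference's.  Rejection sampling
    without replacement (vectorised in chunks), hard-capped at
    ``max_proposals`` proposals; raises reporting the achievable count if the
    pool is exhausted.
    """
    if match_stat not in _MATCH_STATS:
        raise ValidationError(f"unknown match_stat {match_stat!r}")
    regions = list(regions)
    k = len(reference_sites)
    n_regions = len(regions)
    if k < 1 or k > n_regions:
        raise ValidationError("reference seed size incompatible with region list")
    cents = atlas.centroids(regions)
    ref_stat = _MATCH_STATS[match_stat](atlas.centroids(list(reference_sites)))
    lo, hi = ref_stat * (1.0 - tolerance), ref_stat * (1.0 + tolerance)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    forbidden = {frozenset(reference_sites)} | {frozenset(s) for s in exclude}
    seen: set[frozenset] = set()
    out: list[tuple[str, ...]] = []
    proposals = 0
    iu, ju = np.triu_indices(k, 1)
    chunk = 1024
    while len(out) < n_sets:
        if proposals >= max_proposals:
            raise UnfittableError(
                f"matched-seed pool exhausted: {len(out)} of {n_sets} sets "
                f"found in {proposals} proposals (tolerance {tolerance})"
            )
        m = int(min(chunk, max_proposals - proposals))
        # m uniform k-subsets via random-key sort
        keys = rng.random((m, n_regions))
        if k < n_regions:
            idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        else:
            idx = np.tile(np.arange(n_regions), (m, 1))
        proposals += m
        if k >= 2:
            pts = cents[idx]                                    # (m, k, 3)
            d = np.linalg.norm(pts[:, iu, :] - pts[:, ju, :], axis=2)
            s = d.mean(axis=1) if match_stat == "mean_pairwise" else d.max(axis=1)
        else:
            s = np.zeros(m)
        for row in idx[(s >= lo) & (s <= hi)]:
            key = frozenset(regions[i] for i in row)
            if key in seen or key in forbidden:
                continue
            seen.add(key)
            out.append(tuple(sorted(key)))
            if len(out) == n_sets:
                break
    return out


def random_seed_null(
    atlas: RegionAtlas,
    conn: Connectome,
    observed: np.ndarray,
    true_seed: SeedSpec,
    n_sets: int = 500,
    tolerance: float = 0.2,
    rng_seed: int = 0,
    *,
    t: float = DEFAULT_T_MONTHS,
    match_stat: str = "mean_pairwise",
    max_proposals: int = 10 ** 6,
    propagator: Propagator | None = None,
    **fit_kwargs,
) -> NullSeedEnsemble:
    """Seed-specificity null: re-fit the model from spatially matched random seeds.

    Draws ``n_sets`` distinct random seed sets matched to the experimental
    seed's spatial clustering, fits the diffusion rate for each, and reports
    the fraction of null fits strictly below the experimental fit.  Null sets
    never include the experimental set itself; sets whose fit is unfittable
    are replaced (logged).
    """
    prop = propagator if propagator is not None else Propagator(conn, t)
    true_fit = fit_rate(conn, true_seed, observed, t, propagator=prop, **fit_kwargs)
    rng = np.random.default_rng(rng_seed)
    null_fits: list[float] = []
    kept_sets: list[tuple[str, ...]] = []
    n_failed = 0
    while len(null_fits) < n_sets:
        batch = sample_matched_seed_sets(
            atlas, conn.regions, true_seed.sites,
            n_sets - len(null_fits), tolerance, rng,
            match_stat=match_stat, max_proposals=max_proposals,
            exclude=kept_sets,
        )
        for sites in batch:
            seed = SeedSpec(sites=sites, amount=true_seed.amount)
            try:
                fit = fit_rate(conn, seed, observed, t, propagator=prop, **fit_kwargs)
            except UnfittableError:
                n_failed += 1
                if n_failed > 10 * n_sets:
                    raise
                continue
            null_fits.append(fit.fit_r)
            kept_sets.append(sites)
    if n_failed:
        logger.info("random_seed_null: %d unfittable set(s) replaced", n_failed)
    null_arr = np.array(null_fits)
    percentile = float(np.mean(null_arr < true_fit.fit_r))
    return NullSeedEnsemble(
        true_fit=true_fit.fit_r,
        null_fits=null_arr,
        sets=kept_sets,
        n_sets=n_sets,
        matching_tolerance=tolerance,
        percentile_of_true=percentile,
        true_c=true_fit.c_hat,
    )
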