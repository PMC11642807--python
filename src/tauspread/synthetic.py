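"""Synthetic atlas, connectome and cohort generation with known ground truth.

The generator emulates the statistical structure the analysis assumes so
every pipeline stage can be exercised with a known answer:

* a geometry-embedded directed connectome: region centroids uniform in a 3-D
  box, edge probability decaying with distance, log-normal weight
  magnitudes, and a tunable asymmetry blending a shared symmetric component
  with independent directed draws;
* a toy two-level region hierarchy (parents of ~5 leaves under one root) so
  hierarchical count aggregation is testable;
* regional pathology generated by a known mixture of anterograde, retrograde
  and Euclidean diffusion from a known seed set, with multiplicative
  log-normal per-mouse noise (pathology densities are positive and
  right-skewed);
* tdT+ densities generated as a cause-agnostic correlate whose partial
  association with pathology (given the spread predictors) is the configured
  group-specific slope;
* per-mouse behavioural covariates (NOR % novel time, per-minute Racine
  scores) with a configurable correlation to the pathology of target regions.

Defaults: N = 100 regions, 10 mice per genotype x treatment group (within
the 6-15 observed range), log-normal noise sigma = 0.25, horizon t = 3
months.  Every fixture is a pure function of (parameters, rng_seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import (Connectome, RegionAtlas, build_euclidean_connectome,
                    directional_view)
from .diffusion import (DEFAULT_SEED_ACRONYMS, DEFAULT_T_MONTHS, SeedSpec,
                        predict_spread)
from .errors import ValidationError
from .regression import log10_eps, zscore

GROUPS = (("WT", "Sal"), ("WT", "PTZ"), ("5X", "Sal"), ("5X", "PTZ"))


@dataclass(frozen=True)
class GroupBetas:
    """Generative weights for one genotype x treatment group.

    ``a, r, e`` weight the z-scored log anterograde / retrograde / Euclidean
    predictions; ``t`` is the group's tdT slope on the same scale (the
    PTZ - Sal difference within a genotype is the generative
    tdT x treatment interaction).
    """

    a: float
    r: float
    e: float
    t: float = 0.0

    def __post_init__(self):
        for v in (self.a, self.r, self.e, self.t):
            if not np.isfinite(v):
                raise ValidationError("betas must be finite")


#: defaults mirror the qualitative findings the pipeline is meant to detect:
#: retrograde-dominant spread everywhere, an increased anterograde
#: contribution in the amyloid (5X) genotype, and tdT predictive of
#: pathology in every group except PTZ-treated WT.
DEFAULT_BETAS: dict[tuple[str, str], GroupBetas] = {
    ("WT", "Sal"): GroupBetas(a=0.20, r=0.60, e=0.20, t=0.30),
    ("WT", "PTZ"): GroupBetas(a=0.20, r=0.55, e=0.20, t=0.00),
    ("5X", "Sal"): GroupBetas(a=0.45, r=0.45, e=0.10, t=0.35),
    ("5X", "PTZ"): GroupBetas(a=0.45, r=0.40, e=0.15, t=0.35),
}

DEFAULT_C_TRUE = {"anterograde": 0.6, "retrograde": 0.8, "euclidean": 0.3}


@dataclass(frozen=True)
class GroundTruth:
    """Fully serialisable generative configuration for one synthetic study."""

    atlas: RegionAtlas
    connectomes: dict[str, Connectome]
    seed: SeedSpec
    c_true: dict[str, float]
    betas: dict[tuple[str, str], GroupBetas]
    noise_sigma: float = 0.25
    tdt_noise_sigma: float = 0.25
    base_log10: float = 1.5
    tdt_base_log10: float = 1.5
    t: float = DEFAULT_T_MONTHS
    rng_seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0 or self.tdt_noise_sigma < 0:
            raise ValidationError("noise sigmas must be >= 0")
        missing = set(DEFAULT_C_TRUE) - set(self.c_true)
        if missing:
            raise ValidationError(f"c_true missing modes: {sorted(missing)}")

    @property
    def regions(self) -> tuple[str, ...]:
        return self.connectomes["anterograde"].regions

    def predictions(self) -> dict[str, np.ndarray]:
        """Noise-free spread prediction per mode at the true rates."""
        return {
            mode: predict_spread(self.connectomes[mode], self.seed,
                                 self.c_true[mode], self.t).values
            for mode in ("anterograde", "retrograde", "euclidean")
        }

    def manifest(self) -> dict:
        return {
            "seed_sites": list(self.seed.sites),
            "seed_amount": self.seed.amount,
            "c_true": dict(self.c_true),
            "betas": {f"{g}-{tr}": vars(b) for (g, tr), b in self.betas.items()},
            "noise_sigma": self.noise_sigma,
            "tdt_noise_sigma": self.tdt_noise_sigma,
            "base_log10": self.base_log10,
            "tdt_base_log10": self.tdt_base_log10,
            "t": self.t,
            "rng_seed": self.rng_seed,
        }


def generate_atlas_connectome(
    n_regions: int = 100,
    spatial_extent: float = 8000.0,
    density: float = 0.3,
    asymmetry: float = 0.6,
    rng_seed: int = 0,
    *,
    leaves_per_parent: int = 5,
    weight_sigma: float = 1.0,
) -> tuple[RegionAtlas, Connectome]:
    """Random geometry-embedded directed connectome plus a toy hierarchy.

    Centroids are uniform in a ``spatial_extent``-micrometre box.  A directed
    edge i -> j exists with probability ``density ** (1 + d_ij / (extent/2))``
    (so ``density = 1`` yields a complete graph and smaller densities decay
    with distance) and carries a log-normal weight.  ``asymmetry`` in [0, 1]
    blends a shared symmetric edge process (0 = exactly symmetric matrix)
    with fully independent directed draws (1).  The first four leaf regions
    are labelled DG, CA1, CA3 and PTLp; the hippocampal three are placed
    close together so the default seed set is spatially clustered, as the
    injection sites are.  Leaves are grouped under parents of
    ``leaves_per_parent`` below a single root for aggregation tests.
    """
    if n_regions < 10:
        raise ValidationError("n_regions must be >= 10")
    if not (0.0 < density <= 1.0):
        raise ValidationError("density must be in (0, 1]")
    if not (0.0 <= asymmetry <= 1.0):
        raise ValidationError("asymmetry must be in [0, 1]")
    if spatial_extent <= 0:
        raise ValidationError("spatial_extent must be positive")

    rng = np.random.default_rng(rng_seed)
    cents = rng.uniform(0.0, spatial_extent, size=(n_regions, 3))
    # cluster the hippocampal seed triplet (leaves 0..2) around leaf 0
    for k in (1, 2):
        cents[k] = cents[0] + rng.normal(0.0, 0.03 * spatial_extent, size=3)
    cents = np.clip(cents, 0.0, spatial_extent)

    from scipy.spatial.distance import cdist
    D = cdist(cents, cents)
    lam = spatial_extent / 2.0
    prob = density ** (1.0 + D / lam)

    present_dir = rng.random((n_regions, n_regions)) < prob
    w_dir = rng.lognormal(mean=0.0, sigma=weight_sigma, size=(n_regions, n_regions))
    present_sym = rng.random((n_regions, n_regions)) < prob
    present_sym = np.triu(present_sym, 1)
    present_sym = present_sym | present_sym.T
    w_sym = rng.lognormal(mean=0.0, sigma=weight_sigma, size=(n_regions, n_regions))
    w_sym = np.triu(w_sym, 1)
    w_sym = w_sym + w_sym.T

    A = (1.0 - asymmetry) * (present_sym * w_sym) \
        + asymmetry * (present_dir * w_dir)
    np.fill_diagonal(A, 0.0)
    # normalise to unit maximum out-degree so rates of order 0.1-1 per month
    # produce partial (informative) spread over a months-long horizon
    top = A.sum(axis=1).max()
    if top > 0:
        A = A / top

    leaf_ids = [f"R{i:03d}" for i in range(n_regions)]
    acronyms = list(DEFAULT_SEED_ACRONYMS) + leaf_ids[len(DEFAULT_SEED_ACRONYMS):]
    hemis = ["ipsi" if i < n_regions // 2 else "contra" for i in range(n_regions)]

    rows = [{"region_id": "root", "acronym": "root", "name": "root",
             "hemisphere": "ipsi", "parent_id": None,
             "x": float(cents[:, 0].mean()), "y": float(cents[:, 1].mean()),
             "z": float(cents[:, 2].mean())}]
    n_parents = int(np.ceil(n_regions / leaves_per_parent))
    for p in range(n_parents):
        kids = range(p * leaves_per_parent, min((p + 1) * leaves_per_parent, n_regions))
        kc = cents[list(kids)].mean(axis=0)
        rows.append({"region_id": f"P{p:02d}", "acronym": f"P{p:02d}",
                     "name": f"parent {p}", "hemisphere": "ipsi",
                     "parent_id": "root",
                     "x": float(kc[0]), "y": float(kc[1]), "z": float(kc[2])})
    for i in range(n_regions):
        rows.append({"region_id": leaf_ids[i], "acronym": acronyms[i],
                     "name": acronyms[i], "hemisphere": hemis[i],
                     "parent_id": f"P{i // leaves_per_parent:02d}",
                     "x": float(cents[i, 0]), "y": float(cents[i, 1]),
                     "z": float(cents[i, 2])})
    atlas = RegionAtlas.from_frame(pd.DataFrame(rows))
    conn = Connectome(regions=tuple(leaf_ids), A=A, mode="anterograde")
    return atlas, conn


def make_ground_truth(
    n_regions: int = 100,
    *,
    spatial_extent: float = 8000.0,
    density: float = 0.3,
    asymmetry: float = 0.6,
    betas: Mapping[tuple[str, str], GroupBetas] | None = None,
    c_true: Mapping[str, float] | None = None,
    noise_sigma: float = 0.25,
    tdt_noise_sigma: float = 0.25,
    t: float = DEFAULT_T_MONTHS,
    rng_seed: int = 0,
    seed_acronyms: Sequence[str] = DEFAULT_SEED_ACRONYMS,
) -> GroundTruth:
    """Assemble a complete generative configuration from defaults."""
    atlas, conn_a = generate_atlas_connectome(
        n_regions, spatial_extent, density, asymmetry, rng_seed
    )
    conn_r = directional_view(conn_a, "retrograde")
    conn_e = build_euclidean_connectome(atlas, conn_a.regions)
    sites = atlas.resolve_acronyms(seed_acronyms, within=conn_a.regions)
    return GroundTruth(
        atlas=atlas,
        connectomes={"anterograde": conn_a, "retrograde": conn_r,
                     "euclidean": conn_e},
        seed=SeedSpec(sites=tuple(sites)),
        c_true=dict(c_true or DEFAULT_C_TRUE),
        betas=dict(betas or DEFAULT_BETAS),
        noise_sigma=noise_sigma,
        tdt_noise_sigma=tdt_noise_sigma,
        t=t,
        rng_seed=rng_seed,
    )


def _log_stats(pred: np.ndarray) -> tuple[np.ndarray, float, float]:
    """z-scored log prediction plus the (mean, sd) used to invert it.

    eps is omitted when the prediction is strictly positive so the noiseless
    single-mode cohort reproduces the prediction exactly.
    """
    eps = 0.0 if pred.min() > 0 else None
    lp = log10_eps(pred, eps) if eps is None else np.log10(pred)
    mu, sd = float(lp.mean()), float(lp.std(ddof=0))
    if sd == 0:
        raise ValidationError("degenerate (constant) spread prediction")
    return (lp - mu) / sd, mu, sd


def simulate_cohort(
    gt: GroundTruth,
    n_mice: int | Mapping[tuple[str, str], int] = 10,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Simulate a per-mouse, per-region cohort from the ground truth.

    For each group, the regional mean log10 pathology is the configured
    mixture s = beta_a z_a + beta_r z_r + beta_e z_e + beta_t tau of z-scored
    log spread predictions and a group-specific latent activity field tau;
    the mixture is mapped back to density units using the log moments of the
    dominant spread mode, and per-mouse values multiply the regional mean by
    log-normal noise.  tdT densities are 10**tau with their own log-normal
    noise, so the tdT -> pathology partial association equals the configured
    group slope.
    """
    sizes = {g: (n_mice if isinstance(n_mice, int) else n_mice[g]) for g in GROUPS
             if not isinstance(n_mice, Mapping) or g in n_mice}
    for g, n in sizes.items():
        if n < 3:
            raise ValidationError(f"group {g} size {n} < 3")
    rng = np.random.default_rng(rng_seed)
    preds = gt.predictions()
    zhat, stats_by_mode = {}, {}
    for mode, p in preds.items():
        zhat[mode], mu, sd = _log_stats(p)
        stats_by_mode[mode] = (mu, sd)
    regions = list(gt.regions)
    n_reg = len(regions)

    rows = []
    for (genotype, treatment) in GROUPS:
        if (genotype, treatment) not in sizes:
            continue
        b = gt.betas[(genotype, treatment)]
        tau = rng.standard_normal(n_reg)
        s = b.a * zhat["anterograde"] + b.r * zhat["retrograde"] \
            + b.e * zhat["euclidean"] + b.t * tau
        # anchor the density scale to the dominant spread mode
        weights = {"anterograde": abs(b.a), "retrograde": abs(b.r),
                   "euclidean": abs(b.e)}
        dominant = max(("anterograde", "retrograde", "euclidean"),
                       key=lambda m: weights[m])
        mu, sd = stats_by_mode[dominant]
        mean_path = 10.0 ** (mu + sd * s)
        mean_tdt = 10.0 ** (gt.tdt_base_log10 + tau)
        for k in range(sizes[(genotype, treatment)]):
            mouse = f"{genotype}-{treatment}-{k:02d}"
            path = mean_path * np.exp(rng.normal(0.0, gt.noise_sigma, n_reg))
            tdt = mean_tdt * np.exp(rng.normal(0.0, gt.tdt_noise_sigma, n_reg))
            rows.append(pd.DataFrame({
                "mouse_id": mouse, "genotype": genotype, "treatment": treatment,
                "region_id": regions, "pathology": path, "tdt": tdt,
            }))
    return pd.concat(rows, ignore_index=True)


_RACINE_PROFILE = np.array([1, 2, 3, 4, 4, 5, 5, 5, 4, 4, 3, 3, 2, 2, 1], float)


def simulate_behavior(
    cohort: pd.DataFrame,
    target_regions: Sequence[str],
    effect_r: float,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Per-mouse behavioural covariates correlated with target-region pathology.

    A latent severity v is built with population correlation ``effect_r`` to
    each mouse's mean log pathology over ``target_regions`` (and ~0
    elsewhere); the novel-object-recognition % novel time is an affine map of
    v, and the 15 per-minute Racine scores scale a canonical seizure profile
    by v before integer clipping to 0..6, so the Racine AUC inherits the
    correlation approximately.
    """
    if not (abs(effect_r) < 1):
        raise ValidationError("|effect_r| must be < 1")
    target = set(target_regions)
    missing = target - set(cohort["region_id"])
    if missing:
        raise ValidationError(f"target regions not in cohort: {sorted(missing)}")
    rng = np.random.default_rng(rng_seed)
    sub = cohort.loc[cohort["region_id"].isin(target)]
    per_mouse = sub.groupby("mouse_id", observed=True)["pathology"] \
        .apply(lambda v: log10_eps(v.to_numpy()).mean())
    mice = sorted(cohort["mouse_id"].unique())
    m = per_mouse.reindex(mice).to_numpy(dtype=float)
    mz = (m - np.nanmean(m)) / (np.nanstd(m) if np.nanstd(m) > 0 else 1.0)
    v = effect_r * mz + np.sqrt(1.0 - effect_r ** 2) * rng.standard_normal(len(mice))

    nor = np.clip(50.0 + 12.0 * v, 0.0, 100.0)
    racine = np.clip(
        np.rint(_RACINE_PROFILE[None, :] * (0.6 + 0.25 * v)[:, None]
                + rng.normal(0.0, 0.3, (len(mice), 15))),
        0, 6,
    ).astype(int)
    out = pd.DataFrame({"mouse_id": mice, "nor_percent": nor})
    for minute in range(15):
        out[f"racine_m{minute + 1:02d}"] = racine[:, minute]
    return out


def racine_columns(behavior: pd.DataFrame) -> list[str]:
    return [c for c in behavior.columns if c.startswith("racine_m")]
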