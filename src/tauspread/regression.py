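"""Multivariate combination of spread predictions and activity density.

The "Bidirectional Euclidean" family of models explains observed regional
pathology x(t) with a linear combination of the anterograde, retrograde and
Euclidean spread predictions, optionally extended with tdT+ cell density
(a proxy for neuronal activity at labelling time):

    x(t) = beta_a * x̂_a(t) + beta_r * x̂_r(t) + beta_e * x̂_e(t)
           + beta_T * T + eps

All quantities are log10(x + eps)-transformed (the same convention as the
diffusion rate fit) before regression and predictors are z-scored.  Two
coefficient scales are reported: ``betas`` additionally z-scores the
response (fully standardized weights, the scale on which groups are compared
and ratios formed) and ``coefs`` leaves the response in transformed units
(the generative scale on which simulated coefficients are recovered).  The
two differ only by the factor sd(response), which cancels in every ratio.

The tdT-interaction model adds treatment (Sal = 0, PTZ = 1) and a
tdT x treatment term, so the simple slope of tdT is ``b_T`` in the Sal group
and ``b_T + b_TxPTZ`` in the PTZ group; partial residuals for the tdT term
visualise those slopes per region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .atlas import GENOTYPES, TREATMENTS
from .diffusion import PredictionVector
from .errors import UnfittableError, ValidationError

logger = logging.getLogger(__name__)

PRED_ORDER = ("anterograde", "retrograde", "euclidean")
_COND_WARN = 1e6
_RATIO_TOL = 1e-8

#: named beta-weight ratios: anterograde:retrograde, euclidean:retrograde,
#: anterograde:euclidean
RATIO_NAMES = {"a:r": ("anterograde", "retrograde"),
               "e:r": ("euclidean", "retrograde"),
               "a:e": ("anterograde", "euclidean")}


@dataclass(frozen=True)
class CombinedModelFit:
    betas: dict            # fully standardized coefficients (response z-scored)
    coefs: dict            # predictor-standardized coefficients (response in log units)
    intercept: float
    residuals: np.ndarray  # on the response scale of ``coefs``
    r: float               # multiple correlation of fitted vs observed
    n_regions: int
    model_tag: str
    se: dict = field(default_factory=dict)
    pvalues: dict = field(default_factory=dict)
    df_resid: float = 0.0
    cov_params: pd.DataFrame | None = field(default=None, repr=False)


@dataclass(frozen=True)
class SlopeTest:
    """Simple slope of tdT density within one treatment group."""

    group: str
    slope: float
    se: float
    p: float

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValidationError("p-value outside [0, 1]")


def log10_eps(x: np.ndarray, eps: float | None = None) -> np.ndarray:
    """log10(x + eps) with eps defaulting to the smallest positive value."""
    x = np.asarray(x, dtype=float)
    if eps is None:
        pos = x[np.isfinite(x) & (x > 0)]
        eps = float(pos.min()) if pos.size else 1.0
    return np.log10(x + eps)


def zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValidationError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


def _as_values(v) -> np.ndarray:
    if isinstance(v, PredictionVector):
        return np.asarray(v.values, dtype=float)
    return np.asarray(v, dtype=float)


def fit_combined(
    observed: np.ndarray,
    preds: Mapping[str, np.ndarray | PredictionVector],
    tdt: np.ndarray | None = None,
    *,
    transform: bool = True,
) -> CombinedModelFit:
    """OLS combination of spread predictions (and optionally tdT density).

    ``observed`` and every predictor are aligned per-region vectors.  Rows
    with any missing value are dropped.  Constant predictors raise; near-
    collinear designs are fitted but logged with the condition number.
    """
    names = [m for m in PRED_ORDER if m in preds]
    if not names:
        raise ValidationError(f"preds must contain at least one of {PRED_ORDER}")
    y_raw = np.asarray(observed, dtype=float)
    cols = {m: _as_values(preds[m]) for m in names}
    if tdt is not None:
        cols["tdt"] = np.asarray(tdt, dtype=float)
    n = y_raw.shape[0]
    for m, v in cols.items():
        if v.shape != (n,):
            raise ValidationError(f"predictor {m!r} length {v.shape} != {n}")

    keep = np.isfinite(y_raw)
    for v in cols.values():
        keep &= np.isfinite(v)
    if keep.sum() < len(cols) + 2:
        raise UnfittableError(
            f"{int(keep.sum())} complete regions for {len(cols)} predictors"
        )
    y_raw = y_raw[keep]
    cols = {m: v[keep] for m, v in cols.items()}

    y_t = log10_eps(y_raw) if transform else y_raw
    X = np.empty((y_t.size, len(cols)))
    for j, (m, v) in enumerate(cols.items()):
        v_t = log10_eps(v) if transform else v
        if np.ptp(v_t) == 0:
            raise ValidationError(f"constant predictor {m!r}")
        X[:, j] = zscore(v_t)
    if np.ptp(y_t) == 0:
        raise ValidationError("constant response")

    cond = np.linalg.cond(X)
    if cond > _COND_WARN:
        logger.warning("fit_combined: ill-conditioned design (cond=%.3g)", cond)

    y_sd = y_t.std(ddof=0)
    y_z = (y_t - y_t.mean()) / y_sd
    design = sm.add_constant(X, has_constant="add")
    res = sm.OLS(y_z, design).fit()

    pred_names = list(cols)
    betas = dict(zip(pred_names, res.params[1:]))
    coefs = {m: b * y_sd for m, b in betas.items()}
    fitted = res.fittedvalues
    r = float(np.corrcoef(fitted, y_z)[0, 1]) if np.ptp(fitted) > 0 else 0.0
    model_tag = "bidirectional_euclidean" + ("_tdt" if tdt is not None else "")
    return CombinedModelFit(
        betas=betas,
        coefs=coefs,
        intercept=float(res.params[0] * y_sd + y_t.mean()),
        residuals=np.asarray(res.resid) * y_sd,
        r=r,
        n_regions=int(y_t.size),
        model_tag=model_tag,
        se=dict(zip(pred_names, res.bse[1:])),
        pvalues=dict(zip(pred_names, res.pvalues[1:])),
        df_resid=float(res.df_resid),
    )


def beta_ratios(fit: CombinedModelFit, tol: float = _RATIO_TOL) -> dict[str, float | None]:
    """Ratios of standardized beta weights (a:r, e:r, a:e).

    A ratio whose denominator magnitude is below ``tol`` is reported as
    ``None`` (undefined) rather than +/-infinity.
    """
    out: dict[str, float | None] = {}
    for name, (num, den) in RATIO_NAMES.items():
        if num not in fit.betas or den not in fit.betas:
            continue
        d = fit.betas[den]
        if abs(d) < tol:
            logger.warning("beta_ratios: %s undefined (|%s| < %g)", name, den, tol)
            out[name] = None
        else:
            out[name] = float(fit.betas[num] / d)
    return out


def fit_tdt_interaction(
    cohort: pd.DataFrame,
    preds: Mapping[str, np.ndarray | PredictionVector],
    regions: Sequence[str],
    genotype: str,
    *,
    transform: bool = True,
    max_missing_tdt: float = 0.5,
) -> tuple[CombinedModelFit, list[SlopeTest], pd.DataFrame]:
    """Per-genotype model of pathology on spread, tdT and tdT x treatment.

    One regression per genotype over (region, treatment) rows: response is
    the regional mean pathology, predictors are the three z-scored spread
    predictions, z-scored tdT density, treatment (Sal = 0, PTZ = 1) and the
    tdT x treatment interaction.  Returns the fit, the tdT simple slope per
    treatment (Sal slope = b_T, PTZ slope = b_T + b_TxPTZ, with delta-method
    standard errors and two-sided t-tests), and per-region partial residuals
    for the tdT term.
    """
    if genotype not in GENOTYPES:
        raise ValidationError(f"unknown genotype {genotype!r}")
    sub = cohort.loc[cohort["genotype"] == genotype]
    present = sorted(set(sub["treatment"]))
    if set(present) != set(TREATMENTS):
        raise ValidationError(
            f"genotype {genotype!r} needs both treatments, found {present}"
        )
    regions = list(regions)
    pred_cols = {m: _as_values(preds[m]) for m in PRED_ORDER if m in preds}
    if len(pred_cols) != 3:
        raise ValidationError("preds must contain anterograde, retrograde and euclidean")

    g = (
        sub.groupby(["region_id", "treatment"], observed=True)[["pathology", "tdt"]]
        .mean()
        .reset_index()
    )
    g = g.loc[g["region_id"].isin(set(regions))]
    frac_missing = g["tdt"].isna().mean() if len(g) else 1.0
    if frac_missing > max_missing_tdt:
        raise ValidationError(
            f"tdT missing for {frac_missing:.0%} of regions (max {max_missing_tdt:.0%})"
        )
    g = g.dropna(subset=["pathology", "tdt"])
    # regions must appear under both treatments
    both = g.groupby("region_id", observed=True)["treatment"].nunique()
    g = g.loc[g["region_id"].isin(both.index[both == 2])]
    if g["region_id"].nunique() < 8:
        raise UnfittableError("too few regions with tdT under both treatments")

    pos = {r: i for i, r in enumerate(regions)}
    idx = g["region_id"].map(pos).to_numpy()
    y = log10_eps(g["pathology"].to_numpy()) if transform else g["pathology"].to_numpy()
    X_parts, names = [], []
    for m, v in pred_cols.items():
        v_t = log10_eps(v) if transform else v
        col = v_t[idx]
        if np.ptp(col) == 0:
            raise ValidationError(f"constant predictor {m!r}")
        X_parts.append(zscore(col))
        names.append(m)
    tdt_t = log10_eps(g["tdt"].to_numpy()) if transform else g["tdt"].to_numpy()
    if np.ptp(tdt_t) == 0:
        raise ValidationError("constant predictor 'tdt'")
    tdt_z = zscore(tdt_t)
    treat = (g["treatment"] == "PTZ").to_numpy(dtype=float)
    X_parts += [tdt_z, treat, tdt_z * treat]
    names += ["tdt", "treatment", "tdt_x_treatment"]
    X = np.column_stack(X_parts)
    design = sm.add_constant(X, has_constant="add")
    res = sm.OLS(y, design).fit()

    params = dict(zip(["const"] + names, res.params))
    cov = pd.DataFrame(res.cov_params(), index=["const"] + names,
                       columns=["const"] + names)
    slopes = []
    for group in ("Sal", "PTZ"):
        if group == "Sal":
            slope = params["tdt"]
            var = cov.loc["tdt", "tdt"]
        else:
            slope = params["tdt"] + params["tdt_x_treatment"]
            var = (cov.loc["tdt", "tdt"]
                   + cov.loc["tdt_x_treatment", "tdt_x_treatment"]
                   + 2.0 * cov.loc["tdt", "tdt_x_treatment"])
        se = float(np.sqrt(max(var, 0.0)))
        tval = slope / se if se > 0 else np.inf
        p = float(2.0 * stats.t.sf(abs(tval), res.df_resid))
        slopes.append(SlopeTest(group=group, slope=float(slope), se=se, p=min(p, 1.0)))

    partial = np.asarray(res.resid) + params["tdt"] * tdt_z \
        + params["tdt_x_treatment"] * (tdt_z * treat)
    partial_df = pd.DataFrame({
        "region_id": g["region_id"].to_numpy(),
        "treatment": g["treatment"].to_numpy(),
        "tdt_z": tdt_z,
        "partial_residual": partial,
    })

    fitted = res.fittedvalues
    fit = CombinedModelFit(
        betas=dict(zip(names, res.params[1:] / y.std(ddof=0))),
        coefs=dict(zip(names, res.params[1:])),
        intercept=float(res.params[0]),
        residuals=np.asarray(res.resid),
        r=float(np.corrcoef(fitted, y)[0, 1]) if np.ptp(fitted) > 0 else 0.0,
        n_regions=int(g["region_id"].nunique()),
        model_tag="tdt_interaction",
        se=dict(zip(names, res.bse[1:])),
        pvalues=dict(zip(names, res.pvalues[1:])),
        df_resid=float(res.df_resid),
        cov_params=cov,
    )
    return fit, slopes, partial_df


def regional_correlation_screen(
    cohort: pd.DataFrame,
    covariate: Mapping[str, float],
    measure: str = "pathology",
    *,
    min_n: int = 3,
) -> pd.DataFrame:
    """Per-region Pearson correlation between a per-mouse covariate and a
    regional measure (pathology or tdT density).

    Returns a table of (region_id, r, p, n); regions with fewer than
    ``min_n`` complete pairs are skipped with a log entry.  Multiplicity
    adjustment is left to the caller (see :func:`tauspread.inference.fdr_adjust`).
    """
    if measure not in ("pathology", "tdt"):
        raise ValidationError(f"unknown measure {measure!r}")
    cov = pd.Series(covariate, dtype=float)
    if cov.nunique(dropna=True) <= 1:
        raise ValidationError("covariate is constant; correlation undefined")
    rows, skipped = [], 0
    for region, grp in cohort.groupby("region_id", observed=True):
        merged = grp.set_index("mouse_id")[measure].dropna()
        common = merged.index.intersection(cov.dropna().index)
        if len(common) < min_n:
            skipped += 1
            continue
        x = merged.loc[common].to_numpy(dtype=float)
        v = cov.loc[common].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(v) == 0:
            skipped += 1
            continue
        r, p = stats.pearsonr(v, x)
        rows.append({"region_id": region, "r": float(r), "p": float(p),
                     "n": int(len(common))})
    if skipped:
        logger.info("correlation screen: skipped %d region(s) with n < %d "
                    "or zero variance", skipped, min_n)
    return pd.DataFrame(rows, columns=["region_id", "r", "p", "n"])


def racine_auc(per_minute_max_scores: Sequence[int], rule: str = "rectangular") -> float:
    """Seizure-severity AUC from per-minute maximal Racine scores.

    Fifteen integer scores (0-6, one per minute after the final convulsant
    administration) integrated with a 1-minute rectangular rule (the plain
    sum); a trapezoidal option is available.
    """
    scores = np.asarray(per_minute_max_scores)
    if scores.shape != (15,):
        raise ValidationError(f"expected 15 per-minute scores, got {scores.shape}")
    if not np.all(scores == scores.astype(int)):
        raise ValidationError("Racine scores must be integers")
    if scores.min() < 0 or scores.max() > 6:
        raise ValidationError("Racine scores must be in 0..6")
    if rule == "rectangular":
        return float(scores.sum())
    if rule == "trapezoid":
        return float(np.trapezoid(scores))
    raise ValidationError(f"unknown integration rule {rule!r}")
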