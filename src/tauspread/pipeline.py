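"""End-to-end orchestration: simulate/load -> prepare -> fit -> compare -> null.

A run is described by a :class:`RunConfig` (from a YAML file, keyword
arguments, or both — explicit keywords override file values) and executed by
:func:`run_pipeline`, which writes every product into a run directory:
delimited tables for fits, bootstrap distributions, comparisons and null
ensembles, plus a JSON manifest recording the configuration, its hash and
the library versions.  Outputs contain no timestamps, so a run is
byte-identical under a fixed ``rng_seed``.  A stage failure aborts the run,
leaves partial outputs in place and drops a ``FAILED`` marker naming the
stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import (Connectome, RegionAtlas, build_euclidean_connectome,
                    directional_view, filter_regions, load_atlas, load_cohort,
                    load_connectome, oriented_views, regional_means,
                    save_atlas, save_cohort, save_connectome)
from .diffusion import (DEFAULT_SEED_ACRONYMS, DEFAULT_T_MONTHS, Propagator,
                        SeedSpec, fit_rate)
from .errors import TauspreadError, ValidationError
from .inference import (bootstrap_statistics, compare_distributions,
                        fdr_adjust, random_seed_null)
from .regression import beta_ratios, fit_combined
from .synthetic import make_ground_truth, simulate_cohort

logger = logging.getLogger(__name__)

MODES = ("anterograde", "retrograde", "euclidean")
_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    out_dir: str
    rng_seed: int = 0
    # data source: either simulate=True or all three paths
    simulate: bool = False
    atlas_path: str | None = None
    connectome_path: str | None = None
    cohort_path: str | None = None
    direction_convention: str = "anterograde"
    # simulation parameters
    n_regions: int = 100
    n_mice: int = 10
    noise_sigma: float = 0.25
    asymmetry: float = 0.6
    density: float = 0.3
    # analysis parameters
    t: float = DEFAULT_T_MONTHS
    seed_acronyms: tuple[str, ...] = DEFAULT_SEED_ACRONYMS
    min_per_group: int = 6
    modes: tuple[str, ...] = MODES
    B: int = 1000
    n_sets: int = 500
    tolerance: float = 0.2
    null_group: tuple[str, str] = ("WT", "Sal")
    null_mode: str = "retrograde"
    # the seed-specificity null matches the spatial clustering of the two
    # injection sites (hippocampus + cortical area) rather than all four
    # seeded subregions, whose tight hippocampal cluster has few matches
    null_seed_acronyms: tuple[str, str] = ("DG", "PTLp")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        self.seed_acronyms = tuple(self.seed_acronyms)
        self.null_seed_acronyms = tuple(self.null_seed_acronyms)
        self.modes = tuple(self.modes)
        self.null_group = tuple(self.null_group)
        if not self.simulate:
            for name in ("atlas_path", "connectome_path", "cohort_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValidationError(f"config: {name} required unless simulate=true")
                if not Path(p).exists():
                    raise ValidationError(f"config: {name} does not exist: {p}")
        unknown = set(self.modes) - set(MODES)
        if unknown:
            raise ValidationError(f"config: unknown modes {sorted(unknown)}")
        if self.B < 100:
            raise ValidationError("config: B must be >= 100")
        if self.min_per_group < 1:
            raise ValidationError("config: min_per_group must be >= 1")

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def _groups_present(cohort: pd.DataFrame) -> list[tuple[str, str]]:
    return sorted(
        {(g, t) for g, t in cohort[["genotype", "treatment"]].itertuples(index=False)}
    )


def build_connectome_views(
    conn: Connectome, atlas: RegionAtlas
) -> dict[str, Connectome]:
    """All three adjacency views from a stored tracing matrix plus the atlas."""
    views = oriented_views(conn.A, conn.regions, conn.mode)
    views["euclidean"] = build_euclidean_connectome(atlas, conn.regions)
    return views


def run_pipeline(config: RunConfig) -> Path:
    """Execute simulate/load -> prepare -> fit -> combine -> bootstrap ->
    compare -> nullseed, writing all products under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("tauspread")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage = "configure"
    try:
        seed_streams = np.random.SeedSequence(config.rng_seed).generate_state(64) % (2 ** 31)

        # ------------------------------------------------------------ inputs
        stage = "inputs"
        if config.simulate:
            gt = make_ground_truth(
                n_regions=config.n_regions,
                asymmetry=config.asymmetry,
                density=config.density,
                noise_sigma=config.noise_sigma,
                t=config.t,
                rng_seed=int(seed_streams[0]),
                seed_acronyms=config.seed_acronyms,
            )
            atlas = gt.atlas
            conn_stored = gt.connectomes["anterograde"]
            cohort = simulate_cohort(gt, config.n_mice, rng_seed=int(seed_streams[1]))
            inputs = out / "inputs"
            inputs.mkdir(exist_ok=True)
            save_atlas(atlas, inputs / "atlas.csv")
            save_connectome(conn_stored, inputs / "connectome.csv")
            save_cohort(cohort, inputs / "cohort.csv")
            _write_json(gt.manifest(), inputs / "ground_truth.json")
        else:
            atlas = load_atlas(config.atlas_path)
            conn_stored = load_connectome(
                config.connectome_path, mode=config.direction_convention
            )
            cohort = load_cohort(config.cohort_path, atlas=atlas)

        views = build_connectome_views(conn_stored, atlas)
        regions = list(conn_stored.regions)
        seed_sites = atlas.resolve_acronyms(config.seed_acronyms, within=regions)
        seed = SeedSpec(sites=tuple(seed_sites))

        # ----------------------------------------------------------- prepare
        stage = "prepare"
        prepared = out / "prepared"
        prepared.mkdir(exist_ok=True)
        cohort_f, excluded = filter_regions(cohort, config.min_per_group)
        save_cohort(cohort_f, prepared / "cohort_filtered.csv")
        (prepared / "excluded_regions.txt").write_text(
            "\n".join(excluded) + ("\n" if excluded else "")
        )
        groups = _groups_present(cohort_f)
        kept_regions = [r for r in regions if r in set(cohort_f["region_id"])]

        # -------------------------------------------------------------- fits
        stage = "fit"
        fit_dir = out / "fits"
        fit_dir.mkdir(exist_ok=True)
        props = {m: Propagator(views[m], config.t) for m in config.modes}
        fits: dict[tuple[str, str], dict] = {}
        fit_records = []
        for g, tr in groups:
            sub = cohort_f.loc[
                (cohort_f["genotype"] == g) & (cohort_f["treatment"] == tr)
            ]
            observed = regional_means(sub, regions)
            fits[(g, tr)] = {}
            for mode in config.modes:
                fit = fit_rate(views[mode], seed, observed, config.t,
                               propagator=props[mode])
                fits[(g, tr)][mode] = fit
                fit_records.append({
                    "genotype": g, "treatment": tr, "mode": mode,
                    "c_hat": fit.c_hat, "fit_r": fit.fit_r, "n_used": fit.n_used,
                    "seed": ",".join(seed.sites), "t": config.t,
                })
                pd.DataFrame({
                    "region_id": regions, "prediction": fit.prediction.values,
                    "observed": observed,
                }).to_csv(fit_dir / f"prediction_{g}-{tr}_{mode}.csv",
                          index=False, float_format=_FLOAT_FMT)
        pd.DataFrame(fit_records).to_csv(fit_dir / "fits.csv", index=False,
                                         float_format=_FLOAT_FMT)

        # ----------------------------------------------------------- combine
        stage = "combine"
        comb_dir = out / "combined"
        comb_dir.mkdir(exist_ok=True)
        combined_preds: dict[tuple[str, str], dict[str, np.ndarray]] = {}
        beta_rows, ratio_rows = [], []
        for g, tr in groups:
            sub = cohort_f.loc[
                (cohort_f["genotype"] == g) & (cohort_f["treatment"] == tr)
            ]
            observed = regional_means(sub, regions)
            tdt = regional_means(sub, regions, column="tdt")
            preds = {m: fits[(g, tr)][m].prediction.values for m in config.modes}
            combined_preds[(g, tr)] = preds
            if len(preds) == 3:
                fit_be = fit_combined(observed, preds)
                fit_bet = fit_combined(observed, preds,
                                       tdt=tdt if np.isfinite(tdt).any() else None)
                for m, b in fit_bet.betas.items():
                    beta_rows.append({"genotype": g, "treatment": tr,
                                      "model": fit_bet.model_tag,
                                      "predictor": m, "beta": b,
                                      "coef": fit_bet.coefs[m],
                                      "r": fit_bet.r, "n": fit_bet.n_regions})
                for name, val in beta_ratios(fit_be).items():
                    ratio_rows.append({"genotype": g, "treatment": tr,
                                       "ratio": name,
                                       "value": np.nan if val is None else val,
                                       "defined": val is not None})
        pd.DataFrame(beta_rows).to_csv(comb_dir / "betas.csv", index=False,
                                       float_format=_FLOAT_FMT)
        pd.DataFrame(ratio_rows).to_csv(comb_dir / "ratios.csv", index=False,
                                        float_format=_FLOAT_FMT)

        # --------------------------------------------------------- bootstrap
        stage = "bootstrap"
        boot_dir = out / "bootstrap"
        boot_dir.mkdir(exist_ok=True)
        dists: dict[tuple[str, str], dict] = {}
        for gi, (g, tr) in enumerate(groups):
            preds = combined_preds[(g, tr)]

            def stat_fn(resampled, _preds=preds):
                observed = regional_means(resampled, regions)
                rec = {}
                for mode in config.modes:
                    f = fit_rate(views[mode], seed, observed, config.t,
                                 propagator=props[mode])
                    rec[f"fit_r_{mode}"] = f.fit_r
                if len(_preds) == 3:
                    fc = fit_combined(observed, _preds)
                    for m, b in fc.betas.items():
                        rec[f"beta_{m}"] = b
                    for name, val in beta_ratios(fc).items():
                        rec[f"ratio_{name}"] = np.nan if val is None else val
                return rec

            dd = bootstrap_statistics(cohort_f, (g, tr), stat_fn, B=config.B,
                                      rng_seed=int(seed_streams[2 + gi]))
            dists[(g, tr)] = dd
            table = pd.DataFrame({name: d.values for name, d in dd.items()})
            table.to_csv(boot_dir / f"distributions_{g}-{tr}.csv", index=False,
                         float_format=_FLOAT_FMT)
            _write_json({"group": f"{g}-{tr}", "B": config.B,
                         "rng_seed": int(seed_streams[2 + gi]),
                         "statistics": sorted(dd)},
                        boot_dir / f"manifest_{g}-{tr}.json")

        # ----------------------------------------------------------- compare
        stage = "compare"
        cmp_dir = out / "comparisons"
        cmp_dir.mkdir(exist_ok=True)
        stat_names = sorted(next(iter(dists.values())).keys()) if dists else []
        rows = []
        for name in stat_names:
            panel = []
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    gi_, gj_ = groups[i], groups[j]
                    p = compare_distributions(dists[gi_][name], dists[gj_][name])
                    panel.append({"statistic": name,
                                  "group1": f"{gi_[0]}-{gi_[1]}",
                                  "group2": f"{gj_[0]}-{gj_[1]}", "p": p})
            if panel:
                adj = fdr_adjust([r["p"] for r in panel])
                for r, a in zip(panel, adj):
                    r["p_fdr"] = float(a)
                rows.extend(panel)
        pd.DataFrame(rows).to_csv(cmp_dir / "comparisons.csv", index=False,
                                  float_format=_FLOAT_FMT)

        # ---------------------------------------------------------- nullseed
        stage = "nullseed"
        null_dir = out / "nullseed"
        null_dir.mkdir(exist_ok=True)
        g, tr = config.null_group
        if (g, tr) in fits and config.null_mode in config.modes:
            sub = cohort_f.loc[
                (cohort_f["genotype"] == g) & (cohort_f["treatment"] == tr)
            ]
            observed = regional_means(sub, regions)
            null_sites = atlas.resolve_acronyms(config.null_seed_acronyms,
                                                within=regions)
            null_seed = SeedSpec(sites=tuple(null_sites))
            ens = random_seed_null(
                atlas, views[config.null_mode], observed, null_seed,
                n_sets=config.n_sets, tolerance=config.tolerance,
                rng_seed=int(seed_streams[40]), t=config.t,
                propagator=props[config.null_mode],
            )
            pd.DataFrame({
                "set_members": ["|".join(s) for s in ens.sets],
                "fit_r": ens.null_fits,
            }).to_csv(null_dir / "null_fits.csv", index=False,
                      float_format=_FLOAT_FMT)
            _write_json({
                "group": f"{g}-{tr}", "mode": config.null_mode,
                "true_fit_r": ens.true_fit, "true_c": ens.true_c,
                "n_sets": ens.n_sets, "tolerance": ens.matching_tolerance,
                "percentile_of_true": ens.percentile_of_true,
            }, null_dir / "summary.json")

        # ---------------------------------------------------------- manifest
        stage = "manifest"
        _write_json({
            "config": asdict(config),
            "config_hash": config.digest(),
            "tauspread_version": __version__,
            "n_regions_after_filter": len(kept_regions),
            "n_excluded_regions": len(excluded),
            "groups": [f"{g}-{tr}" for g, tr in groups],
        }, out / "manifest.json")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise TauspreadError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
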