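"""End-to-end orchestration: simulate -> summarize -> test -> fit -> convert.

`run_pipeline` executes the whole analysis on either a simulated dataset or
user-supplied pedigree/brood CSV files, writing every artifact (tables,
randomization report, posterior draws, diagnostics, heritabilities, run
manifest) into an output directory so the run is regenerable from config +
seed alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .animal_model import (
    DESK_SETTINGS,
    MCMCSettings,
    ModelSpec,
    Prior,
    build_model,
    diagnostics,
    gibbs_sample,
    heritability_liability,
    pmcmc,
    posterior_summary,
)
from .broods import (
    apply_brood_filter,
    binomial_null_test,
    bsr_summary_table,
    qnorm_sd_by_group,
    read_broods_csv,
    select_analysis_brood,
    write_broods_csv,
)
from .pedigree import read_pedigree_csv, write_pedigree_csv
from .scale import posterior_observed_h2
from .simulate import (
    BroodSizeDistribution,
    CrossDesign,
    GeneticConfig,
    simulate_diallel_dataset,
)

log = logging.getLogger("broodsex")

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run."""

    out_dir: str = "broodsex_run"
    seed: int = 0
    # input: either CSV paths or a simulation
    pedigree_csv: Optional[str] = None
    broods_csv: Optional[str] = None
    simulate: bool = True
    genetics: GeneticConfig = field(default_factory=GeneticConfig)
    design: CrossDesign = field(default_factory=CrossDesign)
    brood_sizes: BroodSizeDistribution = field(default_factory=BroodSizeDistribution)
    n_f1_per_cell: int = 9
    n_backcrosses: int = 223
    # analysis knobs
    min_brood_size: int = 12
    n_sims: int = 5000
    fixed_effects: tuple[str, ...] = ("block", "parental_origin")
    settings: MCMCSettings = field(default_factory=lambda: DESK_SETTINGS)
    prior: Prior = field(default_factory=Prior)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, sub in (
            ("genetics", GeneticConfig),
            ("design", CrossDesign),
            ("brood_sizes", BroodSizeDistribution),
            ("settings", MCMCSettings),
            ("prior", Prior),
        ):
            if key in raw:
                kwargs[key] = sub(**raw.pop(key))
        if "fixed_effects" in raw:
            raw["fixed_effects"] = tuple(raw["fixed_effects"])
        kwargs.update(raw)
        return cls(**kwargs)


@dataclass
class PipelineReport:
    """In-memory results plus the paths of everything written."""

    summary: dict
    files: dict[str, str]


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*a, **k)
            except Exception as exc:  # label the failing stage
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    timings: dict[str, float] = {}
    t_all = time.perf_counter()

    def _save_json(name: str, obj) -> None:
        p = out / name
        with open(p, "w") as fh:
            json.dump(obj, fh, indent=2, default=float)
        files[name] = str(p)

    # --- data
    t0 = time.perf_counter()
    if config.simulate:
        ds = simulate_diallel_dataset(
            gen=config.genetics,
            design=config.design,
            seed=config.seed,
            n_f1_per_cell=config.n_f1_per_cell,
            n_backcrosses=config.n_backcrosses,
            brood_sizes=config.brood_sizes,
        )
        pedigree, broods, phen = ds.pedigree, ds.broods_frame(), ds.phenotypes
        write_pedigree_csv(pedigree, out / "pedigree.csv")
        write_broods_csv(broods, out / "broods.csv")
        files["pedigree.csv"] = str(out / "pedigree.csv")
        files["broods.csv"] = str(out / "broods.csv")
    else:
        if not (config.pedigree_csv and config.broods_csv):
            raise RuntimeError("stage 'data' failed: need pedigree_csv and broods_csv when simulate=False")
        pedigree = read_pedigree_csv(config.pedigree_csv)
        broods = read_broods_csv(config.broods_csv)
        phen = None
    timings["data"] = time.perf_counter() - t0

    # --- brood statistics
    t0 = time.perf_counter()
    one = select_analysis_brood(broods)
    kept, dropped = apply_brood_filter(one, config.min_brood_size)
    table = bsr_summary_table(kept)
    table.to_csv(out / "bsr_summary.csv", index=False)
    files["bsr_summary.csv"] = str(out / "bsr_summary.csv")
    qn = qnorm_sd_by_group(kept)
    qn.to_csv(out / "qnorm_sd.csv", index=False)
    files["qnorm_sd.csv"] = str(out / "qnorm_sd.csv")
    timings["stats"] = time.perf_counter() - t0

    # --- randomization test
    t0 = time.perf_counter()
    rand = binomial_null_test(kept, n_sims=config.n_sims, seed=config.seed + 1)
    _save_json("randomization.json", rand.to_dict())
    timings["test-binomial"] = time.perf_counter() - t0

    # --- threshold animal model
    t0 = time.perf_counter()
    if phen is None:
        raise RuntimeError("stage 'fit' failed: phenotype table unavailable for CSV input (provide simulate=True or extend the loader)")
    keep_ids = set()
    for b in kept.itertuples():
        keep_ids.add(b.dam)
        keep_ids.add(b.sire)
    spec = ModelSpec(fixed_effects=config.fixed_effects)
    model = build_model(phen, pedigree, spec)
    settings = MCMCSettings(
        n_chains=config.settings.n_chains,
        n_iterations=config.settings.n_iterations,
        burn_in=config.settings.burn_in,
        thin=config.settings.thin,
        seed=config.seed + 2,
    )
    samples = gibbs_sample(model, settings, config.prior)
    samples.to_frame().to_csv(out / "posterior.csv", index=False)
    files["posterior.csv"] = str(out / "posterior.csv")
    diag = diagnostics(samples)
    _save_json(
        "diagnostics.json",
        {
            "ess": diag.ess,
            "psrf": diag.psrf,
            "autocorr": {k: list(v) for k, v in diag.autocorr.items()},
            "total_retained": diag.total_retained,
        },
    )
    timings["fit"] = time.perf_counter() - t0

    # --- heritability on both scales
    t0 = time.perf_counter()
    h2_lat = heritability_liability(samples, mode="with_fixed")
    h2_obs = posterior_observed_h2(samples)
    s_lat, s_obs = posterior_summary(h2_lat), posterior_summary(h2_obs)
    pm = {
        name: pmcmc(samples.stacked(name))
        for name in samples.parameter_names()
        if name.startswith("beta:") and name != "beta:intercept"
    }
    h2_report = {
        "h2_lat_mean": s_lat.mean,
        "h2_lat_hpd": [s_lat.hpd_low, s_lat.hpd_high],
        "h2_obs_mean": s_obs.mean,
        "h2_obs_hpd": [s_obs.hpd_low, s_obs.hpd_high],
        "pmcmc": pm,
    }
    _save_json("heritability.json", h2_report)
    timings["convert"] = time.perf_counter() - t0

    summary = {
        "n_broods_analyzed": int(len(kept)),
        "n_broods_dropped": int(dropped),
        "observed_bsr_variance": rand.observed_variance,
        "null_median_variance": rand.null_median,
        "null_ci": [rand.null_ci_low, rand.null_ci_high],
        "randomization_p": rand.p_value,
        **h2_report,
    }
    manifest = {
        "broodsex_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "settings": asdict(config.settings),
        "timings_s": {**timings, "total": time.perf_counter() - t_all},
        "files": files,
    }
    _save_json("report.json", summary)
    _save_json("manifest.json", manifest)
    return PipelineReport(summary=summary, files=files)
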