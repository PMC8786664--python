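"""Pipeline orchestration: configuration, validation, seeded end-to-end runs.

A run is described by a :class:`RunConfig` (typically loaded from a YAML
file): input table paths, labelling parameters, estimator windows, clustering
settings and an output directory.  :func:`run_pipeline` executes the stages

    correct -> enrich -> kinetics (slopes, clustering, MDS) -> flux estimates
    (-> INST-MFA when a network is configured)

writing one tab-separated table per result, and is byte-identical under an
identical config and seed.  :func:`validate_inputs` schema-checks all input
files up front and returns row-level diagnostics instead of raising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fluxest, kinetics, tablesio
from .mids import IsotopeModel
from .network import builtin_network, parse_network

log = logging.getLogger("chloroflux")

__all__ = ["RunConfig", "PipelineError", "validate_inputs", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure carrying the stage name and offending record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated run description.  ``seed`` is mandatory."""

    mid_table: str
    out_dir: str
    seed: int
    label: str = "run"
    pool_table: str | None = None
    biomass_table: str | None = None
    network_file: str | None = None
    network_preset: str | None = None
    medium_enrichment: float = 0.5
    p13: float = 0.0107
    slope_window_s: tuple = (0.0, 40.0)
    product_window_s: tuple = (1800.0, 7200.0)
    cluster: dict = field(default_factory=lambda: {"kmin": 2, "kmax": 8,
                                                   "B": 50, "n_init": 20})
    instmfa: dict | None = None     # {restarts, min_sd, mask, rate_measurements}
    stages: tuple = ("correct", "kinetics", "fluxes")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise PipelineError("config", "seed is mandatory")
        cfg = cls(**raw)
        for key in ("slope_window_s", "product_window_s", "stages"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def resolve_paths(self) -> list:
        problems = []
        for attr in ("mid_table", "pool_table", "biomass_table",
                     "network_file"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                problems.append(f"{attr}: path not found: {p}")
        if "fluxes" in self.stages and self.pool_table is None:
            problems.append("fluxes stage enabled but no pool_table given")
        return problems


def validate_inputs(paths: dict) -> list:
    """Schema-check input files; returns a list of diagnostics (empty = ok).

    ``paths`` maps kind ('mid', 'pool', 'biomass', 'network') to file path.
    """
    diags = []
    if "mid" in paths:
        try:
            df = tablesio.read_mid_table(paths["mid"])
            mcols = [c for c in df.columns if c.startswith("m")
                     and c[1:].isdigit()]
            sums = df[mcols].sum(axis=1)
            for i in np.where(sums <= 0)[0]:
                diags.append(
                    f"mid row {i} ({df.iloc[i]['metabolite']}): "
                    "mass fractions sum to 0")
        except Exception as exc:
            diags.append(f"mid: {exc}")
    if "pool" in paths:
        try:
            tablesio.read_pool_table(paths["pool"])
        except Exception as exc:
            diags.append(f"pool: {exc}")
    if "biomass" in paths:
        try:
            tablesio.read_biomass_table(paths["biomass"])
        except Exception as exc:
            diags.append(f"biomass: {exc}")
    if "network" in paths:
        try:
            spec = yaml.safe_load(Path(paths["network"]).read_text())
            parse_network(spec["reactions"], spec.get("pools", {}),
                          spec.get("fluxes", {}), spec.get("inputs", {}),
                          spec.get("dilutions", {}))
        except Exception as exc:
            diags.append(f"network: {exc}")
    return diags


def _stage_correct(cfg: RunConfig, out: Path) -> pd.DataFrame:
    df = tablesio.read_mid_table(cfg.mid_table)
    model = IsotopeModel(p13=cfg.p13)
    try:
        corrected = tablesio.correct_mid_table(df, model)
    except Exception as exc:
        raise PipelineError("correct", str(exc)) from exc
    tablesio.write_table(corrected, out / "mids_corrected.tsv",
                         metadata={"stage": "correct", "p13": cfg.p13})
    enr = tablesio.enrichment_table(corrected)
    tablesio.write_table(enr, out / "enrichment_long.tsv",
                         metadata={"units": "fraction [0-1]"})
    return enr


def _stage_kinetics(cfg: RunConfig, enr: pd.DataFrame, out: Path) -> None:
    series = tablesio.label_series_from_enrichment(enr)
    rows = []
    for met, s in series.items():
        try:
            slope, intercept, r = kinetics.enrichment_slope(
                s, window=cfg.slope_window_s)
            rows.append((met, slope, intercept, r))
        except ValueError:
            continue
    slopes = pd.DataFrame(rows, columns=["metabolite", "slope_per_s",
                                         "intercept", "r"])
    tablesio.write_table(slopes, out / "enrichment_slopes.tsv",
                         metadata={"window_s": cfg.slope_window_s})
    # metabolite x time matrix (percent) for clustering / MDS
    mat = (enr.pivot_table(index="metabolite", columns="time_s",
                           values="enrichment") * 100.0).dropna()
    c = cfg.cluster
    if mat.shape[0] >= c.get("kmax", 8) + 1:
        result = kinetics.gap_select_k(
            mat, kmin=c.get("kmin", 2), kmax=c.get("kmax", 8),
            B=c.get("B", 50), seed=cfg.seed, n_init=c.get("n_init", 20))
        tablesio.write_table(result.labels.to_frame(), out / "clusters.tsv",
                             metadata={"k": result.k}, index=True)
        tablesio.write_table(result.gap_curve, out / "gap_curve.tsv")
    coords = kinetics.mds_embed(mat)
    tablesio.write_table(coords, out / "mds_coordinates.tsv", index=True)


def _stage_fluxes(cfg: RunConfig, enr: pd.DataFrame, out: Path) -> None:
    pools = tablesio.read_pool_table(cfg.pool_table)
    series = tablesio.label_series_from_enrichment(enr, pools)
    known = [s for s in series.values() if s.metabolite_id in pools]
    rows = []
    try:
        assim = fluxest.min_assimilation_rate(
            known, pools, cfg.medium_enrichment)
        rows.append((assim.name, assim.value, assim.sd, assim.estimator))
    except (ValueError, KeyError) as exc:
        raise PipelineError("fluxes", str(exc)) from exc
    try:
        pepc = fluxest.min_pepc_flux(known, pools, cfg.medium_enrichment)
        rows.append((pepc.name, pepc.value, pepc.sd, pepc.estimator))
    except ValueError:
        log.info("no malate/aspartate series; skipping PEPC estimate")
    report = pd.DataFrame(rows, columns=["estimate", "value_nmolC_gDW_s",
                                         "sd", "estimator"])
    tablesio.write_table(report, out / "flux_estimates.tsv",
                         metadata={"medium_enrichment": cfg.medium_enrichment})


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns {stage: output paths}."""
    problems = cfg.resolve_paths()
    if problems:
        raise PipelineError("validate", "; ".join(problems))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run %s -> %s (seed %d)", cfg.label, out, cfg.seed)
    written: dict = {}
    enr = None
    if "correct" in cfg.stages:
        enr = _stage_correct(cfg, out)
        written["correct"] = [out / "mids_corrected.tsv",
                              out / "enrichment_long.tsv"]
    if "kinetics" in cfg.stages:
        if enr is None:
            raise PipelineError("kinetics", "correct stage must run first")
        _stage_kinetics(cfg, enr, out)
        written["kinetics"] = [out / "enrichment_slopes.tsv",
                               out / "mds_coordinates.tsv"]
    if "fluxes" in cfg.stages:
        if enr is None:
            raise PipelineError("fluxes", "correct stage must run first")
        _stage_fluxes(cfg, enr, out)
        written["fluxes"] = [out / "flux_estimates.tsv"]
    return written
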