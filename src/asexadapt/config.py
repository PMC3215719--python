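"""Simulation parameters, experiment configuration, presets and orchestration.

``SimParams`` carries everything a single simulation needs (N, U_b, U_d,
beta1, beta2, seed, generation budget).  ``ExperimentConfig`` wraps one of
the four experiment kinds (``fixation``, ``longrun``, ``theory``,
``sweep``) with its sizes and output directory; ``run_experiment``
dispatches to the pipelines and serializes results (JSON scalars, TSV
tables, plus a manifest naming parameters, seed and package version so
every output is regenerable).

Presets encode the parameterizations of the published figure panels and
the supplementary table, e.g. ``table-s1`` is N=1e4, beta1=20, beta2=10,
Ub=2.0e-4, Ud=2.0e-1 with M=1000 replicates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .dfe import DFEParams

__all__ = ["SimParams", "ExperimentConfig", "PRESETS", "preset_config",
           "parse_config", "run_experiment"]

log = logging.getLogger(__name__)

EXPERIMENT_KINDS = ("fixation", "longrun", "theory", "sweep")
SWEEP_KINDS = ("fixation", "longrun")


@dataclass(frozen=True)
class SimParams:
    """Parameters of one Wright-Fisher simulation.

    ``fixed_s_b`` / ``fixed_s_d`` optionally replace the exponential DFE by
    a constant effect (used for mutation-selection-balance validation).
    """

    N: int
    Ub: float
    Ud: float
    beta1: float
    beta2: float
    seed: Optional[int] = None
    max_generations: Optional[int] = None
    fixed_s_b: Optional[float] = None
    fixed_s_d: Optional[float] = None

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")
        if self.Ub < 0 or self.Ud < 0:
            raise ValueError("mutation rates Ub, Ud must be >= 0")
        if not (self.beta1 > 0 and self.beta2 > 0):
            raise ValueError("beta1 and beta2 must be > 0")
        if self.seed is not None and self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        if self.max_generations is not None and self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")

    @property
    def dfe(self) -> DFEParams:
        return DFEParams(beta1=self.beta1, beta2=self.beta2)

    def replace(self, **kw) -> "SimParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment: kind, simulation parameters, sizes, sweep grid, output."""

    kind: str
    params: SimParams
    M: Optional[int] = None        # fixation replicates
    T: Optional[int] = None        # long-run generations
    R: Optional[int] = None        # long-run replicates
    sweep_kind: Optional[str] = None      # which pipeline a sweep drives
    sweep_param: Optional[str] = None     # one of Ub, Ud, beta1, beta2, s_bar_b, s_bar_d
    sweep_values: tuple = ()
    outdir: str = "."

    def __post_init__(self) -> None:
        if self.kind not in EXPERIMENT_KINDS:
            raise ValueError(f"unknown experiment kind {self.kind!r}; "
                             f"expected one of {EXPERIMENT_KINDS}")
        if self.kind == "fixation" and (self.M is None or self.M < 1):
            raise ValueError("fixation experiment requires M >= 1")
        if self.kind == "longrun" and (not self.T or not self.R):
            raise ValueError("longrun experiment requires T and R")
        if self.kind == "sweep":
            if not self.sweep_values:
                raise ValueError("sweep requires a non-empty grid")
            if self.sweep_kind not in SWEEP_KINDS:
                raise ValueError(f"sweep_kind must be one of {SWEEP_KINDS}")
            if self.sweep_param not in ("Ub", "Ud", "beta1", "beta2",
                                        "s_bar_b", "s_bar_d"):
                raise ValueError(f"unknown sweep parameter {self.sweep_param!r}")

    def grid(self) -> list[SimParams]:
        """Materialize the sweep grid as SimParams points."""
        out = []
        for v in self.sweep_values:
            if self.sweep_param == "s_bar_b":
                out.append(self.params.replace(beta1=1.0 / v))
            elif self.sweep_param == "s_bar_d":
                out.append(self.params.replace(beta2=1.0 / v))
            else:
                out.append(self.params.replace(**{self.sweep_param: v}))
        return out


_SIM_KEYS = {"N", "Ub", "Ud", "beta1", "beta2", "seed", "max_generations",
             "fixed_s_b", "fixed_s_d"}
_CFG_KEYS = {"kind", "M", "T", "R", "sweep_kind", "sweep_param",
             "sweep_values", "outdir", "preset"}

# Parameterizations of the published figure panels / supplementary table.
_BASE_FIG1 = dict(N=10_000, beta1=20.0, beta2=10.0)
PRESETS: dict[str, dict] = {
    "fig1-a1": dict(kind="fixation", M=1000, **_BASE_FIG1, Ub=2.0e-6, Ud=0.0),
    "fig1-a2": dict(kind="fixation", M=1000, **_BASE_FIG1, Ub=2.0e-6, Ud=2.0e-3),
    "fig1-b1": dict(kind="fixation", M=1000, **_BASE_FIG1, Ub=1.0e-5, Ud=0.0),
    "fig1-b2": dict(kind="fixation", M=1000, **_BASE_FIG1, Ub=1.0e-5, Ud=1.0e-2),
    "fig1-c1": dict(kind="fixation", M=1000, **_BASE_FIG1, Ub=2.0e-4, Ud=0.0),
    "fig1-c2": dict(kind="fixation", M=1000, **_BASE_FIG1, Ub=2.0e-4, Ud=2.0e-1),
    "table-s1": dict(kind="fixation", M=1000, **_BASE_FIG1, Ub=2.0e-4, Ud=2.0e-1),
    "fig2a": dict(kind="sweep", sweep_kind="fixation", sweep_param="Ub",
                  sweep_values=[1e-6, 1e-5, 1e-4, 1e-3], M=1000,
                  N=10_000, beta1=20.0, beta2=20.0, Ub=1e-5, Ud=1.0e-2),
    "fig2b": dict(kind="sweep", sweep_kind="fixation", sweep_param="s_bar_b",
                  sweep_values=[0.01, 0.02, 0.05, 0.1, 0.2], M=1000,
                  N=10_000, beta1=20.0, beta2=20.0, Ub=2.0e-5, Ud=1.0e-2),
    "fig3a": dict(kind="sweep", sweep_kind="fixation", sweep_param="Ud",
                  sweep_values=[1e-3, 1e-2, 0.05, 0.1, 0.2, 0.3], M=1000,
                  N=10_000, beta1=20.0, beta2=20.0, Ub=1.0e-4, Ud=1e-2),
    "fig3b": dict(kind="sweep", sweep_kind="fixation", sweep_param="s_bar_d",
                  sweep_values=[0.01, 0.02, 0.05, 0.1, 0.2], M=1000,
                  N=10_000, beta1=20.0, beta2=20.0, Ub=1.0e-4, Ud=0.1),
    "fig4a": dict(kind="sweep", sweep_kind="longrun", sweep_param="Ub",
                  sweep_values=[2e-6, 1e-5, 2e-5, 1e-4], T=30_000, R=100,
                  N=10_000, beta1=50.0, beta2=10.0, Ub=2e-5, Ud=0.1),
    "fig4b": dict(kind="sweep", sweep_kind="longrun", sweep_param="s_bar_b",
                  sweep_values=[0.01, 0.02, 0.05, 0.1], T=30_000, R=100,
                  N=10_000, beta1=50.0, beta2=10.0, Ub=2e-5, Ud=0.1),
    "fig5a": dict(kind="sweep", sweep_kind="longrun", sweep_param="Ud",
                  sweep_values=[1e-3, 1e-2, 0.05, 0.1, 0.2], T=30_000, R=100,
                  N=10_000, beta1=50.0, beta2=10.0, Ub=2e-5, Ud=0.1),
    "fig5b": dict(kind="sweep", sweep_kind="longrun", sweep_param="s_bar_d",
                  sweep_values=[0.005, 0.01, 0.02, 0.05, 0.1], T=30_000, R=100,
                  N=10_000, beta1=50.0, beta2=50.0, Ub=2e-5, Ud=0.1),
    "figs1": dict(kind="sweep", sweep_kind="longrun", sweep_param="s_bar_b",
                  sweep_values=[0.01, 0.02, 0.05, 0.1], T=30_000, R=100,
                  N=10_000, beta1=50.0, beta2=10.0, Ub=1e-5, Ud=0.1),
    "figs2": dict(kind="sweep", sweep_kind="longrun", sweep_param="Ud",
                  sweep_values=[1e-3, 1e-2, 0.05, 0.1, 0.2], T=30_000, R=100,
                  N=10_000, beta1=5.0, beta2=10.0, Ub=2e-5, Ud=0.1),
}


def preset_config(name: str, **overrides) -> "ExperimentConfig":
    """Build the ExperimentConfig for a named figure/table preset."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: "
                         f"{', '.join(sorted(PRESETS))}")
    merged = {**PRESETS[name], **{k: v for k, v in overrides.items()
                                  if v is not None}}
    return _build_config(merged)


def _build_config(raw: dict) -> ExperimentConfig:
    unknown = set(raw) - _SIM_KEYS - _CFG_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    missing = [k for k in ("N", "Ub", "Ud", "beta1", "beta2")
               if raw.get(k) is None]
    if missing:
        raise ValueError(f"missing required parameters: {missing}")
    sim = SimParams(**{k: raw[k] for k in _SIM_KEYS if raw.get(k) is not None})
    kind = raw.get("kind")
    if kind is None:
        raise ValueError("missing required key: kind")
    sweep_values = tuple(raw.get("sweep_values", ()))
    return ExperimentConfig(
        kind=kind, params=sim, M=raw.get("M"), T=raw.get("T"), R=raw.get("R"),
        sweep_kind=raw.get("sweep_kind"), sweep_param=raw.get("sweep_param"),
        sweep_values=sweep_values, outdir=raw.get("outdir", "."))


def parse_config(path: Optional[str] = None, **flag_overrides) -> ExperimentConfig:
    """Parse a YAML config file and/or flat flag overrides into an ExperimentConfig.

    Flag values override file values; a ``preset`` key (file or flag) seeds
    the defaults.  Validation errors name the offending key.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        raw.update(loaded)
    raw.update({k: v for k, v in flag_overrides.items() if v is not None})
    preset = raw.pop("preset", None)
    if preset is not None:
        base = dict(PRESETS.get(preset) or {})
        if not base:
            raise ValueError(f"unknown preset {preset!r}")
        base.update(raw)
        raw = base
    return _build_config(raw)


def serialize_config(cfg: ExperimentConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["sweep_values"] = list(cfg.sweep_values)
    return d


def config_from_dict(d: dict) -> ExperimentConfig:
    sim = SimParams(**d["params"])
    rest = {k: v for k, v in d.items() if k != "params"}
    rest["sweep_values"] = tuple(rest.get("sweep_values", ()))
    return ExperimentConfig(params=sim, **rest)


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_experiment(cfg: ExperimentConfig) -> list[Path]:
    """Dispatch to the matching pipeline; write outputs and a manifest.

    Returns the list of files written.  Identical config + seed produce
    byte-identical outputs (the manifest stores wall time separately).
    """
    from . import __version__
    from .theory import TheoryParams, scfm_density_ci, scfm_density_sswm, theory_summary

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = cfg.params
    written: list[Path] = []
    t0 = time.perf_counter()

    if cfg.kind == "theory":
        tp = TheoryParams(N=p.N, Ub=p.Ub, Ud=p.Ud, beta1=p.beta1, beta2=p.beta2)
        summary = theory_summary(tp)
        _write_json(outdir / "theory.json", summary)
        written.append(outdir / "theory.json")
        if p.Ub > 0:
            import pandas as pd
            s = np.linspace(1e-4, 10.0 / p.beta1, 200)
            frame = pd.DataFrame({
                "s": s,
                "h_sswm": scfm_density_sswm(s, tp),
                "h_ci": scfm_density_ci(s, tp),
            })
            frame.to_csv(outdir / "scfm_density.tsv", sep="\t", index=False)
            written.append(outdir / "scfm_density.tsv")
    elif cfg.kind == "fixation":
        from .fixation import run_fixation_experiment
        summ = run_fixation_experiment(p, cfg.M, seed=p.seed)
        _write_json(outdir / "fixation_summary.json", {
            "params": dataclasses.asdict(p), "M": summ.M,
            "s_fix": summ.s_fix, "n_b": summ.n_b, "n_d": summ.n_d,
            "mean_w_ca": summ.mean_w_ca, "mean_effect_w": summ.mean_effect_w,
            "mean_t_fix": summ.mean_t_fix,
        })
        summ.to_scfm_frame().to_csv(outdir / "scfm.tsv", sep="\t", index=False)
        written += [outdir / "fixation_summary.json", outdir / "scfm.tsv"]
    elif cfg.kind == "longrun":
        from .longrun import run_longterm
        rates, records = run_longterm(p, cfg.T, cfg.R, seed=p.seed,
                                      return_records=True)
        tp = TheoryParams(N=p.N, Ub=p.Ub, Ud=p.Ud, beta1=p.beta1, beta2=p.beta2)
        _write_json(outdir / "longrun_summary.json", {
            "params": dataclasses.asdict(p), "T": cfg.T, "R": cfg.R,
            "R_alive": rates.R, "E_kb": rates.E_kb, "E_kd": rates.E_kd,
            "dlogw_dt": rates.dlogw_dt,
            "theory": theory_summary(tp),
        })
        written.append(outdir / "longrun_summary.json")
        import pandas as pd
        rows = []
        for i, rec in enumerate(records):
            gens = np.arange(len(rec.log_mean_fitness))
            rows.append(pd.DataFrame({
                "replicate": i, "generation": gens,
                "log_mean_fitness": rec.log_mean_fitness,
                "cum_fixed_b": rec.cum_fixed_b, "cum_fixed_d": rec.cum_fixed_d,
            }))
        traj = pd.concat(rows, ignore_index=True)
        traj_path = outdir / ("longrun_traj.tsv.gz" if len(traj) > 1_000_000
                              else "longrun_traj.tsv")
        traj.to_csv(traj_path, sep="\t", index=False)
        written.append(traj_path)
    elif cfg.kind == "sweep":
        grid = cfg.grid()
        values = list(cfg.sweep_values)
        if cfg.sweep_kind == "fixation":
            from .fixation import sweep as fixation_sweep
            table = fixation_sweep(grid, cfg.M, seed=p.seed,
                                   param_name=cfg.sweep_param,
                                   param_values=values)
        else:
            from .longrun import longrun_sweep
            table = longrun_sweep(grid, cfg.T, cfg.R, seed=p.seed,
                                  param_name=cfg.sweep_param,
                                  param_values=values)
        table.to_csv(outdir / "sweep.tsv", sep="\t", index=False)
        written.append(outdir / "sweep.tsv")

    manifest = {
        "config": serialize_config(cfg),
        "seed": p.seed,
        "package_version": __version__,
        "wall_time_s": round(time.perf_counter() - t0, 3),
        "outputs": [f.name for f in written],
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(outdir / "manifest.json")
    log.info("experiment %s finished in %.1fs; wrote %s", cfg.kind,
             manifest["wall_time_s"], [str(f) for f in written])
    return written
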