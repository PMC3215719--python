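"""Long-horizon evolution: substitution rates and the adaptation rate.

Each replicate evolves a Wright-Fisher population for ``T`` generations.  A
mutation counts as a substitution at the first generation it is carried by
every individual — detected exactly by whole-population common-ancestor
coalescence (all the mutations on the newly coalesced ancestral-path
segment first reach frequency 1 at the generation the coalescence is
detected; checks run every generation).  Outputs are the mean substitution
rates ``E[k_b]``, ``E[k_d]`` (total fixed count / (T*R)) and the adaptation
rate ``dlog w(t)/dt``, estimated per replicate as the least-squares slope
of log mean population fitness on generation and then averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import SimParams
from .engine import (ExtinctionError, collect_fixation, compact_fixed_mutations,
                     init_population, mutate, reproduce)
from .theory import TheoryParams, theory_summary

__all__ = ["LongRunRecord", "SubstitutionRates", "run_longterm", "longrun_sweep"]

log = logging.getLogger(__name__)


@dataclass
class LongRunRecord:
    """One replicate's trajectory over ``T`` generations."""

    T: int
    log_mean_fitness: np.ndarray  # length T+1, generation 0..T
    cum_fixed_b: np.ndarray       # cumulative substitutions, length T+1
    cum_fixed_d: np.ndarray
    seed: int
    extinct: bool = False
    extinct_generation: Optional[int] = None

    @property
    def slope(self) -> float:
        """OLS slope of log mean fitness on generation (dlog w/dt estimate)."""
        t = np.arange(len(self.log_mean_fitness))
        return float(np.polyfit(t, self.log_mean_fitness, 1)[0])


@dataclass
class SubstitutionRates:
    """Replicate-averaged substitution and adaptation rates."""

    E_kb: float
    E_kd: float
    dlogw_dt: float
    R: int                     # replicates included in the averages
    slopes: np.ndarray         # per-replicate dlogw/dt estimates
    kb_per_replicate: np.ndarray
    kd_per_replicate: np.ndarray


def _run_one(params: SimParams, T: int, rng: np.random.Generator,
             seed: int) -> LongRunRecord:
    pop = init_population(params.N)
    logw = np.zeros(T + 1)
    fixed_b = np.zeros(T + 1, dtype=np.int64)
    fixed_d = np.zeros(T + 1, dtype=np.int64)
    for t in range(1, T + 1):
        mutate(pop, params.Ub, params.Ud, params.dfe, rng,
               fixed_s_b=params.fixed_s_b, fixed_s_d=params.fixed_s_d)
        try:
            reproduce(pop, rng)
        except ExtinctionError as exc:
            return LongRunRecord(
                T=T, log_mean_fitness=logw[:t], cum_fixed_b=np.cumsum(fixed_b[:t]),
                cum_fixed_d=np.cumsum(fixed_d[:t]), seed=seed,
                extinct=True, extinct_generation=exc.generation)
        if pop.has_common_ancestor():
            rec = collect_fixation(pop)
            fixed_b[t] += rec.n_b_event
            fixed_d[t] += rec.n_d_event
            compact_fixed_mutations(pop)
        logw[t] = np.log(pop.mean_fitness())
    return LongRunRecord(T=T, log_mean_fitness=logw,
                         cum_fixed_b=np.cumsum(fixed_b),
                         cum_fixed_d=np.cumsum(fixed_d), seed=seed)


def run_longterm(
    params: SimParams,
    T: int,
    R: int,
    seed: Optional[int] = None,
    burn_in_fraction: float = 0.0,
    return_records: bool = False,
):
    """Evolve ``R`` independent replicates for ``T`` generations each.

    ``burn_in_fraction`` optionally discards the initial fraction of each
    trajectory before the slope fit (default 0: the full series is used).
    Extinct replicates are excluded from the averages with a warning.
    Returns :class:`SubstitutionRates`, plus the per-replicate
    :class:`LongRunRecord` list when ``return_records`` is true.
    """
    if T < 1 or R < 1:
        raise ValueError("T and R must be >= 1")
    if not (0.0 <= burn_in_fraction < 1.0):
        raise ValueError("burn_in_fraction must be in [0, 1)")
    if seed is None:
        seed = params.seed
    streams = np.random.SeedSequence(seed).spawn(R)
    records = []
    for r, ss in enumerate(streams):
        child_seed = int(ss.generate_state(1)[0] % (2**31))
        rec = _run_one(params, T, np.random.default_rng(ss), child_seed)
        if rec.extinct:
            log.warning("replicate %d went extinct at generation %s; "
                        "excluded from averages", r, rec.extinct_generation)
        records.append(rec)
        log.info("long run: replicate %d/%d done", r + 1, R)
    alive = [r for r in records if not r.extinct]
    if not alive:
        raise ExtinctionError(-1)
    start = int(burn_in_fraction * T)
    slopes = []
    for r in alive:
        t = np.arange(start, T + 1)
        slopes.append(float(np.polyfit(t, r.log_mean_fitness[start:], 1)[0]))
    slopes = np.array(slopes)
    kb = np.array([r.cum_fixed_b[-1] / T for r in alive])
    kd = np.array([r.cum_fixed_d[-1] / T for r in alive])
    rates = SubstitutionRates(
        E_kb=float(kb.mean()), E_kd=float(kd.mean()),
        dlogw_dt=float(slopes.mean()), R=len(alive),
        slopes=slopes, kb_per_replicate=kb, kd_per_replicate=kd)
    if return_records:
        return rates, records
    return rates


def longrun_sweep(
    params_grid: list[SimParams],
    T: int,
    R: int,
    seed: Optional[int] = None,
    param_name: str = "",
    param_values: Optional[list] = None,
) -> pd.DataFrame:
    """Long-run experiment over a grid, with the analytic predictions beside.

    Each row carries the simulation estimates (``E_kb``, ``E_kd``,
    ``dlogw_dt``) and the independent-fates / CI-corrected predictions for
    the same parameter point.  Per-point failures are recorded and the
    sweep continues.
    """
    if not params_grid:
        raise ValueError("empty parameter grid")
    streams = np.random.SeedSequence(seed).spawn(len(params_grid))
    rows = []
    for i, p in enumerate(params_grid):
        value = param_values[i] if param_values is not None else i
        point_seed = int(streams[i].generate_state(1)[0] % (2**31))
        base = {"param_name": param_name, "param_value": value,
                "N": p.N, "Ub": p.Ub, "Ud": p.Ud,
                "beta1": p.beta1, "beta2": p.beta2,
                "T": T, "R": R, "seed": point_seed}
        th = theory_summary(TheoryParams(N=p.N, Ub=p.Ub, Ud=p.Ud,
                                         beta1=p.beta1, beta2=p.beta2))
        theory_cols = {f"theory_{k}": v for k, v in th.items()}
        try:
            rates = run_longterm(p, T, R, seed=point_seed)
            rows.append({**base, "E_kb": rates.E_kb, "E_kd": rates.E_kd,
                         "dlogw_dt": rates.dlogw_dt, "R_alive": rates.R,
                         **theory_cols, "error": ""})
        except RuntimeError as exc:
            log.warning("long-run sweep point %s=%s failed: %s",
                        param_name, value, exc)
            rows.append({**base, "E_kb": np.nan, "E_kd": np.nan,
                         "dlogw_dt": np.nan, "R_alive": 0,
                         **theory_cols, "error": str(exc)})
    return pd.DataFrame(rows)
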