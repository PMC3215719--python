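"""Replicated single-fixation-event experiments and SCFM aggregation.

Runs ``M`` independent Wright-Fisher populations each until its first
fixation event (whole-population common ancestor), then aggregates the mean
fixed selection coefficient ``s_fix = mean(w_ca - 1)``, the summed fixed
beneficial/deleterious counts ``n_b``/``n_d``, and the pooled list of fixed
mutations' fitness factors (the SCFM sample).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import SimParams
from .engine import FixationRecord, FixationTimeoutError, run_until_fixation

__all__ = ["FixationSummary", "run_fixation_experiment", "scfm_histogram", "sweep"]

log = logging.getLogger(__name__)


@dataclass
class FixationSummary:
    """Aggregate of ``M`` replicate fixation events.

    ``scfm_w`` pools every fixed mutation's fitness factor ``w`` (``1+s_b``
    or ``1-s_d``) across replicates; ``scfm_replicate`` and
    ``scfm_beneficial`` align with it.  Per-event arrays are retained so
    standard errors can be computed downstream.
    """

    params: SimParams
    M: int
    s_fix: float
    n_b: int
    n_d: int
    mean_w_ca: float
    mean_t_fix: float
    scfm_w: np.ndarray
    scfm_s: np.ndarray
    scfm_beneficial: np.ndarray
    scfm_replicate: np.ndarray
    nb_per_event: np.ndarray
    nd_per_event: np.ndarray
    w_ca_per_event: np.ndarray
    t_fix_per_event: np.ndarray
    n_d_before_per_beneficial: np.ndarray
    records: Optional[list] = field(default=None, repr=False)

    @property
    def mean_effect_w(self) -> float:
        """Mean fitness factor over all pooled fixed mutations."""
        return float(self.scfm_w.mean()) if len(self.scfm_w) else float("nan")

    @classmethod
    def from_events(
        cls, params: SimParams, records: list[FixationRecord],
        keep_records: bool = False,
    ) -> "FixationSummary":
        M = len(records)
        w_ca = np.array([r.w_ca for r in records])
        nb = np.array([r.n_b_event for r in records], dtype=np.int64)
        nd = np.array([r.n_d_event for r in records], dtype=np.int64)
        tf = np.array([r.t_fix for r in records], dtype=np.int64)
        if M:
            scfm_w = np.concatenate([r.effects for r in records])
            scfm_s = np.concatenate([r.s_values for r in records])
            scfm_b = np.concatenate([r.beneficial for r in records])
            rep = np.concatenate([np.full(len(r.effects), i, dtype=np.int64)
                                  for i, r in enumerate(records)])
            ndb = np.concatenate([r.n_d_before for r in records])
        else:
            scfm_w = scfm_s = np.empty(0)
            scfm_b = np.empty(0, bool)
            rep = ndb = np.empty(0, np.int64)
        return cls(
            params=params, M=M,
            s_fix=float((w_ca - 1.0).mean()) if M else float("nan"),
            n_b=int(nb.sum()), n_d=int(nd.sum()),
            mean_w_ca=float(w_ca.mean()) if M else float("nan"),
            mean_t_fix=float(tf.mean()) if M else float("nan"),
            scfm_w=scfm_w, scfm_s=scfm_s, scfm_beneficial=scfm_b,
            scfm_replicate=rep,
            nb_per_event=nb, nd_per_event=nd, w_ca_per_event=w_ca,
            t_fix_per_event=tf,
            n_d_before_per_beneficial=ndb,
            records=records if keep_records else None,
        )

    def merge(self, other: "FixationSummary") -> "FixationSummary":
        """Pool two replicate sets; aggregates are recomputed from the union."""
        w_ca = np.concatenate([self.w_ca_per_event, other.w_ca_per_event])
        rep = np.concatenate([self.scfm_replicate,
                              other.scfm_replicate + self.M])
        recs = None
        if self.records is not None and other.records is not None:
            recs = self.records + other.records
        return FixationSummary(
            params=self.params, M=self.M + other.M,
            s_fix=float((w_ca - 1.0).mean()),
            n_b=self.n_b + other.n_b, n_d=self.n_d + other.n_d,
            mean_w_ca=float(w_ca.mean()),
            mean_t_fix=float(np.concatenate(
                [self.t_fix_per_event, other.t_fix_per_event]).mean()),
            scfm_w=np.concatenate([self.scfm_w, other.scfm_w]),
            scfm_s=np.concatenate([self.scfm_s, other.scfm_s]),
            scfm_beneficial=np.concatenate(
                [self.scfm_beneficial, other.scfm_beneficial]),
            scfm_replicate=rep,
            nb_per_event=np.concatenate([self.nb_per_event, other.nb_per_event]),
            nd_per_event=np.concatenate([self.nd_per_event, other.nd_per_event]),
            w_ca_per_event=w_ca,
            t_fix_per_event=np.concatenate(
                [self.t_fix_per_event, other.t_fix_per_event]),
            n_d_before_per_beneficial=np.concatenate(
                [self.n_d_before_per_beneficial,
                 other.n_d_before_per_beneficial]),
            records=recs,
        )

    def to_scfm_frame(self) -> pd.DataFrame:
        """Tidy per-fixed-mutation table (replicate, kind, s, w)."""
        return pd.DataFrame({
            "replicate": self.scfm_replicate,
            "kind": np.where(self.scfm_beneficial, "beneficial", "deleterious"),
            "s": self.scfm_s,
            "w": self.scfm_w,
        })


def run_fixation_experiment(
    params: SimParams,
    M: int,
    seed: Optional[int] = None,
    keep_records: bool = False,
) -> FixationSummary:
    """Run ``M`` independent single-fixation-event replicates and aggregate.

    Each replicate uses a deterministically spawned child RNG stream of
    ``seed`` (replicate ``r`` is reproducible in isolation).  Timeout or
    extinction errors are re-raised annotated with the replicate index.
    """
    if M < 1:
        raise ValueError(f"M must be >= 1, got {M}")
    if seed is None:
        seed = params.seed
    streams = np.random.SeedSequence(seed).spawn(M)
    records = []
    step = max(1, M // 10)
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        try:
            rec = run_until_fixation(
                params.N, params.Ub, params.Ud, params.dfe, rng,
                max_generations=params.max_generations,
                fixed_s_b=params.fixed_s_b, fixed_s_d=params.fixed_s_d)
        except Exception as exc:
            exc.args = (f"replicate {r}: {exc.args[0] if exc.args else exc}",)
            raise
        records.append(rec)
        if (r + 1) % step == 0:
            log.info("fixation experiment: %d/%d replicates done", r + 1, M)
    return FixationSummary.from_events(params, records, keep_records)


def scfm_histogram(
    summary: FixationSummary, bins: int | np.ndarray = 30
) -> dict[str, np.ndarray]:
    """Density-normalized histograms of fixed-mutation selection coefficients.

    Beneficial effects (``s = w - 1``) and deleterious effects
    (``s = 1 - w``) are binned separately so analytic SCFM densities can be
    overlaid directly on the beneficial histogram.
    """
    if len(summary.scfm_w) == 0:
        raise ValueError("empty SCFM: no fixed mutations to histogram")
    out: dict[str, np.ndarray] = {}
    sb = summary.scfm_s[summary.scfm_beneficial]
    sd = summary.scfm_s[~summary.scfm_beneficial]
    if len(sb):
        dens, edges = np.histogram(sb, bins=bins, density=True)
        out["beneficial_density"], out["beneficial_edges"] = dens, edges
    if len(sd):
        dens, edges = np.histogram(sd, bins=bins, density=True)
        out["deleterious_density"], out["deleterious_edges"] = dens, edges
    return out


def sweep(
    params_grid: list[SimParams],
    M: int,
    seed: Optional[int] = None,
    param_name: str = "",
    param_values: Optional[list] = None,
) -> pd.DataFrame:
    """Run the fixation experiment over a parameter grid (tidy long table).

    Per-point failures (timeout/extinction) are recorded in the ``error``
    column and the sweep continues.
    """
    if not params_grid:
        raise ValueError("empty parameter grid")
    streams = np.random.SeedSequence(seed).spawn(len(params_grid))
    rows = []
    for i, p in enumerate(params_grid):
        value = param_values[i] if param_values is not None else i
        point_seed = int(streams[i].generate_state(1)[0] % (2**31))
        base = {
            "param_name": param_name, "param_value": value,
            "N": p.N, "Ub": p.Ub, "Ud": p.Ud,
            "beta1": p.beta1, "beta2": p.beta2, "M": M,
            "seed": point_seed,
        }
        try:
            summ = run_fixation_experiment(p, M, seed=point_seed)
            rows.append({**base, "s_fix": summ.s_fix, "n_b": summ.n_b,
                         "n_d": summ.n_d, "mean_w_ca": summ.mean_w_ca,
                         "mean_t_fix": summ.mean_t_fix, "error": ""})
        except (FixationTimeoutError, RuntimeError) as exc:
            log.warning("sweep point %s=%s failed: %s", param_name, value, exc)
            rows.append({**base, "s_fix": np.nan, "n_b": np.nan, "n_d": np.nan,
                         "mean_w_ca": np.nan, "mean_t_fix": np.nan,
                         "error": str(exc)})
    return pd.DataFrame(rows)
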