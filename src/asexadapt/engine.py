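"""Forward-time Wright-Fisher engine with fixation-event detection.

The model: a haploid asexual population of fixed size ``N``.  Each
generation every individual receives ``Poisson(U_b)`` beneficial and
``Poisson(U_d)`` deleterious mutations whose effects are drawn from the
exponential DFEs; fitness is strictly multiplicative,
``w_i = background * prod(1 + s_b,j) * prod(1 - s_d,k)``.  Offspring are
then sampled with replacement, each choosing parent ``j`` with probability
``w_j / sum_k w_k`` (multinomial reproduction).  A *fixation event* is the
first generation at which all ``N`` individuals share a common ancestor;
the mutations carried by that ancestor (its full ancestral path within the
current tracking window) are the fixed mutations, and its relative fitness
is the fixed fitness gain.

Representation.  Because there is no recombination or back mutation, an
individual's mutation set is exactly the union of the mutations that arose
along its ancestral lineage.  The engine therefore stores, per generation,
the parent-index array (pedigree) and the batch of new mutations
(carrier index, effect, kind), plus a per-individual fitness vector — all
flat numpy arrays, O(N) work per generation.  Whole-population coalescence
is detected incrementally with lineage labels: ``labels[i]`` is the
ancestor of individual ``i`` at the window's anchor generation; the first
generation at which the labels become uniform is exactly the first
fixation event (a single ancestor at any level implies a single ancestor
at every earlier level).  The common ancestor itself (the most recent
single-ancestor generation) is then located by an explicit back-trace
through the pedigree, and the fixed mutations are collected along its path.

After an event, ``compact_fixed_mutations`` folds the fixed effects into a
scalar background fitness and truncates pedigree and mutation logs at the
common ancestor, bounding memory over long runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dfe import DFEParams, sample_beneficial, sample_deleterious

__all__ = [
    "MutationRecord",
    "MutationBatch",
    "PopulationState",
    "FixationRecord",
    "ExtinctionError",
    "FixationTimeoutError",
    "init_population",
    "mutate",
    "reproduce",
    "detect_common_ancestor",
    "find_mrca",
    "collect_fixation",
    "compact_fixed_mutations",
    "run_until_fixation",
    "build_fixture_population",
]


class ExtinctionError(RuntimeError):
    """Raised when every individual has fitness zero (all-lethal population)."""

    def __init__(self, generation: int):
        super().__init__(f"population extinct at generation {generation}: "
                         "all individuals have fitness 0")
        self.generation = generation


class FixationTimeoutError(RuntimeError):
    """Raised when no fixation event occurred within the generation budget."""

    def __init__(self, max_generations: int, pop: "PopulationState"):
        super().__init__(
            f"no fixation event within {max_generations} generations")
        self.max_generations = max_generations
        self.population = pop


@dataclass(frozen=True)
class MutationRecord:
    """One mutation: identity, kind, effect and origin generation."""

    id: int
    kind: str  # "beneficial" | "deleterious"
    s: float
    origin_gen: int

    def __post_init__(self) -> None:
        if self.kind not in ("beneficial", "deleterious"):
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        if self.kind == "beneficial" and not self.s > 0:
            raise ValueError("beneficial mutation requires s > 0")
        if self.kind == "deleterious" and not (0 < self.s <= 1.0):
            raise ValueError("deleterious mutation requires 0 < s <= 1")

    @property
    def effect(self) -> float:
        """Multiplicative fitness factor: 1+s (beneficial) or 1-s (deleterious)."""
        return 1.0 + self.s if self.kind == "beneficial" else 1.0 - self.s


@dataclass
class MutationBatch:
    """New mutations applied to one generation (flat arrays)."""

    idx: np.ndarray        # carrier individual indices (int64)
    s: np.ndarray          # selection coefficients (float64)
    beneficial: np.ndarray  # bool mask
    ids: np.ndarray        # unique mutation ids (int64)

    @classmethod
    def empty(cls) -> "MutationBatch":
        return cls(np.empty(0, np.int64), np.empty(0, float),
                   np.empty(0, bool), np.empty(0, np.int64))

    def __len__(self) -> int:
        return len(self.idx)


@dataclass
class PopulationState:
    """Population of ``N`` individuals plus the current tracking window.

    ``fitness`` is relative to ``background_fitness`` (the compacted product
    of already-fixed effects).  ``pedigree[j]`` maps individuals of
    generation ``anchor_gen + j + 1`` to their parents one generation
    earlier; ``mut_log[j]`` holds the mutation batches applied to
    generation ``anchor_gen + j``.  ``labels[i]`` is the ancestor of
    individual ``i`` at ``anchor_gen``.
    """

    N: int
    generation: int
    anchor_gen: int
    fitness: np.ndarray
    background_fitness: float
    labels: np.ndarray
    pedigree: list = field(default_factory=list)
    mut_log: list = field(default_factory=list)
    next_mutation_id: int = 0

    # -- derived quantities -------------------------------------------------

    def mean_fitness(self) -> float:
        """Arithmetic mean absolute fitness (background included)."""
        return self.background_fitness * float(self.fitness.mean())

    def has_common_ancestor(self) -> bool:
        """True when all current lineages trace to one anchor-generation ancestor."""
        lab = self.labels
        return bool((lab == lab[0]).all())

    def _batches_at(self, gen: int) -> list:
        return self.mut_log[gen - self.anchor_gen]

    def lineage_of(self, i: int) -> list[tuple[int, int]]:
        """Ancestral path of individual ``i``: [(generation, index), ...] old->new."""
        path = []
        a = i
        for j in range(len(self.pedigree) - 1, -1, -1):
            path.append((self.anchor_gen + j + 1, a))
            a = int(self.pedigree[j][a])
        path.append((self.anchor_gen, a))
        path.reverse()
        return path

    def mutations_of(self, i: int) -> list[MutationRecord]:
        """Unfixed mutations carried by individual ``i`` (reconstructed from logs)."""
        out: list[MutationRecord] = []
        for gen, a in self.lineage_of(i):
            for batch in self._batches_at(gen):
                hit = np.nonzero(batch.idx == a)[0]
                for k in hit:
                    kind = "beneficial" if batch.beneficial[k] else "deleterious"
                    out.append(MutationRecord(int(batch.ids[k]), kind,
                                              float(batch.s[k]), gen))
        return out

    def recomputed_fitness(self, i: int) -> float:
        """Individual ``i``'s relative fitness recomputed from its mutation set."""
        w = 1.0
        for m in self.mutations_of(i):
            w *= m.effect
        return w


@dataclass(frozen=True)
class FixationRecord:
    """Outcome of one fixation event.

    ``w_ca`` is the common ancestor's fitness relative to the previous fixed
    background, i.e. the product of the ``effects`` factors (``1+s_b`` or
    ``1-s_d``) of the mutations it carries beyond that background.
    """

    t_fix: int
    mrca_gen: int
    n_b_event: int
    n_d_event: int
    w_ca: float
    effects: np.ndarray      # fitness factors of fixed mutations, path order
    s_values: np.ndarray     # selection coefficients, path order
    beneficial: np.ndarray   # bool mask, path order
    origin_gens: np.ndarray  # origin generation of each fixed mutation
    n_d_before: np.ndarray   # for each fixed beneficial: deleterious fixed earlier
                             # on the same ancestral path (its background load)


# ---------------------------------------------------------------------------
# construction


def init_population(N: int) -> PopulationState:
    """Monomorphic founding population: ``N`` individuals, fitness 1.0."""
    if N < 2:
        raise ValueError(f"N must be >= 2, got {N}")
    return PopulationState(
        N=N, generation=0, anchor_gen=0,
        fitness=np.ones(N), background_fitness=1.0,
        labels=np.arange(N, dtype=np.int64),
        pedigree=[], mut_log=[[]],
    )


def build_fixture_population(
    parent_arrays: Sequence[Sequence[int]],
    mutations: Sequence[tuple[int, int, str, float]] = (),
    N: Optional[int] = None,
) -> PopulationState:
    """Deterministic population from explicit parent arrays and mutation lists.

    ``parent_arrays[g]`` gives, for each individual of generation ``g+1``,
    its parent index in generation ``g``; ``mutations`` is a list of
    ``(generation, individual, kind, s)`` entries.  Fitness is computed by
    tracing each current individual's lineage and multiplying its mutations'
    effects.  Intended for hand-specified small populations in oracle tests.
    """
    errors = []
    ped = [np.asarray(p, dtype=np.int64) for p in parent_arrays]
    if N is None:
        N = len(ped[0]) if ped else 0
    if N < 2:
        errors.append(f"N must be >= 2, got {N}")
    for g, p in enumerate(ped):
        if len(p) != N:
            errors.append(f"parent array for generation {g + 1} has length "
                          f"{len(p)}, expected {N}")
        elif len(p) and (p.min() < 0 or p.max() >= N):
            errors.append(f"parent indices out of range at generation {g + 1}")
    T = len(ped)
    for k, (gen, i, kind, s) in enumerate(mutations):
        if not (0 <= gen <= T):
            errors.append(f"mutation {k}: generation {gen} outside [0, {T}]")
        if not (0 <= i < N):
            errors.append(f"mutation {k}: individual {i} outside [0, {N})")
        if kind not in ("beneficial", "deleterious"):
            errors.append(f"mutation {k}: unknown kind {kind!r}")
        elif kind == "beneficial" and not s > 0:
            errors.append(f"mutation {k}: beneficial requires s > 0")
        elif kind == "deleterious" and not (0 < s <= 1.0):
            errors.append(f"mutation {k}: deleterious requires 0 < s <= 1")
    if errors:
        raise ValueError("inconsistent fixture spec: " + "; ".join(errors))

    mut_log: list[list[MutationBatch]] = [[] for _ in range(T + 1)]
    for mid, (gen, i, kind, s) in enumerate(mutations):
        mut_log[gen].append(MutationBatch(
            np.array([i], np.int64), np.array([float(s)]),
            np.array([kind == "beneficial"]), np.array([mid], np.int64)))

    pop = PopulationState(
        N=N, generation=T, anchor_gen=0,
        fitness=np.ones(N), background_fitness=1.0,
        labels=np.arange(N, dtype=np.int64),
        pedigree=ped, mut_log=mut_log,
        next_mutation_id=len(mutations),
    )
    # labels and fitness follow from the lineages
    anc = np.arange(N, dtype=np.int64)
    for j in range(T - 1, -1, -1):
        anc = ped[j][anc]
    pop.labels = anc
    pop.fitness = np.array([pop.recomputed_fitness(i) for i in range(N)])
    return pop


# ---------------------------------------------------------------------------
# per-generation steps


def mutate(
    pop: PopulationState,
    Ub: float,
    Ud: float,
    dfe: DFEParams,
    rng: np.random.Generator,
    fixed_s_b: Optional[float] = None,
    fixed_s_d: Optional[float] = None,
) -> PopulationState:
    """Apply one generation of mutation to the current individuals (in place).

    Each individual receives independent ``Poisson(Ub)`` beneficial and
    ``Poisson(Ud)`` deleterious mutations (equivalent to ``Poisson(U)``
    thinned with ``p_b = Ub/U``); drawn here as population totals
    ``Poisson(N*U)`` assigned to uniformly random individuals.  Fitness is
    updated multiplicatively.  ``fixed_s_*`` override the DFE with a
    constant effect (used by mutation-selection-balance validation runs).
    """
    if Ub < 0 or Ud < 0:
        raise ValueError("mutation rates must be >= 0")
    N = pop.N
    cur = pop.mut_log[pop.generation - pop.anchor_gen]
    for rate, beneficial, fixed in ((Ub, True, fixed_s_b), (Ud, False, fixed_s_d)):
        if rate == 0.0:
            continue
        n = int(rng.poisson(N * rate))
        if n == 0:
            continue
        idx = rng.integers(0, N, size=n)
        if fixed is not None:
            s = np.full(n, float(fixed))
        elif beneficial:
            s = sample_beneficial(dfe, n, rng)
        else:
            s = sample_deleterious(dfe, n, rng)
        factors = 1.0 + s if beneficial else 1.0 - s
        np.multiply.at(pop.fitness, idx, factors)
        ids = np.arange(pop.next_mutation_id, pop.next_mutation_id + n,
                        dtype=np.int64)
        pop.next_mutation_id += n
        cur.append(MutationBatch(idx.astype(np.int64), s,
                                 np.full(n, beneficial), ids))
    return pop


def reproduce(pop: PopulationState, rng: np.random.Generator) -> PopulationState:
    """Multinomial Wright-Fisher reproduction (in place): next generation of N.

    Each offspring's parent is individual ``j`` with probability
    ``w_j / sum_k w_k``; offspring inherit the parent's full mutation set
    (implicitly, via the pedigree).  Raises :class:`ExtinctionError` when
    the total fitness is zero.
    """
    total = float(pop.fitness.sum())
    if not total > 0:
        raise ExtinctionError(pop.generation)
    counts = rng.multinomial(pop.N, pop.fitness / total)
    parents = np.repeat(np.arange(pop.N, dtype=np.int32), counts)
    pop.pedigree.append(parents)
    pop.fitness = pop.fitness[parents]
    pop.labels = pop.labels[parents]
    pop.generation += 1
    pop.mut_log.append([])
    return pop


# ---------------------------------------------------------------------------
# common-ancestor detection


def detect_common_ancestor(
    pedigree: Sequence[np.ndarray], n_individuals: Optional[int] = None
) -> Optional[tuple[int, int]]:
    """Most recent generation at which all current lineages pass through one
    individual.

    ``pedigree[g]`` maps generation ``g+1`` individuals to generation ``g``
    parents; the current generation is ``len(pedigree)``.  Returns
    ``(mrca_gen, mrca_index)`` or ``None`` when the lineages never coalesce
    within the recorded pedigree (generation-0 founders are distinct
    individuals).  A single ancestor at level ``g`` implies a single
    ancestor at every earlier level, so the returned generation is the MRCA.
    """
    if not pedigree:
        return None
    N = n_individuals if n_individuals is not None else len(pedigree[-1])
    anc = np.arange(N, dtype=np.int64)
    for j in range(len(pedigree) - 1, -1, -1):
        anc = pedigree[j][anc]
        if (anc == anc[0]).all():
            return (j, int(anc[0]))
    return None


def find_mrca(pop: PopulationState) -> tuple[int, int, np.ndarray]:
    """Locate the MRCA once ``pop.has_common_ancestor()`` is true.

    Returns ``(mrca_gen, mrca_index, labels_next)`` where ``labels_next``
    gives each current individual's ancestor at ``mrca_gen + 1`` (the
    anchor labels of the next tracking window).
    """
    if not pop.has_common_ancestor():
        raise ValueError("population has no common ancestor yet")
    N = pop.N
    anc = np.arange(N, dtype=np.int64)
    for j in range(len(pop.pedigree) - 1, -1, -1):
        prev = anc
        anc = pop.pedigree[j][anc]
        if (anc == anc[0]).all():
            return (pop.anchor_gen + j, int(anc[0]), prev.copy())
    raise AssertionError("uniform labels but no single ancestor found")


def collect_fixation(pop: PopulationState) -> FixationRecord:
    """Build the FixationRecord for the current event (labels uniform).

    Collects the mutations along the MRCA's ancestral path from the window
    anchor up to and including the MRCA's own generation — exactly the
    mutations carried by every individual of the current generation, beyond
    the previously fixed background.
    """
    mrca_gen, mrca_idx, _ = find_mrca(pop)
    s_vals, benef, origins, effects = [], [], [], []
    # ancestors of the MRCA at every level from mrca_gen down to the anchor
    a = mrca_idx
    path = []
    for gen in range(mrca_gen, pop.anchor_gen - 1, -1):
        path.append((gen, a))
        if gen > pop.anchor_gen:
            a = int(pop.pedigree[gen - pop.anchor_gen - 1][a])
    for gen, a in reversed(path):
        for batch in pop.mut_log[gen - pop.anchor_gen]:
            hit = np.nonzero(batch.idx == a)[0]
            for k in hit:
                s = float(batch.s[k])
                b = bool(batch.beneficial[k])
                s_vals.append(s)
                benef.append(b)
                origins.append(gen)
                effects.append(1.0 + s if b else 1.0 - s)
    s_vals = np.array(s_vals)
    benef = np.array(benef, dtype=bool)
    effects = np.array(effects)
    n_d_cum = np.cumsum(~benef) - (~benef).astype(int)  # deleterious strictly before
    return FixationRecord(
        t_fix=pop.generation,
        mrca_gen=mrca_gen,
        n_b_event=int(benef.sum()),
        n_d_event=int((~benef).sum()),
        w_ca=float(np.prod(effects)) if len(effects) else 1.0,
        effects=effects,
        s_values=s_vals,
        beneficial=benef,
        origin_gens=np.array(origins, dtype=np.int64),
        n_d_before=n_d_cum[benef],
    )


def compact_fixed_mutations(pop: PopulationState) -> PopulationState:
    """Fold the fixed mutations into the scalar background fitness (in place).

    No-op when the population has no common ancestor (no shared mutations).
    Absolute per-individual fitness (background x relative) is preserved;
    pedigree and mutation logs are truncated at the MRCA so memory stays
    bounded between fixation events.
    """
    if not pop.has_common_ancestor():
        return pop
    rec = collect_fixation(pop)
    mrca_gen, _, labels_next = find_mrca(pop)
    w_path = rec.w_ca
    pop.background_fitness *= w_path
    if w_path > 0:
        pop.fitness = pop.fitness / w_path
    cut = mrca_gen + 1 - pop.anchor_gen
    pop.pedigree = pop.pedigree[cut:]
    pop.mut_log = pop.mut_log[cut:]
    pop.anchor_gen = mrca_gen + 1
    pop.labels = labels_next
    return pop


# ---------------------------------------------------------------------------
# single-fixation-event run


def run_until_fixation(
    N: int,
    Ub: float,
    Ud: float,
    dfe: DFEParams,
    rng: np.random.Generator,
    max_generations: Optional[int] = None,
    fixed_s_b: Optional[float] = None,
    fixed_s_d: Optional[float] = None,
) -> FixationRecord:
    """Mutation + reproduction until the first whole-population common ancestor.

    Returns the :class:`FixationRecord` of the event.  Raises
    :class:`FixationTimeoutError` if ``max_generations`` elapse first (the
    partial population state travels on the exception).
    """
    pop = init_population(N)
    while True:
        mutate(pop, Ub, Ud, dfe, rng, fixed_s_b=fixed_s_b, fixed_s_d=fixed_s_d)
        reproduce(pop, rng)
        if pop.has_common_ancestor():
            return collect_fixation(pop)
        if max_generations is not None and pop.generation >= max_generations:
            raise FixationTimeoutError(max_generations, pop)
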