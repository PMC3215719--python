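# Methods

## Model and simulation engine

The population is haploid, asexual and of fixed size N. One generation is
(i) mutation: every individual receives independent Poisson(U_b) beneficial
and Poisson(U_d) deleterious mutations (equivalent to Poisson(U_b+U_d)
thinned with p_b = U_b/U); (ii) reproduction: N offspring each choose parent
j with probability w_j / sum_k w_k (multinomial sampling with replacement).
Selection coefficients come from exponential DFEs: s_b ~ Exp(beta1)
unbounded, s_d ~ Exp(beta2) truncated at 1.0 so the fitness factor 1 - s_d
stays non-negative. Truncation is by inverse CDF of the renormalized
truncated exponential, which is equivalent in law to rejection sampling and
leaves no atom at 1. Fitness is multiplicative and kept in linear space;
individuals with w = 0 (a lethal s_d = 1 draw) are valid but never
reproduce, and a wholly lethal population raises an explicit extinction
error. Mutation is applied to the current generation before reproduction
samples the next; mutating offspring after sampling instead would be
statistically identical, the ordering is fixed for reproducibility.

Because there is no recombination or back mutation, an individual's
mutation set is exactly the union of mutations along its ancestral lineage.
The engine therefore never copies per-individual sets: it stores the
per-generation parent arrays (pedigree), per-generation mutation batches
(carrier index, effect, kind) and a per-individual fitness vector, all flat
numpy arrays with O(N) work per generation. Explicit sets are reconstructed
on demand (`PopulationState.mutations_of`) for invariant checks.

### Fixation-event detection

A fixation event is the first generation at which all N individuals share a
common ancestor. Detection is incremental: each individual carries a label,
its ancestor at the tracking window's anchor generation, updated by one
fancy-indexing gather per generation. A single ancestor at any generation
implies a single ancestor at every earlier generation, so the first
generation at which the labels become uniform is exactly the first event;
checks therefore run every generation at O(N) cost. The common ancestor
itself is the most recent single-ancestor generation, located by an
explicit back-trace through the pedigree; the most-recent convention makes
the ancestor the post-founding individual whose own mutations are the fixed
ones. All mutations on the newly coalesced path segment first reach
frequency 1 at the detection generation (deeper generations cannot become
single-ancestor before shallower ones), so recorded substitution times are
exact, and counting is insensitive to when compaction runs — verified in
the tests against direct per-individual set intersection.

After an event, the fixed effects are folded into a scalar background
fitness and the pedigree and mutation logs are truncated at the ancestor
(compaction). This bounds memory between events and keeps the per-individual
relative-fitness products short and well-conditioned; absolute fitness
(background x relative) is preserved to better than 1e-12 relative.

### Random numbers

One root seed per experiment; replicate r runs on a deterministically
spawned child stream (`numpy` SeedSequence spawning), so any replicate is
reproducible in isolation and aggregates over replicate subsets merge
exactly. Identical config + seed give byte-identical outputs.

## Experiments

**Single-fixation-event experiment** (`fixation`): M independent
populations each run to their first event. Reported: s_fix = mean(w_CA - 1),
summed fixed beneficial/deleterious counts n_b, n_d, the pooled fixed-
mutation fitness factors (the SCFM sample) and the mean common-ancestor
fitness. "Mean fitness" of the events is interpreted as the mean
common-ancestor fitness across replicates (the per-mutation mean is
arithmetically incompatible with the published counts and DFE means).

**Long-run experiment** (`longrun`): R replicates of T generations.
A mutation counts as a substitution at the first generation it is carried
by all N individuals (frequency 1, exact first-hit; transient
fixation-then-loss is impossible without back mutation). E[k] = total
fixed count / (T R). The adaptation rate dlog w/dt is the per-replicate
ordinary-least-squares slope of log mean population fitness (arithmetic
mean of absolute w_i, background included) on generation, averaged over
replicates — the lowest-variance simple estimator; an optional burn-in
fraction excludes the initial descent to mutation-selection balance and
defaults to 0 (off). No burn-in is applied to E[k].

## Analytic predictions

pi(s) = 1 - exp(-2s) is the branching-process fixation probability, valid
also for large s; the exact diffusion variant
(1 - e^{-2s})/(1 - e^{-2Ns}) is provided for small-N comparisons only (its
error against the exact Markov chain grows ~O(s): ~3% at N=20, s=0.1).
P0 = exp(-U_d/s_bar_d) is the Poisson zero class at mutation-selection
balance, with the mean deleterious effect standing in for the single-s_d
balance argument; an exponential DFE's tiny-effect tail makes the
deterministic zero class ill-defined in the strict sense (the integral of
f(s)/s diverges), so P0 is used as the theory's bookkeeping device, not as
an exact property of the simulated DFE. The interference intensity is the
Gerrish-Lenski integral I(s) = N U_b (ln(Ns)/s) int_s^inf f(x) pi(x) dx,
clamped to 0 where ln(Ns) <= 0. SCFM densities, substitution rates
(K_b = N U_b P0 int pi f; E[K_b] with the extra e^{-I} factor), the mean
fixed effect and dlog w/dt = E[K_b] ln(1 + E[s]) follow; the linearized
E[K_b] E[s] variant is available and differs by <1% at the effect sizes
used here. P0 appears in numerator and denominator of the SCFM densities
and cancels — the densities are independent of U_d, which is the analytic
statement that deleterious mutations do not reshape the SCFM under
one-by-one fixation.

Quadrature is adaptive (absolute/relative tolerance 1e-10) with upper
cutoff 20/beta1 (tail mass < e^{-20}; cutoff insensitivity is tested).
Flux integrals and I(s) evaluations are cached on the frozen parameter
objects, making repeated density evaluation cheap and bit-identical.

## Default study conditions and test scales

The published study conditions are kept as defaults and presets: N = 1e4,
beta1 = 20, beta2 = 10 with the six (U_b, U_d) panels for the
fixation-event experiments (M = 1000), and T = 30,000, R = 100 for the
long-run experiments. The test suite reruns them at reduced size chosen so
the compared signal stands above sampling noise on one CPU: the
supplementary-table check at M = 250 with 3-standard-error tolerances, the
long-run decline at R = 10 full-length replicates, qualitative sweeps at
N = 1000 or shortened horizons with burn-in where the slope transient
would otherwise dominate. The acceptance script runs the full M = 1000
experiment.

## What the generator does and does not emulate

The simulator *is* the study's data generator; no external data exist.
It captures drift, selection, clonal interference, multiple-mutation
fixation, hitchhiking and Muller's ratchet under the stated DFEs. It does
not model recombination, epistasis, variable population size, back
mutation, diploidy, or site-level structure (mutations are independent
draws, never reversions), so conclusions about real genomes carry over
only where those forces are negligible.

## Known limitations

- The branching-process pi(s) ignores O(1/(Ns)) corrections; small-N work
  should use the diffusion variant or the exact chain.
- In regimes with very rare coalescence (near-neutral, large N) the
  pedigree buffer between events grows as N x (event gap); at N = 1e4 and
  30,000-generation gaps this is ~1.2 GB. The study's regimes coalesce
  far more often.
- The OLS dlog w/dt estimator mixes the initial descent to mutation-
  selection balance into the slope when T is short; use the burn-in
  option at short horizons.
- At N U_b ~ 0.02 (the study's "low-U_b" panel) residual clonal
  interference measurably right-shifts the SCFM: with a few hundred pooled
  fixations the pure drift-filtered density is formally rejected by a
  chi-square test while the interference-corrected density fits. The two
  curves are close enough that visual overlays do not distinguish them.
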