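"""Replicate single-fixation-event experiment.

Evolves 40 independent Wright-Fisher populations (N=2000) under joint
beneficial/deleterious mutation pressure until each first reaches a
whole-population common ancestor, then summarizes what fixed.
"""

from asexadapt import SimParams, run_fixation_experiment

params = SimParams(N=2000, Ub=2.0e-4, Ud=2.0e-2, beta1=20.0, beta2=10.0)
summary = run_fixation_experiment(params, M=40, seed=1)

print(f"replicates            M     = {summary.M}")
print(f"mean fixed selection  s_fix = {summary.s_fix:.4f}")
print(f"fixed beneficial      n_b   = {summary.n_b}")
print(f"fixed deleterious     n_d   = {summary.n_d}")
print(f"mean ancestor fitness w_ca  = {summary.mean_w_ca:.4f}")
print(f"mean event time       t_fix = {summary.mean_t_fix:.0f} generations")

# s_fix is the mean excess fitness (w-1) of the events' common ancestors:
# positive here because beneficial drivers outweigh deleterious hitchhikers.
# n_d > 0 shows deleterious mutations fixing by linkage with sweeps.
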