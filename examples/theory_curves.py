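"""Analytic predictions across a deleterious-rate sweep.

Evaluates the zero-class fraction P0, substitution rates and adaptation
rate as U_d varies at fixed beneficial input.
"""

from asexadapt import TheoryParams, theory_summary

print(f"{'Ud':>6} {'P0':>8} {'K_b_sswm':>10} {'K_b_ci':>10} "
      f"{'E[s]':>8} {'dlogw/dt':>10}")
for Ud in (0.0, 0.01, 0.05, 0.1, 0.2):
    tp = TheoryParams(N=1e4, Ub=2e-5, Ud=Ud, beta1=50.0, beta2=10.0)
    t = theory_summary(tp)
    print(f"{Ud:6.2f} {t['P0']:8.4f} {t['K_b_sswm']:10.3e} "
          f"{t['K_b_ci']:10.3e} {t['mean_fixed_s']:8.4f} "
          f"{t['dlogw_dt']:10.3e}")

# P0 = exp(-Ud/s_bar_d) suppresses the substitution rate exponentially in
# Ud: beneficial mutations on loaded backgrounds are assumed lost.  The
# mean fixed effect E[s] is independent of Ud (P0 cancels in the SCFM).
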