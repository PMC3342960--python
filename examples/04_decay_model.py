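"""Exponential decay of genome size from three-species ancestral repeats.

First evaluates the closed-form chain on the published chicken-branch rate
estimates (substitution 4.21%, deletion 2.61%, insertion 0.58%), then
re-estimates the same quantities from simulated chicken/turkey/zebra-finch
style ancestral-repeat triples with a bootstrap confidence interval.
"""

from teindel import (
    bootstrap_ci,
    decay_rate,
    filter_triples,
    fraction_lost,
    loss_per_substitution,
)
from teindel.simulate import simulate_triples

S, D, I = 0.0421, 0.0261, 0.0058
t_split = 0.411  # chicken-lineage divergence since the bird-lizard ancestor

loss = loss_per_substitution(D, I, S)
r = decay_rate(D, I, S)
print("closed form from published branch rates:")
print(f"  loss per substitution (D-I)/S = {loss:.3f}")
print(f"  decay rate r = -ln(1-(D-I))/S = {r:.3f}")
print(f"  cumulative loss over t={t_split}: {100 * fraction_lost(r, t_split):.1f}%")

triples = simulate_triples(
    800, deletion_rate=D, insertion_rate=I, substitution_rate=S,
    length=500, seed=1,
)
params = bootstrap_ci(
    filter_triples(triples), replicates=1000, seed=1, divergence=t_split
)
print("\nre-estimated from 800 simulated ancestral-repeat triples:")
print(f"  D = {params.deletion_rate:.4f}  "
      f"(95% CI {params.ci['deletion_rate'][0]:.4f}-{params.ci['deletion_rate'][1]:.4f})")
print(f"  I = {params.insertion_rate:.4f}  "
      f"(95% CI {params.ci['insertion_rate'][0]:.4f}-{params.ci['insertion_rate'][1]:.4f})")
print(f"  S = {params.substitution_rate:.4f}")
print(f"  r = {params.decay_rate:.3f}  "
      f"(95% CI {params.ci['decay_rate'][0]:.3f}-{params.ci['decay_rate'][1]:.3f})")
lo, hi = params.ci["fraction_lost"]
print(f"  cumulative loss: {100 * fraction_lost(params.decay_rate, t_split):.1f}% "
      f"(95% CI {100 * lo:.1f}-{100 * hi:.1f}%)")
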