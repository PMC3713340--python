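"""How surprising is one tandem dyad in a 2-kb promoter window?

Computes, under an i.i.d. base-composition null at a plant-promoter-like
36% GC, the expected number of core match positions and the exact
probability that a random 2-kb window contains at least one dyad
(linker cap 24 nt), then cross-checks the exact value by Monte Carlo
through the actual scanner.  The punchline: a single dyad within 2 kb is
common by chance, so the published criterion is a candidate filter, not a
significance statement — which is why orientation/linker structure and
functional induction matter.
"""

from beldyad.background import (
    BackgroundSpec,
    dyad_probability,
    expected_core_sites,
    simulate_dyad_rate,
)

spec = BackgroundSpec(base_frequencies=(0.32, 0.18, 0.18, 0.32), window_length=2000, max_linker=24)
p = dyad_probability(spec)
print(f"expected core match positions in 2 kb : {expected_core_sites(spec):.2f}")
print(f"exact P(>= 1 dyad, linker <= 24 nt)   : {p:.4f}")
rate = simulate_dyad_rate(spec, n_sims=2000, seed=7)
print(f"Monte-Carlo rate (2000 windows)       : {rate:.4f}")

short = BackgroundSpec((0.32, 0.18, 0.18, 0.32), 2000, 4)
print(f"with a tight 4-nt linker cap          : {dyad_probability(short):.4f}")
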