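"""End-to-end: simulate a factorial common-garden experiment, then estimate
the proportion of deaths that are selective and the reproductive excess.

The generator emulates 517 inbred genotypes grown in 2 locations x 2 water
levels x 2 densities (30 seeds/pot at high density; ~10 seeds thinned to 1
seedling at low density). The pipeline pools pots into per-genotype
survival rates, corrects the winner's curse in the best rate, gates
fecundity differences behind a permutation test, and converts stage counts
into per-pot reproductive-excess ranges over an assumed 10-fold range of
dispersal survival.
"""

from costsel import PipelineConfig, run_all
from costsel.synthetic import SyntheticConfig, generate

dataset = generate(SyntheticConfig(seed=0, pots_per_genotype=5))
report = run_all(dataset.table, PipelineConfig(seed=0, bootstrap_replicates=500))

print(f"{'environment':36s} {'scope':17s} {'raw':>6s} {'adj':>6s} {'truth':>6s} "
      f"{'RE seeds/pot':>15s} {'RE seedl/pot':>13s}")
for s in report.summaries:
    truth = dataset.truth.loc[s.environment, "prop_selective"]
    print(f"{s.environment:36s} {s.transition_scope:17s} "
          f"{s.prop_selective_raw:6.3f} {s.prop_selective_adjusted:6.3f} {truth:6.3f} "
          f"({s.re_seeds[0]:6.0f},{s.re_seeds[1]:6.0f}) "
          f"({s.re_seedlings[0]:5.2f},{s.re_seedlings[1]:5.2f})")

print()
print("'raw' inflates the selective-death share through the winner's curse of")
print("the best of 517 noisy survival estimates; 'adj' removes it and tracks")
print("the generator's truth. Benign (high-water) environments show larger")
print("seed excess and, at high density, a smaller selective share.")
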