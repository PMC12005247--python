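"""Cost of selection for one selective sweep.

A beneficial allele starting at frequency p0 must replace the resident
allele across the whole population. The deaths (or foregone offspring) that
drive that replacement -- the selective deaths -- accumulate to a nearly
s-independent per-capita total D over the sweep: about -ln(p0) for a
haploid locus and -2 ln(p0) for a diploid locus with genic selection.
"""

from costsel import PloidyModel, SweepParams, cost_per_sweep, instantaneous_cost

p0, s, N = 1e-4, 0.01, 1_000_000

for model in (PloidyModel.HAPLOID, PloidyModel.DIPLOID_GENIC):
    D = cost_per_sweep(SweepParams(p0=p0, s=s, model=model, N=N))
    print(f"{model.value:14s}  D = {D:6.2f} per capita  ->  {D * N:.3g} total deaths")

print()
print("instantaneous cost s(1-p)N at mid-sweep (p=0.5):",
      f"{instantaneous_cost(0.5, s, N):.0f} selective deaths per generation")
print()
print("D is the per-capita price of one substitution; multiplying by N gives")
print("the absolute number of selective deaths the population must 'spend'.")
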