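"""Search the 25^6 function combinations for three-way epistatic models.

A small genetic-algorithm run (the study-scale run uses a population of
100 for 100 generations, i.e. at most 10^4 of the 25^6 models). Fitness is
the pure three-way interaction information of (TF1, TF2, enhancer) on one
dataset simulated from each candidate model.
"""

from epihier import SearchConfig, fitness, ga_search

config = SearchConfig(
    population_size=20, generations=10,           # 200-model demo budget
    pop_size=20_000, n_cases=500, n_controls=500, # fitness dataset size
)
ranked, trace = ga_search(config, seed=3)
baseline = fitness(("ADD",) * 6, config, seed=99)

print(f"evaluated {len(ranked)} models (budget {config.budget})")
print(f"best-so-far fitness per generation: {['%.3f' % f for f in trace]}")
print(f"all-additive baseline three-way IG: {baseline:.4f} bits\n")
print("top 5 discovered models (three-way IG in bits):")
for ind in ranked[:5]:
    print(f"  {','.join(ind.functions):45s} {ind.fitness:.4f}  (gen {ind.generation})")
print("\nhigh-fitness models concentrate class information in the locus "
      "triple rather than in any single variant.")
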