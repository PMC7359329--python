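"""Co-culture growth competition: from futile-cycle cost to fitness defect.

Simulates paired (+/- pheromone) co-cultures of two labelled strains where
the competitor pays a 0.5% growth cost only under stimulation, measures
daily strain ratios by simulated flow cytometry (10,000 cells/sample), and
recovers the selection coefficient from the divergence slope.
"""

from mapkinfo import (
    CocultureConfig,
    divergence_rate,
    fitness_defect,
    growth_rate_from_doubling,
    simulate_coculture,
)

r = growth_rate_from_doubling(100.0)  # 100 min doubling -> ~10 per day
cfg = CocultureConfig(s=0.005, r=r, days=7, seed=4)
traj = simulate_coculture(cfg)
fit = divergence_rate(traj)

print(traj.to_frame().to_string(index=False, float_format="%.4f"))
print(f"\ngrowth rate {r:.2f} /day; fitted divergence slope "
      f"{fit.slope:.4f} /day (95% CI {fit.ci95[0]:.4f}..{fit.ci95[1]:.4f})")
print(f"recovered selection coefficient {fit.slope / r:.4f} (true {cfg.s})")
print(f"fitness defect {fitness_defect(fit.slope, r):.2f}% per generation-time unit")
print("\nThe log of the pheromone/no-pheromone ratio drifts linearly at rate")
print("r*s per day; dividing by the growth rate converts the drift back into")
print("the per-generation fitness cost of running the phosphorylation cycle.")
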