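"""Simulate a single cell's pheromone response and its energetic cost.

Integrates the cascade for one wild-type cell at a saturating and a weak
dose, printing the endpoint pathway state and the terminal-window GTP/ATP
futile-cycle rates.
"""

from mapkinfo import default_parameters, energy_rate_at_endpoint, simulate_cell

params = default_parameters()
for dose in (0.1, 30.0):
    p = params.copy()
    p.theta = dose
    traj = simulate_cell(p, t_end=1000.0)
    end = traj.endpoint()
    fluxes = energy_rate_at_endpoint(traj, window=100.0)
    print(f"dose {dose:6.2f} nM | Fus3-PP {end.Fpp:7.2f} nM | Ste12-P {end.Tp:6.1f} nM "
          f"| reporter {end.Rep:6.1f} a.u.")
    print(f"              | energy rates: GTP {fluxes.jgtp:7.3f}  ATP(Fus3) "
          f"{fluxes.jatp1:7.3f}  ATP(Ste12) {fluxes.jatp2:7.3f}  nM/s")

print("\nHigher dose -> more active kinase and reporter, and a faster-running")
print("phosphorylation futile cycle: the energy rates are what staying")
print("activated costs the cell, in nucleotide hydrolysis events per second.")
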