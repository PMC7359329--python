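"""Information and information-per-energy across feedback-induction
sensitivities.

Sweeps the Ste12-P binding affinity (K_D) of the SST2 and MSG5 promoters on
a small grid and reports where total Fisher information of Fus3-PP and the
efficiency functional (prior-weighted information per unit energy rate) are
maximal.  Desk-scale settings (3x3 grid, 40 cells) keep this to ~2 minutes.
"""

import numpy as np

from mapkinfo import EnsembleConfig, default_parameters, kd_sweep

grid = np.geomspace(4.0, 1e4, 3)
sweep = kd_sweep(default_parameters(), grid, grid,
                 EnsembleConfig(n_cells=40, seed=1), output="Fpp_end")
print(sweep.table[["kd_sst2", "kd_msg5", "total_fisher", "mean_energy",
                   "efficiency"]].to_string(index=False, float_format="%.3g"))

t = sweep.table
fbest = t.loc[t.total_fisher.idxmax()]
ebest = t.loc[t.efficiency.idxmax()]
print(f"\ninformation max at KD_SST2={fbest.kd_sst2:g}, KD_MSG5={fbest.kd_msg5:g} nM")
print(f"efficiency  max at KD_SST2={ebest.kd_sst2:g}, KD_MSG5={ebest.kd_msg5:g} nM")
print("\nSensitive induction of both feedbacks maximizes information, but the")
print("energy bill of running the Fus3 dephosphorylation cycle hard shifts the")
print("information-per-energy optimum to insensitive (late) MSG5 induction --")
print("the configuration observed in the natural pathway.")
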