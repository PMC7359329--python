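"""Fisher and local mutual information of a noisy cell population.

Simulates 60 wild-type and 60 msg5-delta cells across the 15-point dose grid
and compares their dose responses, noise, and information transmission.
"""

from mapkinfo import DoseResponseTable, EnsembleConfig, information_profile, run_ensemble

for genotype in ("wt", "msg5d"):
    ens = run_ensemble(EnsembleConfig(n_cells=60, seed=1, genotype=genotype))
    prof = information_profile(DoseResponseTable(ens.dose_response("Rep_end")))
    s = ens.summary
    print(f"{genotype:6s}: basal reporter {s['mean_Rep'].iloc[0]:6.1f} a.u., "
          f"low-dose CV {s['cv_Rep'].iloc[:4].mean():.3f}, "
          f"aggregated Fisher {prof.aggregated_fisher():6.2f}, "
          f"mean local MI {prof.total_mi():.3f} bits")

print("\nDeleting the Msg5 phosphatase feedback raises basal activity and")
print("noise and compresses the usable output range, so both information")
print("measures drop relative to wild type.")
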