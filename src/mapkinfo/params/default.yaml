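# Wild-type calibration of the pheromone cascade model (concentrations nM,
# time s).  Chosen so that (a) the wild type (KD_MSG5 = 700 nM) shows a graded
# reporter dose response across the 1e-4..480 nM grid, (b) Ste12
# phosphorylation (half-saturated near Fpp ~ 20 nM) and promoter binding
# saturate well before Fus3-PP does, (c) SST2 is induced early (KD 8 nM)
# while MSG5 is induced late (KD 700 nM), and (d) basal pathway activity is
# non-zero, with the upstream Sst2 feedback as its dominant suppressor.
theta: 0.0
KR: 150.0         # receptor half-activation dose, nM
kact: 0.25        # maximal upstream activation rate, 1/s
kact0: 1.0e-6     # dose-independent basal activation (basal pathway activity), 1/s
kgap0: 0.001      # basal deactivation, 1/s
kgap: 0.01        # Sst2-dependent deactivation, 1/(nM s)
kf: 0.1           # Fus3 phosphorylation by active signal, 1/(nM s)
kd0: 0.02         # basal Fus3 dephosphorylation, 1/s
kd: 0.02          # Msg5-dependent dephosphorylation, 1/(nM s)
kt: 1.0e-4        # Ste12 phosphorylation by Fus3-PP, 1/(nM s)
ktb: 0.002        # Ste12 dephosphorylation, 1/s
Ttot: 1000.0      # total Ste12, nM
natp_fus3: 2.0    # ATP per Fus3 activation (dual phosphorylation lumped)
natp_ste12: 1.0   # ATP per Ste12 activation
genes:
  STE2:           # positive feedback: receptor synthesis
    beta0: 0.05
    beta: 0.10
    KD: 8.0
    n: 1.0
    gamma: 0.0005
  FUS3:           # positive feedback: kinase synthesis
    beta0: 0.15
    beta: 0.15
    KD: 8.0
    n: 1.0
    gamma: 0.0005
  SST2:           # upstream negative feedback (sensitive promoter, fast turnover)
    beta0: 0.0002
    beta: 0.30
    KD: 8.0
    n: 1.0
    gamma: 0.002
  MSG5:           # downstream negative feedback (insensitive promoter, fast turnover)
    beta0: 0.002
    beta: 0.50
    KD: 700.0
    n: 1.0
    gamma: 0.002
  FUS1:           # transcriptional reporter (P_FUS1-GFP), arbitrary units
    beta0: 0.005
    beta: 0.5
    KD: 300.0
    n: 1.0
    gamma: 0.0005
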