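# mapkinfo

Information transmission versus energetic cost in the yeast pheromone MAPK
cascade.

Cell signalling pathways transmit graded chemical inputs through noisy
molecular relays, and keeping that transmission accurate costs energy: every
receptor deactivation burns a GTP, every kinase phosphorylation cycle burns
ATP. `mapkinfo` is a simulation and analysis library for studying this
trade-off in the *Saccharomyces cerevisiae* pheromone (mating) pathway,
where two negative transcriptional feedbacks act at different cascade
levels — *SST2* (a GAP accelerating upstream G-protein deactivation, induced
at low pheromone dose) and *MSG5* (a phosphatase for the MAP kinase Fus3,
induced only at high dose). The library reproduces, in silico, the
observation that this natural arrangement maximizes *information per unit
energy* rather than information itself.

It is aimed at systems biologists who want to simulate feedback-regulated
cascades across heterogeneous cell populations, quantify dose–response
channels with information theory, and attach an energy price to signalling
accuracy.

## What it computes

**Model.** A two-step phosphorylation cascade per cell, as ODEs
(concentrations in nM, time in s):

```
dA/dt   = [kact·θ/(θ+K_R) + kact0]·(R_tot − A) − (kgap0 + kgap·Sst2)·A
dFpp/dt = kf·A·(F_tot − Fpp) − (kd0 + kd·Msg5)·Fpp
dTp/dt  = kt·Fpp·(T_tot − Tp) − ktb·Tp
dX_g/dt = β_g0 + β_g·Tp/(Tp + K_D,g) − γ_g·X_g      for g ∈ {STE2, FUS3, SST2, MSG5, FUS1}
```

with cumulative energy counters `dE_GTP/dt = (kgap0 + kgap·Sst2)·A` and
`dE_ATP/dt = 2·kf·A·(F_tot − Fpp) + kt·Fpp·(T_tot − Tp)`. Populations are
simulated by multiplying every synthesis rate and initial concentration by
independent median-1 log-normal factors (extrinsic noise, CV 0.25 by
default), 500 cells for 1000 s across a 15-point serial 3-fold dose grid
(10⁻⁴ to ≈480 nM).

**Information.** Per-input Fisher information of the dose–response channel,
`F(u) = (μ′(u)² + 2σ′(u)²)/σ(u)²` in `u = log10 θ`, evaluated by Gaussian
quadrature with spline-smoothed μ(u), σ(u); and local mutual information in
a sliding window of three inputs with 20 equal-width output bins.

**Energy and efficiency.** Terminal-window GTP/ATP hydrolysis rates per
cell, and the information-per-energy functional

```
efficiency = ∫ F(θ)/E(θ) · P(θ) dθ
```

with a log-uniform input prior by default, swept over the Ste12-P→promoter
affinities (K_D) of the two feedbacks.

**Companion experiments.** A synthetic two-channel single-cell microscopy
assay with known ground truth (log-normal cell variability,
autofluorescence, bleed-through, percentile trimming, correction, EC50
fitting) and a serial-dilution co-culture competition assay (multinomial
flow-cytometry counting, divergence-slope fitting, fitness-defect
conversion) so the full analysis chain is testable end to end.

## Worked example

`python examples/feedback_affinity_sweep.py` sweeps both feedback
affinities on a 3×3 grid (40 cells per dose) and prints:

```
 kd_sst2  kd_msg5  total_fisher  mean_energy  efficiency
       4        4          24.5          249          28
       4      200          20.7          269        37.9
       4    1e+04          18.8          107          38
     200        4            20          369           3
     ...
   1e+04    1e+04          7.63          220       0.609

information max at KD_SST2=4, KD_MSG5=4 nM
efficiency  max at KD_SST2=4, KD_MSG5=10000 nM
```

`total_fisher` is the mean per-input Fisher information of active Fus3
(nats per log10-dose²), `mean_energy` the population-mean hydrolysis rate
(nM/s per cell), `efficiency` their prior-weighted ratio. Information is
maximal when both feedbacks are induced sensitively (low K_D), but
information per energy is maximal with sensitive *SST2* and insensitive
*MSG5* — the induction order found in the real pathway.

The other examples cover single-cell simulation with energy bookkeeping
(`dose_response_simulation.py`), population information analysis of
wild-type versus *msg5Δ* (`population_information.py`), the synthetic
microscopy pipeline (`single_cell_assay_pipeline.py`), and the competition
assay (`competition_assay.py`).

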