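# Methods

## The model

`mapkinfo` models the Fus3-mediated branch of the *S. cerevisiae* pheromone
pathway as a deterministic ODE system per cell: an active upstream signal
`A` (active receptor/G-protein, lumped), the doubly phosphorylated MAP
kinase `Fpp` (Fus3-PP), the phosphorylated transcription factor `Tp`
(Ste12-P), and five Ste12-P-driven gene products — the positive feedbacks
Ste2 (receptor pool `Rtot`) and Fus3 (kinase pool `Ftot`), the negative
feedbacks Sst2 (GAP) and Msg5 (phosphatase), and the FUS1 reporter. Each
promoter is a first-order Hill function of Ste12-P with affinity `K_D`
(Hill coefficient 1 by default; no cooperativity is assumed). The G-protein
cycle is not resolved: receptor occupancy drives `A` directly, and Sst2
accelerates its deactivation.

Two energy counters integrate the futile-cycle costs: one GTP per upstream
deactivation event, `natp_fus3 = 2` ATP per Fus3 activation (the two
phosphorylations of the activation loop are lumped into one step, the
2-phosphate stoichiometry preserved in the count), and `natp_ste12 = 1` ATP
per Ste12 activation. At steady state these rates equal the
dephosphorylation outfluxes, so a constant pathway output shows up as a
constant dissipation rate.

Basal pathway activity is represented by a small dose-independent
activation rate `kact0` (default configuration: 1e-6 s⁻¹; the parameter
defaults to 0 in `ModelParameters`, which recovers a strictly
stimulus-gated cascade). Without basal activity the log-dose channel keeps
a constant logarithmic slope down to arbitrarily small doses, which is both
unphysiological and qualitatively wrong for feedback-deletion phenotypes:
elevated basal activity in *sst2Δ*/*msg5Δ* is a hallmark of the pathway.

The pre-stimulus state is the θ = 0 steady state. Because every induced
total is a function of Ste12-P alone, this reduces to a one-dimensional
fixed point in `Tp`, bracketed in `[0, Ttot]` and solved with Brent's
method (`steady_state`); a long relaxation integration cross-checks it in
the tests. Total Ste12 is a constant parameter (no STE12 synthesis term is
modelled), carried in `CascadeState` only so the invariant `Tp ≤ Ttot` is
checkable.

Integration uses LSODA (`scipy.integrate.odeint`) with rtol = atol = 1e-7
on the nM scale; halving the tolerances moves endpoint Fus3-PP by far less
than 0.1 % (asserted in the tests). Endpoint energy rates are
trapezoid-averaged instantaneous fluxes over a terminal window (default
100 s of the 1000 s simulation), consistent with differencing the
cumulative counters to < 0.5 %.

## Default calibration

The rate constants live in `src/mapkinfo/params/default.yaml`, versioned
as data rather than code. The calibration was chosen to realize, at the
same time:

- a graded wild-type reporter response across the 15-point serial 3-fold
  dose grid (1e-4 to ≈480 nM), with receptor half-activation at
  `K_R = 150 nM`;
- early induction of *SST2* (`K_D` = 8 nM of Ste12-P) and late induction of
  *MSG5* (`K_D` = 700 nM), matching the observed induction order, with the
  positive feedbacks on sensitive promoters (8 nM);
- Ste12 saturating before Fus3-PP: phosphorylation half-saturates near
  Fpp ≈ 20 nM (`ktb/kt`) and the promoters saturate well below maximal
  Ste12-P, so the transcriptional reporter loses information at high dose
  while Fus3-PP remains informative — the reason sweeps score information
  on Fus3-PP;
- a Fus3 cycle fast enough (`kf = 0.1 /nM/s` against `kd0 = 0.02 /s`) that
  weak-phosphatase variants run deep into substrate saturation (cheap but
  information-poor at high dose), while strong Msg5 keeps the cycle
  unsaturated (informative but expensive);
- basal deactivation dominated by Sst2 (`kgap0` small), so losing the
  upstream feedback saturates the G-protein stage well below receptor
  saturation.

Species scales are conventional for yeast: ~100–600 nM protein pools
(~2,500–15,000 copies at ~42 fL), regulator turnover `γ = 0.002 /s` for the
fast feedbacks and `5e-4 /s` for the slower pools, so feedback builds up
substantially within the 1000 s simulation without fully equilibrating —
as in step-stimulation experiments.

## Population (extrinsic) noise

`run_ensemble` simulates `n_cells` (default 500) per dose. Each cell
multiplies every synthesis rate (β₀, β per gene) and every initial
concentration by an independent log-normal factor with median 1 and CV
`cv_extrinsic` (default 0.25, a typical extrinsic-noise magnitude; the
log-scale SD is `sqrt(ln(1+cv²))`). Factors are drawn from a
`numpy` SeedSequence spawned per `(seed, cell_id)`, so results are
independent of execution order and bit-reproducible. Initial totals are the
perturbed basal levels of the genotype; the fast activity variables start
at the unperturbed basal working point (they re-equilibrate within
seconds to minutes) clamped to the perturbed totals. An optional
shared-factor mode is deliberately absent: independence across parameters
is the minimal assumption, and degradation rates are not perturbed.
Molecular-number (intrinsic) stochasticity is out of scope; at the
sub-nanomolar basal Fus3-PP levels of the model this is a real limitation
of the extrinsic-only noise model.

## Information measures

Analysis works in `u = log10 θ` because the dose grid is geometric. The
per-dose mean and SD of the output are smoothed with cubic smoothing
splines (`make_smoothing_spline`, penalty chosen by generalized
cross-validation), the SD floor-clamped at 1e-6 of the response scale.
Fisher information per input is the Gauss–Hermite quadrature of the squared
score of a Gaussian output model — exact for the degree-4 integrand, hence
equal to the closed form `(μ′² + 2σ′²)/σ²` to rounding; units are nats per
(log10 dose)². "Aggregated" information is the trapezoid integral of the
profile over `u` (optionally partitioned by output level), "total" is the
unweighted mean over the grid inputs.

Local mutual information takes each run of three consecutive inputs with
uniform prior, pools their outputs to set 20 equal-width bin edges, and
computes `H(pooled) − mean H(conditional)` in bits with the 0·log 0 = 0
convention; it is clipped to `[0, log2 3]`. No bias correction is applied
by default (small-sample bias at the study's sample sizes is ~0.006 bits
at n = 2000, quantified in the tests). Channel-capacity maximization over
input priors is a non-goal.

Noise projection (`project_noise`) builds a hybrid channel from the mean
response of one data set and the noise of another at matched *output*
level: the donor's σ-vs-mean relation is inverted through its own smoothed
response on a fine grid (400 points), and derivatives follow by the chain
rule. Doses whose mean falls outside the donor's output range are dropped
rather than extrapolated.

## Energy and efficiency

`energy_profile` reports population-mean GTP/ATP rates per dose and the
(relative Fus3-PP, energy) curve, output normalized to its per-profile
maximum. The efficiency functional is the trapezoid quadrature of
`F(θ)/E(θ)` weighted by an input prior on the restricted range
`[θ₁, θ₂]` — by default uniform in log dose over the full simulated grid
(the full 3¹⁴-fold stimulus range). `kd_sweep` runs one ensemble per
(K_D^SST2, K_D^MSG5) pair and scores total Fisher information of the chosen
output, mean energy rate, and efficiency; failed grid cells become NaN,
never zero. The default sweep grid spans 4–10⁴ nM: below a few nM the swept
promoter would sit at or below basal Ste12-P and be constitutively
occupied, i.e. no longer behave as a feedback. Desk-scale defaults
(≤6×6 grid, 100 cells) keep a sweep in minutes; the acceptance analysis
uses 4×4 × 100 cells.

## Synthetic single-cell assay

`generate_population` emulates a two-channel microscopy experiment: true
reporter signal = sigmoid(dose) × mean-1 log-normal cell factor (mean-1, so
the population mean equals the configured sigmoid exactly, unlike the
median-1 convention used for parameter perturbations); channel 1 adds
Gaussian autofluorescence and a linear bleed-through fraction of the
channel-2 (constitutive marker) signal. The reductions mirror standard
practice: upper/lower 3-percentile trimming per field of view and time
point in either channel (linear-interpolation percentiles, ties at the cut
kept); correction constants estimated from single-colour control
populations — channel-2 autofluorescence as the GFP-only strain's mean, and
channel-1 autofluorescence plus bleed coefficient as intercept and slope of
regressing channel 1 on (channel 2 − af2) in the mCherry-only strain; EC50
by least-squares Hill fit with the EC50 on a log10 scale and
multiplicative-error weighting, flagged unidentifiable when the amplitude
is negligible or the log-EC50 uncertainty spans a decade. What passing the
round-trip test shows is that the estimator chain is unbiased on data whose
generative model is known; it does not certify behaviour under segmentation
artefacts, focal drift, or non-log-normal biological variability.

## Competition assay

Growth between twice-daily 1:50 dilutions is purely exponential (the
regime the dilution schedule is designed to maintain); an optional carrying
capacity truncates growth when the combined culture would exceed it. The
selection coefficient `s` penalizes the competitor only in the stimulated
culture of a paired design, so `d/dt ln(ratio) = r·s` exactly and the
unstimulated pair cancels marker-specific costs (modelled as an additive
rate penalty applied in both cultures). Daily measurements draw 10⁴ cells
multinomially, as in flow acquisition. The divergence rate is the OLS slope
of log normalized ratio versus time (fitting in log space is exact where
the paper-style linear fit of near-unity ratios agrees to first order);
`fitness_defect` converts slope to percent via `100·slope/r`, and
`growth_rate_from_doubling` gives `r = ln2/t_double`. At these settings the
per-replicate recovery error is ~9 % RMS, so acceptance asserts RMS and
90th-percentile error bounds plus a <5 % bias over 200 replicates rather
than a hard per-replicate cap that multinomial noise would violate by
chance.

## Numerical and degenerate-input policy

Negative concentrations and doses are rejected on entry; `Tp` is clamped at
zero inside Hill terms against solver round-off. CV is undefined (NaN, with
a warning) at non-positive means. MI windows with zero output spread return
0 bits. The σ → 0 limit with non-zero derivative raises an
infinite-information error instead of returning a large number. All public
randomness flows through integer seeds; ensembles and sweeps are
bit-reproducible given (seed, config).

## Known limitations

- The supplementary ODE system of the original study is reconstructed from
  the described topology, not transcribed; all claims reproduced here are
  qualitative orderings plus printed arithmetic, not parameter-level fits.
- Extrinsic noise only; no stochastic simulation algorithm.
- No Kss1 branch, Dig1/Dig2, Ptp2/Ptp3, receptor trafficking, reporter
  maturation delay, or morphological responses.
- The information-versus-efficiency corner orderings are properties of the
  default calibration at the study's sample sizes; individual seeds at
  n = 100 cells can bring the two most-informative sweep cells within
  estimator noise of each other.
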