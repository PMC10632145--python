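# Methods

## Generative model of the synthetic experiments

A ground-truth network on *n* neurons assigns to each directed edge (j → i)
a causal propagation kernel, drawn as one or two chains of convolved
decaying exponentials with log-uniform rates in [0.05, 2] s⁻¹. Kernels are
normalized so their integral (DC gain) lies in [0.1, 0.6] in magnitude;
without this normalization, chains with two slow rates have integrals of
order 1/γ², and random networks violate the spectral-radius < 1 stability
requirement at any useful density. Inhibitory edges (default fraction 0.11,
the observed share of inhibitory functional connections) carry
negative-integral kernels; inhibition is modelled as negative-going ΔF/F₀ on
a positive tonic baseline. A configurable fraction of edges is flagged
*extrasynaptic*: functionally present but absent from the matched wiring
diagram, emulating dense-core-vesicle (neuropeptidergic) signalling.

A recording simulates one target per 30-s inter-stimulus interval at 2
volumes/s. The stimulated neuron's ΔF/F₀ follows a double-exponential
transient (rise 1.5 s, decay 8 s, peak 1.0); each functional edge adds the
kernel-convolved autoresponse to its downstream neuron, gated per trial by an
independent Bernoulli(response_probability) draw — this is the trial-to-trial
unreliability of connections. By default downstream responses come from the
direct kernel only, keeping per-pair ground truth interpretable; an optional
recursive mode propagates signals over all network paths (effective-connection
semantics). Raw fluorescence is
`baseline · (1 + ΔF/F₀) · bleach(t) + noise` with a multiplicative
double-exponential bleach, i.i.d. Gaussian noise, and an i.i.d. missing-sample
mask. Control recordings use the identical model with no stimulation.

Optionally every neuron also emits spontaneous calcium transients (Poisson
events, default off; the analysis scripts use 1 per 120 s with peak ΔF/F₀
≈ 0.1–0.5). This matters for the equivalence statistics: with pure imaging
noise the empirical null is unrealistically narrow, and the small baseline
contamination that neighbouring trials induce in ΔF/F₀ windows sits many
null SDs from zero, so the TOST (margin 1.2σ) can almost never declare a
pair equivalent to control. Tonic background activity — which real control
recordings certainly contain — broadens σ to a realistic scale.

Matched connectomes contain every non-extrasynaptic functional edge with an
integer synapse count noisily proportional to the edge's functional gain
(count ≈ gain·15·U(0.7, 1.3), at least 1) — anatomically stronger contacts
tend to transmit more — plus optional wired-but-silent edges with weak
counts (1–3).

### What the generator does not emulate

Volumetric imaging, motion, segmentation/tracking errors beyond i.i.d.
missing samples, photophysics of the actuator, state-dependent kernel
variability, slow network-state drifts, and correlated (shared-artifact)
noise across neurons. Passing tests therefore demonstrate the statistical
machinery's behaviour under its own assumptions, not robustness to every
failure mode of real recordings.

## Preprocessing

The five-stage chain: (1) linear interpolation of missing samples (edge gaps
held at the nearest value) — the single non-causal stage; (2) photobleach
removal by dividing a robust double-exponential baseline, fitted by
iteratively reweighted least squares that down-weights samples more than one
residual SD *above* the running fit (so positive transients do not drag the
baseline), renormalized to preserve the baseline's initial value, with a
single-exponential fallback on non-convergence; (3) removal of samples more
than 5 SD from the per-trace mean (computed after bleach correction, since
bleaching inflates raw SD), with one re-estimation pass; (4) causal
Savitzky–Golay smoothing, window 13 samples (6.5 s), order 1, evaluated at
the trailing edge, with shrunken causal windows for the first 12 samples.
Kernel fits always use the non-smoothed (stages 1–3) traces. Response windows
span [−30, +30) s around each stimulus; F₀ is the mean fluorescence over the
30 s before it. The second derivative uses the same causal 13-sample window
at polynomial order 2.

## Inclusion and statistics

The autoresponse classifier demands that ΔF/F₀ and |∂²ΔF/F₀/∂t²| jointly
exceed their thresholds on one contiguous ≥ 4-s stretch of the post-stimulus
window (the stricter of the two possible readings of the joint-contiguity
rule). Downstream response detection uses |ΔF/F₀|, so inhibitory responses
count. Thresholds are a single pair applied to every strain and neuron;
defaults (amplitude 0.1 ΔF/F₀; derivative ≈ 3× the null SD of the
second-derivative statistic) target realistic noise, and the analysis
scripts set them as a small multiple of their regime's noise floor.
Observations are excluded for missing autoresponse, for contiguous missing
gaps > 5% of the window, and (under the dim-neuron override only) for
|ΔF/F₀| > 2.

KS tests operate on per-trial summaries rather than pooled time points:
pooled samples within a window are strongly autocorrelated, which makes the
KS test anticonservative. Fisher's fusion of the amplitude and derivative
p-values assumes independence; the two summaries are computed from the same
window and this caveat is inherited knowingly. Storey's π₀ is estimated on
the λ-grid 0, 0.05, …, 0.90 with a cubic least-squares smoother evaluated at
λ = 0.90 and clipped to (0, 1]; with ~600 tests the estimate carries an SE
near 0.1, which is the dominant source of realized-FDP fluctuation around
the nominal level. The TOST side uses two-sample Welch tests per summary with
margin ε = 1.2σ, takes the max of the two one-sided p-values, fuses the two
summaries with Fisher, and feeds all pairs' p_eq through the same q-value
machinery. Pairs with fewer than two observations get p_eq = 1 (equivalence
cannot be claimed from one trial).

## Kernel algebra and fitting

Chains follow the convention that each factor is the un-normalized
θ(t)e^(−γt), so a chain's integral is c·Π(1/γ). The symbolic expansion
folds factors left-to-right with the four closed-form rules for convolving
a·tⁿ·e^(−γt) with a normalized exponential (dividing by the convolving rate),
merging terms with identical (n, γ). Equal-rate detection is exact
floating-point equality: equal-rate chains are a distinct model class in the
fitter, which never produces near-duplicate free rates, and this avoids the
numerically unstable γ_n − γ_i → 0 limit. Evaluation works in log-space for
overflow safety and is identically zero for t < 0.

Fitting minimizes the sum of squared residuals of
`downstream − k ∗ upstream` on the post-stimulus window (no regularization),
with rates bounded in [1/60, 10] s⁻¹ (set by the 30-s window and 0.5-s
sampling), log-parametrized, multistarted from log-spaced random rates, and
model-selected across chain configurations {(1), (2), (3), (1,1), (1,2),
(2,2)} by small-sample-corrected AIC. A downstream series that is
identically zero (or fails response detection upstream of the fit) yields
the zero kernel. Trial-averaged kernels are exact: kernels are linear in
their chains, so the average is the union of chains with coefficients
divided by the trial count.

Rise time: drop chains whose sign opposes that of the chain with largest
|c·Π(1/γ)| (the saturating, opposite-sign terms), then measure the time from
the earliest 1/e-of-peak crossing of |k| to its peak on a dense (1 ms) grid;
zero when the desaturated kernel peaks at t = 0. Stereotypy convolves every
per-trial kernel with every stimulus in a common set and averages Pearson
correlations over all unordered kernel pairs and stimuli.

## Biophysical model

Voltages in volts, SI units throughout:
`C dV_i/dt = −g_l(V_i−E_l) − Σ_j G_ij(V_i−V_j) − Σ_j S_ij s_j (V_i−E_ij) + I_i`
with gap conductances G = 100 pS per contact, synaptic conductances
S = 100 pS per synapse, C = 1 pF, g_l = 10 pS, E_l = −35 mV, excitatory /
inhibitory reversals 0 / −70 mV, and graded activation
`ds_j/dt = a_r φ(V_j)(1−s_j) − a_d s_j` (a_r = 1 s⁻¹, a_d = 5 s⁻¹, logistic φ
with slope 0.125 mV⁻¹). Each neuron's activation midpoint is set to its
resting potential, so φ = 1/2 and s = a_r/(a_r + 2a_d) at rest; the rest
state then solves a linear system exactly and zero input preserves
equilibrium to solver precision (LSODA, rtol 1e−8, atol 1e−12, the input
step integrated as two segments). Peak-ΔV response matrices can also be
computed from the sustained-input fixed point ("steady" mode, a root solve),
which coincides with the transient peak for monotonic step responses and is
~100× faster; the wiring-masked weight/sign fit uses it inside its
least-squares loop. The response matrix's "large response" threshold is
exposed as `DV_LARGE = 0.1` V. Note that response magnitude grows with
synapse count only in the weak-coupling regime; at 100 pS/synapse a large
count depolarizes the resting point and shunts the driving force, which is a
property of the model, not a defect.

Hop distances iterate strictly-n-hop composition of the binarized union of
chemical (directed) and gap (symmetric) edges, which equals BFS distance and
is tested against an independent BFS oracle. Polarity assignment aggregates
a (possibly partial) sign table across bilateral subtype members (trailing
L/R stripped) by majority, ties and absences excitatory.

## Correlation predictions and the three-way comparison

Kernel-based predictions drive one neuron at a time with a representative
transient (the synthetic autoresponse template), set every other neuron's
activity to its trial-averaged-kernel convolution (zero kernel for pairs
with q > 0.05), average per-drive Pearson correlation matrices over the
drive set, and compare with an observed matrix through the Pearson
correlation of off-diagonal entries. Top-n driver selection is greedy
forward selection with index-order tie-breaks.

The anatomy-side correlation prediction applies the same procedure to the
biophysical model's ΔV time series. Two numerical guards: injected currents
sit in the small-signal regime (0.1 pA), and neurons whose peak |ΔV| falls
below 10⁻³ of the driven neuron's own peak are treated as non-responding —
Pearson correlation is scale-free, so without a floor numerically negligible
responses would contribute full ±1 entries.

The packaged comparison (`compare_prediction_routes`) builds a 16-neuron
network (density 0.15, 20% extrasynaptic edges), takes as "observed" the
correlations of all-paths (recursive) propagation with the recordings'
imaging-noise floor added, fits kernels from three simulated stimulation
recordings per replicate (detection thresholds at ~2× the noise floor, two
trials per pair, 1- and 2-exponential model classes), and scores the three
predictors. Across 20 seeded replicates the mean ordering
kernel > anatomy > counts is clear (≈ 0.80 / 0.46 / 0.27), but the
anatomy-vs-counts margin is within its own cross-seed spread, and roughly
three topologies in twenty invert that leg: both are weak predictors at this
network size, and which one wins on a given graph is substantially luck.
The problem sizes here (16 neurons, 3 × 630-s recordings, 2 fitted trials
per pair) were chosen so a full 20-replicate comparison completes on a
single CPU in minutes.

## Calibration experiments

The false-discovery experiment builds two disjoint pools of control-window
summaries (the KS reference null and the source of pair observations —
mirroring the stimulated-vs-control recording split), forms 500 null pairs
and 100 pairs shifted 3σ in both summaries (10 observations each), and runs
the full KS → Fisher → Storey chain; the realized false-discovery proportion
among q < 0.05 calls is compared with 0.05 plus two binomial SEs. The
equivalence-miscoverage experiment draws 500 pairs shifted 2σ (outside the
1.2σ margin) and measures how often TOST → Storey declares them
non-connected. Both run from a single seed that derives every stream.

## Known limitations

- Fisher fusion of dependent summaries and the discreteness of small-sample
  KS p-values leave the realized FDP fluctuating around (occasionally above)
  the nominal level; the π₀ smoother's variance at m ≈ 600 dominates.
- The symbolic algebra relies on exact rate distinctness; pathological fits
  with two nearly equal free rates lose precision by cancellation (bounded
  in practice by the distinct-model-class design).
- The biophysical model is a point-neuron, graded-synapse caricature;
  its voltage outputs are compared with calcium-derived quantities without
  an indicator model.
- Window-based baselines inherit contamination from preceding trials; at
  high edge density and high SNR this inflates connected calls beyond the
  direct-edge truth (visible in the worked example: 41 calls vs 36 edges).
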