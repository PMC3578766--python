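# Methods

## Model

### Neurons and network

Each neuron is a leaky integrate-and-fire (LIF) unit,

    tau_m dV/dt = -(V - V_rest) + I(t),

with an instantaneous reset to `V_rest` when `V` reaches `V_thresh`.
Defaults: `tau_m = 20 ms`, `V_rest = -60 mV`, `V_thresh = -50 mV`
(reset equals rest).  The input `I` is measured in mV (membrane resistance
absorbed) and is the sum of

* a synaptic term that jumps by the synaptic weight at each presynaptic
  arrival (positive for excitatory, negative for inhibitory sources) and
  decays exponentially with `tau_s = 5 ms`,
* a constant external bias `mu` per neuron, and
* independent Gaussian white noise of amplitude `sigma` (mV·ms^1/2),
  integrated with the Euler–Maruyama rule.

The network is all-to-all (no self-connections) with `n_exc` excitatory and
`n_inh` inhibitory neurons.  The full-scale reference configuration is
500 + 500; desk-scale experiments run at a recorded scale factor of 0.4
(200 + 200).  Non-plastic blocks are drawn once per seed, uniform on
`[0, bound]` with bounds E→I = 2 mV and I→E = I→I = 6 mV; inhibition is
stronger than excitation, which keeps the network in an inhibition-dominated
balanced state.  External noise `sigma = 40 mV·ms^1/2` puts single-neuron
irregularity at an ISI CV ≈ 0.9–1.0 near 20 Hz, the asynchronous irregular
operating regime the pairwise analysis assumes; this is verified on
simulated rasters by `stdpnet.diagnostics` (cross-covariance ≈ 0, CV ≈ 1).

Spikes are detected after the voltage update and take effect one step later
(one-step axonal latency).  The integration step is `dt = 0.1 ms`; the
noise-free suprathreshold ISI matches the closed form
`tau_m · ln(mu/(mu − (V_thresh − V_rest)))` to better than 0.5% at this
step, and halving `dt` changes no qualitative outcome (enforced by tests).

### Plasticity

Only E→E synapses are plastic, under the pair-based STDP window

    dw(dt) =  a_plus  · exp(-(dt - d)/tau_plus),  dt > d
    dw(dt) = -a_minus · exp( (dt - d)/tau_minus), dt < d

with `dt = t_post − t_pre` and hard bounds `[0, w_max]`, `w_max = 2 mV`.
Unshifted windows (`d = 0`) use all-to-all spike pairing, implemented
online with exponentially decaying pre/post traces; shifted windows use
nearest-neighbor pairing via last-spike-time registers (the reduced
symmetric scheme: each spike pairs with the most recent opposite-train
spike at or before it, coincident pairs counted once).  Both online paths
reproduce offline accumulation of the window over the recorded raster to
float precision (tested).  Two conventions close gaps the window formula
leaves open: `dt = d` is assigned the potentiation amplitude for a shifted
window, and exactly-coincident spikes contribute zero under an unshifted
window (preserving the odd symmetry of the balanced rule).

### Regimes

Five shipped parameterizations, all with `tau_plus = tau_minus = 20 ms` and
reference amplitude `A0 = 0.005 mV` (0.25% of the weight range per maximal
pairing):

| regime | amplitudes | shift | pairing |
|---|---|---|---|
| balanced | `a+ = a- = A0` | 0 | all-to-all |
| potentiation_dominant | `a+ = 1.012·A0` | 0 | all-to-all |
| depression_dominant | `a- = 1.012·A0` | 0 | all-to-all |
| rightward_shifted | `a+ = A0, a- = 0.568·A0` | +10 ms | nearest-neighbor |
| leftward_shifted | `a+ = 0.568·A0, a- = A0` | −10 ms | nearest-neighbor |

Two of these numbers are derived rather than free.  The rightward
depression amplitude `0.568·A0` is fixed by requiring the chance-pairing
drift (gamma, below) to change sign at a 40 Hz baseline rate — the upper
edge of the homeostatic band — given `tau = 20 ms` and `d = 10 ms`; the
leftward window is its mirror image.  The 1.2% amplitude tip of the
dominant regimes is the largest perturbation for which the pair phase
plane retains all three basins of attraction at both 20 and 50 Hz: the tip
sets the chance drift gamma ∝ (a+·tau+ − a-·tau-), and when gamma exceeds
`beta·w_max` the unidirectional attractors are washed out and every pair
potentiates, which is a different (and uninteresting) regime.

## Pairwise drift model

For a reciprocal pair extracted from the network, with baseline rates
`r1, r2` imposed by background drive, the average drift of the weights is
linear on the bounded square:

    dw12/dt = alpha·w12 − beta·w21 + gamma   (and the mirror equation)

* `gamma` — chance pairings of the baseline trains: the window integrated
  against the flat cross-correlogram floor `r1·r2`.  For nearest-neighbor
  pairing each backward look-up survives only while no intervening partner
  spike occurs, attenuating the effective window by `exp(−r_partner·|s|)`
  (Poisson survival); this makes gamma rate-dependent and produces the
  sign change that caps the homeostatic band.
* `alpha` — potentiation earned from the causal bump the synapse induces
  in its own postsynaptic neuron.  The bump is modelled as
  `w · c0 · g(r) · tau_s · k(s)` extra spikes, where `g(r)` is the slope of
  the LIF transfer function (Siegert first-passage formula for the
  white-noise-driven LIF, inverted numerically for the operating bias) and
  `k(s)` a normalized double exponential with decay `tau_s = 5 ms` and rise
  1 ms.  The kernel shape was not assumed: conditional-rate histograms of
  the simulated pair show the bump rising within ~1 ms of the presynaptic
  spike and decaying with the synaptic time constant — in the
  fluctuation-driven regime the firing rate tracks the synaptic current,
  not the membrane time constant.  A membrane-filtered kernel (decay
  `tau_m = 20 ms`) was tried first and discarded: it puts almost no mass
  inside a 10 ms depression notch, and with it no shifted-window
  parameterization has a stable fixed point at any rate.
* `beta` — depression inflicted by the reciprocal synapse's bump, the same
  integral on the acausal side.

`c0 = 0.66` is the single dimensionless calibration constant of the model,
measured once by `calibrate_bump_gain`: with a balanced window
(gamma = 0 exactly) and only `w12` nonzero, the simulated drift of `w12`
is purely `alpha·w12`, and `c0` is the ratio of the measured to the
modelled `alpha`.  It is not re-fit per regime or per rate.  The
measured-to-model agreement is then enforced by an oracle test: on a 3×3
grid of frozen weight pairs, for all five regimes at 20 Hz, simulated
drifts match predictions within 3 Monte Carlo standard errors.

Fixed points of the linear system are classified by the Jacobian
`[[alpha, −beta], [−beta, alpha]]` (eigenvectors along the diagonal and
anti-diagonal, eigenvalues `alpha − beta` and `alpha + beta`); a singular,
consistent system yields the line of equilibria of the balanced regime
(tilted line obtained numerically from the null space when `r1 ≠ r2`).
Phase portraits integrate the clipped drift field (components pointing out
of the square are projected to zero) from each grid-cell center with a
fixed step resolving the fastest eigen-timescale; endpoints are matched to
corner/interior attractors within 3% of `w_max`, or to the equilibrium
line; non-settling cells are counted as unresolved, never silently
dropped.

Important property used throughout: the *signs* of `alpha ± beta` and
`gamma` — hence the band edges reported by `rate_scan` — do not depend on
`c0` or `g(r)` (common positive factors for symmetric rates).  The
quantitative location of interior fixed points does.

## The pair Monte Carlo

`simulate_pair` drives two LIF neurons with reciprocal synapses, each
receiving constant bias plus white noise (`sigma = 50 mV·ms^1/2`,
chosen so ISI CV ≈ 1 at 10–20 Hz) — the diffusion limit of the
independent-Poisson network background, i.e. the same drive form the full
network model uses.  The bias per neuron is calibrated by bisection on
short simulations so realized baseline rates match the requested ones.
STDP updates are bookkept but never applied (weights frozen), so the
measurement is the instantaneous drift at a chosen point of the weight
square; standard errors come from batch means over 20 equal segments.

Known accuracy limits, measured during development: at rates ≳ 40 Hz the
LIF trains become sub-Poisson (CV ≈ 0.9), the nearest-neighbor look-back
distribution flattens relative to the exponential survival model, and the
shifted-regime drift predictions acquire an O(30%) bias (signs and zero
crossings survive).  Even at 20 Hz, regressing the measured drift field on
(w12, w21) shows the shifted-window bump coefficients reproduced only to
~15–20% and mild nonlinearity near the corners of the weight square, where
a 2 mV synapse is 20% of the threshold gap and linear response is
strained.  The oracle test therefore pins the model at the 20 Hz operating
point and at Monte Carlo precision (500 s per grid point) commensurate
with that validity; it is a consistency check of the linearization, not a
claim of exactness.

## Graph statistics

The weight matrix is binarized at a threshold (default: mean off-diagonal
weight, with a relative float tolerance so an all-equal matrix thresholded
at its own mean is fully connected); loops of length L are closed directed
walks, `trace(A**L)`, computed in int64 with an exact big-integer fallback
beyond the float53 safety bound (`n**(L−1) ≥ 2^53`).  The null model
permutes the off-diagonal entries uniformly (diagonal pinned at zero),
preserving the weight multiset exactly; ratios are observed counts over
the mean shuffled count, the recurrence index aggregates lengths 2–9, and
lengths with zero mean null count are flagged undefined rather than
divided.  Hub analysis regresses per-neuron above-threshold in-degree on
out-degree by ordinary least squares; a zero-variance out-degree leaves
the slope undefined (`None`).

## Experiment scale and durations

Network experiments default to scale 0.4 (200 E + 200 I), plasticity
amplitudes multiplied by `lr_scale = 8` (2% of the weight range per
maximal pairing), and 150–250 s of model time — sizes at which every
steady-state statistic reported by the acceptance pipeline has converged
(verified by the built-in steady-state detector: trailing-window relative
drifts of rate, mean weight and weight variance below 5%).  The scale
factor and convergence verdicts are recorded in every report.  `lr_scale`
multiplies both window amplitudes equally, so it rescales time in the
drift equations without moving fixed points or basin boundaries; what it
does change is the drift-to-diffusion ratio of individual weight
trajectories (diffusion per unit model time grows with the amplitude), see
limitations.

Bias calibration brackets and bisects the external input against probe
simulations with frozen plasticity and a fixed probe seed, making the
result deterministic; the heterogeneous-drive experiment extends this with
a per-group relaxation loop (measured group rate vs target, gain estimated
on the fly).

## What the synthetic layer does and does not emulate

All inputs are generated internally: Poisson background trains, Gaussian
white-noise drive, uniform random weight matrices, and planted-cycle
graphs with known ground truth for the loop-census oracle.  The generators
reproduce the statistical assumptions of the analysis (independent
homogeneous Poisson background, uncorrelated baseline trains, uniform
initial weights).  They do not emulate: structured external correlations,
conduction-delay distributions, sparse or distance-dependent connectivity,
or weight-dependent (soft-bound) plasticity.  Passing tests therefore
validate the internal consistency of simulator, reduced model and graph
statistics under these idealized conditions, not the biological generality
of the conclusions.

## Known limitations

* **Desk-scale diffusion.** With `lr_scale = 8` at scale 0.4, single-pair
  weight diffusion is strong relative to the 1.2% amplitude tip of the
  dominant regimes.  The balanced-regime structure (reciprocal-loop
  elimination, hub slope −1, mean weight at mid-range) is robust, and the
  orderings between regimes survive (potentiation-dominant networks
  eliminate far fewer reciprocal pairs than balanced ones and depress
  more disconnected pairs when depression dominates), but the
  potentiation-dominant network does not reach net loop *generation*
  (recurrence index > 1) at this scale; that requires a smaller effective
  amplitude and correspondingly longer runs than the desk budget.
* **Network homeostatic band.** The rightward-shifted network buffers
  steady-state rates below the predicted 40 Hz ceiling for all drives
  tested (10–50 Hz initial), but settles lower (≈ 14–21 Hz at desk scale)
  than the pair model's stable band (≈ 37–40 Hz): hard upper bounds cap
  the recurrent excitation a scaled network can recruit, and network
  trains at high rates are sub-Poisson.  The upper-bound claim is the one
  the model makes sharply, and it is the one tested.
* **Leftward shift at high drive** produces runaway potentiation and
  pathologically high rates by design; such runs can exhaust the spike
  record and are flagged per cell rather than aborting an experiment grid.
* The Siegert transfer function ignores the synaptic filtering of the
  recurrent input when used inside the network context; it is only used
  for the pair model's gain, where the background really is white.
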