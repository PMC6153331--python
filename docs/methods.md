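# Methods

## Problem and model

A single leaky integrate-and-fire (LIF) neuron receives spikes from N
afferents, each firing as an independent homogeneous Poisson process at
rate f (Hz).  P spatiotemporal spike patterns of duration L (ms) are
single frozen realizations of that same process, replayed over and over;
at each presentation every spike is shifted by an independent uniform
jitter in [−T, T].  Because the patterns have the same first-order
statistics as the background, only their repetition makes them
detectable: the detector must exploit the *coincidence structure* of the
frozen spikes.

The detector connects (with unit weight) the M afferents that fire at
least once during a chosen subsection of duration Δt ≤ L of at least one
pattern.  With instantaneous synapses the membrane obeys

    τ dV/dt = −V + τ Σ_i w_i δ(t − t_i),

so each input spike through weight w_i kicks V up by w_i.  Detector
quality is the signal-to-noise ratio

    SNR = (V_max − V̄_noise) / σ_noise,

with V_max the peak potential during a presentation and (V̄_noise,
σ_noise) the stationary moments of the potential under pure Poisson
drive.

## Closed forms (`spikesnr.theory`)

With unit weights on M connected afferents the potential is a shot-noise
process, giving V̄_noise = τfM and σ_noise = √(τfM/2) (τ in seconds
against f in Hz).  The peak is expressed through the reduced variable
v_max = (V_max − V̄_noise)/(V̄_∞ − V̄_noise) ∈ [0, 1], where V̄_∞ = τr is
the steady state an infinitely long subsection would reach and r the
input rate during the window.  Exact integration over the uniform jitter
yields

    v_max = min(1, Δt/2T) − (τ/2T) · log(1 − e^{−max(Δt,2T)/τ} + e^{−|Δt−2T|/τ}),

which degenerates to the LIF charging curve 1 − e^{−Δt/τ} as T → 0 (the
implementation switches to that limit below T = 10⁻⁶ ms and uses
`expm1`/`log` guards elsewhere; the branch point Δt = 2T is continuous).

Counting statistics close the formula.  An afferent fires in one Δt
window with probability 1 − e^{−fΔt}; for P independent patterns
(chance-level overlap) the expected connected count is
⟨M⟩ = N(1 − e^{−PfΔt}), and the expected in-window input rate is
⟨r⟩ = fN.  The expected SNR is approximated by the plug-in value

    ⟨SNR⟩ ≈ v_max · √(2τ/f) · (⟨r⟩ − f⟨M⟩)/√⟨M⟩,

an approximation validated numerically by `reduced_snr_sample`
(sampled mean of (r − fM)/√M within 2% of the plug-in value at
P = 1, Δt = 2 ms, f = 1 Hz, 10⁵ draws; the per-realization spread has
coefficient of variation ≈ 0.11).

### Optimization

P, L, N, f, T are imposed; τ and Δt are free.  `optimize_snr` maximizes
⟨SNR⟩ subject to τf⟨M⟩ ≥ 10, the regime in which V is approximately
Gaussian and the SNR is a meaningful false-alarm proxy; Δt ≤ L is
enforced by default (inactive whenever L is large).  The surface is
smooth but can pin at the constraint, so the implementation scans a
coarse log-spaced grid, refines the best starts with SLSQP in log
coordinates (ftol 10⁻¹²), and reports whether the constraint is active
at the optimum (|τf⟨M⟩ − 10| within 0.1%).  A 500×500 log-spaced grid
search is used as the independent oracle in tests.

## Synthetic inputs (`spikesnr.patterns`)

The generator emulates the study conditions exactly: frozen Poisson
patterns drawn once (each afferent's count in a pattern is
Poisson(fL)), presentations every 400 ms cycling through the P patterns,
fresh per-spike uniform jitter at each presentation, and fresh Poisson
noise at rate f between presentations.  During a presentation the frozen
pattern *replaces* background activity for all afferents, so the stream
has rate f everywhere.  Jittered spikes are not clipped to the pattern
window (clipping would distort edge statistics); spills beyond the
stream's ends are dropped.  Poisson blocks are sampled as a Poisson
total scattered uniformly over afferents and time — exactly equivalent
to N independent processes, but O(spikes) rather than O(N).

What the generator does *not* emulate: refractoriness, rate
inhomogeneity, correlated afferents, or irregular presentation
intervals.  Passing tests therefore certify the model under homogeneous
Poisson assumptions only.

## Neuron and plasticity (`spikesnr.neuron`)

Forward Euler with a 0.1 ms bin.  Within a bin: membrane decay by
(1 − dt/τ), input jumps, threshold decay toward θ0 with τ_θ = 80 ms,
trace update, threshold test.  At an output spike: LTP, then LTD, then
V ← 0 and θ ← θ + 1.8·θ0.  The reset-to-zero is our choice where the
model description is silent (the adaptive threshold, not the reset, is
the anti-burst mechanism); it is configurable
(`NeuronConfig.reset_potential`) and there is no refractory period.

STDP is all-to-all with soft bounds.  The presynaptic trace A_pre_i
gains δA_pre = 0.1 per spike of afferent i and decays with
τ_pre = 20 ms (decay applied exactly, the trace ODE being linear).  At
each output spike w_i ← w_i + w_i(1 − w_i)A_pre_i followed by the
homeostatic depression w_i ← w_i + w_i(1 − w_i)w^out, w^out < 0.  The
w(1 − w) factor keeps weights in [0, 1] and drives them to the binary
fixed points, so learning converges by saturation.

Initial weights are uniform at w₀ = θ0/(τfN − √(τfN/2)), placing the
initial noise-potential mean one standard deviation above threshold
(initial output rate ≈ 4 Hz at the reference parameters).

Two simulation paths exist on purpose: `run_reference` is a plain
per-bin loop that *defines* the semantics; `LIFNeuron.run` evaluates the
linear membrane recurrence with an IIR filter between output spikes,
decays the threshold in closed form, and syncs the trace lazily at
output spikes.  Tests assert bin-for-bin equality of spikes, potential
and weights between the two.  Long runs are streamed in ~80 s segments
(whole presentation cycles) with state carried across, bounding memory.

## Experiments and evaluation (`spikesnr.experiments`)

`validate_snr_montecarlo` replays the measurement protocol on a
threshold-free neuron: per pattern draw, connect the afferents firing in
the first Δt of any pattern, present each pattern repeatedly, take
V_max as the mean over presentations of the peak in
[onset, onset + Δt + T], and estimate the noise moments outside
[onset − T, offset + T + 7τ].  The pre-onset margin matters: jitter
moves pattern spikes up to T before the onset, and without the margin
σ_noise is inflated by ~15%, biasing the empirical SNR well below
theory.  Simulation is restricted to connected afferents (others cannot
affect V).

`run_learning` runs the full learning protocol; `evaluate` scores the
final 10% of the run: a presentation is *hit* if an output spike lands
in [onset, onset + L + T]; spikes outside all such windows are false
alarms; a pattern is *learned* if its epoch hit rate exceeds 90% (the
cutoff is configurable — the aggregate ⟨P_learned⟩ is reported without a
published definition).  A run is *optimal* when every pattern is
learned, the potentiated count (w > 0.5) matches the optimal ⟨M⟩ within
5% (10% in the scaled acceptance check), and each pattern opens with a
stretch whose every spike maps to a potentiated synapse (STDP tracks
back to pattern beginnings, so this is where the learned signature
lives).

`hyperparameter_search` scans θ0 × w^out (geometric grids, ratio
~1.025 in the full protocol) and reports the optimal fraction per cell;
pilot scans place the best θ0 at ≈ 0.95–1.0 times the theoretical
optimal peak V̄_noise + v_max(V̄_∞ − V̄_noise) and w^out a few 10⁻³ in
magnitude.  `table1_simulation_row` aggregates ⟨P_learned⟩, hit rate,
false alarms and P(optimal) per pattern count; its defaults are the full
protocol (100 repeats × 12,000 s at N = 10⁴, days of CPU), and tests
exercise it at reduced scale only.

## Problem sizes used in the test suite

Analytic checks run at the full N = 10⁴ reference point (they are
closed-form).  Simulation checks are scaled as the package's own desk
protocol: the Monte-Carlo SNR validation uses 20 pattern draws × 200
presentations (P ∈ {1, 5}, L = Δt = 20 ms, f = 5 Hz, T = 5 ms, τ =
10 ms); the plug-in-approximation check uses 10⁵ draws; the STDP
acceptance check uses N = 2500, P = 2, 3,000 s of simulated time with a
six-cell (θ0, w^out) search, matching the search the full protocol
prescribes.  The convergence index (mean distance of weights to their
binary quantization) falls below 0.01 well before 3,000 s at this
scale.

## Known limitations

* The plug-in SNR is an expectation over pattern realizations; single
  frozen patterns deviate by a few percent (CV ≈ 0.1 at small
  parameters), so occasional scaled learning runs land outside the 5%
  potentiated-count margin — the same sub-optimality mode the full
  protocol quantifies with its P(optimal) column.
* Euler integration at 0.1 ms bins shortens the effective τ by
  ~0.5% (dt/2τ); all empirical-vs-theory tests carry tolerances well
  above this.
* The theory ignores the threshold; with the adaptive threshold the
  optimal V_max is never actually reached, and θ0 must sit slightly
  below it for one-spike-per-presentation behaviour.
* Graded (non-binary) weights, synfire-chain comparisons, multi-neuron
  readout and reward modulation are out of scope.
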