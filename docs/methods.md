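# Methods

## The model family

`qiffre` studies how a single population of recurrently coupled
inhibitory neurons generates fast ("interneuronal gamma", ING)
oscillations, at three levels of description that are kept strictly
consistent with one another.

**Microscopic level.** N all-to-all coupled quadratic
integrate-and-fire (QIF) neurons,

    tau_m dV_i/dt = V_i^2 + eta_i - J tau_m S,

with quenched input currents eta_i drawn from a Lorentzian (Cauchy)
density of center Θ and half-width Δ.  A neuron that reaches +V_θ is
held for a refractory period 2 tau_m/V_θ and re-enters at −V_θ, which
approximates the excursion of the unbounded quadratic trajectory
through infinity; with V_θ = 100 the residual period error of a single
neuron is below 10⁻⁵ relative.  All neurons share one synaptic gating
variable with first-order kinetics, tau_d dS/dt = −S + R, driven by the
instantaneous population rate.

**Macroscopic level.** In the thermodynamic limit the Lorentzian
ansatz closes the population dynamics exactly in three variables — rate
R, mean voltage V, gating S:

    tau_m dR/dt = Δ/(π tau_m) + 2 R V
    tau_m dV/dt = V² − (π tau_m R)² − J tau_m S + Θ
    tau_d dS/dt = −S + R

The R–V interplay encodes spike synchrony: a depolarizing transient
raises R through the bilinear term, the (π tau_m R)² reset term then
hyperpolarizes V, and this latency acts as an effective delay that fast
recurrent inhibition can convert into a sustained collective rhythm.

**Heuristic level.** The Wilson-Cowan-type rate model
tau_m dR/dt = −R + Φ(−J tau_m S + Θ) with the same synaptic equation,
where Φ is the stationary population f-I curve

    Φ(I) = (1/(π tau_m)) sqrt((I + sqrt(I² + Δ²))/2).

Its fixed point coincides with the exact model's, but its eigenvalues
λ = −α(1 ± √(1−β)) have strictly negative real part for any increasing
Φ, so it can never sustain the rhythm — the central dichotomy the
package reproduces.  In the slow-synapse limit tau_d ≫ tau_m both
models collapse onto the scalar flow tau_d dS/dt = −S + Φ(−J tau_m S + Θ)
with the algebraic readout R*(S); this reduction is exposed as its own
model variant because its breakdown under fast drive is itself a result.

## Reduced parameters and stability machinery

For Θ > 0 the exact model nondimensionalizes to three parameters:
j = J/√Θ, δ = Δ/Θ, τ = √Θ tau_d/tau_m, with time measured in units of
tau_m/√Θ (the most-likely intrinsic period is T̄ = π tau_m/√Θ; 15.71 ms
for tau_m = 10 ms, Θ = 4).  The printed rendering of this reduction in
the source material is typographically damaged; the mapping used here
was fixed by requiring that the reduced system is the *exact image* of
the dimensional one under the change of variables, and the test suite
enforces that invariant by integrating both systems and mapping the
trajectories onto each other pointwise.

The fixed point satisfies 0 = v*² − π²r*² − j r* + 1 with
v* = −δ/(2π r*), solved by bracketed root finding (the residual is kept
below 10⁻¹²; for δ = 0 the closed form is used).  Perturbation growth
rates solve

    −2 j r* = (1 + λτ)[(2π r*)² + (λ − 2v*)²],

expanded into a cubic whose roots are computed from the companion
matrix and cross-checked, in tests, against the numerical eigenvalues of
the 3×3 Jacobian (agreement to 10⁻⁸ over random parameter triples).
Setting λ = iω and eliminating ω yields a quadratic in τ whose real
positive roots τ±(r*) are the two Hopf branches; together with
j(r*) = (v*²+1)/r* − π²r* they trace the marginal curve parametrically.
Because j(r*) is strictly decreasing, point-in-region queries reduce to
one bracketed inversion plus a branch comparison.  The branches merge
where the discriminant vanishes; solving that condition for the
heterogeneity gives δ*(r*), and its interior maximum defines the
critical heterogeneity δ_c ≈ 0.14531 at r*_c ≈ 0.15052, above which no
oscillation survives at any (j, τ).  All of the legible anchors (zeros
of δ* at 0 and 1/π, the region geometry, δ_c, r*_c) are used as
validation, never as sources of coefficients.

## Conductance-based cross-check

The Wang-Buzsáki interneuron (spiking Na⁺/K⁺ currents, instantaneous
m∞, gating rates scaled by φ = 5) is simulated with Euler stepping at
dt = 0.001 ms, spike times taken from linearly interpolated upward
0 mV crossings, and the same shared first-order synapse injected as the
current I_syn = k C_m S.  The leak reversal is E_L = −65 mV, the value
of the original interneuron model; it is validated rather than assumed,
since with it the rheobase found by bisection is 0.1605 μA/cm², matching
the published SNIC offset 0.1601 μA/cm² well inside the bisection
tolerance.  The removable singularities of α_m at −35 mV and α_n at
−34 mV are replaced by their analytic limits (1 and 0.1 per ms).

The rheobase search brackets the constant current in [0, 1] μA/cm² and
bisects on "at least two spikes in a 2 s probe after a 0.5 s discard"
to a tolerance of 10⁻⁴.  The probe is long compared to the arbitrarily
slow firing near a saddle-node-on-invariant-circle bifurcation, so the
tolerance, not the probe length, limits the result; the square-root
scaling of the firing rate just above threshold is verified separately.

Initial network voltages form a deterministic Lorentzian quantile grid
(half-width 5 mV around −62 mV) clipped to [E_K, E_Na]: the raw
Lorentzian tails would place membrane potentials thousands of mV from
rest, which is unphysical and overflows the gating exponentials.

## Estimators and measurement protocols

* **Population rate**: trailing-window spike count over τ_s divided by
  N τ_s.  The gating variable is always driven by the per-step
  instantaneous rate; τ_s only affects the reported channel.  Defaults:
  τ_s = 10⁻² tau_m for the QIF network and 10⁻² ms for the
  conductance-based network, with 2 ms (and 3·10⁻² tau_m) smoothing
  variants for display and for comparisons.
* **Oscillation amplitude**: mean over five 200 ms windows of the
  in-window max − min after a 1000 ms transient (reduced-scale variants
  state their windows explicitly).
* **Oscillation frequency**: mean inter-peak interval with a peak
  prominence floor of 5 % of the post-transient range, which rejects
  finite-size ripple in network rate estimates.
* **Model distance**: symmetric relative L2,
  ‖a−b‖ / (½(‖a‖+‖b‖)), on a common post-transient grid.

When a network rate estimate is compared against a mean-field
trajectory, the mean-field rate is passed through the *same* trailing
window first, so the filter delay and bandwidth cancel instead of
contaminating the distance.

## Problem sizes and numerical choices

* Mean-field integration: classical fixed-step RK4 with dt = tau_m/100
  by default.  Fixed step keeps reruns bit-identical; the gamma-band
  frequency of the reference oscillation changes by < 0.1 % under dt
  halving.
* QIF network: Euler with dt = 10⁻³ tau_m (validated by dt halving:
  peak times of the collective oscillation move by < 0.05 ms per cycle).
  The micro–macro agreement test runs the full published network size
  N = 5·10⁴ for 160 ms per regime and compares rate and gating channels
  over 10–150 ms with a matched 2 ms filter; at this size both channels
  agree with the mean-field trajectories to better than 10 % relative
  L2 in both synaptic regimes.  The residual discrepancy is a slow
  phase drift: the finite network oscillates ~0.2 % faster than its
  thermodynamic limit, so the relative L2 grows roughly linearly with
  the comparison span — which is why smaller networks (e.g. N = 5000,
  drift ~0.7 %) leave the 10 % band even though their amplitude and
  frequency are correct to a few percent.
* Conductance-based phase diagram: the full protocol (N = 1000, 6×6
  grid, 1 s transient + 1 s measurement per cell, two sweep directions)
  is available through the `sweep` command and the `fig5_*` presets.
  The shipped regression test uses a 4×4 grid at N = 300 with 200 ms
  transient + four 100 ms windows and continuation in k, which resolves
  the qualitative fragility result: many cells above a 10 mV mean-V
  amplitude threshold at δ = 0, strictly fewer at δ = 0.05, none at
  δ = 0.06.  At this reduced scale the surviving δ = 0.05 region is
  already below the amplitude threshold (longer probes at N = 1000 show
  only a weak ~5 mV remnant near tau_d ≈ 20 ms, k ≈ 10 mV), so the
  desk-scale check demonstrates shrinkage-to-vanishing rather than the
  precise 6 % critical value, which requires cluster-scale averaging.
* Periodic-drive comparison: the three presets use forcing periods
  1000, 100 and 20 ms (slow / comparable-to-tau_d / comparable-to-tau_m);
  the source figure does not print its periods, so these were chosen
  once to span the three regimes and are not calibrated further.

## What the generator does and does not emulate

The synthetic study conditions are exactly the published ones:
deterministic Lorentzian quantile grids for quenched currents (no
sampling noise, no finite-moment tails), all-to-all coupling with a
single shared gating variable, no conduction delays, no dynamic noise,
and current-based (not conductance-based) synapses in both spiking
models.  Passing tests therefore say nothing about sparse connectivity,
noise-driven (sparsely synchronized) regimes, synaptic reversal
effects, or Class 2 membranes — all outside this package's scope.

## Known limitations

* The mean voltage channel of the QIF network excludes refractory
  neurons; it is an observable convenience, not part of the exact
  correspondence, and is not used in quantitative comparisons.
* `identical_growth_rate` is a first-order expansion about the neutral
  pair; it degrades, as it should, once J τ is no longer small.
* Hysteresis of the conductance-based network at strong coupling is
  exposed by the two sweep directions but deliberately not asserted in
  tests: at desk scale the classification is reproducible, while the
  bistable slivers require the full protocol.
* The Hopf classification is linear only: no normal form, no
  continuation of the limit cycle itself.
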