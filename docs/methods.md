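# Methods

## The gating model

Channel gating is a reversible continuous-time Markov chain. Transition
rates follow a single-barrier exponential voltage dependence,
k(V) = k₀·exp(k₁·V), with k₀ in s⁻¹ at 0 mV and k₁ in mV⁻¹ (0 for
voltage-independent steps). The shipped 6-state scheme represents
voltage-dependent potentiation (VDP) as two gating modes:

```
normal:       C1  ⇌α/β  C2   ⇌γ/δ   O1
                 mode link (detailed balance)   ⇅ ε/ε_r
potentiated:  C1p ⇌α/β  C2p  ⇌ο/κ   O2
```

* α: k₀ = 80 s⁻¹, k₁ = 0.025 mV⁻¹; β: k₀ = 600 s⁻¹, k₁ = −0.025 mV⁻¹ —
  the shared voltage-sensing step of both tiers.
* γ = 60 / δ = 200 s⁻¹ — the normal, weakly favourable opening step
  (K = 0.3), giving a high activation midpoint.
* ο = 5000 / κ = 70 s⁻¹ — the potentiated opening step (K ≈ 71), ~240-fold
  more favourable, giving the left-shifted midpoint and slower deactivation
  (O2 closes at ~κ⁻¹ ≈ 14 ms vs O1 at ~δ⁻¹ ≈ 5 ms).
* ε = 35 s⁻¹ — the slow O1→O2 mode shift.

Because the opening equilibria of the two tiers differ, thermodynamics fixes
the ratio of the closed-tier mode link once the open-tier link is chosen:
K(C1→C1p) = (γ/δ)·(ε/ε_r)·(κ/ο), so the closed-state mode shift is ~240-fold
less favourable than the open-state one. That asymmetry is the whole
mechanism: channels reach the potentiated mode almost exclusively through
the open state, which makes the mode shift voltage dependent and couples it
to activation.

Two rates are not fixed by the forward parameter set and are package
defaults, not literature values: the reverse mode shift ε_r = 2 s⁻¹ and the
closed-tier reverse link C1p→C1 = 7.2 s⁻¹ (the forward link, 0.529 s⁻¹,
then follows from detailed balance). They were chosen once so that recovery
from potentiation at −100 mV relaxes with τ ≈ 136 ms, the experimental
recovery time constant; both are overridable in the YAML config or through
`GatingScheme.with_rate`.

### Propagation

Voltage protocols are ordered constant-voltage epochs, so within each epoch
the master equation dp/dt = Q(V)p has the exact solution
p(t) = expm(Q·t)·p₀. The propagator advances sample-by-sample with a
precomputed expm(Q·Δt) and jumps exactly to each epoch boundary with
expm(Q·dur), so there is no ODE truncation error; the suite checks agreement
with an adaptive LSODA integration to < 10⁻⁶ and probability conservation to
< 10⁻⁹. Each sweep of a protocol family starts from the stationary
distribution (Q null vector) at the holding voltage, mimicking steady
holding. Default sampling interval 0.1 ms.

Validation enforces reversibility (every edge has a reverse edge), graph
connectivity, rejection of duplicate edges and zero-duration epochs, and
detailed balance (cycle products of equilibrium-constant ratios equal 1,
checked via the cycle basis of the scheme graph).

## Electrophysiological analyses

* **Exponential fits**: offset + Σ aᵢ·exp(−(t−t₀)/τᵢ) with t₀ the window
  start (translation invariant). Time constants are seeded from log-spaced
  fractions of the window; for each seed the offset/amplitudes are solved
  linearly before joint trust-region refinement (tolerances 10⁻¹⁴), and the
  best fit is kept with components ordered τ₁ ≤ τ₂. Constant traces are
  flagged degenerate rather than failed.
* **Instantaneous tails**: the first post-step sample is skipped (the
  capacitive-transient convention — "instantaneous" would otherwise be
  sampling-rate dependent), a 3-component exponential is fitted over 60 ms
  of tail and back-extrapolated to the step time. Three components are used
  internally because the 6-state scheme's tail relaxation contains a
  sub-millisecond tier component on top of the two open-state decays;
  against occupancy ground truth the extrapolation is accurate to < 0.5%.
* **G–V curves**: one tail amplitude per test voltage at a common tail
  voltage (−100 mV); magnitudes by default (inward tails), raw and
  normalised forms both available since prepulses change I_max as well as
  V₁/₂.
* **Boltzmann fits**: least squares on
  I = I_min + (I_max − I_min)/(1 + exp[(V₁/₂ − V)/V_s]) with V_s > 0
  enforced; midpoints outside the sampled range are flagged extrapolated
  (> 50 mV outside: unreliable). Energetics use ΔG = RT·V₁/₂/V_s with
  R = 8.314 J mol⁻¹ K⁻¹ and T = 295 K by default (room-temperature
  recordings); ΔΔG(prepulse) = ΔG(after) − ΔG(before).
* **Recovery courses**: V₁/₂ (or tail amplitude) vs recovery duration fitted
  with y_inf + (y₀ − y_inf)·exp(−t/τ); non-monotone courses beyond what the
  fitted amplitude explains are flagged, not rejected.
* The slope factor V_s is never constrained by the gating data used here;
  synthetic G–V defaults use V_s = 12 mV, a typical delayed-rectifier value.

## tmFRET analysis

Quenching of the donor by the dihistidine-bound metal is treated as kinetic
competition between photon emission (k_ph), transfer to the bound metal
(k_HH) and nonspecific relaxation (k_no). The forward model
E = k_HH/(k_ph+k_HH), F_noHH = k_ph/(k_ph+k_no),
F_HH = k_ph/(k_ph+k_HH+k_no) is implemented separately from the corrected
estimator E = (F_noHH − F_HH)/(F_HH·F_noHH + F_noHH − F_HH), and the suite
verifies the inversion to < 10⁻¹² on randomized rate triplets. The corrected
estimator is the default (the nonspecific quenching here is plausibly
collisional or FRET to an endogenous site); the simple estimator
E = 1 − F_HH/F_noHH is exposed for comparison and always underestimates
when k_no > 0, which is why the correction exists.

Titration analysis pairs each test concentration with the no-dihistidine
control (linear interpolation when the grids differ), computes corrected
efficiencies and fits the single-site Langmuir isotherm. Normalised
fluorescence up to 1.05 is accepted (clipping at exactly 1 would truncate
symmetric noise and bias efficiencies downward at low concentrations);
values above 1.05 warn and are clipped. Fits lacking saturation coverage
(max concentration < 5·K₁/₂) are flagged unreliable; flat titrations mark
K₁/₂ unidentifiable. Distances use R = R₀·(1/E − 1)^{1/6} with
R₀ = 12 Å for the L-Anap/Co²⁺-dihistidine pair (an input, not computed from
spectral overlap) and are reported to 0.1 Å.

## Synthetic data

Generators are the study-condition oracles for every fitter; at σ = 0 each
analysis returns its generating parameters to numerical tolerance
(generator/analyzer adjointness, enforced by the suite).

* **Currents**: exact simulations plus additive Gaussian noise; the
  "excised" preset locks channels in the potentiated mode (mode-reverse
  rates ~0), emulating patches that have lost VDP after excision, without
  modelling the underlying lipid chemistry.
* **Titrations**: fluorescence through the kinetic forward model with
  k_HH(c) set so corrected efficiencies follow a Langmuir curve
  (defaults E_max = 0.71, K₁/₂ = 66.1 µM without ATP; 0.46, 48.0 µM with
  ATP/Mg²⁺), a collisional k_no(c) ∝ c scaled so the control falls to 0.9
  at the 1 mM top of the 10/30/100/300/1000 µM ladder, and 3% multiplicative
  Gaussian noise as the default noisy condition (the experimental
  fluorescence SNR is unreported; this is a package assumption). Each
  titration has a single no-metal baseline draw — one patch, one baseline —
  while each concentration's quenched value gets an independent draw.
* **Fluorescence time courses**: mono-exponential relaxations between
  voltage-dependent levels (defaults τ = 261 ms development, 137.5 ms
  recovery), sampled as 100 ms frames with 50 ms exposure integration.
  Exposure averaging of an exponential rescales amplitudes but not time
  constants, so the fitted τ is unbiased; the suite checks < 5% bias for
  τ ≥ 3 frames.
* **G–V data, recovery courses, spectra**: exact functional forms plus
  seeded noise (additive σ quoted as a fraction of I_max for G–V data).

Identical seeds give bit-identical output; one RNG stream per dataset with
draws in a documented fixed order.

What the generators do *not* emulate: patch leak and capacitive currents,
channel inactivation above +60 mV, shot noise/camera artifacts, rundown and
patch-to-patch variability. Passing recovery tests therefore demonstrate the
estimators are correct and unbiased under the stated noise models, not that
they are robust to every artifact of real recordings.

## Problem sizes and numerical choices

The stochastic recovery experiments use 100 titration replicates per
condition and 50 G–V replicates, enough to pin the means well inside the
10%/1 mV acceptance bands. G–V families use 13 test voltages (−120…+120 mV,
20 mV steps) with 100 ms test pulses and 150 ms tails; the activation-
kinetics family uses 500 ms pulses so the slow component is resolved. All
nonlinear fits are trust-region least squares with multi-start
initialisation; ties in exponential components are broken by canonical τ
ordering.

## Known limitations

* The two mode-reverse rates are implementer defaults (see above); absolute
  magnitudes of simulated shifts (e.g. the −50.7 mV prepulse shift, the
  3.7-fold tail growth) therefore track the experimental phenomenology
  directionally rather than numerically.
* Conductance is an arbitrary scale (no absolute current calibration).
* Only step protocols are supported (no ramps/sinusoids), and no stochastic
  single-channel simulation is provided.
* R₀ is an input; spectral-overlap integration is out of scope.
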