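# Methods

## The kinetic model

`slowbind` analyses time-dependent ("slow-binding") enzyme inhibition of
the induced-fit type. The scheme is

```
E + I  <==[k+3, k-3]==>  EI  <==[k+4, k-4]==>  EI*
                                EI* --[k_acyl]--> acyl-E --[k_react]--> E + I
```

A fast, reversible encounter complex EI (initial inhibition constant
K_i = k-3/k+3) isomerizes slowly to a tightened complex EI*. With an
excess of inhibitor over enzyme, product accumulation in a continuous
assay follows the integrated slow-onset law

    P(t) = v_ss t + (v_i - v_ss)(1 - e^(-k_obs t)) / k_obs,

where v_i is the velocity after the fast step has equilibrated, v_ss the
steady-state velocity once the isomerization has too, and 1/k_obs the lag
time. For the induced-fit ("type B") mechanism the onset rate saturates in
inhibitor,

    k_obs = k-4 + k+4 [I] / ( K_i (1 + [S]/K_m) + [I] ),

with intercept k-4, asymptote k-4 + k+4, and a competitive-substrate
protection factor (1 + [S]/K_m). A one-step slow binder ("type A") instead
gives a straight line in [I]. The steady-state constant, overall off-rate,
residence time, dissociation half-time and target occupancy follow from the
elementary constants:

    K_i*  = K_i k-4/(k-4 + k+4)
    tau   = (k-3 + k+4 + k-4)/(k-3 k-4),   k_off = 1/tau,   t_1/2 = ln2/k_off
    FO    = [I]/([I] + K_i*)

The occupancy expression uses the steady-state constant, i.e. it describes
the fully equilibrated system; it is the quantity of pharmacological
interest for inhibitors whose residence time exceeds the fluctuation time
of the free-drug concentration.

The optional covalent extension (acylation of the catalytic serine from
EI*, slow deacylation regenerating free enzyme and releasing intact
inhibitor) produces the transient-inactivation / reactivation behaviour
seen with serine-hydrolase transition-state analogs. Deacylation is
modelled as regenerating E directly; routing recovery back through EI*
would be indistinguishable at the single-exponential resolution of
activity-recovery data and is not implemented.

Two-conformer ("hysteretic") covalent inactivation — an enzyme existing as
two slowly interconverting forms that react at different rates with a
phosphylating agent — is described at the residual-activity level by the
two-exponential law

    E(t) = E0_fast e^(-k_obs t) + E0_slow e^(-k'_obs t),
    k_obs = k_p [I]/(K_I + [I])  per phase.

## The simulator

`simulate_progress` integrates the full mass-action scheme with
`scipy.integrate.solve_ivp` (LSODA, rtol 1e-9, atol 1e-12·E0). No
pseudo-first-order assumption is made: inhibitor depletion by binding is
part of the state. Substrate turnover is carried as a Michaelis–Menten
flux, with the inhibitor-free enzyme pool partitioned between free enzyme
and the Michaelis complex in rapid equilibrium; only the free fraction
1/(1+S/K_m) binds inhibitor. This reproduces the closed-form velocity and
onset laws exactly in their regime of validity while keeping the state
small. Only the bound enzyme species and the substrate are integrated;
free enzyme and free inhibitor are recovered from the conserved totals, so
mass balances hold to floating-point roundoff by construction, and
negative concentrations or bound-exceeding-total states abort with an
error rather than being clipped.

Noise is additive Gaussian on the final signal, with standard deviation
configurable and, in the pipeline, defaulting to 0.3% of each trace's
signal range — a photometric noise floor proportional to the recorded
deflection. All noise is drawn from `numpy.random.default_rng(seed)` with
explicit seeds; identical spec and seed give bit-identical traces.

Two deliberate idealizations: dilution in reactivation experiments is
instantaneous and perfect (no mixing dead time), and the signal conversion
is a pure Beer–Lambert gain (extinction coefficient × path length) with no
instrument drift.

### Default study conditions

The defaults encode the reference experiment: enzyme at 1e-10 M, substrate
at 0.1/0.5/1 mM with K_m defaulting to 0.1 mM (a configuration value — the
workflow does not measure it, and everything depending on it is tagged
"assumed" in reports), inhibitor spanning 0.1–50 nM over a 60-min window
sampled at 0.25-min intervals, extinction coefficient 13,600 M⁻¹cm⁻¹ and a
1-cm path. Generating constants: K_i = 5.15 nM, k+4 = 0.456 min⁻¹,
k-4 = 0.054 min⁻¹, and an association rate k+3 = 3e9 M⁻¹min⁻¹ — the one
constant the analysis itself must assume, since the initial binding step is
too fast to resolve.

The turnover number is not part of the analysed constants and only sets
the signal scale; its default (200 min⁻¹) is chosen so the uninhibited
control converts under ~6% of substrate over the window, keeping the whole
grid inside the linear-assay regime that the closed-form laws assume. At
much higher turnover, substrate depletion masquerades as slow-onset
curvature in weakly inhibited traces and biases k_obs — a real assay
artifact the simulator will happily reproduce if configured to.

### What the generator does not emulate

Real Ellman-type data additionally contain instrument drift, correlated
(non-white) noise, mixing dead time, occasional outliers and temperature
fluctuations. Passing recovery tests on this generator therefore
demonstrates the statistical identifiability of the constants under the
stated design and noise — not robustness to every laboratory artifact.

## Fitting stages

All nonlinear fits use `lmfit` (Levenberg–Marquardt) with weights 1/SE
where standard errors are available. Model selection throughout uses the
small-sample-corrected Akaike criterion (AICc) with a decision threshold
of 2: a richer model must improve AICc by at least 2, ties going to the
simpler model.

**Progress curves.** Initialization is derivative-free: v_i from the slope
of the first 10% of points, v_ss and the terminal-line intercept b from
the last 20%, k_obs = (v_i − v_ss)/b. Three nested candidates compete: a
lag-free line through the origin (returned as an explicit "no-lag" result,
the uninhibited-control case), the slow-onset law, and the slow-onset law
with a fitted baseline offset. The offset — standard practice in
progress-curve regression — absorbs blank offsets and the small product
burst left by the sub-resolution fast binding step, which the pure law
(pinned to P(0)=0) would otherwise convert into a few-percent bias in
k_obs. Traces shorter than 3/k_obs, or with v_ss > v_i (burst rather than
lag kinetics), are flagged, not rejected.

**Inhibition-type diagnosis.** The velocity grid is fitted to the four
nested variants of the general linear inhibition rate law, parameterized
by the inverse constants 1/K_ci and 1/K_ui so that the pure competitive
and uncompetitive limits are interior points (zero) rather than infinities.
The Dixon (1/v vs [I]) and Cornish-Bowden ([S]/v vs [I]) graphical
statistics — pairwise line intersections and a slope-difference
parallelism t-test at α = 0.05 — are computed independently; discordance
between the graphical verdict and the model selection is reported as a
warning and never silently resolved. Numerically parallel lines (relative
slope difference < 1e-6) contribute no intersection, and the Dixon
abscissa seeds the nonlinear fit only when it falls within two decades of
the inhibitor range.

**Secondary plot.** Each substrate series of (I, k_obs) values is fitted
to the saturating type-B law and the linear type-A alternative; the joint
AICc over all series decides the mechanism. A significantly negative
intercept is an error (the reverse isomerization rate must be positive);
absence of detectable curvature yields a type-A verdict with an explicit
"or undersampled" warning recommending a wider inhibitor range.
Per-substrate constants must agree within 3 pooled standard errors to be
averaged; both the unweighted and the inverse-variance pooled means are
reported, the unweighted one being primary.

**Biphasic inactivation.** Per trace, single- vs two-exponential nested
comparison; phases labelled fast/slow by rate, ties broken by amplitude; a
phase below 2% of the total amplitude demotes the trace to effectively
monophasic. Across ≥3 inactivator levels the phase rates are fitted to the
saturation hyperbola k_p[I]/(K_I+[I]).

**Reactivation.** A(t) = A∞ − (A∞ − A0)e^(−kt), with the plateau either
free or pinned to the uninhibited control; the classical log-slope
estimator (slope of ln(A∞ − A) vs t) is reported alongside. A trace whose
activity does not increase raises an explicit error.

## Numerical choices

- AICc comparisons floor the residual sum of squares at (1e-8 × data
  scale)² per point: noiseless fits converge to optimizer precision, not
  zero, and without the floor the selection would chase meaningless
  1e-12-level differences instead of resolving ties toward the simpler
  model.
- Rates are in min⁻¹, concentrations molar, throughout; file headers
  declare units explicitly.
- Absent (infinite) inhibition constants are represented as `None`
  (absent), never as a large number; classification logic branches on it.
- Per-trace seeds are derived from the run seed with
  `numpy.random.SeedSequence([seed, index])`, keeping every stream
  independent and the whole run reproducible from one integer.

## Known limitations

- The closed forms carry no tight-binding (Morrison) depletion
  correction; conditions with [I] approaching [E] are only handled by the
  ODE simulator.
- No global fit of all raw traces to the full ODE model is offered as an
  inference mode; the simulator serves for validation only.
- No pH/temperature/ionic-strength corrections, no outlier-robust losses,
  no Bayesian uncertainty; standard errors are asymptotic.
- The two-conformer inactivation model is fitted at the residual-activity
  level; conformer interconversion during the reaction (which would bend
  the slow phase) is not modelled.
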