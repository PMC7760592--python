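# slowbind

Analysis of **slow-binding enzyme inhibition** from continuous-assay
progress curves: the kind of time-dependent inhibition shown, for
example, by transition-state-analog inhibitors of cholinesterases, where
a fast encounter complex tightens through a slow induced-fit step and the
pharmacologically relevant constants are the steady-state inhibition
constant, the drug–target residence time and the fractional target
occupancy.

It is written for enzymologists and kinetic pharmacologists who have (or
want to simulate) Ellman-type assay traces and need the complete
classical workflow as tested, scriptable code rather than spreadsheet
steps.

## The model

For the two-step (induced-fit, "type B") scheme

```
E + I <==[k+3, k-3]==> EI <==[k+4, k-4]==> EI*        K_i = k-3/k+3
```

product accumulation under inhibitor excess follows the slow-onset law

> P(t) = v_ss·t + (v_i − v_ss)(1 − e^(−k_obs·t))/k_obs

and the onset rate saturates in inhibitor with competitive-substrate
protection:

> k_obs = k₋₄ + k₊₄·[I] / ( K_i(1 + [S]/K_m) + [I] )

From the fitted elementary constants the package derives

> K_i\* = K_i·k₋₄/(k₋₄+k₊₄),  τ = (k₋₃+k₊₄+k₋₄)/(k₋₃·k₋₄),
> k_off = 1/τ,  t½ = ln2/k_off,  FO = [I]/([I]+K_i\*)

The toolkit covers, end to end:

- **Simulation** — deterministic mass-action ODE integration of the full
  scheme (plus optional serine-acylation/deacylation and dilution
  protocols), converted to noisy assay signals with seeded Gaussian noise.
- **Progress-curve fitting** — (v_i, v_ss, k_obs) with model selection
  against lag-free and baseline-offset alternatives.
- **Inhibition-type diagnosis** — competitive/uncompetitive/
  noncompetitive/mixed by nested rate-law fits (AICc) cross-checked
  against Dixon and Cornish-Bowden graphical statistics.
- **Slow-binding type selection** — hyperbolic (type B) vs linear
  (type A) secondary plots, pooled constants with consistency checks.
- **Derived constants & occupancy** — K_i\*, k_off, residence time,
  dissociation half-time, occupancy tables.
- **Covalent stages** — two-exponential (hysteretic) inactivation fits
  with nested comparison, and first-order reactivation fits.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

Simulate the reference experiment (3 substrate × 8 inhibitor levels,
0.3% signal noise) and analyze it:

```python
from slowbind import RunConfig
from slowbind.pipeline import run_pipeline

traces, report = run_pipeline(RunConfig(seed=7))
print(report.reversible_mechanism, report.sbi_type)
for name in ("Ki", "k_minus4", "k_plus4", "Ki_star", "tau"):
    c = report.constants[name]
    print(f"{name:10s} {c.value:.4g}  [{c.provenance}]")
```

prints

```
competitive B
Ki         5.245e-09  [fitted]
k_minus4   0.05196  [fitted]
k_plus4    0.4411  [fitted]
Ki_star    5.528e-10  [derived]
tau        19.85  [derived]
```

i.e. the pipeline recovers the generating mechanism (competitive fast
step, slow-binding type B) and the generating constants (K_i = 5.15 nM,
k₋₄ = 0.054 min⁻¹, k₊₄ = 0.456 min⁻¹) to within a few percent, and chains
them to a sub-nanomolar steady-state constant and a ~20-min residence
time. Every constant in a report carries a provenance tag (`fitted`,
`assumed`, `derived`, `config`); derived values are recomputable from the
stored elementary ones, and a stored config + seed reproduces a run
bit-identically.

The same workflow is available from the shell:

```sh
slowbind simulate --seed 7 --out traces/
slowbind analyze traces/ --seed 7 --out report.json
slowbind derive --ki 5.15e-9 --kplus4 0.456 --kminus4 0.054
slowbind occupancy --ki-star 5.45e-10 4.3e-9 4.3e-6
```

`slowbind derive` on the constants above prints the full chain
(K_i\* = 0.545 nM, k₋₃ = 15.45 min⁻¹, τ = 19.1 min, k_off = 0.052 min⁻¹,
t½ = 13.3 min), and the occupancy table gives 88.7% at 4.3 nM and 99.99%
at 4.3 µM free inhibitor.

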