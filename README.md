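# mtbundle

Multiscale analysis of motor-driven microtubule bundles.

Bundles of stabilized microtubules crosslinked by the minus-end-directed
motor kinesin-14 extend continuously, but the same mesoscopic extension can
be powered by two different microscopic behaviours: coherent **antiparallel
sliding** (half the filaments move at `+V`, half at `-V`) or **telescoping
extension** (material velocity grows with position at strain rate `γ_∥`).
A depletion agent (PEG) switches the bundles between the two regimes and
simultaneously changes the cross-sectional packing of the filaments from an
open hexagonal lattice to a tight rectangular one.  `mtbundle` implements
the analyses that tell these regimes apart, plus a synthetic-data generator
so every stage can be validated by recovering known ground truth:

* **Photobleach-line kinetics** (`mtbundle.bleach`) — track two bleached
  stripes in a kymograph; under sliding each stripe splits into two
  counter-moving dips with `V_split = 2V` while the centres of mass stay put
  (`V_cen = 0`); under extension stripes broaden and drift apart.  A mark's
  centre of mass weighs the split band positions by their integrated bleach
  deficits: `COM = (L₁I₁ + L₂I₂)/(I₁ + I₂)`.
* **Tracer statistics** (`mtbundle.tracers`) — velocity series of sparsely
  labelled filaments, the autocorrelation `C(τ) = ⟨V(t)V(t+τ)⟩/⟨V²⟩`
  (reversals at rate `k` give `C(τ) = e^{−2kτ}`), the slowness exponent
  `S_c = 1/⟨|V − V̄|⟩`, and strain rates from OLS fits of `L(t)/L₀`.
* **SAXS modelling and fitting** (`mtbundle.saxs_model`, `mtbundle.saxs_fit`)
  — orientationally averaged scattering of bundles of hollow (circular or
  elliptical) cylinders on finite hexagonal (`L_h = 45.8` nm) or rectangular
  (`{20.2, 27.2}` nm) lattices,

      I(q) = K·e^{−q²σ_d²}/q · ⟨|Σ_j F_j(q,ψ) e^{iq·r_j·u(ψ)}|²⟩_ψ ,

  with weighted-least-squares fitting and BIC model selection between
  hexagonal, rectangular and coexistence models.
* **Synthetic data** (`mtbundle.synthetic`) — bundle kinematics with
  log-normal filament lengths (mean 4.9 μm, mode 2.8 μm), bleached-kymograph
  rendering with Poisson photon noise, tracer-track export, and noisy
  scattering curves/detector frames.

See `docs/methods.md` for the full model description, parameter defaults
and limitations.

## Worked example

Generate a pure-sliding bundle (filament speed `V = 22.5` nm/s), render a
photon-noise kymograph, and run the full bleach + tracer analysis:

```sh
mtbundle demo --regime sliding --seed 1 --out demo_sliding/
```

The recovery report (`demo_sliding/report.json`) contains, among others:

```json
{
  "bleach": {
    "classification": "split",
    "V_cen_nm_s": -14.7,
    "V_split_nm_s": 46.0
  },
  "expected": {
    "V_cen_nm_s": 0.0,
    "V_split_nm_s": 45.0
  }
}
```

The two bleach marks split (`classification: "split"`), and the recovered
splitting speed of 46.0 nm/s matches the imposed `2V = 45` nm/s to ~2%.
The centre-of-mass speed of a single noisy rendering wanders by tens of
nm/s from seed to seed — the labelling inhomogeneity moves with the
filament populations, so it survives flat-fielding and dominates the COM
estimate; averaged over seeds, and exactly in the noiseless limit, it is
zero.  Running with `--regime extension` instead classifies the bundle
`"broadened"` with no defined `V_split`.

The SAXS analogue synthesizes a noisy hexagonal-bundle curve at
`L_h = 45.8` nm, fits all three lattice models and selects by BIC:

```sh
mtbundle saxs-demo --phase hex --seed 1 --out demo_saxs/
# prints: hex
```

with the fitted spacing in `demo_saxs/report.json` within a few tenths of a
nanometre of 45.8.

The same workflows are available as library calls in `mtbundle.recovery`
(used by the tests) and as the lower-level commands `mtbundle simulate`,
`mtbundle bleach`, `mtbundle tracers`, `mtbundle saxs-model`,
`mtbundle saxs-fit`.

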