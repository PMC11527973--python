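# sprkinetics

Simulation and global kinetic fitting of surface plasmon resonance (SPR)
sensorgrams with multi-site binding models.

SPR screens of small-molecule imaging ligands (amyloid-binding dyes such
as q-FTAA, h-FTAA, HS-84 and HS-169, and drugs like lansoprazole or
methylene blue) against immobilized amyloid fibrils (Aβ42, K18-tau,
2N4R-tau, α-synuclein) produce sensorgrams that a simple 1:1 Langmuir
model cannot fit: fibrils expose several classes of binding sites. This
package is for analysts of such screens. It provides:

- **Forward simulation.** Exact piecewise closed-form response of 1–3
  independent site classes over arbitrary injection schedules
  (full-kinetics dilution series and single-cycle titrations), with
  optional per-curve bulk refractive-index boxes and a two-compartment
  mass-transport-limited variant. Each class obeys
  `dR_i/dt = ka_i·C·(Rmax_i − R_i) − kd_i·R_i`, giving the familiar
  sum-of-exponentials ("1+1", sum2exp/heterogeneous-ligand, sum3exp)
  models, with `KD_i = kd_i/ka_i`.
- **Global fitting.** Multistart trust-region least squares in log10
  parameter space with analytic Jacobians, shared kinetic parameters
  across a concentration series, χ² (= SSR/N) and a Wald–Wolfowitz runs
  test on the residuals, stepwise model-order selection, and a
  perturb-and-refit stability probe that flags ill-conditioned
  (typically over-parameterized sum3exp) fits.
- **Reporting.** KD tables recomputed from fitted rates and a
  Type 1 / Type 2 classification of each interaction by the kinetics of
  its main (largest-Rmax) component — slow-kinetics (Type 2) binders are
  the better imaging candidates.
- **Synthetic data.** A seeded generator emulating the acquisition
  design (5–8 concentrations in duplicate, 10 Hz sampling, Gaussian
  noise, baseline drift, jump/injection-decrease artifacts), bundled with
  a 12-interaction ground-truth preset bank so that every analysis step
  can be validated by round trip.

See `docs/methods.md` for the model, the numerical choices and their
rationale.

## Worked example

Simulate a noisy dilution series for the α-synuclein/HS-169 preset and
fit it globally with a two-site model:

```python
from sprkinetics import *
from sprkinetics.fitting import FitOptions, FitProblem, global_fit
from sprkinetics.analysis import build_report, format_text_table

preset = get_preset("asyn_hs169")
curves, truth = generate_dataset(preset, NoiseModel(sigma_RU=0.5, seed=7))
result = global_fit(FitProblem(curves=curves, model_order=2),
                    FitOptions(n_starts=8, seed=0))
print("chi2 =", round(result.chi2, 4), "RU^2; runs-test p =",
      round(result.runs_test_p, 3))
meta = {"fibril": preset.fibril, "ligand": preset.ligand,
        "surface": preset.surface, "density_RU": preset.surface_density_RU}
print(format_text_table(build_report([(meta, result)])))
```

prints

```
chi2 = 0.2491 RU^2; runs-test p = 0.92
fibril ligand surface density_RU  component_index       ka      kd       KD  rmax   chi2 class
  aSyn HS-169 CMD200M       2940                1 2.88e+05 0.00254  8.8e-09 16.29 0.2491 type1
  aSyn HS-169 CMD200M       2940                2 1.45e+05  0.0418 2.89e-07 45.49 0.2491 type1
```

χ² ≈ 0.25 RU² is the injected noise variance (σ = 0.5 RU) and the runs
test finds no residual structure, i.e. the two-site model explains the
data. Both site classes are recovered from the noisy series: the
slow-dissociating class with KD = 8.8 nM (ka 2.88e5 M⁻¹s⁻¹,
kd 2.54e-3 s⁻¹) and the high-capacity fast class with KD = 289 nM —
matching the generating ground truth. The interaction classifies Type 1
(fast kinetics of the main, largest-Rmax component).

The same pipeline is available from the shell:

```sh
sprkinetics simulate --preset asyn_hs169 --seed 7 --sigma 0.5 --out run/
sprkinetics fit --csv run/asyn_hs169.csv --config run/asyn_hs169.run.yaml \
            --order 2 --out run/fit.json
sprkinetics report --fits run/fit.json --out run/report.csv
sprkinetics compare --csv run/asyn_hs169.csv --config run/asyn_hs169.run.yaml
sprkinetics recovery --preset asyn_hs169 --seed 7 --replicates 20
```

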