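# speckleflow

Simulation framework for comparing the two leading diffuse-optical
techniques for non-invasive cerebral blood flow (CBF) monitoring:

* **DCS** (diffuse correlation spectroscopy) — measures the *temporal*
  intensity autocorrelation `g2(τ)` of diffusely scattered coherent
  light with photon-counting detectors;
* **SCOS** (speckle contrast optical spectroscopy) — measures the
  *spatial* blurring of the speckle pattern over a camera exposure,
  quantified by the squared speckle contrast `K² = σ_I²/⟨I⟩²`.

Both recover the blood flow index BFi (cm²/s), the effective Brownian
diffusion coefficient of the scatterers (`⟨Δr²(τ)⟩ = 6·BFi·τ`).  The
package answers a design question: for realistic detectors, lasers,
fibers and skin-safe illumination, which technique, at which operating
point, gives the best contrast-to-noise ratio for a cerebral flow
change?

## What is inside

| module | contents |
| --- | --- |
| `speckleflow.forward` | Siegert relation `g2 = 1 + β\|g1\|²`; semi-infinite correlation-diffusion solution for `g1(τ)`; photon-history estimator `G1(τ) = (1/Np) Σ_n exp(-(k²/3) Σ_i Y_{n,i}·6·BFi_i·τ)·exp(-Σ_i μ_{a,i} L_{n,i})`; fundamental speckle contrast `Kf² = (2β/T) ∫₀ᵀ g1²(τ)(1-τ/T) dτ` |
| `speckleflow.montecarlo` | layered-slab dynamic-light-scattering Monte Carlo (numba): per-detected-photon partial pathlengths `L_i` and momentum transfer `Y_i` per tissue (scalp/skull/CSF/brain), diffuse reflectance vs separation |
| `speckleflow.histories` | photon-history tables, TSV and HDF5 round-trip |
| `speckleflow.instruments` | ANSI Z136.1 skin-safe power, LP-mode counting for step-index fibers, bundle mode counts, speckle-to-pixel sampling limits, detector dead-time saturation, the four laser delivery strategies, photon-flux calibration |
| `speckleflow.noise` | analytic correlogram noise `σ(τ)`; dynamic speckle simulator (spatial Gaussian-correlated fields, exact temporal `g1` tracking) for `σ(K²)`, `β(s/p)` and independent-observation counts; photon timestamps with dark counts and dead time; multi-tau software correlator |
| `speckleflow.fitting` | `DcsBfiModel` / `ScosBfiModel`: bounded 1-parameter inversion of BFi from noisy `g2` or `Kf²`, fit-range control, effective decay rate `Γ` |
| `speckleflow.pipeline` | sensitivity `= (ΔBFi/BFi)/(ΔCBF/CBF)`, CoV `= σ_BFi/μ_BFi` at 10 Hz, CNR `= sensitivity/CoV`, with sweep drivers over fit range, exposure time, illumination strategy, modal content and extracerebral thickness |
| `speckleflow.config` / `speckleflow.cli` | validated YAML run configs, hardware presets, `speckleflow` command-line tool |

## Worked example

Simulate photon transport through a head-like slab (15 mm scalp-to-brain
distance), then evaluate an 850 nm single-mode DCS measurement and an
850 nm SCOS measurement at a 20 mm source-detector separation:

```python
from speckleflow import (MeasurementConfig, evaluate_configuration,
                         run_layered_mc, slab_preset)
from speckleflow.montecarlo import TABLE1_OPTICS

run = run_layered_mc(slab_preset(15.0), TABLE1_OPTICS[850],
                     n_photons=1_000_000, seed=11)
refl = run.reflectance_curve()

dcs = evaluate_configuration(
    MeasurementConfig.dcs_preset(850, sds_mm=20.0, seed=0),
    run.histories, run.histories, refl)
scos = evaluate_configuration(
    MeasurementConfig.scos_preset(sds_mm=20.0, t_exp=1e-3, s_over_p=0.41,
                                  strategy="pulsed_frame_limited", seed=0),
    run.histories, run.histories, refl)
for name, m in (("DCS ", dcs), ("SCOS", scos)):
    print(f"{name} sensitivity={m.sensitivity:.3f}  CoV={m.cov:.4f}  "
          f"CNR={m.cnr:.2f}")
```

prints

```
DCS  sensitivity=0.142  CoV=0.0849  CNR=1.68
SCOS sensitivity=0.082  CoV=0.0005  CNR=154.64
```

Read: a +20% cerebral flow change shows up as a +2.8% change in the DCS
BFi (sensitivity 0.142 of the true 20%), with an instrument CoV of
0.085 at 10 Hz — a CNR of 1.7, a marginally usable single-sample
measurement.  SCOS at the same separation recovers a bit less of the
change (camera exposures integrate over the decorrelation), but the
~2.5 million-pixel parallel speckle average cuts the CoV by two orders
of magnitude, putting its CNR near 150.

The same pipeline is scriptable from the shell:

```bash
speckleflow simulate-histories --extracerebral-mm 15 --n 1e6 --seed 11 --out slab.h5
speckleflow sweep --preset fit_range --histories slab.h5 \
    --reflectance slab.reflectance.csv --technique dcs --seed 0 --out sweep.csv
```

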