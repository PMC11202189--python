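# relkin

Release-kinetics analysis for membrane drug-delivery experiments: a
compressed-exponential kinetic model, a two-instrument spectroscopic
calibration chain, Levenberg–Marquardt fitting with uncertainties, and the
derived release descriptors (half-release time, lifetime power law, yield).

## The problem

A solute (here: fluorescein sodium salt, a standard dye/drug surrogate) is
loaded into a hollow polymer cylinder immersed in a stirred bath, and its
concentration in the bath is monitored spectroscopically for months. Polymer
swelling and slow hydrolysis make the escape timescale change over the run,
so classical first-order kinetics does not fit. `relkin` is for
experimentalists who have such long-horizon release series (raw fluorescence
or absorbance readings plus calibration standards) and want fitted kinetic
parameters with standard errors and the derived descriptors used to compare
formulations.

## The model

Release is treated as first-order kinetics with a time-varying residence
lifetime τ(t). The observable lifetime τ_exp(t) = τ(t)/φ (φ = V_m/V is the
membrane-to-bath volume ratio) is modelled as a power law
τ_exp(t) = B·t^(1−σ), which integrates to the compressed exponential

    χ(t) = m(t)/m_∞ = 1 − exp(−(t/τ₀)^σ),   τ₀ = (σB)^(1/σ)

with three parameters: the plateau released mass m_∞ (µg), the
characteristic time τ₀ (h) and the shape exponent σ. σ > 1 gives a
sigmoidal curve with an initial lag (swelling-controlled release); σ = 1
recovers the simple exponential. Derived descriptors:

- half-release time t₀.₅ = τ₀·(ln 2)^(1/σ)
- lifetime coefficient B = τ₀^σ/σ
- release yield = 100·m_∞ / (c₀·V_inner), the percentage of the loaded mass
  that ever reaches the bath.

The fitter is a Levenberg–Marquardt optimizer with an analytic Jacobian,
log-parameter positivity and gain-ratio damping; covariance is
s²(JᵀJ)⁻¹ with s² = SSR/(n−k).

Raw signals are converted to bath concentrations through per-instrument
calibration curves — linear for the fluorimeter (trace range,
c ≤ 0.06 mg dm⁻³), saturating parabola for the UV-Vis spectrophotometer
(0.06–14 mg dm⁻³, decade dilution above) — with ICH-style detection limits
LOD = 3.3·s/S, LOQ = 10·s/S from the regression scatter.

## Worked example

Simulate the low-load scenario (initial load 0.03763 g dm⁻³; true triple
m_∞ = 3.0 µg, τ₀ = 808 h, σ = 1.37) with realistic instrument noise, then
run the full pipeline:

```
relkin simulate --preset low --out-dir demo/low
cat > demo/run.yaml <<EOF
calibration_path: demo/low/standards.csv
kinetics_path: demo/low/kinetics.csv
geometry:
  c0: 0.03763
output_dir: demo/low/out
EOF
relkin report --config demo/run.yaml
```

which prints (abridged):

```
--- kinetic fit ---
parameter        value        stderr
m_inf [ug]          3.03405     0.0355
tau0 [h]            811.138       17.5
sigma [-]           1.34869      0.036
R^2:             0.993417
RMSE:            0.0866372 ug (0.028555 on the chi scale)
--- derived quantities ---
half-release time t_0.5 [h]            618.121
lifetime coefficient B [h^sigma]       6216.77
membrane/bath volume ratio phi [-]     0.00893909
loaded mass [ug]                       29.5545
release yield [%]                      10.2659
```

Reading: the fitted triple recovers the generating values within one
standard error; σ ≈ 1.35 > 1 confirms the lag-type (compressed) release;
half the plateau mass is released after ≈ 618 h; about 10 % of the loaded
dye is ever released. The same pipeline is available as a library:

```python
import relkin as rk

series = rk.ReleaseSeries(times_h, masses_ug)
result = rk.fit_release(series)
print(result.params, rk.half_release_time(result.params))
```

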