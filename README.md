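# nadhtrf

Simulation and analysis of NADH time-resolved fluorescence measured by
time-correlated single photon counting (TCSPC).

NADH is the principal electron donor of glycolysis and oxidative
metabolism and the workhorse label-free metabolic biomarker: its
fluorescence intensity, lifetime, emission spectrum and anisotropy all
shift with temperature, pH, and binding to enzymes such as lactate
dehydrogenase (LDH). Quantifying those shifts requires a specific analysis
chain — IRF-reconvolution multi-exponential fitting with incomplete-decay
correction, polarisation-resolved global fitting, constrained free/bound
decomposition — that this package implements as a tested library, together
with a synthetic-instrument module that replaces the cuvette
spectrofluorimeter so every stage can be validated against known ground
truth.

## The models

**Decay.** A measured histogram is modelled as a multi-exponential decay
convolved with the instrument response function (IRF):

    I(t) = I0 * sum_i alpha_i exp(-t/tau_i) + C,      sum_i alpha_i = 1

with pre-exponential fractions `alpha_i`, lifetimes `tau_i` (strictly
increasing), and a constant background `C`. Pulsed excitation at 40 MHz
(25 ns period) leaves residual fluorescence from previous pulses, handled
in closed form by the periodic wrap `exp(-t/tau)/(1 - exp(-T/tau))`. The
intensity-weighted mean lifetime is
`tau_m = sum_i alpha_i tau_i^2 / sum_i alpha_i tau_i`. Fitting is weighted
nonlinear least squares over an 12.5 ns analysis window, with the temporal
IRF shift `t0` co-fitted or fixed.

**Anisotropy.** Steady-state anisotropy is
`r = (Ipar - G*Iperp)/(Ipar + 2*G*Iperp)` with G-factor `G = I'par/I'perp`.
Time-resolved analysis fixes the decay parameters from a magic-angle
(54.7°) fit and globally fits the parallel and perpendicular channels with
a single-exponential anisotropy decay `r(t) = r0 exp(-t/theta)`, where
`theta` is the 1/e rotational correlation time (~0.4 ns for free NADH,
~16 ns when bound to the LDH tetramer).

**Binding.** An LDH titration is decomposed by a quadruple-exponential fit
in which the free and bound two-component shapes are entirely fixed and
only the bound intensity fraction `f` (plus overall amplitude) is free; `f`
is compared with the quadratic dissociation-constant model
`B = (S + N + Kd - sqrt((S + N + Kd)^2 - 4SN))/2`.

## Worked example

```python
import nadhtrf as nt

settings = nt.AcquisitionSettings()                      # 4096 bins x 6.1 ps, 25 ns period
irf = nt.gaussian_irf(settings, center=1000.0, fwhm=200.0)
hist = nt.simulate_decay(nt.FREE_NADH_25C, settings, irf, seed=1, photon_budget=1e6)
result = nt.fit_decay(hist, irf)
```

This simulates one million-photon free-NADH decay (25 °C parameter set:
tau1 = 266 ps, tau2 = 781 ps, alpha1 = 0.793) and fits it back. Running
`python examples/simulate_and_fit_decay.py` prints:

```
true:   tau1=266.0 ps  tau2=781.0 ps  alpha1=0.793  tau_m=489.4 ps
fitted: tau1=266.7 ps  tau2=780.1 ps  alpha1=0.792  tau_m=489.7 ps
t0=-0.64 ps  chi2_red=0.567
```

i.e. at this photon budget the short and long lifetimes are recovered to
within ~1 ps and the amplitude fraction to ~0.001; `tau_m` is the
intensity-weighted mean lifetime of the fitted parameters. The other
scripts in `examples/` walk through the anisotropy pipeline
(`anisotropy_bound_nadh.py`), the titration decomposition
(`ldh_titration_binding.py`), temperature-slope recovery
(`temperature_trends.py`), and the on-disk CSV workflow
(`fixture_bundle_and_cli.py`).

A thin CLI mirrors the file-based workflow:

```bash
nadhtrf fixtures --out bundle --seed 0
nadhtrf fit bundle/free_nadh_25C_magic.csv bundle/irf_200ps.csv
nadhtrf anisotropy --par bundle/polarized/bound_parallel.csv \
    --perp bundle/polarized/bound_perpendicular.csv \
    --magic bundle/polarized/bound_magic.csv --irf bundle/irf_35ps.csv
```

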