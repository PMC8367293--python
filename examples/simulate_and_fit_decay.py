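"""Simulate a free-NADH TCSPC decay and recover its lifetimes by reconvolution fitting.

Free NADH in aqueous solution at 25 degC decays bi-exponentially
(tau1 = 266 ps, tau2 = 781 ps, alpha1 = 0.793). We simulate one
1e6-photon histogram on a 40 MHz instrument with a 200 ps FWHM Gaussian
IRF and fit it back with the IRF-reconvolved double-exponential model.
"""

import nadhtrf as nt

settings = nt.AcquisitionSettings()  # 4096 bins x 6.1035 ps, 25 ns period
irf = nt.gaussian_irf(settings, center=1000.0, fwhm=200.0)

hist = nt.simulate_decay(nt.FREE_NADH_25C, settings, irf, seed=1, photon_budget=1e6)
result = nt.fit_decay(hist, irf)

tau1, tau2 = result.params.lifetimes
a1 = result.params.fractions[0]
print(f"true:   tau1=266.0 ps  tau2=781.0 ps  alpha1=0.793  tau_m={nt.mean_lifetime(nt.FREE_NADH_25C):.1f} ps")
print(
    f"fitted: tau1={tau1:.1f} ps  tau2={tau2:.1f} ps  alpha1={a1:.3f}  "
    f"tau_m={nt.mean_lifetime(result.params):.1f} ps"
)
print(f"t0={result.t0:.2f} ps  chi2_red={result.chi2_reduced:.3f}")
print(
    "The fitted lifetimes land within a few ps of the ground truth at this "
    "photon budget; tau_m is the intensity-weighted mean lifetime."
)
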