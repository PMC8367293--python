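"""Time-resolved anisotropy of fully LDH-bound NADH.

NADH bound to the large LDH tetramer tumbles slowly: its anisotropy decays
with a rotational correlation time near 16 ns, ~47x that of free NADH.
We simulate polarized detection channels (~1e6 photons each), fit the
magic-angle decay, fix those parameters, and run the global
parallel/perpendicular single-exponential anisotropy fit.
"""

import nadhtrf as nt
from nadhtrf.datatypes import FitSpec, PolarizedMeasurement

settings = nt.AcquisitionSettings()
irf = nt.gaussian_irf(settings, center=1000.0, fwhm=35.0)

par, perp, magic = nt.simulate_polarized(
    nt.BOUND_NADH, nt.BOUND_ANISOTROPY, settings, irf, seed=1, photon_budget=3e6
)
meas = PolarizedMeasurement(parallel=par, perpendicular=perp, magic=magic, g_factor=1.0)

magic_fit = nt.fit_decay(magic, irf, FitSpec(n_components=2))
r0_hat, theta_hat, result = nt.fit_anisotropy_decay(
    meas, magic_fit.params, irf, t0=magic_fit.t0
)

r_ss = nt.steady_state_from_measurement(meas)
r_model = nt.steady_state_from_model(nt.BOUND_NADH, nt.BOUND_ANISOTROPY)

print(f"true:   r0=0.350  theta=15900 ps")
print(f"fitted: r0={r0_hat:.3f}  theta={theta_hat:.0f} +/- {result.stderr['theta']:.0f} ps")
print(f"steady-state r from channel sums: {r_ss:.3f}")
print(f"steady-state r from closed form:  {r_model:.3f}")
print(
    "theta is the 1/e rotational correlation time; the windowed channel-sum "
    "anisotropy agrees with the closed-form model value near 0.32."
)
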