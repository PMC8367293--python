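"""LDH titration: constrained free/bound decomposition vs the Kd binding model.

At increasing [LDH]:[NADH] ratios (0 to 4) a growing fraction of NADH is
enzyme-bound. Each decay is a quadruple-exponential mixture of the free
and bound two-component shapes; with all lifetimes and internal amplitude
ratios fixed, the only fitted quantity is the bound intensity fraction f.
The fitted f is compared with the fraction predicted by the quadratic
dissociation-constant model.
"""

import nadhtrf as nt

settings = nt.AcquisitionSettings()
irf = nt.gaussian_irf(settings, center=1000.0, fwhm=35.0)

nadh_uM, kd_uM = 12.5, 1.5
ratios = [0.0, 0.25, 0.5, 1.0, 2.0, 4.0]
conditions = [
    nt.BindingCondition(nadh_total=nadh_uM, ldh_total=r * nadh_uM, kd=kd_uM, sites_per_protein=1)
    for r in ratios
]

model = nt.TitrationModel(free_shape=nt.FREE_NADH_37C, bound_shape=nt.BOUND_NADH)
records = nt.simulate_condition_series(model, conditions, settings, irf, seed=1)

estimates = [
    nt.fit_bound_fraction(rec.histograms["magic"], irf, nt.FREE_NADH_37C, nt.BOUND_NADH)[0]
    for rec in records
]
table = nt.binding_curve(conditions, estimates)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(f"Spearman(theory, fitted) = {table.attrs['spearman']:.3f}")
print(
    "f_theory is the detected-intensity bound fraction from the Kd model "
    "(bound NADH is ~3.3x brighter); f_fitted tracks it closely and rises "
    "monotonically with protein concentration."
)
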