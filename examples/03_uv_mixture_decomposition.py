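"""Decompose a UV-anomalous action spectrum into two pigment states.

A pigment whose Schiff base is only partially protonated behaves as two
pools: a UV-absorbing deprotonated form and a blue-absorbing protonated
form.  This example simulates such an assay on the UV-shifted protocol,
derives per-wavelength EC50 relative sensitivities, and compares a
single-template fit against a two-template mixture.
"""

from opsinspec import (
    PhotoresponseModel,
    TemplateMixture,
    compare_models,
    default_protocol,
    fit_all_wavelengths,
    fit_dual_template,
    fit_single_template,
    relative_sensitivity,
    simulate_responses,
)

truth = TemplateMixture(((363.0, 0.69), (438.0, 0.31)))
protocol = default_protocol("uv_shifted")
model = PhotoresponseModel(truth=truth, noise_sd=0.0)
dataset = simulate_responses(protocol, model, seed=7)

spectrum = relative_sensitivity(fit_all_wavelengths(dataset))
for wl, v in zip(spectrum.wavelengths, spectrum.values):
    print(f"  {wl:.0f} nm: relative sensitivity {v:.3f}")

single = fit_single_template(spectrum, (330.0, 550.0))
dual = fit_dual_template(spectrum, (330.0, 550.0))
print(f"single template: lambda_max = "
      f"{single.mixture.components[0][0]:.0f} nm, R^2 = {single.r_squared:.3f}")
comps = ", ".join(f"{l:.0f} nm ({100 * w:.0f}%)"
                  for l, w in dual.mixture.components)
print(f"dual template:   {comps}, R^2 = {dual.r_squared:.3f}")
print(compare_models(single, dual).report())
print("-> no single pigment explains the spectrum; the two-state mixture "
      "fits almost perfectly, recovering both peaks and the pool weights.")
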