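"""Estimate a pigment's λmax from a simulated action-spectroscopy assay.

Simulates a noisy wavelength × intensity photoresponse dataset from a
488-nm pigment, then recovers λmax by effective-photon-flux fitting with a
stratified bootstrap SE — the "λmax ± SE" a spectral-sensitivity table
would report.
"""

from opsinspec import (
    PhotoresponseModel,
    TemplateMixture,
    bootstrap_lambda_max,
    default_protocol,
    simulate_responses,
)

protocol = default_protocol("standard")
model = PhotoresponseModel(truth=TemplateMixture.single(488.0),
                           noise_sd=0.05, n_replicates=4)
dataset = simulate_responses(protocol, model, seed=42)
print(f"simulated {len(dataset.records)} records at "
      f"{len(dataset.wavelengths)} wavelengths (truth: 488 nm)")

estimate = bootstrap_lambda_max(dataset, n_boot=100, seed=42)
print(f"lambda_max = {estimate.report()}")
print(f"shared-sigmoid R^2 in effective-flux coordinates = "
      f"{estimate.shared_fit.r_squared:.4f}")
print("-> at the estimated lambda_max, irradiance-response curves from all "
      "wavelengths collapse onto one sigmoid; the SE is the spread of "
      "re-estimates over stratified resamples of replicate wells.")
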