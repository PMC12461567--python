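# opsinspec

Action-spectroscopy analysis of opsin photopigments.

Heterologous action spectroscopy infers a photopigment's wavelength of peak
sensitivity (λmax) from biological response amplitudes: cells expressing an
opsin and a luminescent calcium reporter are stimulated with monochromatic
pulses across a grid of wavelengths and intensities, and the peak response
per well is recorded. `opsinspec` implements the full analysis chain for
such assays, plus the comparative sequence/structure screen used to ask
*which residues* set λmax — developed around melanopsin (Opn4), the
blue-light-sensitive photopigment of intrinsically photosensitive retinal
ganglion cells, whose λmax is remarkably conserved (~474–497 nm) across
mammals.

## The model

A pigment with an A1 (11-cis retinal) chromophore follows the Govardovskii
template, the sum of an α-band and a β-band, parameterised only by λmax:

```
S(λ) = 1 / (exp[A(a − x)] + exp[B(b − x)] + exp[C(c − x)] + D)     (α-band)
     + A_β · exp{−[(λ − λ_mβ)/b_β]²}                               (β-band)
```

with `x = λmax/λ`, `A = 69.7`, `a = 0.8795 + 0.0459·exp[−(λmax−300)²/11940]`,
`B = 28`, `b = 0.922`, `C = −14.9`, `c = 1.104`, `D = 0.674`,
`A_β = 0.26`, `λ_mβ = 189 + 0.315·λmax`, `b_β = −40.5 + 0.195·λmax`.

**λmax estimation.** For a candidate λmax, every stimulus is re-expressed
as *effective photon flux* `E = I + log₁₀ S(λ)`. At the correct λmax,
irradiance-response curves (IRCs) from all wavelengths collapse onto one
four-parameter sigmoid in `E`; the estimator scans candidates on a 1-nm
grid, scores each by the residual SSE of a single shared sigmoid fit to the
pooled records, refines the minimum, and attaches a bootstrap SE from
stratified resampling of replicate wells ("480.0 ± 1.1 nm").

**Mixture decomposition.** For pigments that exist as two spectral states
(e.g. protonated vs deprotonated retinal Schiff base), per-wavelength EC50s
give relative sensitivities `EC50_min/EC50(λ)`, which are fit with a single
template or the weighted sum of two templates; the dual model is preferred
only when it earns its extra parameters (ΔR² and minimum-weight rules).

**Tuning-site screen.** Aligned opsin sequences are indexed by a reference
numbering; residues at chromophore-adjacent sites are extracted and each
substitution is classified by the OH-rule (gain of Ser/Thr/Tyr near the
β-ionone ring → red-shift; near the Schiff base → blue-shift; loss reverses
the sign). Binding-pocket sites themselves come from structure: minimum
side-chain distances to the β-ionone ring centroid and Schiff-base nitrogen,
with a 10-Å cutoff. Packaged reference tables (22 mammalian melanopsin λmax
values; 8 non-conserved pocket sites with modelled chromophore distances)
back the comparative analysis out of the box.

## Worked example

Estimate λmax with bootstrap uncertainty from a simulated assay
(`python examples/02_lambda_max_estimation.py`):

```
simulated 264 records at 6 wavelengths (truth: 488 nm)
lambda_max = 487.8 ± 1.2 nm
shared-sigmoid R^2 in effective-flux coordinates = 0.9939
```

The estimate recovers the simulated 488-nm pigment to a fraction of a
nanometre; R² ≈ 0.99 says the six per-wavelength IRCs collapsed onto a
single sigmoid once intensities were expressed as effective flux — the
signature that the candidate λmax is right. Decomposing a UV-anomalous
spectrum (`python examples/03_uv_mixture_decomposition.py`):

```
single template: lambda_max = 373 nm, R^2 = 0.674
dual template:   363 nm (69%), 438 nm (31%), R^2 = 1.000
model choice: dual (single R²=0.674, dual R²=1.000, ΔR²=0.326; ...)
```

No single pigment explains the spectrum; a 69/31% mixture of a UV
(deprotonated) and a blue (protonated) state fits almost perfectly. The
other examples cover template evaluation, the comparative tuning-site
screen (mean 484.4 nm, 23-nm range, 19-nm divergence among identical
pocket profiles), and pocket-distance measurement; a thin CLI
(`opsinspec simulate|fit-lambda|fit-mixture|screen-sites|pocket`) wraps the
same functions for shell use.

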