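# Methods

## Spectral templates

The A1 pigment template is implemented exactly as the standard
Govardovskii parameterisation: α-band in normalised wavenumber
`x = λmax/λ` with constants `A = 69.7`, `B = 28`, `b = 0.922`,
`C = −14.9`, `c = 1.104`, `D = 0.674` and the λmax-dependent steepness
`a = 0.8795 + 0.0459·exp[−(λmax−300)²/11940]`; β-band as a Gaussian with
amplitude 0.26, centre `189 + 0.315·λmax` and width `−40.5 + 0.195·λmax`
(division by the width inside the squared exponent — the standard form).
Templates are **not** renormalised: the raw value at the nominal peak is
≈ 1.001, and the grid argmax can sit 1–2 nm from nominal λmax because the
β-band tilts the sum slightly. λmax is validated to [300, 700] nm; A2
chromophore templates and other template families (Lamb, Stavenga) are out
of scope. Mixtures are convex combinations of one or two templates;
weights must sum to 1 to 1e-9.

## Synthetic assay generator

The generator emulates a plate-reader bioluminescence assay: 1-s
monochromatic pulses, either the standard protocol (435/460/470/490/500/525
nm at 11–16 log photons·cm⁻²·s⁻¹) or the UV-shifted protocol
(365/385/405/435/490 nm at 12–17 log). Intensity grids use 0.5-log steps
(11 levels) and 4 replicate wells per condition by default — a grid density
and replication typical of such dose–response designs; only the ranges are
fixed by the protocols themselves.

Responses are peak fold-changes: a four-parameter sigmoid in log10
*effective* flux (floor 1.0, ceiling 9.0 fold-change, log EC50 13.5, Hill
slope 1) with multiplicative log-normal noise, `response = mean·exp(ε)`,
`ε ~ N(0, σ²)`, σ = 0.05 by default. Multiplicative noise reflects the
positive, right-skewed nature of luminescence fold-changes; an additive
Gaussian option exists for robustness checks. The generator emulates the
sigmoidal intensity–response structure and replicate noise of the real
assay but not its kinetics (no time courses, no reporter consumption, no
plate-position effects, no LED bandwidth) — passing tests therefore
demonstrate estimator correctness under the assumed generative model, not
robustness to every artefact of real plates.

## IRC fitting and relative sensitivity

Per-wavelength 4PL fits use bounded least squares in log10 intensity with
positive Hill slope, deterministic quantile-derived initial values and a
fixed set of slope starts; at least 5 distinct intensities are required.
Degenerate inputs (flat responses, EC50 escaping the sampled range,
collapsed dynamic range) return *flagged* fits, never silent numbers, and
flagged fits poison downstream sensitivity computation with an explicit
error. R² is clipped at 0. Replicates are pooled into one fit per
wavelength (per-experiment averaging can be done by fitting experiments
separately and averaging the spectra).

Relative sensitivity uses the reciprocal EC50 ratio on the linear flux
scale, `EC50_min/EC50(λ)`: needing 10× more photons means 0.1× the
sensitivity, so the most sensitive wavelength scores 1 and all others < 1.

## λmax estimation

The objective for a candidate λmax is the SSE of one shared 4PL fit to all
records re-expressed as effective flux. The search is a 1-nm grid scan
over 400–600 nm (330–550 nm when the dataset contains sub-400-nm stimuli),
ties broken toward the lower candidate, followed by bounded scalar
refinement (±1 nm, xatol 1e-3) warm-started from the grid minimum's fit.
The profile is retained on the estimate so alternative objectives can be
compared. Fewer than 3 wavelengths, or a flat profile, raises a
non-identifiability error.

The bootstrap resamples records with replacement *within* each
(wavelength, intensity) cell — preserving the stimulus design; resampling
whole wavelengths would leave only ~6 units. Each resample is re-estimated
over a ±20-nm grid around the full-data point estimate (warm-started, one
optimizer start) for speed; the SE is the SD of the bootstrap
distribution, and the point estimate always comes from the full data.
Resample failures are counted; > 10% aborts the run.

## Mixture fitting

Spectra are fit by bounded least squares with a free amplitude scale in
[0.5, 2] (absorbing the max-equals-1 normalisation of EC50-ratio spectra):
single template over (λmax, amplitude), seeded from a 5-nm grid with the
amplitude solved in closed form; dual template over (λ₁, λ₂, w₁,
amplitude) with simplex weights (w₂ = 1 − w₁), multi-started from a 20-nm
λ-pair grid × three weights, components sorted ascending. A dual solution
with a boundary weight (w < 0.01) or coincident peaks (< 2 nm apart) is
flagged as effectively single. Model choice uses ΔR² > 0.05 plus a 5%
minimum-weight rule — mirroring the qualitative adequacy argument used for
such spectra — with AIC reported for transparency rather than used for
selection.

## Tuning-site screen

Alignment columns are mapped to 1-based reference numbering by walking the
reference sequence past its gaps; site extraction reads each species'
residue at the mapped column, recording gaps explicitly. The OH-rule
classifier takes the OH-bearing set as exactly {S, T, Y} — asparagine's
amide is deliberately excluded, which the S→N substitutions at site 329
require — and compares each site's distance to the β-ionone ring against
its distance to the Schiff-base nitrogen: the nearer moiety wins, gains
red-shift near the ring and blue-shift near the Schiff base, losses
reverse the sign. Sites whose two distances differ by less than the
ambiguity margin (default 1.0 Å; site 152's Δ = 0.3 Å motivates it)
predict no change; the margin is configurable and this reconstruction of
the "no expected change" rule is a declared design choice. Pocket
membership (≤ 10 Å) is decided upstream by the geometry module, not inside
the classifier.

Packaged tables transcribe the published 22-species melanopsin λmax
summary and the 8 non-conserved pocket sites with modelled chromophore
distances; where the two printed sources disagree on an SE at the 0.1-nm
level, the species-table value is kept. Table statistics use plain
arithmetic means of point estimates (SEs ignored), range = max − min, and
shifts relative to a reference species.

## Pocket geometry

The β-ionone reference point is the unweighted centroid of retinal ring
carbons C1–C6 (nearest-ring-atom is available as an option); the Schiff
base is the NZ of the linked lysine, auto-detected as the lysine NZ
nearest retinal C15 when unspecified. "Side chain or functional group"
means all non-hydrogen atoms outside {N, CA, C, O, OXT} (glycine falls
back to Cα); an all-atom mode exists. Distances are minimum Euclidean
side-chain distances; the ≤ 10 Å cutoff is inclusive. Structure I/O goes
through gemmi (PDB in/out); homology-model construction and structure
superposition are out of scope — printed distance tables are consumed as
data. The synthetic structure generator scripts exact side-chain
distances (a single Cβ placed on a seed-jittered ray from the chosen
anchor) and mimics real RET/LYS atom naming; it is labelled synthetic and
encodes no measured structure.

## Problem sizes and determinism

Default analysis sizes: 1-nm candidate grids; 100–200 bootstrap resamples
for reported SEs (SEs stabilise to ~0.1 nm by 100); 20 simulated assays
for recovery summaries; 10 replicate experiment pairs for the mutant-shift
summary (a single pair has ~2-nm Monte-Carlo SD on an 8-nm shift). All
randomness flows through explicit integer seeds (numpy Generator /
SeedSequence); every fit is deterministic given its data via fixed
multi-start rules.

## Known limitations

- The estimator assumes the A1 template family; pigments that deviate from
  it (or mixtures fit as single pigments) bias λmax.
- The pooled shared-sigmoid objective treats all records as exchangeable;
  per-well correlation structure beyond the stimulus cell is not modelled.
- The OH-rule classifier encodes an electrostatic heuristic only; steric
  or protonation-state tuning mechanisms are outside its vocabulary (the
  comparative results themselves show its predictions are often wrong for
  melanopsins — that failure is a finding, not a bug).
- Mixtures are limited to two components, and mixture fitting operates on
  relative-sensitivity spectra, not raw IRC data.
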