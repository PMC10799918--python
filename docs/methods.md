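# Methods

`quenchbind` analyses steady-state fluorescence titrations of a protein
fluorophore (serum albumin in the motivating system) with a small-molecule
quencher, and derives the binding mechanism, affinity, thermodynamics and
donor–acceptor geometry from the standard spectroscopic models.

## Data model

A titration is a set of emission spectra (one per quencher concentration,
shared wavelength grid) at one temperature. Intensities `F0` (no quencher)
and `F` are read at the *fixed* band maximum of the unquenched spectrum
(340 nm by default) rather than at per-spectrum maxima: if the band drifts
during the titration, per-spectrum maxima would contaminate the F0/F ratios
with the drift. All interpolation is piecewise-linear; typical grids are
dense (1 nm) so higher-order schemes would change nothing measurable.
Concentrations are molar internally; file metadata must declare its units.

Inner-filter attenuation is removed by
`F_cor = F_obs · exp((A_ex + A_em(λ))/2)` with the absorbance at the
excitation wavelength and at each emission wavelength, per concentration.
Since A ≥ 0 the correction never decreases an intensity. Negative
absorbance (baseline noise after background subtraction) is clipped to
zero with a warning.

## Quenching mechanism

The Stern–Volmer relation `F0/F = 1 + K_sv[Q]` is fit by ordinary least
squares with a free intercept. Theory fixes the intercept at 1, but real
baselines do not; the fit therefore leaves it free and reports its
deviation from 1 as a diagnostic. The bimolecular rate is
`k_q = K_sv/τ0`, with τ0 = 6.2 ns as the default unquenched-albumin
lifetime (overridable).

The mechanism call uses the temperature trend of K_sv:

* decreasing → **static** (ground-state complex dissociates on heating);
* increasing with all k_q at or below the diffusion-controlled limit
  (2×10¹⁰ M⁻¹ s⁻¹ by default) → **dynamic**;
* increasing with k_q above the limit → **static-dominant (ambiguous)** —
  a collisional process cannot outrun diffusion, so complex formation must
  dominate despite the dynamic-looking trend;
* anything else → **inconclusive**.

Trend calls require strict monotonicity across *every* temperature pair;
a relative spread below 5% is treated as flat (fitted-slope errors in this
kind of data are a few percent, so smaller spreads are not trends).

## Binding affinity

For static quenching with n equivalent sites,
`log10((F0−F)/F) = log10 K_a + n·log10[Q]`. The zero-quencher point only
defines F0 (log 0 is undefined); points with F ≥ F0 carry no quenching
signal and are excluded with a warning. Base-10 logs are used here; the
van't Hoff step uses natural logs — mixing the two is the classic failure
mode, so both are fixed and tested. The K_a uncertainty is reported as a
multiplicative factor `10^SE(intercept)` (the error is additive on the log
axis, so an additive ± in M⁻¹ would be meaningless).

Site-probe displacement compares K_a with and without a competitor bound
at a known pocket (warfarin for Sudlow site I, ibuprofen for site II).
`fold_change = K_a(without)/K_a(with)`; above 1.5-fold (configurable) the
call is competitive, below the reciprocal cooperative. Published effects
in this class of systems are ≥3-fold, so any sane threshold reproduces
the calls.

## Thermodynamics

`ln K_a` is regressed on 1/T: ΔH = −R·slope, ΔS = R·intercept, with
R = 8.314 J mol⁻¹ K⁻¹. ΔG(T) is computed primarily from the regressed
pair via `ΔG = ΔH − TΔS` (units: ΔH, ΔG in kJ mol⁻¹, ΔS in J mol⁻¹ K⁻¹);
`−RT ln K_a` is reported alongside as a diagnostic — the two coincide only
when the K_a lie exactly on the van't Hoff line. With exactly two
temperatures the line is exact by construction and the result is flagged
`minimal_design`. The (ΔH, ΔS) sign pattern classifies the dominant
force: (+,+) hydrophobic, (−,+) electrostatic/ionic, (−,−) hydrogen
bonding + van der Waals, (+,−) non-spontaneous; a zero member inherits the
sign of the other.

## FRET

The overlap integral `J = ∫Fελ⁴dλ / ∫Fdλ` is evaluated by the trapezoidal
rule on the native grid over a 285–450 nm window (J is invariant to donor
scaling because the normalisation cancels). The Förster radius is
`R0 = 0.211(κ²Φ_D η⁻⁴ J)^{1/6}`: with J in M⁻¹ cm⁻¹ nm⁴ the prefactor
yields Å, reported as nm. The refractive-index term is exposed as the
η⁻⁴ factor itself (default 0.3139, i.e. η = 1.336) because that is the
number entering the sixth root; κ² defaults to 0.476 (parallel transition
dipoles), with 2/3 available for the isotropic assumption. Distance
follows from `E = 1 − F/F0` and `r = R0(1/E − 1)^{1/6}`.

Reliability flags use the strict rules 0.5·R0 < r < 1.5·R0 and r < 10 nm.
Note an algebraic consequence: for E < 0.0808, (1/E−1)^{1/6} > 1.5, so a
single-point efficiency below ~8% always places r outside the strict
1.5·R0 bound regardless of the spectra. The package reports the strict
outcome rather than rounding it away.

## Synchronous scans

Constant-offset synchronous spectra (Δλ = 15 nm reports tyrosine, 60 nm
tryptophan microenvironments) are tracked by their band maximum per
concentration; the net shift is the peak at the highest concentration
minus the zero-quencher peak. Shifts below half a grid step are classified
as "none" — sub-resolution displacements are not claims.

## Synthetic data generator

The simulator emits Gaussian emission bands scaled per concentration by a
generative quenching model — linear Stern–Volmer `F = F0/(1+K_sv[Q])`,
one-to-n-site binding `F = F0/(1+K_a[Q]^n)`, or the product of both — with
K_a(T) optionally derived from a (ΔH, ΔS) pair through the van't Hoff
relation. The default design is the emulated study: 2 µM fluorophore,
quencher at 0, 1, 5, 10, 20, 30, 40, 50, 60 and 80 µM, 290/300/310 K,
excitation 280 nm, emission 285–450 nm at 1 nm. Noise is multiplicative
Gaussian (σ = noise_rel·signal), clipped at ±5σ so intensities stay
positive — a shot-noise-like model; the default study noise is 1%.
Absorbance fixtures are Beer–Lambert Gaussian extinction bands. The RNG is
`numpy.default_rng` (PCG64), recorded in output metadata; equal seeds give
bit-identical series. Absolute band amplitudes are arbitrary since every
downstream statistic uses intensity ratios only.

What the generator does *not* model: photobleaching, scattering,
instrument drift, wavelength-correlated noise, or upward-curving
(sphere-of-action) quenching. Passing recovery tests therefore show the
estimators are correct inverses of these generative models under
shot-like noise, not that they are robust to every instrument artefact.

### A caveat on log-log recovery at 1% noise

With single-point intensities and this design, the lowest concentrations
quench by about as much as the noise level, so the double-log ordinate
`log10((F0−F)/F)` is extremely heavy-tailed there and the intercept is an
extrapolation ~5 log-units beyond the data. Single-titration K_a estimates
then scatter by factors of several (the multiplicative error factor the
fit reports makes this visible), and ΔH/ΔS obtained from three such fits
over a 20 K span inherit tens of kJ mol⁻¹ of spread. K_sv and n, by
contrast, are recovered tightly. Users fitting real data should weight
their confidence accordingly or extend the concentration range.

## Numerical choices

* OLS everywhere is `scipy.stats.linregress`; tests verify it against the
  closed-form slope/intercept formulas to 1e-12.
* Peak ties break toward the shorter wavelength (documented, tested).
* Background subtraction interpolates the background onto the sample grid;
  extrapolation is refused.
* A constant F0/F series yields K_sv = 0 with r² reported as 0 (the
  regression line carries no information).
* Serialized reports use shortest-roundtrip float formatting; reloading a
  written titration reproduces the arrays bit for bit.

## Problem sizes

Every quantity derived from published table inputs is a ≤10-point
regression or a closed-form evaluation. The parameter-recovery study runs
200 simulated titrations per estimator (plus 200×3 for the thermodynamic
chain) at the full study design; the whole suite completes in seconds.
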