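# Methods

This note documents the models, conventions and numerical choices behind
`melanoscene`, in the order the pipeline applies them.

## Spectral representation

All computation happens on a common wavelength grid of 400–700 nm sampled
at 5 nm (61 points), the range covered by outdoor hyperspectral scene
sets. Input cubes on coarser grids are resampled per pixel by linear
interpolation; interpolation is exact at shared grid points and requests
outside a spectrum's support raise an error rather than extrapolate.
Quantities are relative throughout — the public radiance cubes carry no
absolute calibration — so every cross-environment statistic the package
reports is either scale-free (contrasts, ratios, NRD) or a within-unit
comparison. An optional global calibration factor on the excitation maps
is exposed for users with calibrated data.

### Photoreceptor sensitivities

Corneal spectral sensitivities for the L, M and S cones and melanopsin are
bundled as two-column text tables at 1 nm resolution, generated from the
Govardovskii A1 visual-pigment nomogram multiplied by a single-exponential
ocular-media transmittance model (optical density 1.0 at 400 nm, decay
scale 40 nm). The pigment peak parameters (563, 531, 419, 480 nm) were
chosen so that the corneal peaks land at the physiological values: L
565 nm, M 535 nm, S 440 nm, melanopsin 490 nm — the melanopsin corneal
peak shifted long of its 480 nm pigment absorbance peak by the
short-wavelength media filtering, as expected. These are analytic template
curves, not copies of the official CIE tabulations; any two-column text
table (e.g. the CIE physiological fundamentals) can be substituted through
the same loader for bit-exact standards conformance. Photopic luminous
efficiency V(λ) is taken from the bundled CIE 1931 ybar colour-matching
column; the 2° and 10° photopic curves differ too little to matter for
relative scene statistics. Tables are truncated to the working range
without renormalization (all peaks lie inside it, so the maximum stays 1);
truncation affects only absolute scale.

### Illuminants

Daylight illuminants are reconstructed from the standard CIE
three-component daylight model (S0 + M1·S1 + M2·S2, mixing coefficients
from the daylight-locus chromaticity) for any correlated colour
temperature in 4000–25 000 K, normalized to 100 at 560 nm. The bundled
basis-component and colour-matching tables reproduce the daylight-locus
chromaticity to ~1e-4 over the whole CCT range, which the test suite
checks. An equal-energy spectrum (EES) and arbitrary user tables are also
supported. Reflectance scenes are rendered to radiance by the per-pixel,
per-wavelength product with the illuminant.

## Excitation maps and ipRGC codification

Per-pixel excitation is the rectangle-rule integral of the radiance
spectrum against a sensitivity (step 5 nm). Luminance integrates against
the V(λ) table directly rather than through an explicit L+M weight pair —
bit-reproducible and equivalent up to the fundamental-to-V(λ) fit error.
Two linear cone/melanopsin combinations model the outer-ipRGC response:

    ipRGC1 = 0.667·L + 0.333·M + 0.69·Mel − 0.12·S
    ipRGC2 = L + M + Mel − S

The first carries pupillometry-derived weights, the second unit weights.
The subtractive S term can make ipRGC maps negative; no rectification is
applied, and in the daylight regime the generator produces this never
occurs at the patch level. All channel computations are linear in
radiance, which makes every downstream contrast invariant to global
rescaling — a property the tests exercise explicitly.

## Receptive-field windows and patches

Spatial pooling is modeled as a circular window of diameter 1.37°
(ipRGC dendritic field, parafovea), 2.4° (ipRGC, ~31° eccentricity) or
0.36° (parasol/luminance cell), converted to pixels via the scene's
pixels-per-degree and to retinal millimetres via 0.291 mm/deg. The
default window weight is the raised cosine ½(1 + cos(π·d/r)), normalized
to sum 1 over the patch: non-negative everywhere and zero at the rim,
consistent with the absence of spatial opponency in outer ipRGCs. A
`literal_cosine` mode evaluates the bare cos(π·d/r) form for replication;
note that on a full disk that form's normalizing sum is *negative* (the
rim ring outweighs the centre), so its normalized weights invert sign —
one reason the raised-cosine form is the default.

Pixels belong to a patch when their centres (0-based integer row/column,
origin top-left) lie within the radius. Patches tile on a square grid
anchored top-left, spaced one integer-rounded diameter apart, with partial
circles discarded; an optional jittered mode places non-overlapping
circles at random (seeded) for sensitivity analysis. Local excitation E_j
is the window-weighted mean of the channel map under patch j; local
radiance is the plain unweighted mean of wavelength-summed radiance.

## Between-patch contrast and channel pairing

The contrast of patch j is C_j = |E_j − E_s| / E_s, where E_s is the
unweighted arithmetic mean of that scene's local values for the channel
and field size (the "mean excitation of the patches"). Contrasts are
non-negative, scale-free and unbounded above; the pipeline never truncates
them (any clipping at 1 belongs to plotting, not analysis).

Comparing melanopsin against luminance contrast per receptive field
requires a pairing rule because the two channels use different field
sizes. The default `physiological` mode tiles melanopsin at 1.37° and
reads luminance through 0.36° windows co-centred on the same patch
centres — the only pairing that yields exactly one luminance value per
ipRGC field without arbitrary matching. The `matched` mode windows both
channels identically at the ipRGC size, the convention used by equal-field
analyses. The decile-binned median ± IQR readout of the paired contrasts
is configurable in bin count.

## Statistics

Group comparisons use the classical parametric toolkit: an optional
natural-log transform of strictly positive values (the standard variance
stabilizer for right-skewed intensity data; the transform is a config
switch and is reported in every output), pooled-variance independent
t-tests alongside two-sample F-tests for equal variances (Welch available
by flag), paired t-tests, and one-way ANOVA with Tukey–Kramer post-tests
honouring unequal group sizes (via `scipy.stats.tukey_hsd`). Summaries are
median and interquartile range with linear-interpolation (type-7)
quantiles. A Monte-Carlo check in the suite confirms the transformed
t-test holds its nominal 5% size on lognormal nulls.

The normalized relative difference across illuminants for a metric is
NRD_k = ((HM_k − Nat_k)/Nat_k) / max_k((HM_k − Nat_k)/Nat_k), so the most
differentiating illuminant scores exactly 1 and common rescalings cancel.

## Synthetic scenes

The generator emulates the statistical structure the analysis rests on,
not photorealism. Per pixel, reflectance is m(x,y) · (1 + Σ_k c_k(x,y)
b_k(λ)): a spatially correlated intensity field m around the target mean
reflectance, times a spectral shape built from four zero-mean smooth basis
functions (a red-edge sigmoid, a blue-heavy rolloff, and two Gaussian
bands) with correlated coefficient fields. Spatial structure is white or
1/f (FFT-filtered); coefficients scale with the relative reflectance sd,
so a zero-sd spec yields a uniform flat scene. Values are clipped to
[0.001, 1], and a spec whose clipping drags the realized mean more than
10% from the target is rejected. Fixed seeds give bit-identical cubes.

Environment defaults encode the empirical regularities the analysis
assumes: mean reflectance 0.2 (natural) vs 0.5 (human-made), with the
spatial sd fixed at 30% of the mean in both. Equal *relative* variability
is what makes absolute excitations differ strongly between environments
while contrast distributions remain statistically indistinguishable —
the pattern the scene data show. Scenes default to 160×160 px at
28 px/deg, which yields 16 parafoveal ipRGC patches per scene, matching
the per-scene patch count implied by the reported ANOVA degrees of
freedom. What the generator does **not** model — 3-D geometry, shadows,
specularities, camera noise, scale-invariant edge structure — means that
passing tests demonstrate the pipeline's correctness and the
reflectance-driven excitation gap, not the full second-order statistics of
real scenes.

### Silent-substitution validation stimuli

Validation scenes confine contrast to one channel. Over a set of primary
spectra, the solver finds a weight change dw with R·dw zero on every
silenced channel and equal to the required excitation step on the target,
where R is the (channel × primary) matrix of integrated responses. The
modulation is split symmetrically about the background operating point, so
the rendered pair is (background − dw/2, background + dw/2) and the
Michelson contrast between the two regions equals the between-patch
contrast the pipeline measures on a balanced two-region scene. When the
constraint system leaves spare degrees of freedom, the modulation
direction is chosen by a small linear program minimizing max_i |dw_i|/w_i,
i.e. maximizing the head-room to the non-negativity walls of the primary
gamut; otherwise it is the exact linear solve.

Defaults: six Gaussian primaries (peaks 405/445/485/525/565/625 nm, 15 nm
FWHM) and a frozen background weight vector placed at the gamut point that
maximizes melanopsin modulation depth. Six primaries (rather than the
minimal four) let photopic luminance — an independent V(λ) readout, not an
exact combination of the bundled cone templates — be silenced alongside
L, M and S when isolating melanopsin. With these defaults the maximum
achievable Michelson contrasts are roughly 0.55 (Mel), 0.8 (Lum), 0.98
(S) and 0.25 (L, M). "Luminance-only" stimuli co-modulate L and M in
proportion to their background excitations while silencing S and
melanopsin, since luminance is not independent of L and M. Isolation
holds to machine precision through the full rendering-and-readout path;
the suite asserts ≤1e-6.

## Pipeline conventions

Channel-to-field assignment: Mel, ipRGC1, ipRGC2 at 1.37° (Mel also at
2.4° for the field-size analysis), Lum at 0.36°, local radiance at the
ipRGC field. Field sizes a scene is too small to tile with at least two
patches are skipped and logged rather than aborting the run. The
field-size comparison pairs scenes by their mean excitation/contrast at
each size, since the two tilings have different patch counts. Every
output CSV embeds a hash of the configuration (excluding the output
directory), and the run log records window mode, transform, tiling and
seeds, so any reported number is regenerable.

## Known limitations

- Absolute excitations are in relative units; no α-opic calibration
  constant is applied (none is available for the source imagery).
- No ocular aging, pupil-size, or eccentricity-dependent sensitivity
  models; no rod or chromatic-opponent channels; no centre–surround
  fields.
- The synthetic generator's contrast spectrum is set by its 1/f or white
  coefficient fields and is not fit to any measured scene ensemble.
- The literal-cosine window is provided for replication only; its
  sign-inverting normalization on full disks makes it physiologically
  implausible.
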