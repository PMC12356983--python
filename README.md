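# melanoscene

Melanopsin and ipRGC image statistics from hyperspectral scenes.

Intrinsically photosensitive retinal ganglion cells (ipRGCs) express the
photopigment melanopsin and drive non-image-forming responses to light —
circadian entrainment, pupil control, alertness. How strongly they are
excited, and how much spatial contrast they see, depends jointly on the
spectral and spatial statistics of the environment and on their unusually
large receptive fields. `melanoscene` computes those statistics from
hyperspectral imagery: it turns radiance cubes (or reflectance cubes under
a chosen illuminant) into per-pixel photoreceptor excitation maps, pools
them through physiology-sized receptive-field windows, and compares the
resulting local excitations and between-patch contrasts across natural and
human-made environments. It is aimed at visual/circadian neuroscientists
and lighting researchers who want reproducible α-opic scene statistics
without hand-rolled spectral bookkeeping.

## The model

For each pixel, excitation of channel *c* is the integral of spectral
radiance against a corneal sensitivity (5 nm rectangle rule over
400–700 nm). Photopic luminance integrates against V(λ). Two linear
codification models combine cone and melanopsin inputs into an ipRGC
response:

    ipRGC1 = 0.667·L + 0.333·M + 0.69·Mel − 0.12·S
    ipRGC2 = L + M + Mel − S

Spatial pooling uses raised-cosine windows ω_i ∝ ½(1 + cos(π·d_i/r)),
normalized to sum 1, on non-overlapping circular patches of diameter
1.37° (ipRGC parafovea), 2.4° (ipRGC periphery) or 0.36° (parasol /
luminance), with 0.291 mm/deg retinal magnification. The local excitation
of patch *j* is E_j = Σ_i ω_i E_i and its between-patch Michelson contrast
is

    C_j = |E_j − E_s| / E_s,

with E_s the mean of the patches' local excitations in the scene.
Environment comparisons use median/IQR summaries, (optionally
log-transformed) t- and F-tests, one-way ANOVA with Tukey–Kramer
post-tests, and the normalized relative difference
NRD_k = ((HM_k − Nat_k)/Nat_k) / max_k(·) across illuminants. A synthetic
scene generator supplies reflectance cubes with environment-dependent
statistics, and silent-substitution stimuli (melanopsin-only or
luminance-only contrast) validate that the readout path isolates exactly
the intended channel. See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
import melanoscene as ms
from melanoscene.synthetic import SceneGeneratorSpec
from melanoscene.receptive_field import ReceptiveFieldSpec

scene = ms.generate_scene(SceneGeneratorSpec(environment="human_made", seed=42))
radiance = ms.apply_illuminant(scene, ms.cie_daylight_spd(6500.0))
maps = ms.compute_all_channels(radiance)

layout = ms.tile_patches(radiance.shape, ReceptiveFieldSpec(1.37),
                         radiance.pixels_per_degree, radiance.scene_id)
contrasts = ms.between_patch_contrast(ms.local_excitation(maps["Mel"], layout))
print(f"{len(layout)} patches")
print(f"melanopsin local excitation mean: {contrasts.scene_mean:.1f}")
print(f"melanopsin contrast median: {np.median(contrasts.contrasts):.3f}")
print(f"max contrast: {contrasts.contrasts.max():.3f}")
```

prints

```
16 patches
melanopsin local excitation mean: 4719.9
melanopsin contrast median: 0.185
max contrast: 0.536
```

i.e. a 160×160 px human-made-like scene at 28 px/deg holds 16 parafoveal
ipRGC fields whose melanopsin excitations (relative α-opic units) scatter
around their scene mean with a median absolute Michelson contrast of
about 0.19, the largest patch deviating by 54%. The same objects drive
the command line:

```
melanoscene synth --env natural --seed 7 --out scene.mat
melanoscene analyze contrast --scene scene.mat --quantity reflectance \
    --ppd 28 --channel Mel --field-deg 1.37 --out contrasts.csv
melanoscene run --config config.yaml --out-dir reports/
```

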