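"""Per-pixel photoreceptor excitation maps and ipRGC codification models.

Excitation is the rectangle-rule integral of the pixel radiance spectrum
against a spectral sensitivity (step 5 nm on the working grid). Photopic
luminance integrates radiance against V(lambda) directly. Two linear
cone+melanopsin combinations model the outer-ipRGC response:

    ipRGC1 = 0.667 L + 0.333 M + 0.69 Mel - 0.12 S   (pupillometry-derived weights)
    ipRGC2 = L + M + Mel - S                          (unit weights)

Both retain the subtractive S-cone term, so ipRGC maps may be negative;
no rectification is applied. All outputs are in consistent relative units
(the source cubes carry no absolute calibration); an optional global
``calibration`` factor rescales every map for users with calibrated data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionMismatchError, GridMismatchError, SceneFormatError
from .spectra import HyperspectralScene, SpectralFunction, sensitivity

#: trapezoid/rectangle step of the working grid, nm
_DELTA = 5.0

#: Eq-style ipRGC combination weights, order (L, M, Mel, S-subtractive)
IPRGC1_WEIGHTS = {"L": 0.667, "M": 0.333, "Mel": 0.69, "S": -0.12}
IPRGC2_WEIGHTS = {"L": 1.0, "M": 1.0, "Mel": 1.0, "S": -1.0}

CHANNELS = ("L", "M", "S", "Mel", "Lum", "ipRGC1", "ipRGC2", "Rad")


@dataclass
class ChannelMap:
    """Per-pixel scalar excitation of one channel for one scene."""

    values: np.ndarray
    channel: str
    scene_id: str
    pixels_per_degree: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionMismatchError(
                f"channel map must be 2-D, got shape {self.values.shape}"
            )
        if self.channel not in CHANNELS:
            raise SceneFormatError(f"unknown channel {self.channel!r}")
        if not np.all(np.isfinite(self.values)):
            raise SceneFormatError(f"{self.channel} map contains non-finite values")
        # additive channels are non-negative; ipRGC maps may dip below zero
        # through the subtractive S input
        if self.channel not in ("ipRGC1", "ipRGC2") and np.any(self.values < 0):
            raise SceneFormatError(f"{self.channel} map contains negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _require_radiance(scene: HyperspectralScene) -> None:
    if scene.quantity != "radiance":
        raise SceneFormatError(
            f"excitation requires a radiance scene, got {scene.quantity!r}; "
            "use apply_illuminant on reflectance data first"
        )


def compute_excitation(
    scene: HyperspectralScene,
    sens: SpectralFunction,
    channel: str = "L",
    calibration: float = 1.0,
) -> ChannelMap:
    """Integrate each pixel's radiance spectrum against a sensitivity.

    ``excitation = sum_lambda radiance(lambda) * sens(lambda) * 5 nm``.
    Scene and sensitivity must share the working grid exactly.
    """
    _require_radiance(scene)
    if scene.wavelengths_nm.size != sens.wavelengths_nm.size or not np.allclose(
        scene.wavelengths_nm, sens.wavelengths_nm
    ):
        raise GridMismatchError(
            "scene and sensitivity are on different wavelength grids"
        )
    values = calibration * _DELTA * (scene.cube @ sens.values)
    return ChannelMap(values, channel, scene.scene_id, scene.pixels_per_degree)


def compute_luminance(
    scene: HyperspectralScene, calibration: float = 1.0
) -> ChannelMap:
    """Photopic luminance map: radiance integrated against V(lambda)."""
    vlambda = sensitivity("Vlambda", scene.wavelengths_nm)
    out = compute_excitation(scene, vlambda, channel="Lum", calibration=calibration)
    return out


def integrated_radiance(scene: HyperspectralScene) -> ChannelMap:
    """Wavelength-summed radiance per pixel (the 'Rad' channel)."""
    _require_radiance(scene)
    values = _DELTA * scene.cube.sum(axis=2)
    return ChannelMap(values, "Rad", scene.scene_id, scene.pixels_per_degree)


def _combine(
    weights: dict[str, float],
    channel: str,
    L: ChannelMap,
    M: ChannelMap,
    S: ChannelMap,
    Mel: ChannelMap,
) -> ChannelMap:
    maps = {"L": L, "M": M, "S": S, "Mel": Mel}
    shapes = {m.shape for m in maps.values()}
    if len(shapes) != 1:
        raise DimensionMismatchError(f"input maps differ in shape: {sorted(shapes)}")
    ids = {m.scene_id for m in maps.values()}
    if len(ids) != 1:
        raise DimensionMismatchError(f"input maps come from different scenes: {ids}")
    values = sum(weights[name] * maps[name].values for name in ("L", "M", "Mel", "S"))
    return ChannelMap(values, channel, L.scene_id, L.pixels_per_degree)


def iprgc1(L: ChannelMap, M: ChannelMap, S: ChannelMap, Mel: ChannelMap) -> ChannelMap:
    """Pupillometry-weighted ipRGC codification: 0.667L + 0.333M + 0.69Mel - 0.12S."""
    return _combine(IPRGC1_WEIGHTS, "ipRGC1", L, M, S, Mel)


def iprgc2(L: ChannelMap, M: ChannelMap, S: ChannelMap, Mel: ChannelMap) -> ChannelMap:
    """Unit-weighted ipRGC codification: L + M + Mel - S."""
    return _combine(IPRGC2_WEIGHTS, "ipRGC2", L, M, S, Mel)


def compute_all_channels(
    scene: HyperspectralScene, calibration: float = 1.0
) -> dict[str, ChannelMap]:
    """All channel maps for a radiance scene in one call.

    Returns a dict with keys L, M, S, Mel, Lum, ipRGC1, ipRGC2, Rad; the
    ipRGC maps are exact linear combinations of the returned L/M/S/Mel maps.
    """
    _require_radiance(scene)
    maps: dict[str, ChannelMap] = {}
    for name in ("L", "M", "S", "Mel"):
        sens = sensitivity(name, scene.wavelengths_nm)
        maps[name] = compute_excitation(scene, sens, channel=name, calibration=calibration)
    maps["Lum"] = compute_luminance(scene, calibration=calibration)
    maps["ipRGC1"] = iprgc1(maps["L"], maps["M"], maps["S"], maps["Mel"])
    maps["ipRGC2"] = iprgc2(maps["L"], maps["M"], maps["S"], maps["Mel"])
    rad = integrated_radiance(scene)
    maps["Rad"] = ChannelMap(
        calibration * rad.values, "Rad", scene.scene_id, scene.pixels_per_degree
    )
    return maps
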