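"""Spectral data types, resampling, illuminants, and photoreceptor sensitivities.

Everything downstream works on a common 5-nm wavelength grid spanning
400-700 nm (61 samples), the range covered by outdoor hyperspectral scene
sets. Spectral sensitivities are bundled as two-column text tables at 1-nm
resolution and are truncated to the working range without renormalization;
since every statistic in the pipeline is relative (contrasts, ratios,
between-group comparisons), the truncation affects only the absolute scale.

Illuminants are either CIE daylight spectra reconstructed from the standard
three-component daylight model at any correlated colour temperature between
4000 K and 25,000 K, or an equal-energy spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np

from .errors import (
    ExtrapolationError,
    GridMismatchError,
    ReflectanceRangeError,
    SceneFormatError,
)

#: the pipeline's working wavelength grid: 400-700 nm at 5 nm (61 samples)
WORKING_GRID = np.arange(400.0, 700.0 + 1e-9, 5.0)

#: wavelength step of the working grid, nm
DELTA_LAMBDA = 5.0

_CHANNELS_WITH_TABLES = ("L", "M", "S", "Mel", "Vlambda")

_SENSITIVITY_FILES = {
    "L": "l_cone_sensitivity.csv",
    "M": "m_cone_sensitivity.csv",
    "S": "s_cone_sensitivity.csv",
    "Mel": "melanopic_sensitivity.csv",
    "Vlambda": "photopic_luminosity.csv",
}

Quantity = Literal["radiance", "reflectance"]
Environment = Literal["natural", "human_made"]


@dataclass(frozen=True)
class SpectralFunction:
    """A sampled function of wavelength.

    Used for photoreceptor sensitivities (unitless, peak-normalized to 1),
    illuminant spectral power distributions (relative power) and single-pixel
    radiance or reflectance spectra (relative energy units).

    Parameters
    ----------
    wavelengths_nm :
        Strictly increasing wavelength grid in nanometres, within [380, 780].
    values :
        Non-negative, finite samples, one per grid point.
    name :
        Free-text label carried through resampling.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", v)
        if wl.ndim != 1 or v.ndim != 1 or wl.size != v.size:
            raise SceneFormatError(
                f"wavelengths ({wl.shape}) and values ({v.shape}) must be "
                "1-D arrays of equal length"
            )
        if wl.size < 2:
            raise SceneFormatError("a spectrum needs at least two samples")
        if not np.all(np.diff(wl) > 0):
            raise SceneFormatError("wavelength grid must be strictly increasing")
        if wl[0] < 380.0 - 1e-9 or wl[-1] > 780.0 + 1e-9:
            raise SceneFormatError(
                f"wavelength grid [{wl[0]}, {wl[-1]}] outside the supported "
                "range [380, 780] nm"
            )
        if not np.all(np.isfinite(v)):
            raise SceneFormatError("spectral values must be finite")
        if np.any(v < 0):
            raise SceneFormatError("spectral values must be non-negative")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralFunction):
            return NotImplemented
        return bool(
            np.array_equal(self.wavelengths_nm, other.wavelengths_nm)
            and np.array_equal(self.values, other.values)
        )

    def __call__(self, wavelength_nm: float) -> float:
        """Linearly interpolated value at ``wavelength_nm`` (no extrapolation)."""
        wl = float(wavelength_nm)
        if wl < self.wavelengths_nm[0] or wl > self.wavelengths_nm[-1]:
            raise ExtrapolationError(
                f"{wl} nm outside spectrum support "
                f"[{self.wavelengths_nm[0]}, {self.wavelengths_nm[-1]}]"
            )
        return float(np.interp(wl, self.wavelengths_nm, self.values))

    def normalized(self) -> "SpectralFunction":
        """Peak-normalized copy (max value 1)."""
        peak = float(self.values.max())
        if peak <= 0:
            raise SceneFormatError("cannot peak-normalize an all-zero spectrum")
        return replace(self, values=self.values / peak)


@dataclass
class HyperspectralScene:
    """A wavelength-indexed image cube with the metadata the pipeline needs.

    Parameters
    ----------
    cube :
        ``(height, width, n_wavelengths)`` non-negative array. Reflectance
        cubes must lie in [0, 1].
    wavelengths_nm :
        Grid matching the cube's third axis.
    quantity :
        ``"radiance"`` or ``"reflectance"``.
    environment :
        ``"natural"`` or ``"human_made"`` scene label (taken as input
        metadata; no classifier is run here).
    pixels_per_degree :
        Angular sampling of the image, needed to convert receptive-field
        diameters from degrees of visual angle to pixels.
    scene_id :
        Identifier carried into every downstream record.
    """

    cube: np.ndarray
    wavelengths_nm: np.ndarray
    quantity: Quantity
    environment: Environment
    pixels_per_degree: float
    scene_id: str = ""

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.cube.ndim != 3:
            raise SceneFormatError(f"cube must be 3-D, got shape {self.cube.shape}")
        if self.wavelengths_nm.ndim != 1 or self.wavelengths_nm.size != self.cube.shape[2]:
            raise SceneFormatError(
                f"wavelength axis length {self.wavelengths_nm.size} does not "
                f"match cube third axis {self.cube.shape[2]}"
            )
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise SceneFormatError("scene wavelength axis must be strictly increasing")
        if self.quantity not in ("radiance", "reflectance"):
            raise SceneFormatError(f"unknown quantity {self.quantity!r}")
        if self.environment not in ("natural", "human_made"):
            raise SceneFormatError(f"unknown environment {self.environment!r}")
        n_bad = int(np.size(self.cube) - np.isfinite(self.cube).sum())
        if n_bad:
            raise SceneFormatError(f"cube contains {n_bad} non-finite pixel value(s)")
        n_neg = int((self.cube < 0).sum())
        if n_neg:
            raise SceneFormatError(f"cube contains {n_neg} negative value(s)")
        if self.quantity == "reflectance":
            n_over = int((self.cube > 1.0).sum())
            if n_over:
                raise ReflectanceRangeError(
                    f"reflectance cube contains {n_over} value(s) above 1"
                )
        if not self.pixels_per_degree > 0:
            raise SceneFormatError("pixels_per_degree must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cube.shape[:2]


def resample_spectrum(f: SpectralFunction, target_grid: np.ndarray) -> SpectralFunction:
    """Linearly resample ``f`` onto ``target_grid``.

    Values at grid points shared with the source are unchanged; requests
    outside the source support raise :class:`ExtrapolationError` rather than
    silently extrapolating.
    """
    target = np.asarray(target_grid, dtype=float)
    if target[0] < f.wavelengths_nm[0] - 1e-9 or target[-1] > f.wavelengths_nm[-1] + 1e-9:
        raise ExtrapolationError(
            f"target grid [{target[0]}, {target[-1]}] extends beyond source "
            f"support [{f.wavelengths_nm[0]}, {f.wavelengths_nm[-1]}]"
        )
    values = np.interp(target, f.wavelengths_nm, f.values)
    return SpectralFunction(target, values, name=f.name)


def resample_scene(scene: HyperspectralScene, step_nm: float = 5.0) -> HyperspectralScene:
    """Resample every pixel spectrum of ``scene`` to a uniform ``step_nm`` grid.

    The target grid is 400-700 nm; the scene's own grid must span it. A scene
    already on the target grid is returned with a bitwise-equal cube.
    """
    target = np.arange(400.0, 700.0 + 1e-9, float(step_nm))
    if scene.wavelengths_nm[0] > 400.0 + 1e-9 or scene.wavelengths_nm[-1] < 700.0 - 1e-9:
        raise ExtrapolationError(
            f"scene grid [{scene.wavelengths_nm[0]}, {scene.wavelengths_nm[-1]}] "
            "does not span [400, 700] nm"
        )
    if scene.wavelengths_nm.size == target.size and np.allclose(
        scene.wavelengths_nm, target
    ):
        cube = scene.cube.copy()
    else:
        # np.interp along the wavelength axis, vectorized over pixels
        h, w, _ = scene.cube.shape
        flat = scene.cube.reshape(h * w, -1)
        idx = np.searchsorted(scene.wavelengths_nm, target, side="right") - 1
        idx = np.clip(idx, 0, scene.wavelengths_nm.size - 2)
        x0 = scene.wavelengths_nm[idx]
        x1 = scene.wavelengths_nm[idx + 1]
        t = (target - x0) / (x1 - x0)
        cube = (flat[:, idx] * (1.0 - t) + flat[:, idx + 1] * t).reshape(h, w, -1)
    return HyperspectralScene(
        cube=cube,
        wavelengths_nm=target,
        quantity=scene.quantity,
        environment=scene.environment,
        pixels_per_degree=scene.pixels_per_degree,
        scene_id=scene.scene_id,
    )


# ---------------------------------------------------------------------------
# illuminants


def _load_table(filename: str) -> np.ndarray:
    path = resources.files("melanoscene").joinpath("data", filename)
    with resources.as_file(path) as p:
        return np.loadtxt(p, delimiter=",", comments="#")


def daylight_locus_chromaticity(cct_kelvin: float) -> tuple[float, float]:
    """CIE daylight-locus chromaticity (x_D, y_D) for a CCT in [4000, 25000] K."""
    T = float(cct_kelvin)
    if not 4000.0 <= T <= 25000.0:
        raise ValueError(f"CCT {T} K outside the daylight model range [4000, 25000] K")
    if T <= 7000.0:
        x = 0.244063 + 0.09911e3 / T + 2.9678e6 / T**2 - 4.6070e9 / T**3
    else:
        x = 0.237040 + 0.24748e3 / T + 1.9018e6 / T**2 - 2.0064e9 / T**3
    y = -3.000 * x * x + 2.870 * x - 0.275
    return x, y


def cie_daylight_spd(
    cct_kelvin: float, grid: np.ndarray | None = None
) -> SpectralFunction:
    """Relative SPD of a CIE daylight illuminant at the given CCT.

    Reconstructed from the three daylight basis components
    ``S0 + M1*S1 + M2*S2`` with the mixing coefficients determined by the
    daylight-locus chromaticity, then normalized to 100 at 560 nm. The
    default grid is the working 400-700 nm / 5 nm grid; pass a wider `grid`
    (within 380-780) for colorimetric checks.
    """
    T = float(cct_kelvin)
    if not 4000.0 <= T <= 25000.0:
        raise ValueError(f"CCT {T} K outside the supported range [4000, 25000] K")
    xD, yD = daylight_locus_chromaticity(T)
    M = 0.0241 + 0.2562 * xD - 0.7341 * yD
    M1 = (-1.3515 - 1.7703 * xD + 5.9114 * yD) / M
    M2 = (0.0300 - 31.4424 * xD + 30.0717 * yD) / M
    table = _load_table("cie_daylight_components.csv")
    target = WORKING_GRID if grid is None else np.asarray(grid, dtype=float)
    S0 = np.interp(target, table[:, 0], table[:, 1])
    S1 = np.interp(target, table[:, 0], table[:, 2])
    S2 = np.interp(target, table[:, 0], table[:, 3])
    spd = S0 + M1 * S1 + M2 * S2
    # 560 nm is the conventional normalization point; S1 and S2 vanish there
    ref = float(np.interp(560.0, target, spd))
    return SpectralFunction(target, 100.0 * spd / ref, name=f"D_{T:.0f}K")


def equal_energy_spd(
    value: float = 100.0, grid: np.ndarray | None = None
) -> SpectralFunction:
    """Equal-energy spectrum: constant relative power at every wavelength."""
    target = WORKING_GRID if grid is None else np.asarray(grid, dtype=float)
    return SpectralFunction(target, np.full(target.size, float(value)), name="EES")


def apply_illuminant(
    scene: HyperspectralScene, illuminant: SpectralFunction
) -> HyperspectralScene:
    """Render a reflectance scene under an illuminant.

    Per pixel and wavelength the radiance is ``reflectance * illuminant``;
    both operands must already share the working grid.
    """
    if scene.quantity != "reflectance":
        raise SceneFormatError(
            f"apply_illuminant needs a reflectance scene, got {scene.quantity!r}"
        )
    if scene.wavelengths_nm.size != illuminant.wavelengths_nm.size or not np.allclose(
        scene.wavelengths_nm, illuminant.wavelengths_nm
    ):
        raise GridMismatchError(
            "scene and illuminant are not on the same wavelength grid; "
            "resample both to the working grid first"
        )
    return HyperspectralScene(
        cube=scene.cube * illuminant.values,
        wavelengths_nm=scene.wavelengths_nm.copy(),
        quantity="radiance",
        environment=scene.environment,
        pixels_per_degree=scene.pixels_per_degree,
        scene_id=scene.scene_id,
    )


def parse_illuminant(spec: str) -> SpectralFunction:
    """Parse an illuminant selector: ``"EES"``, ``"D:<CCT>"`` or a file path.

    File-based illuminants use the two-column (wavelength_nm, value) text
    format and are resampled to the working grid.
    """
    s = spec.strip()
    if s.upper() == "EES":
        return equal_energy_spd()
    if s.upper().startswith("D:"):
        return cie_daylight_spd(float(s[2:]))
    return resample_spectrum(load_spectrum(Path(s)), WORKING_GRID)


# ---------------------------------------------------------------------------
# sensitivities and colorimetry


def load_spectrum(path: Path | str, name: str = "") -> SpectralFunction:
    """Load a two-column (wavelength_nm, value) plain-text spectrum."""
    data = np.loadtxt(path, delimiter=",", comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise SceneFormatError(f"{path}: expected two comma-separated columns")
    return SpectralFunction(data[:, 0], data[:, 1], name=name or str(path))


def sensitivity(channel: str, grid: np.ndarray | None = None) -> SpectralFunction:
    """Bundled spectral sensitivity for ``channel``.

    Channels: ``"L"``, ``"M"``, ``"S"`` (cone fundamentals), ``"Mel"``
    (melanopic corneal sensitivity) and ``"Vlambda"`` (photopic luminous
    efficiency). Tables are stored at 1-nm resolution, peak-normalized, and
    resampled onto the working grid (or ``grid``) without renormalization.
    """
    if channel not in _SENSITIVITY_FILES:
        raise KeyError(
            f"unknown sensitivity {channel!r}; choose from {_CHANNELS_WITH_TABLES}"
        )
    table = _load_table(_SENSITIVITY_FILES[channel])
    f = SpectralFunction(table[:, 0], table[:, 1], name=channel)
    target = WORKING_GRID if grid is None else np.asarray(grid, dtype=float)
    return resample_spectrum(f, target)


def color_matching_functions(grid: np.ndarray | None = None) -> np.ndarray:
    """CIE 1931 colour-matching functions on ``grid`` (default: table grid).

    Returns an ``(n, 4)`` array of columns (wavelength, xbar, ybar, zbar).
    """
    table = _load_table("cie1931_cmf_2deg.csv")
    if grid is None:
        return table
    target = np.asarray(grid, dtype=float)
    out = np.empty((target.size, 4))
    out[:, 0] = target
    for j in (1, 2, 3):
        out[:, j] = np.interp(target, table[:, 0], table[:, j])
    return out


def chromaticity(f: SpectralFunction) -> tuple[float, float]:
    """CIE 1931 (x, y) chromaticity of a spectral power distribution."""
    cmf = color_matching_functions(f.wavelengths_nm)
    X = float(np.sum(f.values * cmf[:, 1]))
    Y = float(np.sum(f.values * cmf[:, 2]))
    Z = float(np.sum(f.values * cmf[:, 3]))
    total = X + Y + Z
    if total <= 0:
        raise SceneFormatError("chromaticity undefined for an all-zero spectrum")
    return X / total, Y / total
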