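"""Synthetic hyperspectral scenes and silent-substitution validation stimuli.

The scene generator emulates the statistical structure the analysis relies
on: per-pixel reflectance spectra built from a small smooth spectral basis
with spatially correlated coefficients, under a configurable daylight
illuminant. Environment defaults encode the empirical regularity that
human-made scenes have higher mean reflectance than natural ones
(0.5 vs 0.2) with the same *relative* spatial variability (sd = 30% of the
mean), so absolute excitations differ strongly between environments while
contrast distributions do not.

Silent substitution solves for a pair of spectra straddling a background
such that exactly one photoreceptor channel sees a Michelson contrast
between the two while the others are held constant. The default system
uses six narrowband Gaussian primaries so that photopic luminance (an
independent V(lambda) readout, not an exact combination of the bundled
cone templates) can be silenced alongside the three non-target receptor
channels when isolating melanopsin; the modulation is split symmetrically
about the background, and when the constraint system leaves spare degrees
of freedom the modulation direction is chosen by a small linear program
that maximizes the available contrast gamut. "Luminance-only" stimuli
co-modulate L and M in proportion to their background excitations while
silencing S and melanopsin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InfeasibleSpecError, RankDeficientError
from .spectra import (
    WORKING_GRID,
    HyperspectralScene,
    SpectralFunction,
    sensitivity,
)

#: environment-specific generator defaults: mean reflectance, natural < human-made
ENV_MEAN_REFLECTANCE = {"natural": 0.2, "human_made": 0.5}

#: spatial sd of pixel mean reflectance, as a fraction of the mean
RELATIVE_REFLECTANCE_SD = 0.3

#: default angular sampling of generated scenes, pixels per degree
DEFAULT_PIXELS_PER_DEGREE = 28.0

#: default primary peak wavelengths (nm) and common FWHM (nm)
DEFAULT_PRIMARY_PEAKS = (405.0, 445.0, 485.0, 525.0, 565.0, 625.0)
DEFAULT_PRIMARY_FWHM = 15.0

#: default background primary weights: a gamut-centered operating point that
#: maximizes the melanopsin modulation depth of the default primary system
DEFAULT_BACKGROUND_WEIGHTS = (1.6786, 0.6020, 0.0839, 0.7625, 1.1944, 1.6786)

_SS_CHANNELS = ("L", "M", "S", "Mel", "Lum")

#: channels held constant for each isolation target
SILENCED_CHANNELS = {
    "L": ("M", "S", "Mel"),
    "M": ("L", "S", "Mel"),
    "S": ("L", "M", "Mel"),
    "Mel": ("L", "M", "S", "Lum"),
    "Lum": ("S", "Mel"),
}


@dataclass
class SceneGeneratorSpec:
    """Parameters of one generated reflectance scene.

    ``mean_reflectance`` and ``reflectance_sd`` default per environment
    (natural: 0.2 +/- 0.06; human-made: 0.5 +/- 0.15). ``spatial_correlation``
    selects white or 1/f spatial structure for the coefficient fields.
    """

    environment: str = "natural"
    height: int = 160
    width: int = 160
    pixels_per_degree: float = DEFAULT_PIXELS_PER_DEGREE
    mean_reflectance: float | None = None
    reflectance_sd: float | None = None
    spatial_correlation: str = "one_over_f"
    seed: int = 0
    scene_id: str = ""

    def resolved_mean(self) -> float:
        if self.mean_reflectance is not None:
            return float(self.mean_reflectance)
        return ENV_MEAN_REFLECTANCE[self.environment]

    def resolved_sd(self) -> float:
        if self.reflectance_sd is not None:
            return float(self.reflectance_sd)
        return RELATIVE_REFLECTANCE_SD * self.resolved_mean()


@dataclass
class SilentSubstitutionSpec:
    """Target channel, contrast, and primary system of a validation stimulus."""

    target_channel: str = "Mel"
    target_contrast: float = 0.3
    primaries: list[SpectralFunction] | None = None
    background_weights: np.ndarray | None = None
    layout: str = "two_region"  # or "checkerboard"

    def __post_init__(self) -> None:
        if self.target_channel not in _SS_CHANNELS:
            raise ValueError(f"unknown target channel {self.target_channel!r}")
        if self.target_contrast < 0 or self.target_contrast >= 1:
            raise InfeasibleSpecError(
                f"target Michelson contrast must be in [0, 1), got {self.target_contrast}"
            )
        if self.layout not in ("two_region", "checkerboard"):
            raise ValueError(f"unknown layout {self.layout!r}")


# ---------------------------------------------------------------------------
# reflectance scene generation


def _correlated_field(h: int, w: int, rng: np.random.Generator, kind: str) -> np.ndarray:
    """Zero-mean, unit-variance random field, spatially white or 1/f."""
    z = rng.standard_normal((h, w))
    if kind == "white":
        out = z
    elif kind == "one_over_f":
        fy = np.fft.fftfreq(h)[:, None]
        fx = np.fft.fftfreq(w)[None, :]
        f = np.hypot(fy, fx)
        amp = np.zeros_like(f)
        nonzero = f > 0
        amp[nonzero] = 1.0 / f[nonzero]
        out = np.fft.ifft2(np.fft.fft2(z) * amp).real
    else:
        raise InfeasibleSpecError(f"unknown spatial correlation {kind!r}")
    out = out - out.mean()
    sd = out.std()
    if sd == 0:
        return out
    return out / sd


def _spectral_basis(grid: np.ndarray) -> np.ndarray:
    """Zero-mean smooth spectral shapes (rows) mimicking surface reflectances."""
    lam = grid
    shapes = [
        1.0 / (1.0 + np.exp(-(lam - 580.0) / 20.0)),  # red edge (vegetation-like)
        1.0 / (1.0 + np.exp((lam - 520.0) / 20.0)),   # blue-heavy rolloff
        np.exp(-((lam - 550.0) ** 2) / (2 * 40.0**2)),  # mid-band bump
        np.exp(-((lam - 450.0) ** 2) / (2 * 30.0**2)),  # short-wave bump
    ]
    basis = []
    for s in shapes:
        s = s - s.mean()
        basis.append(s / np.abs(s).max())
    return np.array(basis)


def generate_scene(spec: SceneGeneratorSpec) -> HyperspectralScene:
    """Generate a reflectance scene with the configured spatial/spectral statistics.

    Per pixel the reflectance spectrum is ``m(x, y) * (1 + sum_k c_k(x, y)
    b_k(lambda))`` with ``m`` a correlated intensity field around
    ``mean_reflectance`` and zero-mean spectral basis shapes ``b_k`` whose
    coefficient amplitude scales with the relative reflectance sd (so
    ``reflectance_sd = 0`` yields a spatially uniform, spectrally flat
    scene). Values are clipped to [0.001, 1]; if clipping drags the realized
    scene mean more than 10% away from the requested mean the spec is
    rejected. Fixed seed -> bit-identical scene.
    """
    mean = spec.resolved_mean()
    sd = spec.resolved_sd()
    if not 0.0 < mean < 1.0:
        raise InfeasibleSpecError(f"mean_reflectance must be in (0, 1), got {mean}")
    if sd < 0:
        raise InfeasibleSpecError(f"reflectance_sd must be >= 0, got {sd}")
    rng = np.random.default_rng(spec.seed)
    grid = WORKING_GRID
    h, w = spec.height, spec.width
    m = mean + sd * _correlated_field(h, w, rng, spec.spatial_correlation)
    basis = _spectral_basis(grid)
    chroma_amp = 0.5 * (sd / mean)
    shape = np.ones((h, w, grid.size))
    for b in basis:
        c = chroma_amp * _correlated_field(h, w, rng, spec.spatial_correlation)
        shape += c[:, :, None] * b[None, None, :]
    cube = np.clip(m[:, :, None] * shape, 0.001, 1.0)
    realized = float(cube.mean())
    if abs(realized - mean) > 0.1 * mean:
        raise InfeasibleSpecError(
            f"clipping moved the scene mean to {realized:.4f}, more than 10% "
            f"from the requested {mean:.4f}; reduce reflectance_sd"
        )
    scene_id = spec.scene_id or f"synthetic_{spec.environment}_{spec.seed}"
    return HyperspectralScene(
        cube=cube,
        wavelengths_nm=grid.copy(),
        quantity="reflectance",
        environment=spec.environment,
        pixels_per_degree=spec.pixels_per_degree,
        scene_id=scene_id,
    )


# ---------------------------------------------------------------------------
# silent substitution


def gaussian_primaries(
    peaks: tuple[float, ...] = DEFAULT_PRIMARY_PEAKS,
    fwhm_nm: float = DEFAULT_PRIMARY_FWHM,
) -> list[SpectralFunction]:
    """Gaussian primary SPDs on the working grid, unit peak."""
    sigma = fwhm_nm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    out = []
    for peak in peaks:
        vals = np.exp(-((WORKING_GRID - peak) ** 2) / (2 * sigma**2))
        out.append(SpectralFunction(WORKING_GRID, vals, name=f"primary_{peak:.0f}"))
    return out


def _response_matrix(primaries: list[SpectralFunction]) -> np.ndarray:
    """(5 channels x n primaries) matrix of integrated responses."""
    sens = {ch: sensitivity(ch if ch != "Lum" else "Vlambda") for ch in _SS_CHANNELS}
    R = np.empty((len(_SS_CHANNELS), len(primaries)))
    for j, prim in enumerate(primaries):
        if prim.wavelengths_nm.size != WORKING_GRID.size or not np.allclose(
            prim.wavelengths_nm, WORKING_GRID
        ):
            raise InfeasibleSpecError("primaries must be on the working grid")
        for i, ch in enumerate(_SS_CHANNELS):
            R[i, j] = 5.0 * float(np.dot(prim.values, sens[ch].values))
    return R


def _gamut_direction(
    A: np.ndarray, b: np.ndarray, w_bg: np.ndarray
) -> np.ndarray:
    """Solve A dw = b; spare degrees of freedom maximize the contrast gamut.

    For a square system this is the plain linear solve. Underdetermined
    systems have a solution family ``u0 + N alpha`` (N spanning the null
    space); the spare coordinates are set by a linear program minimizing
    ``max_i |dw_i| / w_i``, i.e. pushing the modulation as far from the
    non-negativity walls of the primary gamut as possible. Falls back to
    the least-norm solution if the program fails.
    """
    from scipy.linalg import null_space
    from scipy.optimize import linprog

    if A.shape[0] == A.shape[1]:
        return np.linalg.solve(A, b)
    u0, *_ = np.linalg.lstsq(A, b, rcond=None)
    N = null_space(A)
    k = N.shape[1]
    if k == 0:
        return u0
    n = w_bg.size
    cost = np.zeros(k + 1)
    cost[-1] = 1.0
    A_ub = np.zeros((2 * n, k + 1))
    b_ub = np.zeros(2 * n)
    for i in range(n):
        A_ub[2 * i, :k] = N[i]
        A_ub[2 * i, -1] = -w_bg[i]
        b_ub[2 * i] = -u0[i]
        A_ub[2 * i + 1, :k] = -N[i]
        A_ub[2 * i + 1, -1] = -w_bg[i]
        b_ub[2 * i + 1] = u0[i]
    res = linprog(
        cost, A_ub=A_ub, b_ub=b_ub, bounds=[(None, None)] * k + [(1e-12, None)]
    )
    if not res.success:
        return u0
    return u0 + N @ res.x[:k]


def solve_silent_substitution(
    spec: SilentSubstitutionSpec,
) -> tuple[SpectralFunction, SpectralFunction]:
    """Solve for a (background, modulated) spectrum pair isolating one channel.

    The modulation is split symmetrically about the nominal background, so
    the returned pair is (background - delta/2, background + delta/2). The
    Michelson contrast between the two spectra on the target channel,
    ``(E_mod - E_bg) / (E_mod + E_bg)``, equals ``target_contrast`` — which
    is exactly the between-patch contrast a balanced two-region scene
    produces — while the excitation of every silenced channel (see
    ``SILENCED_CHANNELS``) is unchanged to numerical precision.
    """
    if spec.primaries is not None:
        primaries = spec.primaries
        default_bg = np.ones(len(primaries))
    else:
        primaries = gaussian_primaries()
        default_bg = np.array(DEFAULT_BACKGROUND_WEIGHTS)
    n = len(primaries)
    if n < 4:
        raise RankDeficientError(f"need >= 4 primaries, got {n}")
    R = _response_matrix(primaries)
    core = [_SS_CHANNELS.index(c) for c in ("L", "M", "S", "Mel")]
    if np.linalg.matrix_rank(R[core, :]) < 4:
        # name the channel whose response row is (nearly) dependent on the rest
        deficient = "unknown"
        for ch, i in zip(("L", "M", "S", "Mel"), core):
            others = [j for j in core if j != i]
            if np.linalg.matrix_rank(R[others, :]) == np.linalg.matrix_rank(R[core, :]):
                deficient = ch
                break
        raise RankDeficientError(
            f"primary system cannot independently control channel {deficient}"
        )
    w_mid = (
        default_bg
        if spec.background_weights is None
        else np.asarray(spec.background_weights, dtype=float)
    )
    if w_mid.size != n or np.any(w_mid <= 0):
        raise InfeasibleSpecError("background_weights must be positive, one per primary")
    e_mid = R @ w_mid
    target = spec.target_channel
    c = spec.target_contrast
    t_idx = _SS_CHANNELS.index(target)
    # symmetric split: E_a = E - dE/2, E_b = E + dE/2 -> Michelson dE / (2 E)
    delta_target = 2.0 * c * e_mid[t_idx]

    rows = [_SS_CHANNELS.index(ch) for ch in SILENCED_CHANNELS[target]]
    A = [R[i] for i in rows]
    b = [0.0] * len(rows)
    if target == "Lum":
        # co-modulate L and M in proportion to their background excitations
        iL, iM = _SS_CHANNELS.index("L"), _SS_CHANNELS.index("M")
        A.append(R[iL] / e_mid[iL] - R[iM] / e_mid[iM])
        b.append(0.0)
    A.append(R[t_idx])
    b.append(delta_target)
    try:
        dw = _gamut_direction(np.array(A), np.array(b), w_mid)
    except np.linalg.LinAlgError as exc:
        raise RankDeficientError(f"isolation system singular for {target}: {exc}")
    w_a = w_mid - 0.5 * dw
    w_b = w_mid + 0.5 * dw
    spectra = []
    for name, w in (("background", w_a), ("modulated", w_b)):
        values = sum(wi * p.values for wi, p in zip(w, primaries))
        if np.any(values < 0):
            raise InfeasibleSpecError(
                f"{name} spectrum goes negative for {target} at contrast {c}; "
                "lower the contrast or change the primaries/background"
            )
        spectra.append(SpectralFunction(WORKING_GRID, values, name=name))
    return spectra[0], spectra[1]


def render_validation_scene(
    spec: SilentSubstitutionSpec,
    pixels_per_degree: float = DEFAULT_PIXELS_PER_DEGREE,
    field_diameter_deg: float = 1.37,
    blocks_per_region: int = 2,
) -> HyperspectralScene:
    """Radiance scene carrying the solved stimulus in a patch-aligned layout.

    The image is built from square blocks one receptive-field diameter wide
    so that the default grid tiling places every patch wholly inside one
    region: ``two_region`` fills the left half with the background spectrum
    and the right half with the modulated one; ``checkerboard`` alternates
    per block.
    """
    bg, mod = solve_silent_substitution(spec)
    d = math.ceil(field_diameter_deg * pixels_per_degree)
    k = blocks_per_region
    if k < 1:
        raise InfeasibleSpecError("blocks_per_region must be >= 1")
    h, w = d * k, d * 2 * k
    cube = np.empty((h, w, WORKING_GRID.size))
    if spec.layout == "two_region":
        cube[:, : w // 2, :] = bg.values
        cube[:, w // 2 :, :] = mod.values
    else:
        for bi in range(k):
            for bj in range(2 * k):
                vals = bg.values if (bi + bj) % 2 == 0 else mod.values
                cube[bi * d : (bi + 1) * d, bj * d : (bj + 1) * d, :] = vals
    return HyperspectralScene(
        cube=cube,
        wavelengths_nm=WORKING_GRID.copy(),
        quantity="radiance",
        environment="human_made",
        pixels_per_degree=pixels_per_degree,
        scene_id=f"silent_substitution_{spec.target_channel}",
    )
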