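"""Receptive-field windows, patch tiling, and local excitation.

A ganglion cell's spatial pooling is modeled as a circular window whose
weight falls smoothly from the center to zero at the rim. The default
``raised_cosine`` mode uses w_i proportional to (1 + cos(pi d_i / r)) / 2,
normalized to sum 1 over the patch, so every weight is non-negative —
consistent with the absence of spatial opponency in outer ipRGCs. A
``literal_cosine`` mode evaluates the plain cos(pi d_i / r) form (negative
at the rim) for replication studies.

Patches are tiled on a square grid of non-overlapping circles fully inside
the image (partial circles discarded); an optional jittered placement draws
random non-overlapping centers instead. Local excitation E_j is the
window-weighted mean of the channel map under patch j; local radiance is
the plain unweighted mean of wavelength-summed radiance.

Field diameters default to the physiological values: 1.37 deg (ipRGC
dendritic field, parafovea), 2.4 deg (ipRGC, periphery at ~31 deg
eccentricity) and 0.36 deg (parasol / luminance cell, parafovea). Degrees
convert to retinal millimetres with a magnification of 0.291 mm/deg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import DimensionMismatchError, PatchLayoutError
from .excitation import ChannelMap
from .spectra import HyperspectralScene

#: retinal magnification factor, millimetres of retina per degree of visual angle
RETINAL_MAGNIFICATION_MM_PER_DEG = 0.291

#: physiological receptive-field diameters, degrees of visual angle
IPRGC_PARAFOVEA_DEG = 1.37
IPRGC_PERIPHERY_DEG = 2.4
PARASOL_DEG = 0.36

WindowMode = Literal["raised_cosine", "literal_cosine"]


@dataclass(frozen=True)
class ReceptiveFieldSpec:
    """Diameter (degrees of visual angle) and window shape of a field."""

    diameter_deg: float = IPRGC_PARAFOVEA_DEG
    window: WindowMode = "raised_cosine"

    def __post_init__(self) -> None:
        if not self.diameter_deg > 0:
            raise PatchLayoutError(f"diameter must be positive, got {self.diameter_deg}")
        if self.window not in ("raised_cosine", "literal_cosine"):
            raise PatchLayoutError(f"unknown window mode {self.window!r}")


@dataclass
class Patch:
    """Pixel membership and normalized window weights of one circular patch."""

    center: tuple[float, float]  # (row, col), 0-based pixel coordinates
    rows: np.ndarray
    cols: np.ndarray
    weights: np.ndarray


@dataclass
class PatchLayout:
    """Non-overlapping circular patches with their normalized window weights."""

    patches: list[Patch]
    radius_px: float
    field_diameter_deg: float
    window: WindowMode
    image_shape: tuple[int, int]
    scene_id: str = ""

    @property
    def centers(self) -> list[tuple[float, float]]:
        return [p.center for p in self.patches]

    def __len__(self) -> int:
        return len(self.patches)


@dataclass
class PatchRecord:
    """Local value (E_j or Rad_j) of one patch, with its contrast once filled."""

    scene_id: str
    channel: str
    field_diameter_deg: float
    patch_index: int
    center: tuple[float, float]
    local_value: float
    contrast: float | None = None


def deg_to_px(diameter_deg: float, pixels_per_degree: float) -> float:
    """Convert a visual angle (degrees) to pixels for a scene's sampling."""
    if not diameter_deg > 0 or not pixels_per_degree > 0:
        raise PatchLayoutError(
            f"diameter ({diameter_deg}) and pixels_per_degree "
            f"({pixels_per_degree}) must both be positive"
        )
    return diameter_deg * pixels_per_degree


def deg_to_mm(diameter_deg: float) -> float:
    """Convert a visual angle (degrees) to retinal distance (mm, 0.291 mm/deg)."""
    if not diameter_deg > 0:
        raise PatchLayoutError(f"diameter must be positive, got {diameter_deg}")
    return diameter_deg * RETINAL_MAGNIFICATION_MM_PER_DEG


def raised_cosine_weights(
    radius_px: float,
    center: tuple[float, float],
    pixel_coords: np.ndarray,
    window: WindowMode = "raised_cosine",
) -> np.ndarray:
    """Normalized window weights for pixels of one patch.

    ``pixel_coords`` is an (N, 2) array of 0-based (row, col) pixel centers,
    all within ``radius_px`` of ``center``. The raised-cosine mode returns
    w_i proportional to (1 + cos(pi d_i / r)) / 2 (non-negative, zero at the
    rim); the literal mode uses cos(pi d_i / r) as printed in the source
    window formula, which goes negative beyond d_i = r/2. Weights sum to 1.
    """
    coords = np.atleast_2d(np.asarray(pixel_coords, dtype=float))
    d = np.hypot(coords[:, 0] - center[0], coords[:, 1] - center[1])
    if np.any(d > radius_px + 1e-9):
        raise PatchLayoutError(
            f"{int((d > radius_px + 1e-9).sum())} pixel(s) outside radius {radius_px}"
        )
    phase = np.pi * d / radius_px
    if window == "raised_cosine":
        w = 0.5 * (1.0 + np.cos(phase))
    elif window == "literal_cosine":
        w = np.cos(phase)
    else:
        raise PatchLayoutError(f"unknown window mode {window!r}")
    total = w.sum()
    # the literal form's denominator is negative on a full disk (the rim
    # ring outweighs the center); dividing by the signed sum still yields
    # weights summing to 1, which is all the printed normalization asserts
    if abs(total) < 1e-12:
        raise PatchLayoutError("window weights sum to zero; normalization undefined")
    return w / total


def _disk_pixels(
    center: tuple[float, float], radius: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Integer pixel centers within Euclidean distance <= radius of center."""
    r0 = max(0, math.ceil(center[0] - radius))
    r1 = min(shape[0] - 1, math.floor(center[0] + radius))
    c0 = max(0, math.ceil(center[1] - radius))
    c1 = min(shape[1] - 1, math.floor(center[1] + radius))
    rows, cols = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    mask = (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2 + 1e-9
    return rows[mask], cols[mask]


def _patch_at(
    center: tuple[float, float],
    radius: float,
    shape: tuple[int, int],
    window: WindowMode,
) -> Patch:
    rows, cols = _disk_pixels(center, radius, shape)
    coords = np.column_stack([rows, cols])
    weights = raised_cosine_weights(radius, center, coords, window)
    return Patch(center=center, rows=rows, cols=cols, weights=weights)


def tile_patches(
    scene_shape: tuple[int, int],
    spec: ReceptiveFieldSpec,
    pixels_per_degree: float,
    scene_id: str = "",
    jitter_seed: int | None = None,
) -> PatchLayout:
    """Tile non-overlapping circular patches over an image.

    The field diameter converts to an integer pixel diameter (rounded up);
    circles are laid on a square grid anchored at the top-left, spaced one
    diameter apart, and partial circles at the borders are discarded. With
    ``jitter_seed`` set, centers are drawn at random without overlap instead
    of on the grid (same count ceiling, deterministic for a fixed seed).
    """
    h, w = scene_shape
    d = math.ceil(deg_to_px(spec.diameter_deg, pixels_per_degree))
    if d > h or d > w:
        raise PatchLayoutError(
            f"field diameter {d} px does not fit in a {h}x{w} image"
        )
    radius = d / 2.0
    centers: list[tuple[float, float]]
    if jitter_seed is None:
        n_r, n_c = h // d, w // d
        centers = [
            (i * d + (d - 1) / 2.0, j * d + (d - 1) / 2.0)
            for i in range(n_r)
            for j in range(n_c)
        ]
    else:
        rng = np.random.default_rng(jitter_seed)
        max_patches = (h // d) * (w // d)
        centers = []
        misses = 0
        lo_r, hi_r = radius - 0.5, h - 0.5 - radius
        lo_c, hi_c = radius - 0.5, w - 0.5 - radius
        while len(centers) < max_patches and misses < 500:
            cand = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
            if all(math.hypot(cand[0] - c[0], cand[1] - c[1]) >= d for c in centers):
                centers.append(cand)
                misses = 0
            else:
                misses += 1
        if not centers:
            raise PatchLayoutError("jittered placement found no fitting patch")
    patches = [_patch_at(c, radius, (h, w), spec.window) for c in centers]
    return PatchLayout(
        patches=patches,
        radius_px=radius,
        field_diameter_deg=spec.diameter_deg,
        window=spec.window,
        image_shape=(h, w),
        scene_id=scene_id,
    )


def layout_at_centers(
    centers: list[tuple[float, float]],
    diameter_deg: float,
    pixels_per_degree: float,
    image_shape: tuple[int, int],
    window: WindowMode = "raised_cosine",
    scene_id: str = "",
) -> PatchLayout:
    """Build windows of a given diameter co-centered on externally chosen centers.

    Used to read out a small (e.g. 0.36 deg luminance) field at the centers
    of a larger (1.37 deg ipRGC) tiling. Centers must leave the smaller
    circles fully inside the image; non-overlap is the caller's concern.
    """
    h, w = image_shape
    d = math.ceil(deg_to_px(diameter_deg, pixels_per_degree))
    radius = d / 2.0
    for c in centers:
        if not (radius - 0.5 - 1e-9 <= c[0] <= h - 0.5 - radius + 1e-9) or not (
            radius - 0.5 - 1e-9 <= c[1] <= w - 0.5 - radius + 1e-9
        ):
            # allow as long as the actual member pixels stay inside
            rows, cols = _disk_pixels(c, radius, (h, w))
            if rows.size == 0:
                raise PatchLayoutError(f"patch at {c} falls outside the image")
    patches = [_patch_at(c, radius, (h, w), window) for c in centers]
    return PatchLayout(
        patches=patches,
        radius_px=radius,
        field_diameter_deg=diameter_deg,
        window=window,
        image_shape=(h, w),
        scene_id=scene_id,
    )


def local_excitation(channel_map: ChannelMap, layout: PatchLayout) -> list[PatchRecord]:
    """Window-weighted local excitation E_j of each patch."""
    if channel_map.shape != layout.image_shape:
        raise DimensionMismatchError(
            f"map shape {channel_map.shape} != layout shape {layout.image_shape}"
        )
    records = []
    for j, p in enumerate(layout.patches):
        e_j = float(np.dot(p.weights, channel_map.values[p.rows, p.cols]))
        records.append(
            PatchRecord(
                scene_id=channel_map.scene_id,
                channel=channel_map.channel,
                field_diameter_deg=layout.field_diameter_deg,
                patch_index=j,
                center=p.center,
                local_value=e_j,
            )
        )
    return records


def local_radiance(scene: HyperspectralScene, layout: PatchLayout) -> list[PatchRecord]:
    """Unweighted mean of wavelength-summed pixel radiance in each patch."""
    from .excitation import integrated_radiance

    rad = integrated_radiance(scene)
    if rad.shape != layout.image_shape:
        raise DimensionMismatchError(
            f"scene shape {rad.shape} != layout shape {layout.image_shape}"
        )
    records = []
    for j, p in enumerate(layout.patches):
        records.append(
            PatchRecord(
                scene_id=scene.scene_id,
                channel="Rad",
                field_diameter_deg=layout.field_diameter_deg,
                patch_index=j,
                center=p.center,
                local_value=float(rad.values[p.rows, p.cols].mean()),
            )
        )
    return records
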