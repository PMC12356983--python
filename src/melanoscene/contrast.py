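"""Between-patch Michelson contrast and the melanopsin-vs-luminance pairing.

The contrast of patch j within a scene is the absolute deviation of its
local excitation from the scene mean of local excitations, relative to that
mean: C_j = |E_j - E_s| / E_s, with E_s the unweighted mean of the E_j for
that scene, channel and field size. Contrasts are scale-free (invariant to
a global rescaling of the channel map) and unbounded above; no truncation
at 1 is applied anywhere in the computation.

Channel pairing supports two modes. ``physiological`` follows the anatomy:
melanopsin contrasts from a 1.37-deg tiling, luminance read out through
0.36-deg parasol windows co-centered on the same patch centers — the only
pairing that yields exactly one luminance value per ipRGC field when the
two channels use different field sizes. ``matched`` windows both channels
identically at the ipRGC size, the convention used to reconcile with
equal-field analyses in the literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, DimensionMismatchError
from .excitation import ChannelMap
from .receptive_field import (
    IPRGC_PARAFOVEA_DEG,
    PARASOL_DEG,
    PatchLayout,
    PatchRecord,
    ReceptiveFieldSpec,
    layout_at_centers,
    local_excitation,
    tile_patches,
)


@dataclass
class SceneContrastSet:
    """Per-patch contrasts of one scene/channel/field size, plus the scene mean."""

    scene_id: str
    channel: str
    field_diameter_deg: float
    scene_mean: float  # E_s: unweighted mean of the patches' local values
    records: list[PatchRecord]

    @property
    def contrasts(self) -> np.ndarray:
        return np.array([r.contrast for r in self.records])

    @property
    def local_values(self) -> np.ndarray:
        return np.array([r.local_value for r in self.records])


def between_patch_contrast(records: list[PatchRecord]) -> SceneContrastSet:
    """Fill C_j = |E_j - E_s| / E_s for the patches of one scene and channel."""
    if len(records) < 2:
        raise DegenerateDataError(
            f"between-patch contrast needs >= 2 patches, got {len(records)}"
        )
    values = np.array([r.local_value for r in records])
    e_s = float(values.mean())
    if e_s == 0.0:
        raise DegenerateDataError("scene mean excitation is zero; contrast undefined")
    filled = []
    for r in records:
        filled.append(
            PatchRecord(
                scene_id=r.scene_id,
                channel=r.channel,
                field_diameter_deg=r.field_diameter_deg,
                patch_index=r.patch_index,
                center=r.center,
                local_value=r.local_value,
                contrast=abs(r.local_value - e_s) / e_s,
            )
        )
    first = records[0]
    return SceneContrastSet(
        scene_id=first.scene_id,
        channel=first.channel,
        field_diameter_deg=first.field_diameter_deg,
        scene_mean=e_s,
        records=filled,
    )


def pair_channel_contrasts(
    map_a: ChannelMap,
    map_b: ChannelMap,
    pixels_per_degree: float,
    mode: str = "physiological",
    diameter_a_deg: float = IPRGC_PARAFOVEA_DEG,
    diameter_b_deg: float = PARASOL_DEG,
    window: str = "raised_cosine",
    jitter_seed: int | None = None,
) -> list[tuple[float, float]]:
    """Per-receptive-field contrast pairs (C_a, C_b) for two channels.

    physiological:
        channel a (e.g. melanopsin) is tiled at ``diameter_a_deg``; channel b
        (e.g. luminance) is read through ``diameter_b_deg`` windows
        co-centered on the same patch centers. Contrasts for each channel
        are computed over its own local values.
    matched:
        both channels share the identical ``diameter_a_deg`` tiling.

    Pairs are ordered by patch index.
    """
    if map_a.shape != map_b.shape:
        raise DimensionMismatchError(
            f"channel maps differ in shape: {map_a.shape} vs {map_b.shape}"
        )
    spec_a = ReceptiveFieldSpec(diameter_a_deg, window)
    layout_a = tile_patches(
        map_a.shape, spec_a, pixels_per_degree, map_a.scene_id, jitter_seed
    )
    if mode == "physiological":
        layout_b: PatchLayout = layout_at_centers(
            layout_a.centers,
            diameter_b_deg,
            pixels_per_degree,
            map_b.shape,
            window,
            map_b.scene_id,
        )
    elif mode == "matched":
        layout_b = layout_a
    else:
        raise ValueError(f"unknown pairing mode {mode!r}")
    set_a = between_patch_contrast(local_excitation(map_a, layout_a))
    set_b = between_patch_contrast(local_excitation(map_b, layout_b))
    return list(zip(set_a.contrasts.tolist(), set_b.contrasts.tolist()))


def contrast_excitation_independence(
    contrast_sets: list[SceneContrastSet],
) -> dict[str, float]:
    """Pearson correlation between local excitation and contrast, pooled.

    Pools the (E_j, C_j) pairs of all given scene sets (typically the scenes
    of one environment and one channel) and reports ``r``, the two-sided
    ``p`` and the number of pairs.
    """
    e = np.concatenate([s.local_values for s in contrast_sets])
    c = np.concatenate([s.contrasts for s in contrast_sets])
    if e.size < 3:
        raise DegenerateDataError(f"need >= 3 (E_j, C_j) pairs, got {e.size}")
    if np.ptp(e) == 0 or np.ptp(c) == 0:
        raise DegenerateDataError("zero-variance input; correlation undefined")
    r, p = sps.pearsonr(e, c)
    return {"r": float(r), "p": float(p), "n": int(e.size)}


def binned_contrast_comparison(
    pairs: list[tuple[float, float]], n_bins: int = 10
) -> list[dict[str, float]]:
    """Median +/- IQR of both channels' contrasts in quantile bins of the first.

    Implements the 'where does luminance contrast overtake melanopsin
    contrast' readout: pairs are binned into ``n_bins`` quantile bins of
    C_a (melanopsin), and each bin reports the median and IQR of C_a and
    C_b. The bin scheme (decile default) is configurable.
    """
    if len(pairs) < n_bins:
        raise DegenerateDataError(
            f"need at least {n_bins} pairs for {n_bins} bins, got {len(pairs)}"
        )
    arr = np.asarray(pairs, dtype=float)
    edges = np.quantile(arr[:, 0], np.linspace(0, 1, n_bins + 1))
    out = []
    for k in range(n_bins):
        lo, hi = edges[k], edges[k + 1]
        if k < n_bins - 1:
            mask = (arr[:, 0] >= lo) & (arr[:, 0] < hi)
        else:
            mask = (arr[:, 0] >= lo) & (arr[:, 0] <= hi)
        if not mask.any():
            continue
        sel = arr[mask]
        q1a, meda, q3a = np.percentile(sel[:, 0], [25, 50, 75])
        q1b, medb, q3b = np.percentile(sel[:, 1], [25, 50, 75])
        out.append(
            {
                "bin_low": float(lo),
                "bin_high": float(hi),
                "n": int(mask.sum()),
                "median_a": float(meda),
                "iqr_a": float(q3a - q1a),
                "median_b": float(medb),
                "iqr_b": float(q3b - q1b),
            }
        )
    return out
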