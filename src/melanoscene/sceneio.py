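"""Readers and writers for hyperspectral cube containers.

Two container flavours are supported: MATLAB-style ``.mat`` files (the
distribution format of the public outdoor scene sets; both classic v5 and
v7.3/HDF5 layouts are read) and the package's own HDF5 layout (datasets
``cube`` and ``wavelengths_nm`` plus string/scalar attributes). Variable
names inside third-party ``.mat`` containers vary across releases, so the
reader accepts a configurable key map.

Channel maps export as plain-text matrices with a YAML sidecar carrying the
scene_id, channel and pixels_per_degree.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import scipy.io
import yaml

from .errors import SceneFormatError
from .excitation import ChannelMap
from .spectra import HyperspectralScene

#: candidate variable names tried, in order, inside .mat containers
DEFAULT_KEY_MAP = {
    "cube": ("cube", "radiance", "reflectances", "ref", "hsi", "data"),
    "wavelengths": ("wavelengths_nm", "wavelengths", "wavelength", "wl", "bands"),
}


def _pick(store: dict, candidates: tuple[str, ...], what: str) -> np.ndarray:
    for key in candidates:
        if key in store:
            return np.asarray(store[key])
    raise SceneFormatError(
        f"no {what} variable found; tried {candidates}. "
        "Pass key_map={...} with the container's variable names."
    )


def read_scene(
    path: str | Path,
    quantity: str,
    environment: str,
    pixels_per_degree: float,
    scene_id: str | None = None,
    key_map: dict | None = None,
) -> HyperspectralScene:
    """Read a hyperspectral cube with its metadata into a validated scene.

    ``quantity`` ("radiance"/"reflectance"), ``environment`` and
    ``pixels_per_degree`` come from external metadata — the containers of
    the public scene sets do not carry them. Reflectance cubes with values
    above 1, NaN pixels, or a non-ascending wavelength axis are rejected
    with named errors.
    """
    path = Path(path)
    if not path.exists():
        raise SceneFormatError(f"no such file: {path}")
    keys = {**DEFAULT_KEY_MAP, **(key_map or {})}
    suffix = path.suffix.lower()
    if suffix == ".mat":
        try:
            store = scipy.io.loadmat(path)
        except NotImplementedError:  # MATLAB v7.3 files are HDF5
            with h5py.File(path, "r") as fh:
                store = {k: fh[k][()] for k in fh.keys()}
                # HDF5 MATLAB files store arrays transposed
                cube = _pick(store, keys["cube"], "cube")
                if cube.ndim == 3:
                    store = dict(store)
                    for k in list(store):
                        if store[k] is cube:
                            store[k] = np.transpose(cube, (2, 1, 0))
    elif suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            store = {k: fh[k][()] for k in fh.keys()}
            attrs = dict(fh.attrs)
        scene_id = scene_id or str(attrs.get("scene_id", path.stem))
    else:
        raise SceneFormatError(f"unsupported container {suffix!r} (use .mat or .h5)")
    cube = np.asarray(_pick(store, keys["cube"], "cube"), dtype=float)
    wl = np.asarray(_pick(store, keys["wavelengths"], "wavelength"), dtype=float).ravel()
    if cube.ndim != 3:
        raise SceneFormatError(f"cube in {path} is {cube.ndim}-D, expected 3-D")
    if wl.size == 0:
        raise SceneFormatError(f"{path}: wavelength vector is empty")
    if not np.all(np.diff(wl) > 0):
        raise SceneFormatError(f"{path}: wavelength axis is not strictly ascending")
    return HyperspectralScene(
        cube=cube,
        wavelengths_nm=wl,
        quantity=quantity,  # type: ignore[arg-type]
        environment=environment,  # type: ignore[arg-type]
        pixels_per_degree=pixels_per_degree,
        scene_id=scene_id or path.stem,
    )


def write_scene(scene: HyperspectralScene, path: str | Path) -> Path:
    """Write a scene to ``.mat`` (v5) or ``.h5``; round-trips bit-identically."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".mat":
        scipy.io.savemat(
            path,
            {
                "cube": scene.cube,
                "wavelengths_nm": scene.wavelengths_nm,
                "quantity": scene.quantity,
                "environment": scene.environment,
                "pixels_per_degree": scene.pixels_per_degree,
                "scene_id": scene.scene_id,
            },
        )
    elif suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("cube", data=scene.cube)
            fh.create_dataset("wavelengths_nm", data=scene.wavelengths_nm)
            fh.attrs["quantity"] = scene.quantity
            fh.attrs["environment"] = scene.environment
            fh.attrs["pixels_per_degree"] = scene.pixels_per_degree
            fh.attrs["scene_id"] = scene.scene_id
    else:
        raise SceneFormatError(f"unsupported container {suffix!r} (use .mat or .h5)")
    return path


def export_channel_map(channel_map: ChannelMap, path: str | Path) -> Path:
    """Write a channel map as a text matrix with a YAML metadata sidecar."""
    path = Path(path)
    np.savetxt(path, channel_map.values)
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    sidecar.write_text(
        yaml.safe_dump(
            {
                "scene_id": channel_map.scene_id,
                "channel": channel_map.channel,
                "pixels_per_degree": channel_map.pixels_per_degree,
                "shape": list(channel_map.shape),
            }
        )
    )
    return path
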