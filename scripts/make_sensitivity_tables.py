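"""Regenerate the bundled photoreceptor sensitivity tables.

Writes the five two-column CSV resource files under
``src/melanoscene/data/`` from the analytic templates in
``melanoscene._templates`` (L/M/S cone fundamentals, melanopic corneal
sensitivity) and from the bundled CIE 1931 ybar column (photopic luminous
efficiency). Run from the repository root:

    python scripts/make_sensitivity_tables.py
"""

from pathlib import Path

import numpy as np

from melanoscene import _templates
from melanoscene.spectra import _load_table

DATA_DIR = Path(__file__).resolve().parents[1] / "src" / "melanoscene" / "data"

HEADERS = {
    "L": "L-cone corneal sensitivity (template: A1 nomogram x media filter; corneal peak 565 nm)",
    "M": "M-cone corneal sensitivity (template: A1 nomogram x media filter; corneal peak 535 nm)",
    "S": "S-cone corneal sensitivity (template: A1 nomogram x media filter; corneal peak 440 nm)",
    "Mel": "melanopic corneal sensitivity (template: A1 nomogram x media filter; corneal peak 490 nm)",
}

FILES = {
    "L": "l_cone_sensitivity.csv",
    "M": "m_cone_sensitivity.csv",
    "S": "s_cone_sensitivity.csv",
    "Mel": "melanopic_sensitivity.csv",
}


def main() -> None:
    wl = _templates.TABLE_GRID
    for channel, filename in FILES.items():
        values = _templates.corneal_sensitivity(channel, wl)
        _write(filename, HEADERS[channel], wl, values)

    cmf = _load_table("cie1931_cmf_2deg.csv")
    ybar = np.interp(wl, cmf[:, 0], cmf[:, 2])
    _write(
        "photopic_luminosity.csv",
        "photopic luminous efficiency V(lambda) (CIE 1931 ybar column, interpolated to 1 nm)",
        wl,
        ybar / ybar.max(),
    )


def _write(filename: str, title: str, wl: np.ndarray, values: np.ndarray) -> None:
    path = DATA_DIR / filename
    with path.open("w") as fh:
        fh.write(f"# {title}\n# wavelength_nm,value\n")
        for w, v in zip(wl, values):
            fh.write(f"{w:.0f},{v:.6e}\n")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
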