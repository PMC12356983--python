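"""Analytic templates used to generate the bundled sensitivity tables.

The photoreceptor sensitivities ship as plain-text tables built from the
Govardovskii A1 visual-pigment nomogram multiplied by a single-exponential
ocular-media (lens) transmittance model, with the pigment peak wavelengths
chosen so that the *corneal* sensitivity peaks land at the physiological
values: L 565 nm, M 535 nm, S 440 nm, melanopsin 490 nm (shifted from the
480-nm pigment absorbance peak by the short-wavelength media filtering).
These template curves are generated sensitivities, not copies of the
official CIE tabulations; users who need bit-exact standard tables can load
their own via the two-column text format (see ``spectra.load_spectrum``).
The photopic luminous efficiency V(lambda) is taken from the bundled CIE
1931 ybar colour-matching column.

Regenerate the tables with ``scripts/make_sensitivity_tables.py``.
"""

from __future__ import annotations

import numpy as np

#: pigment peak wavelengths (nm) producing the target corneal peaks
PIGMENT_LAMBDA_MAX = {"L": 563.0, "M": 531.0, "S": 419.0, "Mel": 480.0}

#: ocular-media optical density at 400 nm and its exponential decay scale (nm)
MEDIA_DENSITY_400 = 1.0
MEDIA_DECAY_NM = 40.0

#: tabulation grid for the generated resource files
TABLE_GRID = np.arange(380.0, 781.0, 1.0)


def pigment_nomogram(wavelengths_nm: np.ndarray, lambda_max: float) -> np.ndarray:
    """Govardovskii A1 pigment absorbance template (alpha + beta band)."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lam_beta = 189.0 + 0.315 * lambda_max
    b_beta = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((wl - lam_beta) / b_beta) ** 2))
    return alpha + beta


def media_transmittance(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Ocular-media transmittance: 10**(-D), D decaying exponentially with wavelength."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    density = MEDIA_DENSITY_400 * np.exp(-(wl - 400.0) / MEDIA_DECAY_NM)
    return 10.0 ** (-density)


def corneal_sensitivity(channel: str, wavelengths_nm: np.ndarray | None = None) -> np.ndarray:
    """Peak-normalized corneal sensitivity template for L, M, S or Mel."""
    wl = TABLE_GRID if wavelengths_nm is None else np.asarray(wavelengths_nm, float)
    s = pigment_nomogram(wl, PIGMENT_LAMBDA_MAX[channel]) * media_transmittance(wl)
    return s / s.max()
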