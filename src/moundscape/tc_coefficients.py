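"""Tasseled Cap coefficients for Landsat 5 TM reflectance data.

Transcribed from Crist (1985), "A TM Tasseled Cap equivalent transformation
for reflectance factor data", Remote Sensing of Environment 17(3):301-306,
Table 1 — the reflectance-factor coefficient set for TM bands 1, 2, 3, 4,
5 and 7 (the thermal band 6 does not enter the transform).  This is the set
used by the RStoolbox ``spectralIndices`` implementation for Landsat 5 TM.

Do not edit these numbers; they are a published constant.  Sign structure
(checked by the test suite): brightness weights are all positive; greenness
weighs the visible bands (b1-b3) negatively and the near-infrared band (b4)
positively; wetness contrasts the visible/NIR bands against the two
shortwave-infrared bands (b5, b7).
"""

from __future__ import annotations

import numpy as np

TM_BANDS = ("b1", "b2", "b3", "b4", "b5", "b7")

CRIST_1985_TM_REFLECTANCE = {
    "brightness": (0.2043, 0.4158, 0.5524, 0.5741, 0.3124, 0.2303),
    "greenness": (-0.1603, -0.2819, -0.4934, 0.7940, -0.0002, -0.1446),
    "wetness": (0.0315, 0.2021, 0.3102, 0.1594, -0.6806, -0.6109),
}

TASSELED_CAP_INDICES = tuple(CRIST_1985_TM_REFLECTANCE)


def coefficient_matrix() -> np.ndarray:
    """3x6 matrix with rows (brightness, greenness, wetness), columns TM_BANDS."""
    return np.array([CRIST_1985_TM_REFLECTANCE[i] for i in TASSELED_CAP_INDICES])
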