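"""ROI band means and vegetation indices.

Eleven standard five-band vegetation indices (VIs) computed from ROI-mean
reflectances.  EXG is computed and reported but excluded from the default
model-input list: its correlation with canopy LAI is characteristically
poor because the excess-green signal saturates at full cover.
"""

from __future__ import annotations

import warnings

import numpy as np

from .synthetic import BAND_NAMES, BandStack

#: all implemented vegetation indices, in reporting order
VI_NAMES = (
    "GNDVI", "NDVI", "DVI", "RVI", "OSAVI", "SAVI",
    "EVI", "VARI", "EXG", "EXR", "CIRE",
)

#: default model-input VIs (EXG excluded)
MODEL_VI_NAMES = (
    "OSAVI", "SAVI", "DVI", "GNDVI", "RVI", "EVI", "NDVI", "CIRE", "EXR", "VARI",
)


def trim_roi(arr: np.ndarray, inner_buffer_frac: float) -> np.ndarray:
    """Centred sub-window after trimming ``inner_buffer_frac`` from each side."""
    if not 0.0 <= inner_buffer_frac < 0.5:
        raise ValueError("inner_buffer_frac must lie in [0, 0.5)")
    h, w = arr.shape
    dy = int(h * inner_buffer_frac)
    dx = int(w * inner_buffer_frac)
    roi = arr[dy : h - dy, dx : w - dx]
    if roi.size == 0:
        raise ValueError("ROI empty after trimming")
    return roi


def extract_roi_means(stack: BandStack, inner_buffer_frac: float = 0.1) -> dict[str, float]:
    """Mean reflectance per band over the interior ROI (edges avoided)."""
    return {
        name: float(trim_roi(stack.bands[name], inner_buffer_frac).mean())
        for name in BAND_NAMES
    }


def _ratio(num: float, den: float, name: str) -> float:
    if abs(den) < 1e-12:
        warnings.warn(f"zero denominator in {name}; set to missing", stacklevel=3)
        return float("nan")
    return num / den


def compute_vis(m: dict[str, float]) -> dict[str, float]:
    """The 11 vegetation indices from the five ROI band means.

    A zero denominator makes the affected ratio index NaN (flagged via a
    warning) rather than infinite.
    """
    B, G, R, RE, NIR = (float(m[b]) for b in BAND_NAMES)
    vis = {
        "GNDVI": _ratio(NIR - G, NIR + G, "GNDVI"),
        "NDVI": _ratio(NIR - R, NIR + R, "NDVI"),
        "DVI": NIR - R,
        "RVI": _ratio(NIR, R, "RVI"),
        "OSAVI": _ratio(1.16 * (NIR - R), NIR + R + 0.16, "OSAVI"),
        "SAVI": _ratio(1.5 * (NIR - R), NIR + R + 0.5, "SAVI"),
        "EVI": _ratio(2.5 * (NIR - R), NIR + 6 * R - 7.5 * B + 1, "EVI"),
        "VARI": _ratio(G - R, G + R - B, "VARI"),
        "EXG": 2 * G - R - B,
        "EXR": 1.4 * R - G,
        "CIRE": _ratio(NIR, RE, "CIRE") - 1 if abs(RE) >= 1e-12 else float("nan"),
    }
    return vis
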