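"""Sliding-window GLCM texture features.

Eight texture metrics per band (mean, var, hom, con, dis, et, sem, cor)
computed from per-window gray-level co-occurrence matrices and averaged
over all window positions — 8 metrics x 5 bands = 40 features per sample.

Metric definitions, with p(i, j) the normalised symmetric co-occurrence
matrix, mu_i = sum_i,j i p(i,j) and sigma_i its standard deviation:

    mean = mu_i                        var  = sum (i - mu_i)^2 p
    hom  = sum p / (1 + (i - j)^2)     con  = sum (i - j)^2 p
    dis  = sum |i - j| p               et   = -sum p ln p   (0 ln 0 := 0)
    sem  = sum p^2  (angular second moment)
    cor  = sum (i - mu_i)(j - mu_j) p / (sigma_i sigma_j), := 0 when
           sigma_i sigma_j = 0

The default window is 4 x 4 pixels sliding with stride 1, single offset
(dx, dy) = (1, 1), symmetric matrix, 32 gray levels from per-band min–max
quantisation.  Because quantisation rescales each band onto its own range,
every texture feature is invariant to per-band affine radiometric changes
(illumination gain, calibration drift).

The windowed engine is fully vectorised: for a symmetric GLCM every metric
decomposes into sums over the window's pixel pairs, with entropy and
energy recovered from per-window pair multiplicities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .synthetic import BAND_NAMES, BandStack
from .spectral import trim_roi

TEXTURE_METRICS = ("mean", "var", "hom", "con", "dis", "et", "sem", "cor")

#: the 40 texture feature names, band-major
TF_NAMES = tuple(f"{b}_{m}" for b in BAND_NAMES for m in TEXTURE_METRICS)


@dataclass
class CooccurrenceMatrix:
    p: np.ndarray
    levels: int
    offset: tuple[int, int]
    symmetric: bool

    def __post_init__(self):
        if self.p.shape != (self.levels, self.levels):
            raise ValueError("matrix shape must be levels x levels")
        if np.any(self.p < 0) or abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("entries must be non-negative and sum to 1")


def quantize_band(band_array: np.ndarray, levels: int) -> np.ndarray:
    """Linear min–max quantisation onto integer levels 0..levels-1.

    A constant band maps entirely to level 0.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    arr = np.asarray(band_array, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    if hi <= lo:
        return np.zeros(arr.shape, dtype=np.intp)
    q = np.floor((arr - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def _pair_fields(level_window: np.ndarray, offset: tuple[int, int]):
    """First/second-pixel level arrays for every in-bounds pair at ``offset``.

    ``offset`` is (dx, dy): the partner of pixel (row, col) is
    (row + dy, col + dx).
    """
    dx, dy = offset
    h, w = level_window.shape
    r0, r1 = max(0, -dy), h - max(0, dy)
    c0, c1 = max(0, -dx), w - max(0, dx)
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"window {level_window.shape} has no valid pair at offset {offset}")
    first = level_window[r0:r1, c0:c1]
    second = level_window[r0 + dy : r1 + dy, c0 + dx : c1 + dx]
    return first, second


def compute_glcm(
    level_window: np.ndarray,
    offset: tuple[int, int] = (1, 1),
    symmetric: bool = True,
    levels: int | None = None,
) -> CooccurrenceMatrix:
    """Normalised co-occurrence matrix of one window of integer levels."""
    level_window = np.asarray(level_window)
    if levels is None:
        levels = int(level_window.max()) + 1
    first, second = _pair_fields(level_window, offset)
    mat = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(mat, (first.ravel(), second.ravel()), 1.0)
    if symmetric:
        np.add.at(mat, (second.ravel(), first.ravel()), 1.0)
    mat /= mat.sum()
    return CooccurrenceMatrix(mat, levels, tuple(offset), symmetric)


def glcm_metrics(g: CooccurrenceMatrix) -> dict[str, float]:
    """The eight texture metrics of one co-occurrence matrix."""
    p = g.p
    idx = np.arange(g.levels, dtype=np.float64)
    i = idx[:, None]
    j = idx[None, :]
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    var_i = float(((i - mu_i) ** 2 * p).sum())
    var_j = float(((j - mu_j) ** 2 * p).sum())
    d = i - j
    nz = p > 0
    cov = float(((i - mu_i) * (j - mu_j) * p).sum())
    denom = np.sqrt(var_i * var_j)
    return {
        "mean": mu_i,
        "var": var_i,
        "hom": float((p / (1.0 + d * d)).sum()),
        "con": float((d * d * p).sum()),
        "dis": float((np.abs(d) * p).sum()),
        "et": float(-(p[nz] * np.log(p[nz])).sum()),
        "sem": float((p * p).sum()),
        "cor": cov / denom if denom > 0 else 0.0,
    }


def _windowed_metric_maps(
    level_array: np.ndarray,
    window: int,
    offset: tuple[int, int],
    levels: int,
) -> dict[str, np.ndarray]:
    """Per-window-position metric values over a quantised array.

    Vectorised equivalent of computing a symmetric GLCM in every
    window x window sliding window and applying :func:`glcm_metrics`.
    Returns, per metric, an array over the (H-window+1, W-window+1) grid
    of window top-left positions.
    """
    dx, dy = offset
    h, w = level_array.shape
    if window > min(h, w):
        raise ValueError(f"ROI {level_array.shape} smaller than window {window}")
    if window <= max(abs(dx), abs(dy)):
        raise ValueError(f"window {window} has no valid pair at offset {offset}")
    first, second = _pair_fields(level_array, offset)
    wy, wx = window - abs(dy), window - abs(dx)
    # (nwy, nwx, wy, wx): the pairs whose both pixels fall inside each window
    fw = sliding_window_view(first, (wy, wx))
    sw = sliding_window_view(second, (wy, wx))
    nwy, nwx = fw.shape[:2]
    n = wy * wx  # pairs per window
    I = fw.reshape(nwy * nwx, n).astype(np.float64)
    J = sw.reshape(nwy * nwx, n).astype(np.float64)

    tot = 2.0 * n  # symmetric matrix mass in counts
    mu = (I + J).sum(axis=1) / tot
    d = I - J
    con = (d * d).sum(axis=1) / n
    dis = np.abs(d).sum(axis=1) / n
    hom = (1.0 / (1.0 + d * d)).sum(axis=1) / n
    ic = I - mu[:, None]
    jc = J - mu[:, None]
    var = (ic * ic + jc * jc).sum(axis=1) / tot
    cov = (ic * jc).sum(axis=1) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.where(var > 0, cov / np.where(var > 0, var, 1.0), 0.0)

    # entropy / energy need per-window pair multiplicities
    ii = np.minimum(I, J).astype(np.int64)
    jj = np.maximum(I, J).astype(np.int64)
    key = ii * levels + jj  # canonical unordered pair id
    m = (key[:, :, None] == key[:, None, :]).sum(axis=2).astype(np.float64)
    q = np.where(I == J, 2.0, 1.0)  # diagonal cells carry both orders
    sem = (q * m).sum(axis=1) / (2.0 * n * n)
    et = -np.log(q * m / tot).sum(axis=1) / n

    shape = (nwy, nwx)
    return {
        "mean": mu.reshape(shape),
        "var": var.reshape(shape),
        "hom": hom.reshape(shape),
        "con": con.reshape(shape),
        "dis": dis.reshape(shape),
        "et": et.reshape(shape),
        "sem": sem.reshape(shape),
        "cor": cor.reshape(shape),
    }


def band_texture_metrics(
    band_array: np.ndarray,
    window: int = 4,
    offset: tuple[int, int] | list[tuple[int, int]] = (1, 1),
    levels: int = 32,
    mode: str = "sliding",
) -> dict[str, float]:
    """Window-averaged texture metrics of one reflectance band.

    ``mode='sliding'`` averages over all stride-1 window positions;
    ``mode='block'`` averages over non-overlapping tiles only.  ``offset``
    may be a list of displacement vectors, in which case per-window metrics
    are averaged across offsets before the spatial mean.
    """
    offsets = offset if isinstance(offset, list) else [tuple(offset)]
    q = quantize_band(band_array, levels)
    maps = None
    for off in offsets:
        mm = _windowed_metric_maps(q, window, tuple(off), levels)
        maps = mm if maps is None else {k: maps[k] + mm[k] for k in mm}
    maps = {k: v / len(offsets) for k, v in maps.items()}
    if mode == "block":
        maps = {k: v[::window, ::window] for k, v in maps.items()}
    elif mode != "sliding":
        raise ValueError(f"unknown mode {mode!r}")
    return {k: float(v.mean()) for k, v in maps.items()}


def texture_features_for_sample(
    stack: BandStack,
    inner_buffer_frac: float = 0.1,
    window: int = 4,
    offset: tuple[int, int] | list[tuple[int, int]] = (1, 1),
    levels: int = 32,
    mode: str = "sliding",
) -> dict[str, float]:
    """The 40 named texture features (8 metrics x 5 bands) of one sample."""
    out: dict[str, float] = {}
    for band in BAND_NAMES:
        roi = trim_roi(stack.bands[band], inner_buffer_frac)
        metrics = band_texture_metrics(roi, window=window, offset=offset, levels=levels, mode=mode)
        for metric in TEXTURE_METRICS:
            out[f"{band}_{metric}"] = metrics[metric]
    return out
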