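"""Savitzky-Golay filtering that tolerates missing samples.

The classic Savitzky-Golay filter is a sliding least-squares polynomial fit
evaluated at the window centre.  Depth stacks are gappy (sensor dropout), so
the fit must be restricted to the valid samples of each window, which makes
the filter weights position dependent.  A window keeps a well-defined fit as
long as at least ``polyorder + 1`` valid samples remain; otherwise the output
sample is marked missing (NaN).

The weights depend only on (a) the bit-pattern of valid samples inside the
window and (b) the evaluation offset, so they are computed once per distinct
pattern and applied vectorised to every window that shares it.  Edge samples
are handled like ``scipy.signal.savgol_filter(mode="interp")``: the first or
last full window is fitted and evaluated off-centre, which keeps the filter
exact for polynomial signals up to ``polyorder`` everywhere.
"""
from __future__ import annotations

import numpy as np

_WEIGHT_CACHE: dict[tuple[int, int, int, int], np.ndarray | None] = {}


def _pattern_weights(window: int, polyorder: int, pattern: int,
                     eval_at: int) -> np.ndarray | None:
    """Linear weights of a masked polynomial fit, or None if underdetermined.

    ``pattern`` has bit k set when sample k of the window is valid;
    ``eval_at`` is the in-window position (0-based) where the fitted
    polynomial is evaluated.
    """
    key = (window, polyorder, pattern, eval_at)
    try:
        return _WEIGHT_CACHE[key]
    except KeyError:
        pass
    idx = np.array([k for k in range(window) if (pattern >> k) & 1])
    full = idx.size == window
    if idx.size < polyorder + 1:
        w = None
    elif not full and not idx.min() <= eval_at <= idx.max():
        # a gappy window may interpolate but never extrapolate: evaluating
        # a sparse fit outside its valid-sample span amplifies noise into
        # centimetre-scale spikes next to dropout blobs
        w = None
    else:
        vand = np.vander(idx.astype(float), polyorder + 1, increasing=True)
        phi = np.array([float(eval_at) ** j for j in range(polyorder + 1)])
        w = np.zeros(window)
        w[idx] = phi @ np.linalg.pinv(vand)
    _WEIGHT_CACHE[key] = w
    return w


def _lut(window: int, polyorder: int, patterns: np.ndarray,
         eval_at: int) -> np.ndarray:
    """Weight lookup table (max_pattern+1, window); NaN rows mark bad fits."""
    lut = np.full((int(patterns.max()) + 1, window), np.nan)
    for m in patterns:
        w = _pattern_weights(window, polyorder, int(m), eval_at)
        if w is not None:
            lut[m] = w
    return lut


def savgol_masked(y: np.ndarray, window: int, polyorder: int,
                  axis: int = -1) -> np.ndarray:
    """Apply a NaN-aware Savitzky-Golay filter along ``axis``.

    Returns an array of the same shape; positions whose window retains fewer
    than ``polyorder + 1`` valid samples are NaN.  Exact (to round-off) for
    polynomial signals of degree <= ``polyorder``.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if polyorder < 0 or polyorder >= window:
        raise ValueError(
            f"polyorder must satisfy 0 <= polyorder < window, got "
            f"polyorder={polyorder}, window={window}")
    y = np.moveaxis(np.asarray(y, dtype=float), axis, -1)
    n = y.shape[-1]
    if n < window:
        raise ValueError(f"series length {n} is shorter than window {window}")
    valid = np.isfinite(y)
    yfill = np.where(valid, y, 0.0)
    out = np.full_like(y, np.nan)
    half = window // 2
    nwin = n - window + 1

    # Interior: sliding windows, evaluated at the centre.  The validity
    # pattern is packed into an int per window so weights can be looked up.
    pattern = np.zeros(y.shape[:-1] + (nwin,), dtype=np.int32)
    for k in range(window):
        pattern |= valid[..., k:k + nwin].astype(np.int32) << k
    lut = _lut(window, polyorder, np.unique(pattern), half)
    acc = np.zeros(pattern.shape)
    for k in range(window):
        acc += lut[pattern, k] * yfill[..., k:k + nwin]
    out[..., half:half + nwin] = acc

    # Edges: anchor the first/last full window, evaluate off-centre.
    pat_first = pattern[..., 0]
    pat_last = pattern[..., -1]
    uniq_first = np.unique(pat_first)
    uniq_last = np.unique(pat_last)
    for i in range(half):
        lut_l = _lut(window, polyorder, uniq_first, i)
        out[..., i] = sum(lut_l[pat_first, k] * yfill[..., k]
                          for k in range(window))
        lut_r = _lut(window, polyorder, uniq_last, window - 1 - i)
        out[..., n - 1 - i] = sum(
            lut_r[pat_last, k] * yfill[..., n - window + k]
            for k in range(window))
    return np.moveaxis(out, -1, axis)
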