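"""Temporal cleaning of BOLD series: detrend, nuisance regression, band-pass.

All three operations are linear maps applied independently per voxel, with
time on the last axis, and preserve series length.  The driver applies them
in the fixed order detrend -> regress -> band-pass.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidInputError, InvalidParameterError

__all__ = ["detrend_linear", "regress_confounds", "bandpass", "clean", "clean_volume"]

DEFAULT_BAND = (0.01, 0.10)


def detrend_linear(series: np.ndarray, axis: int = -1) -> np.ndarray:
    """Remove the least-squares straight line (slope and mean) from a series."""
    x = np.asarray(series, dtype=float)
    n = x.shape[axis]
    if n < 3:
        raise InvalidInputError(f"detrending needs length >= 3, got {n}")
    t = np.arange(n, dtype=float)
    t -= t.mean()
    x = np.moveaxis(x, axis, -1)
    mean = x.mean(axis=-1, keepdims=True)
    slope = (x - mean) @ t / (t @ t)
    out = x - mean - slope[..., None] * t
    return np.moveaxis(out, -1, axis)


def regress_confounds(series: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """OLS residuals of the series on confound regressors plus an intercept.

    ``series`` may be 1D (timepoints,) or 2D (n_series, timepoints);
    ``confounds`` is (timepoints, k).  Residuals are orthogonal to every
    regressor and to the constant, so they are mean-centered.
    """
    x = np.atleast_2d(np.asarray(series, dtype=float))
    conf = np.asarray(confounds, dtype=float)
    if conf.ndim != 2:
        raise InvalidInputError("confounds must be a (timepoints, k) matrix")
    if not np.isfinite(conf).all():
        raise InvalidInputError("confounds contain non-finite values")
    n = x.shape[-1]
    if conf.shape[0] != n:
        raise InvalidInputError(
            f"confound rows ({conf.shape[0]}) != series length ({n})"
        )
    design = np.column_stack([np.ones(n), conf])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # pinpoint collinear columns via the R diagonal of a QR factorization
        r = np.abs(np.diag(np.linalg.qr(design, mode="r")))
        bad = [int(i) - 1 for i in np.nonzero(r < 1e-10 * r.max())[0]]
        raise InvalidInputError(
            f"confound design is rank deficient; collinear column indices: {bad}"
        )
    beta, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    resid = x - (design @ beta).T
    return resid[0] if np.asarray(series).ndim == 1 else resid


def bandpass(
    series: np.ndarray,
    low_hz: float,
    high_hz: float,
    tr: float,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase ideal (FFT boxcar) band-pass filter with inclusive edges.

    Frequency bins f with low_hz <= f <= high_hz are kept with unit gain;
    everything else, including DC, is zeroed.
    """
    if tr <= 0:
        raise InvalidParameterError(f"TR must be positive, got {tr}")
    nyquist = 0.5 / tr
    if not (0.0 <= low_hz < high_hz):
        raise InvalidParameterError(f"need 0 <= low < high, got ({low_hz}, {high_hz})")
    if high_hz >= nyquist:
        raise InvalidParameterError(
            f"high cutoff {high_hz} Hz must be below Nyquist {nyquist} Hz"
        )
    x = np.asarray(series, dtype=float)
    n = x.shape[axis]
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(x, axis=axis)
    spec = np.moveaxis(spec, axis, -1)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(np.moveaxis(spec, -1, axis), n=n, axis=axis)


def clean(
    series: np.ndarray,
    confounds: np.ndarray | None = None,
    low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
    tr: float = 2.0,
) -> np.ndarray:
    """Full temporal cleaning in pipeline order: detrend, regress, band-pass."""
    out = detrend_linear(series)
    if confounds is not None and np.asarray(confounds).size:
        out = regress_confounds(out, confounds)
    return bandpass(out, low_hz, high_hz, tr)


def clean_volume(
    volume: np.ndarray,
    mask: np.ndarray | None = None,
    confounds: np.ndarray | None = None,
    low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
    tr: float = 2.0,
) -> np.ndarray:
    """Clean a 4D volume voxelwise inside a 3D boolean mask (default: all)."""
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 4:
        raise InvalidInputError(f"expected 4D volume, got {vol.ndim}D")
    if mask is None:
        mask = np.ones(vol.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.shape[:3]:
        raise InvalidInputError("mask shape does not match volume grid")
    out = np.zeros_like(vol)
    out[mask] = clean(vol[mask], confounds, low_hz, high_hz, tr)
    return out
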