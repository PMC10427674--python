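"""Fluorescence processing: hemodynamic correction and dF/F normalisation.

The blue-excited calcium indicator signal is contaminated by hemodynamics:
blood absorbs both the excitation and the emitted fluorescence, so blood
volume and oxygenation changes modulate the measured intensity.  Because
the green/amber/red reflectance channels are each modulated by the same two
hemoglobin species (with different spectral weights), a per-pixel linear
regression of the fluorescence trace on the three reflectance traces
removes most of the contamination without assuming pathlengths or baseline
concentrations.

Normalisation then extracts the neuronal band: the baseline F0 is the
< 0.3 Hz low-pass of the corrected trace and dF/F is the 0.3-3 Hz band-pass
divided by F0, both with zero-phase 4th-order Butterworth filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .acquisition import ChannelStack

logger = logging.getLogger(__name__)

__all__ = ["FluoMaps", "hemodynamic_correction", "compute_dff", "windowed_std"]

BANDPASS_HZ = (0.3, 3.0)
BASELINE_LOWPASS_HZ = 0.3


@dataclass
class FluoMaps:
    """Hemodynamics-corrected, band-passed dF/F maps."""

    dff: np.ndarray                 # (time, rows, cols) fraction
    baseline_f0: np.ndarray         # (time, rows, cols) counts (slow baseline)
    fps: float
    brain_mask: np.ndarray
    correction_coeffs: np.ndarray | None = None   # (rows, cols, n_regressors + 1)


def _resample_to(traces: np.ndarray, src_t: np.ndarray, dst_t: np.ndarray) -> np.ndarray:
    """Linear interpolation of (time, ...) data onto new timestamps."""
    if len(src_t) == len(dst_t) and np.allclose(src_t, dst_t):
        return traces
    flat = traces.reshape(len(src_t), -1)
    out = np.empty((len(dst_t), flat.shape[1]), dtype=np.float64)
    for j in range(flat.shape[1]):
        out[:, j] = np.interp(dst_t, src_t, flat[:, j])
    return out.reshape((len(dst_t),) + traces.shape[1:])


def hemodynamic_correction(
    fluo: ChannelStack,
    reflectance: dict[str, ChannelStack],
    mask: np.ndarray | None = None,
    fit_window: slice | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Regress hemodynamic contamination out of the fluorescence channel.

    Per pixel, the fluorescence trace is fitted by least squares on the
    reflectance traces of the same pixel (plus an intercept); the corrected
    trace is the residual plus the intercept, so its slow mean is preserved
    while reflectance-explained variance is removed.  Reflectance channels
    are resampled to the fluorescence timestamps by linear interpolation.

    ``fit_window`` optionally restricts the frames used to estimate the
    coefficients (e.g. normoxia only); the correction is always applied to
    the full trace.  Rank-deficient pixels (constant reflectance) fall back
    to an intercept-only fit and are logged.

    Returns (corrected frames, coefficients[rows, cols, n_channels + 1])
    with the intercept last.
    """
    frames = fluo.frames.astype(np.float64)
    n_t, rows, cols = frames.shape
    if mask is None:
        mask = np.ones((rows, cols), dtype=bool)

    regs = []
    for name in sorted(reflectance):
        ch = reflectance[name]
        regs.append(_resample_to(ch.frames.astype(np.float64), ch.timestamps, fluo.timestamps))
    n_reg = len(regs)
    if n_reg == 0:
        raise ValueError("no reflectance channels supplied")

    # per-pixel regressor stack, (n_pix, time, n_reg); standardised so the
    # least-squares system stays well conditioned (raw counts are huge and
    # the three channels are nearly collinear — two hemoglobin species drive
    # all of them)
    x = np.stack([r[:, mask] for r in regs], axis=-1).transpose(1, 0, 2)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    degenerate = sd[..., 0, :] == 0
    n_flat = int(degenerate.any(axis=-1).sum())
    if n_flat:
        logger.warning("%d pixel(s) have constant reflectance regressors", n_flat)
    sd[sd == 0] = 1.0
    xs = (x - mu) / sd

    y = frames[:, mask].T                            # (n_pix, time)
    y_mean = y.mean(axis=1, keepdims=True)

    sel = slice(None) if fit_window is None else fit_window
    # minimum-norm least squares via batched pseudoinverse: collinear or
    # constant regressors degrade gracefully instead of failing
    pinv = np.linalg.pinv(xs[:, sel], rcond=1e-8)    # (n_pix, n_reg, t_fit)
    beta_std = (pinv @ (y[:, sel] - y_mean)[..., None])[..., 0]   # (n_pix, n_reg)

    fitted = (xs @ beta_std[..., None])[..., 0]      # (n_pix, time), zero-mean regressors
    corrected_pix = y - fitted                       # residual keeps the pixel's mean

    corrected = frames.copy()
    corrected[:, mask] = corrected_pix.T

    # coefficients on the original intensity scale, intercept last
    beta = beta_std / sd[:, 0, :]
    intercept = y_mean[:, 0] - (beta * mu[:, 0, :]).sum(axis=1)
    coeff_img = np.zeros((rows, cols, n_reg + 1))
    coeff_img[mask] = np.column_stack([beta, intercept])
    return corrected.astype(np.float32), coeff_img


def _sos_lowpass(fps: float, cutoff: float = BASELINE_LOWPASS_HZ) -> np.ndarray:
    return signal.butter(4, cutoff, btype="lowpass", fs=fps, output="sos")


def _sos_bandpass(fps: float) -> np.ndarray:
    low, high = BANDPASS_HZ
    high = min(high, 0.45 * fps)
    return signal.butter(4, [low, high], btype="bandpass", fs=fps, output="sos")


def compute_dff(
    frames: np.ndarray,
    fps: float,
    brain_mask: np.ndarray | None = None,
) -> FluoMaps:
    """Band-passed fractional fluorescence change dF/F per pixel.

    F0 is the zero-phase < 0.3 Hz low-pass of each pixel's trace and
    dF/F = bandpass_{0.3-3 Hz}(F) / F0.  Pixels whose F0 dips to zero or
    below anywhere are flagged and removed from the mask.
    """
    if fps <= 2 * BANDPASS_HZ[1]:
        raise ValueError(f"fps={fps} too low for a {BANDPASS_HZ[1]} Hz passband")
    frames = np.asarray(frames, dtype=np.float64)
    n_t, rows, cols = frames.shape
    mask = np.ones((rows, cols), bool) if brain_mask is None else brain_mask.copy()

    f0 = signal.sosfiltfilt(_sos_lowpass(fps), frames, axis=0)
    bad = (f0 <= 0).any(axis=0) & mask
    if bad.any():
        logger.warning("masking %d pixel(s) with nonpositive baseline F0", int(bad.sum()))
        mask &= ~bad

    band = signal.sosfiltfilt(_sos_bandpass(fps), frames, axis=0)
    dff = np.zeros_like(frames, dtype=np.float32)
    with np.errstate(divide="ignore", invalid="ignore"):
        dff[:, mask] = (band[:, mask] / f0[:, mask]).astype(np.float32)
    return FluoMaps(dff=dff, baseline_f0=f0.astype(np.float32), fps=fps, brain_mask=mask)


def windowed_std(trace: np.ndarray, window_frames: int = 10) -> np.ndarray:
    """Centered moving sample standard deviation (10 frames = 500 ms at 20 Hz).

    Edges are truncated, not padded: positions near the boundary use the
    samples that fall inside the trace.
    """
    if window_frames < 2:
        raise ValueError("window must span at least 2 frames")
    x = np.asarray(trace, dtype=float)
    if len(x) < window_frames:
        raise ValueError(f"trace of {len(x)} frames shorter than window {window_frames}")
    import pandas as pd

    s = pd.Series(x)
    return s.rolling(window_frames, center=True, min_periods=2).std(ddof=1).to_numpy()
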