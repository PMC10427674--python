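"""Hemoglobin spectroscopy: modified Beer-Lambert inversion and epoch metrics.

Reflectance changes at green (535 nm), amber (590 nm) and red (620 nm)
report on oxy-/deoxyhemoglobin concentration changes through the modified
Beer-Lambert law

    -log(R_lambda(t) / R_lambda(0)) = D_lambda * (eps_HbO(lambda) * dHbO
                                                  + eps_HbR(lambda) * dHbR)

with wavelength-specific molar extinction coefficients eps (cm^-1 M^-1) and
differential pathlength factors D (cm).  The three-channel, two-species
system is solved per pixel by ordinary least squares.  Baseline
concentrations of HbO 60 µM and HbR 40 µM give a baseline oxygen saturation
sO2 = HbO / (HbO + HbR) of exactly 60%.

Epoch metrics mirror the hypoxia protocol: plateau means over minutes
14.5-19.5 compared with a 4.5-9.5 baseline, the transient sO2/HbO dip after
hypoxia onset, and the post-hypoxia overshoot between minutes 20 and 21.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "OpticalModel",
    "HemoMaps",
    "EpochSummary",
    "beer_lambert_invert",
    "compute_so2",
    "make_brain_mask",
    "exclude_outliers",
    "quantify_epoch_dynamics",
]

# Molar extinction coefficients (cm^-1 M^-1) from the standard tabulated
# hemoglobin absorption spectra (Prahl compilation), evaluated at the LED
# center wavelengths.  Each LED is treated as monochromatic.
DEFAULT_EPSILON: dict[float, tuple[float, float]] = {
    # wavelength nm: (eps_HbO, eps_HbR)
    475.0: (33209.2, 16156.4),
    515.0: (25773.6, 32851.2),   # GCaMP emission band
    535.0: (53236.0, 47638.0),
    590.0: (14677.0, 37020.0),
    620.0: (942.0, 6510.0),
}

# Differential pathlength factors (cm): longer at red where absorption is
# weak, shorter at green.  Configurable; forward simulation and inversion
# share whatever table is in use, so derived quantities do not depend on the
# absolute scale.
DEFAULT_PATHLENGTH_CM: dict[float, float] = {535.0: 0.057, 590.0: 0.070, 620.0: 0.45}

CHANNEL_WAVELENGTHS = {"green": 535.0, "amber": 590.0, "red": 620.0, "blue": 475.0}

HBO_BASELINE_UM = 60.0
HBR_BASELINE_UM = 40.0


@dataclass
class OpticalModel:
    """Wavelengths, extinction coefficients, pathlengths and baselines."""

    epsilon: dict[float, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EPSILON)
    )
    pathlength_cm: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_PATHLENGTH_CM)
    )
    pathlength_fluo_cm: float = 0.056
    baseline_hbo_uM: float = HBO_BASELINE_UM
    baseline_hbr_uM: float = HBR_BASELINE_UM

    def __post_init__(self) -> None:
        for lam, (e_hbo, e_hbr) in self.epsilon.items():
            if e_hbo <= 0 or e_hbr <= 0:
                raise ValueError(f"extinction coefficients at {lam} nm must be positive")
        a = self.design_matrix()
        self.condition_number = float(np.linalg.cond(a))
        if not np.isfinite(self.condition_number) or self.condition_number > 1e6:
            raise ValueError(
                f"spectral system is ill-conditioned (cond={self.condition_number:.3g})"
            )

    @property
    def baseline_hbt_uM(self) -> float:
        return self.baseline_hbo_uM + self.baseline_hbr_uM

    @property
    def reflectance_wavelengths(self) -> list[float]:
        return sorted(self.pathlength_cm)

    def wavelength_of(self, channel: str) -> float:
        return CHANNEL_WAVELENGTHS[channel]

    def design_matrix(self) -> np.ndarray:
        """(n_wavelengths, 2) matrix A with rows D_lam * (eps_HbO, eps_HbR), µM units."""
        rows = []
        for lam in self.reflectance_wavelengths:
            e_hbo, e_hbr = self.epsilon[lam]
            d = self.pathlength_cm[lam]
            rows.append([d * e_hbo * 1e-6, d * e_hbr * 1e-6])
        return np.asarray(rows)

    def fluorescence_epsilons(self) -> tuple[float, float]:
        """Mean of excitation (475 nm) and emission (515 nm) coefficients.

        The fluorescence photon traverses tissue twice — in at the excitation
        and out at the emission wavelength — so its hemodynamic attenuation
        is modelled with the average of the two absorption spectra.
        """
        ex_hbo, ex_hbr = self.epsilon[475.0]
        em_hbo, em_hbr = self.epsilon[515.0]
        return (ex_hbo + em_hbo) / 2.0, (ex_hbr + em_hbr) / 2.0


@dataclass
class HemoMaps:
    """Per-pixel hemoglobin concentration changes and oxygen saturation."""

    delta_hbo: np.ndarray          # (time, rows, cols), µM
    delta_hbr: np.ndarray
    so2: np.ndarray                # fraction in [0, 1]; NaN where undefined
    brain_mask: np.ndarray
    fps: float

    @property
    def delta_hbt(self) -> np.ndarray:
        return self.delta_hbo + self.delta_hbr

    def whole_brain_mean(self, which: str = "hbo") -> np.ndarray:
        arr = {"hbo": self.delta_hbo, "hbr": self.delta_hbr,
               "hbt": self.delta_hbt, "so2": self.so2}[which]
        return np.nanmean(arr[:, self.brain_mask], axis=1)


@dataclass
class EpochSummary:
    """Group-level plateau/dip/overshoot summary for one condition."""

    condition: str
    per_subject: pd.DataFrame      # subject x metric
    group: pd.DataFrame            # metric -> mean, sem, n


def _baseline_window_frames(n_frames: int, fps: float, window_s: tuple[float, float]) -> slice:
    i0 = int(np.floor(window_s[0] * fps))
    i1 = int(np.floor(window_s[1] * fps))
    if i1 > n_frames or i0 >= i1:
        raise ValueError(f"baseline window {window_s} s outside acquisition of {n_frames} frames")
    return slice(i0, i1)


def beer_lambert_invert(
    reflectance: dict,
    optical: OpticalModel | None = None,
    brain_mask: np.ndarray | None = None,
    baseline_window_s: tuple[float, float] = (0.0, 600.0),
) -> HemoMaps:
    """Invert reflectance channels to per-pixel (dHbO, dHbR, sO2) maps.

    Per pixel, the per-frame log-ratios -log(R(t)/R0) across the available
    reflectance channels are solved for the two concentration changes by
    least squares (pseudoinverse of the extinction design matrix).  R0 is
    the temporal mean over the baseline window (default: the first 10-minute
    normoxia epoch, truncated to the acquisition if shorter).

    Pixels with nonpositive intensities anywhere are flagged and removed
    from the brain mask.
    """
    optical = optical or OpticalModel()
    channels = [c for c in ("green", "amber", "red") if c in reflectance]
    if len(channels) < 2:
        raise ValueError(f"need >= 2 reflectance channels, got {channels}")

    first = reflectance[channels[0]]
    n_frames, rows, cols = first.frames.shape
    fps = first.fps
    window = (baseline_window_s[0], min(baseline_window_s[1], n_frames / fps))
    base_sl = _baseline_window_frames(n_frames, fps, window)

    if brain_mask is None:
        brain_mask = np.ones((rows, cols), dtype=bool)
    mask = brain_mask.copy()

    a_full = optical.design_matrix()
    lam_index = {lam: i for i, lam in enumerate(optical.reflectance_wavelengths)}
    rows_used = [lam_index[optical.wavelength_of(c)] for c in channels]
    a = a_full[rows_used]

    logratios = np.empty((len(channels), n_frames, rows, cols), dtype=np.float64)
    for k, c in enumerate(channels):
        fr = reflectance[c].frames.astype(np.float64)
        bad = (fr <= 0).any(axis=0)
        if bad.any():
            n_bad = int((bad & mask).sum())
            if n_bad:
                logger.warning("excluding %d pixel(s) with nonpositive intensity", n_bad)
            mask &= ~bad
        r0 = fr[base_sl].mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            logratios[k] = -np.log(fr / r0)

    if not mask.any():
        raise ValueError("no valid pixels remain after intensity screening")

    pinv = np.linalg.pinv(a)                      # (2, n_channels)
    y = logratios[:, :, mask]                     # (n_channels, time, n_pix)
    sol = np.einsum("sc,ctp->stp", pinv, y)       # (2, time, n_pix)

    hbo = np.zeros((n_frames, rows, cols), dtype=np.float32)
    hbr = np.zeros((n_frames, rows, cols), dtype=np.float32)
    hbo[:, mask] = sol[0]
    hbr[:, mask] = sol[1]

    maps = HemoMaps(
        delta_hbo=hbo, delta_hbr=hbr,
        so2=np.empty(0), brain_mask=mask, fps=fps,
    )
    maps.so2 = compute_so2(maps, optical)
    return maps


def compute_so2(hemo: HemoMaps, optical: OpticalModel | None = None) -> np.ndarray:
    """Oxygen saturation sO2 = (HbO0 + dHbO) / (HbT0 + dHbT) per pixel/frame.

    Frames where total hemoglobin would be nonpositive are set to NaN.
    """
    optical = optical or OpticalModel()
    hbt = optical.baseline_hbt_uM + hemo.delta_hbt.astype(np.float64)
    hbo = optical.baseline_hbo_uM + hemo.delta_hbo.astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        so2 = np.where(hbt > 0, hbo / hbt, np.nan)
    return so2


def make_brain_mask(
    atlas: np.ndarray,
    sinus_label: int = 99,
    edge_margin_px: int = 5,
) -> np.ndarray:
    """Brain mask excluding the midline sinus stripe and an eroded edge margin.

    The mask covers labelled cortical regions; the sinus label is removed
    and the outer boundary of the brain is eroded by ``edge_margin_px`` to
    drop partial-volume pixels at the brain edge.
    """
    brain = atlas > 0
    if edge_margin_px > 0:
        brain = ndimage.binary_erosion(brain, iterations=edge_margin_px)
    mask = brain & (atlas != sinus_label)
    if not mask.any():
        raise ValueError("brain mask is empty after sinus/edge exclusion")
    return mask


def exclude_outliers(series: np.ndarray, n_sd: float = 3.0) -> np.ndarray:
    """Replace values more than ``n_sd`` standard deviations from the mean by NaN.

    Mean and sd come from the full trace in a single pass; a constant trace
    is returned unchanged.
    """
    x = np.asarray(series, dtype=float).copy()
    finite = np.isfinite(x)
    sd = x[finite].std()
    if sd == 0:
        return x
    mean = x[finite].mean()
    x[finite & (np.abs(x - mean) > n_sd * sd)] = np.nan
    return x


DEFAULT_WINDOWS_MIN = {
    "baseline": (4.5, 9.5),
    "plateau": (14.5, 19.5),
    "dip": (10.0, 11.0),
    "overshoot": (20.0, 21.0),
}


def _window_mean(trace: np.ndarray, fps: float, win_min: tuple[float, float], how: str) -> float:
    i0 = int(np.floor(win_min[0] * 60.0 * fps))
    i1 = int(np.floor(win_min[1] * 60.0 * fps))
    if i1 > len(trace) or i0 >= i1:
        raise ValueError(
            f"window {win_min} min lies outside the acquisition "
            f"({len(trace) / fps / 60.0:.2f} min)"
        )
    seg = trace[i0:i1]
    if np.all(np.isnan(seg)):
        return np.nan
    return {"mean": np.nanmean, "min": np.nanmin, "max": np.nanmax}[how](seg)


def quantify_epoch_dynamics(
    traces: dict[str, np.ndarray] | np.ndarray,
    fps: float,
    condition: str = "hypoxia",
    windows_min: dict[str, tuple[float, float]] | None = None,
    outlier_exclusion: bool = True,
) -> EpochSummary:
    """Plateau / baseline / dip / overshoot statistics on whole-brain traces.

    ``traces`` maps subject id -> whole-brain mean trace (a single array is
    treated as one subject).  Per subject: plateau = mean over minutes
    14.5-19.5; baseline = mean over 4.5-9.5; dip = minimum in the window
    after hypoxia onset (default minutes 10-11); overshoot = maximum after
    the return to normoxia (default minutes 20-21).  The group table holds
    mean, SEM (sd/sqrt(n)) and n over subjects.
    """
    if isinstance(traces, np.ndarray):
        traces = {"s1": traces}
    windows = {**DEFAULT_WINDOWS_MIN, **(windows_min or {})}

    records = []
    for subject, trace in traces.items():
        trace = np.asarray(trace, dtype=float)
        if outlier_exclusion:
            trace = exclude_outliers(trace)
        records.append(
            {
                "subject": subject,
                "baseline": _window_mean(trace, fps, windows["baseline"], "mean"),
                "plateau": _window_mean(trace, fps, windows["plateau"], "mean"),
                "dip": _window_mean(trace, fps, windows["dip"], "min"),
                "overshoot": _window_mean(trace, fps, windows["overshoot"], "max"),
            }
        )
    per_subject = pd.DataFrame.from_records(records).set_index("subject")
    n = len(per_subject)
    group = pd.DataFrame(
        {
            "mean": per_subject.mean(),
            "sem": per_subject.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            "n": n,
        }
    )
    return EpochSummary(condition=condition, per_subject=per_subject, group=group)
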