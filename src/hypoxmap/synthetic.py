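"""Forward simulation of a dual-modality widefield acquisition.

The generator emulates the full measurement chain of a mesoscale imaging
experiment in awake mice breathing a controlled atmosphere:

1. resting-state calcium activity in 8 bilateral cortical regions (Motor,
   Somatosensory, Retrosplenial, Visual x left/right) as correlated
   band-limited (0.3-3 Hz) Gaussian processes with an anterior/posterior
   macrocluster correlation structure that changes during the hypoxia epoch;
2. hemodynamics as a global, epoch-driven piecewise-exponential ramp (fast
   HbR plateau; HbO initial dip then slow rise; on return to normoxia an HbO
   overshoot and HbR undershoot) plus a local neurovascular component
   (calcium convolved with a gamma kernel, positive for HbO and smaller
   negative for HbR);
3. optics via the modified Beer-Lambert law: reflectance at 535/590/620 nm
   attenuated by the hemoglobin changes, and a fluorescence channel whose
   hemodynamic contamination follows the mean excitation/emission
   absorption;
4. an sCMOS-like sensor: time-interlaced 4-color acquisition at 4x the
   per-channel rate, additive Gaussian noise, optional rigid motion.

Every stage records its ground truth so each downstream analysis stage has a
recoverable target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage, signal

from .acquisition import COLOR_ORDER, InterlacedStack
from .hemodynamics import OpticalModel

logger = logging.getLogger(__name__)

__all__ = [
    "HemoRampParams",
    "ScenarioConfig",
    "GroundTruth",
    "make_atlas",
    "simulate_calcium",
    "simulate_hemodynamics",
    "render_optics",
    "simulate_scenario",
    "write_fixture",
]

REGION_NAMES = ("MotL", "MotR", "SenL", "SenR", "RetL", "RetR", "VisL", "VisR")
#: anterior = motor + somatosensory, posterior = retrosplenial + visual
MACROCLUSTER = {
    "Mot": "anterior",
    "Sen": "anterior",
    "Ret": "posterior",
    "Vis": "posterior",
}
SINUS_LABEL = 99


@dataclass(frozen=True)
class HemoRampParams:
    """Whole-brain hemodynamic trajectory during a hypoxia epoch.

    Amplitudes are in µM, time constants in seconds.  Defaults emulate a
    severe (8% O2) challenge: HbR rises fast to a ~21 µM plateau while HbO
    dips briefly and then climbs slowly toward ~28 µM; on return to room air
    HbO transiently overshoots and HbR undershoots before both relax back.
    """

    hbr_plateau_uM: float = 21.0
    hbo_plateau_uM: float = 28.0
    hbr_tau_s: float = 20.0
    hbo_tau_s: float = 150.0
    dip_amp_uM: float = 5.0
    dip_tau_s: float = 20.0
    hbo_overshoot_uM: float = 15.0
    hbr_undershoot_uM: float = 6.0
    overshoot_tau_s: float = 45.0
    recovery_tau_s: float = 60.0


#: per-oxygen-level ramp amplitudes; HbR plateaus follow the graded severity
#: of the challenge, HbO plateaus lag behind with slower kinetics
RAMPS_BY_OXYGEN: dict[int, HemoRampParams] = {
    21: HemoRampParams(0.0, 0.0, 20.0, 150.0, 0.0, 20.0, 0.0, 0.0, 45.0, 60.0),
    12: HemoRampParams(hbr_plateau_uM=10.9, hbo_plateau_uM=7.8, hbo_tau_s=60.0,
                       dip_amp_uM=3.0, hbo_overshoot_uM=5.0, hbr_undershoot_uM=2.0),
    10: HemoRampParams(hbr_plateau_uM=13.4, hbo_plateau_uM=20.0, hbo_tau_s=100.0,
                       dip_amp_uM=4.0, hbo_overshoot_uM=10.0, hbr_undershoot_uM=4.0),
    8: HemoRampParams(),
}


@dataclass
class ScenarioConfig:
    """Parameters of one simulated 40-minute acquisition.

    The default timeline follows the experimental protocol: 10 min normoxia,
    10 min at the hypoxic oxygen level, then 20 min normoxia.
    """

    image_shape: tuple[int, int] = (192, 192)
    fov_mm: tuple[float, float] = (10.0, 10.0)
    fps_per_channel: float = 20.0
    duration_s: float = 2400.0
    epoch_timeline: list[tuple[str, float, float]] = field(default_factory=list)
    oxygen_level: int = 8
    within_cluster_r: float = 0.8
    between_cluster_r: float = 0.5
    between_cluster_r_hypoxia: float = 0.1
    hemo_ramp_params: HemoRampParams | None = None
    calcium_sd: float = 0.05          # resting dF/F fluctuation amplitude
    neurovascular_gain_uM: float = 20.0   # µM HbO per unit dF/F (unit-area kernel)
    neurovascular_ratio: float = -0.4     # HbR amplitude relative to HbO
    kernel_delay_s: float = 1.5
    kernel_fwhm_s: float = 2.0
    baseline_counts: float = 10000.0
    noise_sd: float = 50.0            # sensor noise, counts (~0.5% of baseline)
    motion_amplitude_px: float = 0.0
    fluorescence_neural: bool = True  # False = GFP analog (no calcium signal)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.epoch_timeline:
            self.epoch_timeline = default_timeline(self.duration_s, self.oxygen_level)
        self._validate()
        if self.hemo_ramp_params is None:
            self.hemo_ramp_params = RAMPS_BY_OXYGEN[self.oxygen_level]

    def _validate(self) -> None:
        if self.oxygen_level not in (21, 12, 10, 8):
            raise ValueError(f"oxygen_level must be one of 21/12/10/8, got {self.oxygen_level}")
        if not (0.0 <= self.between_cluster_r <= self.within_cluster_r <= 1.0):
            raise ValueError(
                "need 0 <= between_cluster_r <= within_cluster_r <= 1, got "
                f"between={self.between_cluster_r}, within={self.within_cluster_r}"
            )
        if not (0.0 <= self.between_cluster_r_hypoxia <= 1.0):
            raise ValueError("between_cluster_r_hypoxia must lie in [0, 1]")
        t = 0.0
        for label, start, end in self.epoch_timeline:
            if label not in ("normoxia", "hypoxia"):
                raise ValueError(f"unknown epoch label {label!r}")
            if not np.isclose(start, t):
                raise ValueError(f"epoch timeline has a gap/overlap at t={start}s")
            if end <= start:
                raise ValueError(f"epoch ({label}, {start}, {end}) has non-positive length")
            t = end
        if not np.isclose(t, self.duration_s):
            raise ValueError(f"epoch timeline ends at {t}s, expected duration_s={self.duration_s}s")

    @property
    def n_frames_per_channel(self) -> int:
        return int(round(self.duration_s * self.fps_per_channel))

    @property
    def fps_total(self) -> float:
        return self.fps_per_channel * len(COLOR_ORDER)

    def frame_times(self) -> np.ndarray:
        """Per-channel sample times (seconds), one per demultiplexed frame."""
        return np.arange(self.n_frames_per_channel) / self.fps_per_channel


def default_timeline(duration_s: float, oxygen_level: int) -> list[tuple[str, float, float]]:
    """10 min normoxia, 10 min hypoxia, 20 min normoxia — scaled to duration.

    A pure-normoxia control (oxygen_level=21) is a single epoch.  For short
    test scenarios the 1:1:2 split is preserved.
    """
    if oxygen_level == 21:
        return [("normoxia", 0.0, duration_s)]
    q = duration_s / 4.0
    return [
        ("normoxia", 0.0, q),
        ("hypoxia", q, 2 * q),
        ("normoxia", 2 * q, duration_s),
    ]


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    config: ScenarioConfig
    calcium: pd.DataFrame                      # time x region dF/F
    true_corr_normoxia: np.ndarray             # 8x8 target correlations
    true_corr_hypoxia: np.ndarray
    true_hbo: np.ndarray                       # whole-brain ramp, µM, per channel-frame
    true_hbr: np.ndarray
    atlas: np.ndarray                          # label image (0 = outside brain)
    regions: pd.DataFrame                      # label, name, hemisphere, macrocluster, centroid
    brain_mask: np.ndarray
    motion_trace: np.ndarray | None = None     # (n_camera_frames, 2) row/col shifts, px
    hbo_maps: np.ndarray | None = None         # per-pixel µM (filled by simulate_hemodynamics)
    hbr_maps: np.ndarray | None = None


# ---------------------------------------------------------------------------
# atlas


def make_atlas(image_shape: tuple[int, int]) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Build a ground-truth cortical atlas: label image, region table, brain mask.

    The brain is an ellipse filling most of the field of view; a narrow
    midline stripe stands in for the middle cerebral (sagittal) sinus.  The
    8 regions tile the ellipse in four anteroposterior bands (Mot, Sen, Ret,
    Vis front to back) split at the midline into left/right.
    """
    rows, cols = image_shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    brain = ((rr - cy) / (0.45 * rows)) ** 2 + ((cc - cx) / (0.42 * cols)) ** 2 <= 1.0

    sinus_half = max(1, rows // 64)
    sinus = brain & (np.abs(cc - cx) <= sinus_half)

    labels = np.zeros(image_shape, dtype=np.uint16)
    band_edges = np.quantile(rr[brain], [0.0, 0.25, 0.5, 0.75, 1.0])
    order = ("Mot", "Sen", "Ret", "Vis")
    records = []
    label = 0
    for i, base in enumerate(order):
        in_band = brain & (rr >= band_edges[i]) & (rr <= band_edges[i + 1] + (i == 3))
        for hemi, sel in (("L", cc < cx - sinus_half), ("R", cc > cx + sinus_half)):
            label += 1
            region = in_band & sel & ~sinus
            labels[region] = label
            ry, rx = np.nonzero(region)
            records.append(
                {
                    "label": label,
                    "name": f"{base}{hemi}",
                    "hemisphere": hemi,
                    "macrocluster": MACROCLUSTER[base],
                    "centroid_row": int(round(ry.mean())),
                    "centroid_col": int(round(rx.mean())),
                    "n_pixels": int(region.sum()),
                }
            )
    labels[sinus] = SINUS_LABEL
    regions = pd.DataFrame.from_records(records)
    # reorder rows to the canonical name order used everywhere downstream
    regions = regions.set_index("name").loc[list(REGION_NAMES)].reset_index()
    return labels, regions, brain


# ---------------------------------------------------------------------------
# calcium


def _target_correlation(config: ScenarioConfig, between_r: float) -> np.ndarray:
    clusters = [MACROCLUSTER[name[:3]] for name in REGION_NAMES]
    n = len(REGION_NAMES)
    corr = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                corr[i, j] = 1.0
            elif clusters[i] == clusters[j]:
                corr[i, j] = config.within_cluster_r
            else:
                corr[i, j] = between_r
    return corr


def _cholesky_or_raise(corr: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        eigvals = np.linalg.eigvalsh(corr)
        off = np.abs(corr - np.eye(len(corr)))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise ValueError(
            "target correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigvals.min():.4g}); largest off-diagonal is "
            f"r={corr[i, j]:.3g} for pair ({REGION_NAMES[i]}, {REGION_NAMES[j]})"
        ) from None


def _bandpass_sos(fps: float, low: float = 0.3, high: float = 3.0) -> np.ndarray:
    high = min(high, 0.45 * fps)  # keep the corner below Nyquist for slow test rates
    return signal.butter(4, [low, high], btype="bandpass", fs=fps, output="sos")


def simulate_calcium(config: ScenarioConfig) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Simulate 8 regional dF/F traces with epoch-dependent correlations.

    Independent white-noise sources are band-passed to 0.3-3 Hz, standardised
    within each epoch, and mixed with the Cholesky factor of that epoch's
    target correlation matrix, so empirical epoch-wise correlations converge
    to the targets as the epoch grows.

    Returns (traces, target_corr_normoxia, target_corr_hypoxia).
    """
    corr_norm = _target_correlation(config, config.between_cluster_r)
    corr_hyp = _target_correlation(config, config.between_cluster_r_hypoxia)
    chol = {"normoxia": _cholesky_or_raise(corr_norm), "hypoxia": _cholesky_or_raise(corr_hyp)}

    rng = np.random.default_rng(config.rng_seed)
    n_frames = config.n_frames_per_channel
    sources = rng.standard_normal((n_frames, len(REGION_NAMES)))
    sos = _bandpass_sos(config.fps_per_channel)
    sources = signal.sosfiltfilt(sos, sources, axis=0)

    t = config.frame_times()
    n_reg = len(REGION_NAMES)
    traces = np.empty_like(sources)
    for label, start, end in config.epoch_timeline:
        sel = (t >= start) & (t < end)
        block = sources[sel]
        block = block - block.mean(axis=0)
        sd = block.std(axis=0)
        sd[sd == 0] = 1.0
        block = block / sd
        if sel.sum() > 4 * n_reg:
            # whiten residual sample correlation so the epoch-wise empirical
            # correlation matches the target (band-limited noise decorrelates
            # slowly; raw mixing would need far longer epochs to converge)
            emp = np.corrcoef(block.T)
            block = block @ np.linalg.inv(np.linalg.cholesky(emp)).T
        traces[sel] = block @ chol[label].T
    traces *= config.calcium_sd
    df = pd.DataFrame(traces, index=pd.Index(t, name="time_s"), columns=list(REGION_NAMES))
    return df, corr_norm, corr_hyp


# ---------------------------------------------------------------------------
# hemodynamics forward model


def _dip_shape(t: np.ndarray, tau: float) -> np.ndarray:
    """Unit-peak transient: (t/tau) exp(1 - t/tau), maximal at t = tau."""
    t = np.maximum(t, 0.0)
    return (t / tau) * np.exp(1.0 - t / tau)


def global_ramp(config: ScenarioConfig, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Whole-brain (∆HbO, ∆HbR) trajectories in µM at the given times.

    Piecewise exponential per epoch: during hypoxia HbR saturates fast,
    HbO dips then rises slowly; on return to normoxia both relax
    exponentially with an added overshoot (HbO) / undershoot (HbR)
    transient.  Pure-normoxia timelines give identically zero.
    """
    p = config.hemo_ramp_params
    hbo = np.zeros_like(times)
    hbr = np.zeros_like(times)
    hbo_state = hbr_state = 0.0
    for label, start, end in config.epoch_timeline:
        sel = (times >= start) & (times < end if end < config.duration_s else times <= end)
        dt = times[sel] - start
        if label == "hypoxia":
            hbr[sel] = p.hbr_plateau_uM + (hbr_state - p.hbr_plateau_uM) * np.exp(-dt / p.hbr_tau_s)
            hbo[sel] = (
                p.hbo_plateau_uM
                + (hbo_state - p.hbo_plateau_uM) * np.exp(-dt / p.hbo_tau_s)
                - p.dip_amp_uM * _dip_shape(dt, p.dip_tau_s)
            )
        else:
            hbr[sel] = hbr_state * np.exp(-dt / p.recovery_tau_s)
            hbo[sel] = hbo_state * np.exp(-dt / p.recovery_tau_s)
            if hbr_state != 0.0 or hbo_state != 0.0:  # post-hypoxia rebound
                hbo[sel] += p.hbo_overshoot_uM * _dip_shape(dt, p.overshoot_tau_s)
                hbr[sel] -= p.hbr_undershoot_uM * _dip_shape(dt, p.overshoot_tau_s)
        if sel.any():
            hbo_state = float(hbo[sel][-1])
            hbr_state = float(hbr[sel][-1])
    return hbo, hbr


def neurovascular_kernel(config: ScenarioConfig) -> np.ndarray:
    """Unit-area gamma impulse response (delay ~1.5 s, FWHM ~2 s by default)."""
    sigma = config.kernel_fwhm_s / 2.355
    shape = (config.kernel_delay_s / sigma) ** 2 + 1.0
    scale = config.kernel_delay_s / (shape - 1.0)
    dt = 1.0 / config.fps_per_channel
    t = np.arange(0.0, config.kernel_delay_s + 6 * sigma, dt)
    k = t ** (shape - 1.0) * np.exp(-t / scale)
    return k / (k.sum() * dt)


def simulate_hemodynamics(
    config: ScenarioConfig, calcium: pd.DataFrame, truth: GroundTruth
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel true (∆HbO, ∆HbR) maps in µM, (time, rows, cols) float32.

    Each in-brain pixel carries the global epoch ramp plus the neurovascular
    response of its region: calcium convolved with a gamma kernel, scaled by
    ``neurovascular_gain_uM`` for HbO and by ``neurovascular_ratio`` of that
    for HbR.  Pixels outside the brain stay at zero.
    """
    t = config.frame_times()
    ramp_hbo, ramp_hbr = global_ramp(config, t)
    kernel = neurovascular_kernel(config)
    dt = 1.0 / config.fps_per_channel

    n_frames = len(t)
    rows, cols = config.image_shape
    hbo = np.zeros((n_frames, rows, cols), dtype=np.float32)
    hbr = np.zeros((n_frames, rows, cols), dtype=np.float32)

    region_hbo = {}
    for name in REGION_NAMES:
        conv = signal.fftconvolve(calcium[name].to_numpy(), kernel * dt)[:n_frames]
        region_hbo[name] = config.neurovascular_gain_uM * conv

    base_hbo = ramp_hbo.astype(np.float32)
    base_hbr = ramp_hbr.astype(np.float32)
    hbo[:, truth.brain_mask] = base_hbo[:, None]
    hbr[:, truth.brain_mask] = base_hbr[:, None]
    for _, reg in truth.regions.iterrows():
        sel = truth.atlas == reg["label"]
        local = region_hbo[reg["name"]].astype(np.float32)
        hbo[:, sel] += local[:, None]
        hbr[:, sel] += (config.neurovascular_ratio * local)[:, None]

    truth.true_hbo, truth.true_hbr = ramp_hbo, ramp_hbr
    truth.hbo_maps, truth.hbr_maps = hbo, hbr
    return hbo, hbr


# ---------------------------------------------------------------------------
# optics + sensor


def _texture_field(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative gain field in [0.7, 1.3] (vessel-like texture)."""
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=min(shape) / 24)
    field_ = field_ / (np.abs(field_).max() or 1.0)
    return 1.0 + 0.3 * field_


def _smooth_motion(n: int, amplitude: float, fps: float, rng: np.random.Generator) -> np.ndarray:
    drift = rng.standard_normal((n, 2))
    drift = ndimage.gaussian_filter1d(drift, sigma=fps, axis=0)  # ~1 s smoothness
    sd = drift.std(axis=0)
    sd[sd == 0] = 1.0
    return amplitude * drift / sd


def render_optics(
    truth: GroundTruth,
    optical: OpticalModel | None = None,
    config: ScenarioConfig | None = None,
) -> InterlacedStack:
    """Render the interlaced 4-color stack from the simulated ground truth.

    Reflectance channels follow the modified Beer-Lambert forward model
    R(t) = R0 * exp(-D * (eps_HbO * dHbO + eps_HbR * dHbR)); the fluorescence
    channel is F0 * (1 + dF/F) attenuated by the mean excitation/emission
    absorption.  Channels are interleaved blue, green, amber, red at 4x the
    per-channel rate; all four frames of a cycle sample the signals at that
    cycle's time (zero-order hold within a cycle).  Gaussian sensor noise is
    added last; negative intensities are clipped at zero with a logged count.
    """
    config = config or truth.config
    optical = optical or OpticalModel()
    if truth.hbo_maps is None:
        raise ValueError("ground truth has no hemodynamic maps; run simulate_hemodynamics first")
    rng = np.random.default_rng(config.rng_seed + 1)

    rows, cols = config.image_shape
    n_cycles = config.n_frames_per_channel
    n_colors = len(COLOR_ORDER)
    frames = np.empty((n_cycles * n_colors, rows, cols), dtype=np.float32)

    # per-pixel dF/F from the regional calcium (zero for the GFP analog)
    dff = np.zeros((n_cycles, rows, cols), dtype=np.float32)
    if config.fluorescence_neural:
        for _, reg in truth.regions.iterrows():
            sel = truth.atlas == reg["label"]
            dff[:, sel] = truth.calcium[reg["name"]].to_numpy(dtype=np.float32)[:, None]

    hbo, hbr = truth.hbo_maps, truth.hbr_maps
    for k, color in enumerate(COLOR_ORDER):
        base = config.baseline_counts * _texture_field((rows, cols), rng).astype(np.float32)
        if color == "blue":
            eps_hbo, eps_hbr = optical.fluorescence_epsilons()
            d = optical.pathlength_fluo_cm
            atten = np.exp(-d * 1e-6 * (eps_hbo * hbo + eps_hbr * hbr))
            frames[k::n_colors] = base[None] * (1.0 + dff) * atten
        else:
            lam = optical.wavelength_of(color)
            d = optical.pathlength_cm[lam]
            e_hbo, e_hbr = optical.epsilon[lam]
            frames[k::n_colors] = base[None] * np.exp(-d * 1e-6 * (e_hbo * hbo + e_hbr * hbr))

    motion = None
    if config.motion_amplitude_px > 0:
        motion = _smooth_motion(len(frames), config.motion_amplitude_px, config.fps_total, rng)
        for i in range(len(frames)):
            frames[i] = ndimage.shift(frames[i], motion[i], order=1, mode="nearest")
        truth.motion_trace = motion

    if config.noise_sd > 0:
        frames += rng.normal(0.0, config.noise_sd, size=frames.shape).astype(np.float32)
        n_neg = int((frames < 0).sum())
        if n_neg:
            logger.info("render_optics: clipped %d negative intensities at 0", n_neg)
            np.clip(frames, 0.0, None, out=frames)

    metadata = {
        "fov_mm": list(config.fov_mm),
        "epoch_timeline": [[lab, float(s), float(e)] for lab, s, e in config.epoch_timeline],
        "oxygen_level": config.oxygen_level,
        "rng_seed": config.rng_seed,
    }
    return InterlacedStack(
        frames=frames,
        fps_total=config.fps_total,
        color_order=tuple(COLOR_ORDER),
        metadata=metadata,
    )


def simulate_scenario(config: ScenarioConfig) -> tuple[InterlacedStack, GroundTruth]:
    """Run the full forward model: calcium -> hemodynamics -> optics."""
    atlas, regions, brain = make_atlas(config.image_shape)
    calcium, corr_n, corr_h = simulate_calcium(config)
    truth = GroundTruth(
        config=config,
        calcium=calcium,
        true_corr_normoxia=corr_n,
        true_corr_hypoxia=corr_h,
        true_hbo=np.zeros(config.n_frames_per_channel),
        true_hbr=np.zeros(config.n_frames_per_channel),
        atlas=atlas,
        regions=regions,
        brain_mask=brain,
    )
    simulate_hemodynamics(config, calcium, truth)
    stack = render_optics(truth, config=config)
    return stack, truth


# ---------------------------------------------------------------------------
# fixtures on disk


def write_fixture(stack: InterlacedStack, truth: GroundTruth, path: str | Path) -> Path:
    """Write a dataset: stack.tif + sidecar.yaml + ground-truth tables + atlas.

    The stack is stored as float32 multi-page TIFF so the write->read round
    trip is lossless.  Ground truth goes to CSV (calcium traces, whole-brain
    hemoglobin ramps, correlation targets, region table, motion) and the
    atlas to an integer TIFF.
    """
    path = Path(path)
    try:
        path.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path / "stack.tif", stack.frames, photometric="minisblack")
        sidecar = {
            "color_order": list(stack.color_order),
            "fps_total": float(stack.fps_total),
            "fps_per_channel": float(stack.fps_total / len(stack.color_order)),
            "n_frames": int(len(stack.frames)),
            **stack.metadata,
        }
        (path / "sidecar.yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))

        truth.calcium.to_csv(path / "calcium.csv")
        pd.DataFrame(
            {"time_s": truth.config.frame_times(), "hbo_uM": truth.true_hbo, "hbr_uM": truth.true_hbr}
        ).to_csv(path / "global_hemodynamics.csv", index=False)
        names = list(REGION_NAMES)
        pd.DataFrame(truth.true_corr_normoxia, index=names, columns=names).to_csv(
            path / "corr_normoxia.csv"
        )
        pd.DataFrame(truth.true_corr_hypoxia, index=names, columns=names).to_csv(
            path / "corr_hypoxia.csv"
        )
        truth.regions.to_csv(path / "regions.csv", index=False)
        tifffile.imwrite(path / "atlas.tif", truth.atlas.astype(np.uint16), photometric="minisblack")
        if truth.motion_trace is not None:
            pd.DataFrame(truth.motion_trace, columns=["d_row", "d_col"]).to_csv(
                path / "motion.csv", index=False
            )
    except OSError as exc:
        raise OSError(f"failed writing fixture to {path}: {exc}") from exc
    return path


def read_truth_tables(path: str | Path) -> dict[str, pd.DataFrame | np.ndarray]:
    """Reload the ground-truth tables written by :func:`write_fixture`."""
    path = Path(path)
    out: dict[str, pd.DataFrame | np.ndarray] = {
        "calcium": pd.read_csv(path / "calcium.csv", index_col=0),
        "global_hemodynamics": pd.read_csv(path / "global_hemodynamics.csv"),
        "corr_normoxia": pd.read_csv(path / "corr_normoxia.csv", index_col=0),
        "corr_hypoxia": pd.read_csv(path / "corr_hypoxia.csv", index_col=0),
        "regions": pd.read_csv(path / "regions.csv"),
        "atlas": tifffile.imread(path / "atlas.tif"),
    }
    if (path / "motion.csv").exists():
        out["motion"] = pd.read_csv(path / "motion.csv").to_numpy()
    return out
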