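"""Acquisition I/O: stack containers, channel demultiplexing, co-registration.

A widefield acquisition interlaces four illumination colors (blue for
fluorescence excitation; green 535 nm, amber 590 nm and red 620 nm for
reflectance) frame by frame at the camera rate, so an 80 Hz camera yields
20 Hz per color.  This module reads/writes those stacks, splits them into
per-channel streams with correct timestamps, and co-registers frames —
within an acquisition to its first frame, and between sessions to the
subject's first acquisition — using an affine transform optimised on mean
squared error, optionally refined by a smooth (diffeomorphic) displacement
field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage
from skimage.registration import phase_cross_correlation

import SimpleITK as sitk

logger = logging.getLogger(__name__)

__all__ = [
    "COLOR_ORDER",
    "InterlacedStack",
    "ChannelStack",
    "RegistrationResult",
    "read_acquisition",
    "demultiplex",
    "interleave",
    "register_within",
    "register_between_days",
    "apply_affine",
]

#: fixed illumination sequence, repeated for the whole acquisition
COLOR_ORDER = ("blue", "green", "amber", "red")


@dataclass
class InterlacedStack:
    """Raw time-interlaced multicolor stack straight off the camera."""

    frames: np.ndarray                       # (time, rows, cols) counts
    fps_total: float
    color_order: tuple[str, ...] = COLOR_ORDER
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_colors = len(self.color_order)
        extra = len(self.frames) % n_colors
        if extra:
            logger.warning(
                "dropping %d trailing frame(s) of a partial %d-color cycle", extra, n_colors
            )
            self.frames = self.frames[: len(self.frames) - extra]
        if self.frames.size and self.frames.min() < 0:
            raise ValueError("interlaced stack contains negative intensities")

    @property
    def n_cycles(self) -> int:
        return len(self.frames) // len(self.color_order)


@dataclass
class ChannelStack:
    """One demultiplexed illumination channel with per-frame timestamps."""

    channel: str
    frames: np.ndarray
    fps: float
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        if len(self.timestamps) != len(self.frames):
            raise ValueError("timestamps and frames disagree in length")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass
class RegistrationResult:
    """Per-frame affine parameters and before/after MSE to the reference."""

    affines: np.ndarray            # (n_frames, 2, 3) matrices mapping output -> input coords
    reference_index: int
    mse_before: np.ndarray
    mse_after: np.ndarray
    displacement_field: np.ndarray | None = None   # (rows, cols, 2) px, between-day only

    def to_frame(self) -> pd.DataFrame:
        a = self.affines.reshape(len(self.affines), 6)
        df = pd.DataFrame(a, columns=["a11", "a12", "a13", "a21", "a22", "a23"])
        df.insert(0, "frame", np.arange(len(a)))
        df["mse_before"] = self.mse_before
        df["mse_after"] = self.mse_after
        return df


# ---------------------------------------------------------------------------
# reading / demultiplexing


def read_acquisition(path: str | Path) -> InterlacedStack:
    """Read a fixture directory (stack.tif + sidecar.yaml) into a stack.

    The sidecar must agree with the TIFF on frame count; a mismatch is
    reported with both numbers.
    """
    path = Path(path)
    tif = path / "stack.tif"
    sidecar_path = path / "sidecar.yaml"
    if not tif.exists():
        raise FileNotFoundError(f"no stack.tif in {path}")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"no sidecar.yaml next to {tif}")
    sidecar = yaml.safe_load(sidecar_path.read_text())
    frames = tifffile.imread(tif)
    expected = int(sidecar["n_frames"])
    if len(frames) != expected:
        raise ValueError(
            f"frame count mismatch in {path}: sidecar says {expected}, TIFF holds {len(frames)}"
        )
    meta = {
        k: v
        for k, v in sidecar.items()
        if k not in ("color_order", "fps_total", "fps_per_channel", "n_frames")
    }
    return InterlacedStack(
        frames=frames,
        fps_total=float(sidecar["fps_total"]),
        color_order=tuple(sidecar["color_order"]),
        metadata=meta,
    )


def demultiplex(stack: InterlacedStack) -> dict[str, ChannelStack]:
    """Split an interlaced stack into per-channel streams.

    Channel k (0-based position in ``color_order``) receives frames
    k, k+n, k+2n, ... and timestamps offset by k / fps_total, so each channel
    runs at fps_total / n_colors.
    """
    n = len(stack.color_order)
    fps = stack.fps_total / n
    out = {}
    for k, color in enumerate(stack.color_order):
        frames = stack.frames[k::n]
        ts = k / stack.fps_total + np.arange(len(frames)) / fps
        out[color] = ChannelStack(channel=color, frames=frames, fps=fps, timestamps=ts)
    return out


def interleave(channels: dict[str, ChannelStack], color_order: tuple[str, ...] = COLOR_ORDER) -> InterlacedStack:
    """Inverse of :func:`demultiplex` (exact round trip)."""
    missing = [c for c in color_order if c not in channels]
    if missing:
        raise KeyError(f"missing channel(s) {missing} for interleave")
    n_cycles = min(len(channels[c].frames) for c in color_order)
    first = channels[color_order[0]]
    frames = np.empty((n_cycles * len(color_order), *first.frames.shape[1:]), dtype=first.frames.dtype)
    for k, color in enumerate(color_order):
        frames[k :: len(color_order)] = channels[color].frames[:n_cycles]
    return InterlacedStack(frames=frames, fps_total=first.fps * len(color_order), color_order=tuple(color_order))


# ---------------------------------------------------------------------------
# registration


def _mse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((np.asarray(a, float) - np.asarray(b, float)) ** 2))


def apply_affine(frame: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Resample a frame through a 2x3 affine (output->input coords, bilinear)."""
    return ndimage.affine_transform(
        frame, affine[:, :2], offset=affine[:, 2], order=1, mode="nearest"
    )


_IDENTITY = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])


def _estimate_affine(
    reference: np.ndarray, moving: np.ndarray, refine: bool = True
) -> np.ndarray:
    """Affine (output->input) aligning ``moving`` onto ``reference``.

    Initialised by subpixel phase cross-correlation (translation), then
    refined with a full 2-D affine optimised on the mean-squares metric
    (gradient descent, linear interpolation).  If the optimiser fails the
    translation-only estimate is kept.
    """
    shift, _, _ = phase_cross_correlation(
        np.asarray(reference, float), np.asarray(moving, float), upsample_factor=50
    )
    affine = _IDENTITY.copy()
    affine[:, 2] = -shift  # output->input offset undoing the measured shift

    if not refine:
        return affine

    ref = sitk.GetImageFromArray(np.asarray(reference, np.float64))
    mov = sitk.GetImageFromArray(np.asarray(moving, np.float64))
    tx = sitk.AffineTransform(2)
    # sitk uses (x, y) = (col, row) ordering
    tx.SetTranslation((float(-shift[1]), float(-shift[0])))
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-5, numberOfIterations=100, relaxationFactor=0.6
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetInitialTransform(tx, inPlace=True)
    try:
        result = reg.Execute(ref, mov)
        m = np.array(result.GetMatrix()).reshape(2, 2)
        t = np.array(result.GetTranslation())
        c = np.array(result.GetCenter())
        # sitk maps fixed (x,y) -> moving: x_mov = M (x_fix - c) + c + t;
        # convert to (row, col) output->input form for ndimage
        p = np.eye(2)[::-1]  # swap axes
        m_rc = p @ m @ p
        offset_rc = p @ (c + t - m @ c)
        affine = np.hstack([m_rc, offset_rc[:, None]])
    except RuntimeError as exc:
        logger.warning("affine refinement failed (%s); keeping translation estimate", exc)
    return affine


def _displacement_refine(
    reference: np.ndarray, moving: np.ndarray, sigma: float = 2.0, iterations: int = 30
) -> np.ndarray:
    """Smooth displacement field (diffeomorphic demons) refining an affine fit.

    Returns a (rows, cols, 2) field in pixels, (row, col) order, to be added
    to the identity grid when resampling.
    """
    ref = sitk.GetImageFromArray(np.asarray(reference, np.float64))
    mov = sitk.GetImageFromArray(np.asarray(moving, np.float64))
    demons = sitk.DiffeomorphicDemonsRegistrationFilter()
    demons.SetNumberOfIterations(iterations)
    demons.SetStandardDeviations(sigma)
    field_img = demons.Execute(ref, mov)
    field_xy = sitk.GetArrayFromImage(field_img)       # (rows, cols, (x, y))
    return field_xy[..., ::-1]                         # -> (row, col)


def _warp_with_field(frame: np.ndarray, field: np.ndarray) -> np.ndarray:
    rows, cols = frame.shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    coords = np.stack([rr + field[..., 0], cc + field[..., 1]])
    return ndimage.map_coordinates(frame, coords, order=1, mode="nearest")


def register_within(
    channel: ChannelStack,
    reference_index: int = 0,
    refine_affine: bool = True,
    diffeomorphic: bool = False,
) -> tuple[ChannelStack, RegistrationResult]:
    """Co-register every frame of a channel to a reference frame.

    Each frame gets the affine that minimises its MSE to the reference; if a
    frame's fitted transform increases the MSE it falls back to the identity
    (with a warning), so registration never degrades a frame.  The optional
    diffeomorphic pass adds a smooth displacement-field refinement per frame
    (off by default; it is slow and only matters for non-rigid residuals).
    """
    frames = channel.frames
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to register")
    ref = np.asarray(frames[reference_index], float)

    n = len(frames)
    affines = np.tile(_IDENTITY, (n, 1, 1))
    out = np.empty_like(frames, dtype=np.float32)
    mse_before = np.empty(n)
    mse_after = np.empty(n)
    for i in range(n):
        mov = np.asarray(frames[i], float)
        mse_before[i] = _mse(ref, mov)
        if i == reference_index:
            out[i] = mov
            mse_after[i] = mse_before[i]
            continue
        aff = _estimate_affine(ref, mov, refine=refine_affine)
        resampled = apply_affine(mov, aff)
        if diffeomorphic:
            field = _displacement_refine(ref, resampled)
            resampled = _warp_with_field(resampled, field)
        err = _mse(ref, resampled)
        if err > mse_before[i]:
            logger.warning("frame %d: registration worsened MSE; keeping identity", i)
            aff, resampled, err = _IDENTITY.copy(), mov, mse_before[i]
        affines[i] = aff
        out[i] = resampled
        mse_after[i] = err

    registered = ChannelStack(
        channel=channel.channel, frames=out, fps=channel.fps, timestamps=channel.timestamps
    )
    return registered, RegistrationResult(
        affines=affines,
        reference_index=reference_index,
        mse_before=mse_before,
        mse_after=mse_after,
    )


def register_between_days(
    session_ref_frame: np.ndarray,
    session_new_frame: np.ndarray,
    diffeomorphic: bool = True,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Transform mapping a new session's coordinates onto the reference session.

    Returns (2x3 affine, displacement field or None).  Applied downstream to
    carry the atlas/ROIs of the first acquisition onto later ones.
    """
    ref = np.asarray(session_ref_frame, float)
    new = np.asarray(session_new_frame, float)
    if ref.shape != new.shape:
        raise ValueError(f"frame shapes differ: {ref.shape} vs {new.shape}")
    if ref.std() == 0 or new.std() == 0:
        raise ValueError("cannot register constant images")
    affine = _estimate_affine(ref, new, refine=True)
    field = None
    if diffeomorphic:
        resampled = apply_affine(new, affine)
        field = _displacement_refine(ref, resampled)
        if _mse(ref, _warp_with_field(resampled, field)) > _mse(ref, resampled):
            logger.warning("between-day displacement refinement worsened MSE; dropping it")
            field = None
    return affine, field


def warp_labels(labels: np.ndarray, affine: np.ndarray, inverse: bool = False) -> np.ndarray:
    """Carry a label image through a recovered affine (nearest-neighbour).

    By default warps in the same direction as :func:`apply_affine` (a label
    image living on the moving frame lands in reference coordinates); with
    ``inverse=True`` the reference atlas is pushed onto the moving session.
    """
    m, off = affine[:, :2], affine[:, 2]
    if inverse:
        m = np.linalg.inv(m)
        off = -m @ affine[:, 2]
    return ndimage.affine_transform(labels, m, offset=off, order=0, mode="constant", cval=0)
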