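"""Two-channel movie quantification of receptor dissociation.

The input is a pair of aligned image stacks acquired at ~1 Hz: a membrane
marker channel (prenylated far-red label) and the reporter channel carrying
the receptor's intracellular fragment.  The marker defines a per-frame binary
membrane mask (difference-of-Gaussians bandpass + Otsu threshold); the
reporter's membrane/cytoplasm mean-intensity ratio over time is the
dissociation readout, normalized so the pre-illumination mean is 1 and the
minimum 0, then fit with single exponentials for the illumination (decay) and
recovery (rise) phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import difference_of_gaussians, threshold_otsu
from skimage.registration import phase_cross_correlation

from .kinetics_fit import DecayTrace, normalize_trace

__all__ = [
    "TwoChannelStack",
    "register_channels",
    "correct_stack",
    "membrane_mask",
    "membrane_ratio_trace",
]


@dataclass
class TwoChannelStack:
    """Frames x height x width arrays for the marker and reporter channels."""

    marker: np.ndarray
    reporter: np.ndarray
    frame_interval: float = 1.0  # s
    illumination_window: tuple[float, float] = (25.0, 50.0)  # s
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.marker = np.asarray(self.marker, dtype=float)
        self.reporter = np.asarray(self.reporter, dtype=float)
        if self.marker.shape != self.reporter.shape or self.marker.ndim != 3:
            raise ValueError("marker and reporter must be equal-shape (frames, h, w) stacks")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.marker.shape[0]) * self.frame_interval


def register_channels(stack: TwoChannelStack) -> tuple[TwoChannelStack, tuple[int, int]]:
    """Translate the reporter channel onto the marker channel.

    The integer-pixel shift maximizing the cross-correlation of the two
    time-averaged channels is applied to every reporter frame.  A correlation
    peak at the image border means registration cannot be trusted and raises.
    """
    ref = stack.marker.mean(axis=0)
    mov = stack.reporter.mean(axis=0)
    shift, _, _ = phase_cross_correlation(ref, mov, upsample_factor=1)
    dy, dx = int(round(shift[0])), int(round(shift[1]))
    h, w = ref.shape
    if abs(dy) >= h // 2 or abs(dx) >= w // 2:
        raise ValueError("registration peak at image border; channels do not overlap")
    reporter = np.roll(stack.reporter, (dy, dx), axis=(1, 2))
    out = TwoChannelStack(stack.marker, reporter, stack.frame_interval, stack.illumination_window, dict(stack.meta))
    return out, (dy, dx)


def correct_stack(
    stack: TwoChannelStack,
    background_roi: tuple[slice, slice],
    whole_cell_roi: tuple[slice, slice],
) -> TwoChannelStack:
    """Per-frame background subtraction and bleach correction.

    The mean of the background ROI is subtracted frame-wise from each
    channel.  The bleach factor is the whole-cell mean of the *reporter*
    channel normalized to frame 0 (the reporter pool is conserved as the
    fragment redistributes, so its whole-cell mean tracks photobleaching
    only) and is divided out of both channels, which leaves the
    membrane/cytoplasm ratio within a frame untouched.
    """
    out = {}
    for name in ("marker", "reporter"):
        frames = getattr(stack, name).copy()
        bg_region = frames[:, background_roi[0], background_roi[1]]
        if bg_region[0].size == 0:
            raise ValueError("empty background ROI")
        frames -= bg_region.mean(axis=(1, 2))[:, None, None]
        out[name] = frames
    cell = out["reporter"][:, whole_cell_roi[0], whole_cell_roi[1]]
    if cell[0].size == 0:
        raise ValueError("empty whole-cell ROI")
    cell_mean = cell.mean(axis=(1, 2))
    if np.any(cell_mean <= 0):
        raise ValueError("whole-cell reporter mean non-positive after background subtraction")
    bleach = (cell_mean / cell_mean[0])[:, None, None]
    out = {name: frames / bleach for name, frames in out.items()}
    return TwoChannelStack(out["marker"], out["reporter"], stack.frame_interval, stack.illumination_window, dict(stack.meta))


def membrane_mask(marker_frame: np.ndarray, sigma_low: float = 1.0, sigma_high: float = 4.0) -> np.ndarray:
    """Binary membrane mask from a corrected marker frame.

    Difference-of-Gaussians bandpass (default sigmas 1 and 4 px) isolates the
    thin membrane ring; Otsu thresholding of the bandpassed image gives the
    mask.  An empty mask raises so flagged frames are excluded upstream.
    """
    band = difference_of_gaussians(np.asarray(marker_frame, dtype=float), sigma_low, sigma_high)
    if np.ptp(band) == 0:
        raise ValueError("flat frame: no membrane signal")
    mask = band > threshold_otsu(band)
    if not mask.any():
        raise ValueError("empty membrane mask")
    return mask


def membrane_ratio_trace(
    stack: TwoChannelStack,
    cytoplasm_roi: tuple[slice, slice],
    masks: list[np.ndarray] | None = None,
    normalized: bool = True,
) -> DecayTrace:
    """Per-frame (membrane mean)/(cytoplasm mean) of the reporter channel.

    Masks default to :func:`membrane_mask` of each marker frame; frames whose
    mask is empty are excluded and reported in the trace metadata.  With
    ``normalized=True`` the trace is rescaled so the pre-illumination mean is
    1 and the minimum 0, ready for the two-phase exponential fits.
    """
    times, values, skipped = [], [], []
    for i in range(stack.marker.shape[0]):
        try:
            mask = masks[i] if masks is not None else membrane_mask(stack.marker[i])
        except ValueError:
            skipped.append(i)
            continue
        cyto = stack.reporter[i][cytoplasm_roi[0], cytoplasm_roi[1]]
        cyto_mean = float(cyto.mean())
        if cyto_mean <= 0:
            skipped.append(i)
            continue
        values.append(float(stack.reporter[i][mask].mean()) / cyto_mean)
        times.append(i * stack.frame_interval)
    if not values:
        raise ValueError("no usable frames for the ratio trace")
    trace = DecayTrace(
        times=np.array(times),
        values=np.array(values),
        t_zero=stack.illumination_window[0],
        unit="s",
        meta={"skipped_frames": skipped},
    )
    if normalized:
        trace = normalize_trace(trace, mode="pre_mean_to_unit_min_to_zero")
    return trace
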