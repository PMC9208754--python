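"""Spatially resolved degree-of-correlation (activity) maps.

Motile bacteria inside biofilm channels scramble the local image intensity on
the timescale of their swimming, while matrix-bound regions stay frozen. The
intensity correlation between two frames separated by tau, evaluated over a
small region of interest (ROI) centred at r,

    c_I(tau; t, r) = <I_p(t) I_p(t+tau)>_r / (<I_p(t)>_r <I_p(t+tau)>_r) - 1,

is, at tau = 0, the squared coefficient of variation of the ROI texture, and
decays toward 0 as the ROI decorrelates. Averaging over many frame pairs and
normalizing by the same quantity at a one-frame lag removes the static
texture contrast, leaving a map that is ~1 in static regions and ~0 where
bacteria are active. Low normalized correlation therefore marks activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from wrinklekit.io import ImageStack


def roi_correlation(frame_t: np.ndarray, frame_t_tau: np.ndarray, roi: tuple[slice, slice]) -> float:
    """Raw degree of correlation of one ROI between two frames.

    Symmetric in the two frames and invariant under a common global intensity
    rescaling. ROIs with non-positive mean intensity are not interpretable
    under the multiplicative normalization and return NaN (flagged, excluded
    downstream).
    """
    a = np.asarray(frame_t, float)[roi]
    b = np.asarray(frame_t_tau, float)[roi]
    if a.shape != b.shape:
        raise ValueError("frames must have the same shape")
    ma, mb = a.mean(), b.mean()
    if ma <= 0 or mb <= 0:
        return float("nan")
    return float((a * b).mean() / (ma * mb) - 1.0)


@dataclass
class CorrelationMap:
    """Grid of ROI correlation values with its normalization reference.

    ``raw`` is the pair-averaged c_I at the analysis lag; ``reference`` the
    same at the one-frame lag; ``normalized`` their ratio clamped to [0, 1]
    (NaN where a ROI was flagged). ``roi_px`` is the ROI edge in pixels.
    """

    normalized: np.ndarray
    raw: np.ndarray
    reference: np.ndarray
    tau_s: float
    roi_px: int
    n_pairs: int


def _roi_reduce(frame: np.ndarray, roi_px: int) -> np.ndarray:
    h, w = frame.shape
    return frame.reshape(h // roi_px, roi_px, w // roi_px, roi_px).mean(axis=(1, 3))


def _pair_averaged_map(frames: np.ndarray, lag: int, n_pairs: int, roi_px: int) -> np.ndarray:
    n = frames.shape[0]
    starts = range(min(n_pairs, n - lag))
    acc = None
    for t in starts:
        a = frames[t].astype(np.float64)
        b = frames[t + lag].astype(np.float64)
        prod = _roi_reduce(a * b, roi_px)
        ma = _roi_reduce(a, roi_px)
        mb = _roi_reduce(b, roi_px)
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.where((ma > 0) & (mb > 0), prod / (ma * mb) - 1.0, np.nan)
        acc = c if acc is None else acc + c
    return acc / len(list(starts))


def activity_map(
    movie: ImageStack,
    tau_s: float = 1.0,
    n_pairs: int = 200,
    roi_um: float = 2.5,
    frame_range: tuple[int, int] | None = None,
    min_reference: float = 2e-4,
) -> CorrelationMap:
    """Normalized degree-of-correlation map of a movie.

    Per ROI, c_I is averaged over ``n_pairs`` frame pairs separated by
    ``tau_s`` (start frames stepping by one) and divided by the same average
    at a one-frame lag, clamping to [0, 1]. Static regions map to ~1, fully
    decorrelated (active) regions toward 0. ``frame_range`` restricts the
    analysis window, e.g. to the frames after an activity switch.

    ROIs whose one-frame reference correlation falls below ``min_reference``
    carry no contrast beyond camera noise; their ratio is meaningless and they
    are flagged NaN rather than classified.
    """
    if movie.pixel_size_um is None:
        raise ValueError("pixel_size_um is required for the ROI grid")
    fps = movie.fps
    lag = round(tau_s * fps)
    if lag < 1 or abs(lag - tau_s * fps) > 0.01 * max(lag, 1):
        nearest = max(round(tau_s * fps), 1) / fps
        raise ValueError(
            f"tau = {tau_s} s is not representable at {fps} fps; nearest representable tau is {nearest} s"
        )
    frames = movie.frames
    if frame_range is not None:
        frames = frames[frame_range[0] : frame_range[1]]
    if frames.shape[0] <= lag + 1:
        raise ValueError(f"movie window has {frames.shape[0]} frames, needs more than lag + 1 = {lag + 1}")

    roi_px = max(2, 2 * round(roi_um / movie.pixel_size_um / 2.0))
    h = frames.shape[1] // roi_px * roi_px
    w = frames.shape[2] // roi_px * roi_px
    frames = frames[:, :h, :w]

    raw = _pair_averaged_map(frames, lag, n_pairs, roi_px)
    ref = _pair_averaged_map(frames, 1, n_pairs, roi_px)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(ref > min_reference, np.clip(raw / ref, 0.0, 1.0), np.nan)
    return CorrelationMap(
        normalized=norm,
        raw=raw,
        reference=ref,
        tau_s=lag / fps,
        roi_px=roi_px,
        n_pairs=n_pairs,
    )


def classify_rois(cmap: CorrelationMap, threshold: float = 0.5) -> np.ndarray:
    """Boolean active/static call per ROI: active where normalized correlation < threshold."""
    return cmap.normalized < threshold
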