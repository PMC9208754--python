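"""Wrinkle/channel-network quantification from timelapse micrographs.

Wrinkles appear as dark curvilinear ridges on a bright biofilm background in
phase-contrast timelapses. The measurement chain follows the classic binary
pipeline: a single Otsu threshold determined on a reference frame (by
convention the last frame, where the network is fully developed) binarizes
every frame; objects smaller than 5 pixels are removed and a 3x3 binary
opening cleans ragged edges; the cleaned mask is thinned to a one-pixel-wide,
topology-preserving skeleton whose 8-connected components are labeled. Per
frame this yields the number of isolated wrinkles N and the length L of the
longest connected wrinkle (total skeleton length of the largest component,
reported in mm). The N(t)/L(t) curves are then segmented into the three
characteristic growth stages: nucleation of many small wrinkles (N rises, L
small), connection into a network (N falls, L grows), and a mature plateau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure, morphology

from wrinklekit.io import ImageStack


def otsu_threshold(frame: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold (maximizing between-class variance) for one frame.

    On well-separated bimodal histograms the between-class variance is exactly
    constant for every threshold inside the empty gap between the modes; the
    maximizer is then a plateau, and picking its edge would leave the
    threshold hugging one mode's noise tail. The plateau midpoint is returned
    instead, which centres the threshold in the gap and makes binarization
    robust to rare noise excursions.

    Raises on a constant frame, whose histogram is degenerate and admits no
    two-class split.
    """
    frame = np.asarray(frame)
    if frame.min() == frame.max():
        raise ValueError("degenerate histogram: frame has a single intensity value")
    counts, edges = np.histogram(frame.ravel(), bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = counts.astype(np.float64)
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    s0 = np.cumsum(counts * centers)
    s1 = s0[-1] - s0
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = s0 / w0
        m1 = s1 / w1
        var_between = w0 * w1 * (m0 - m1) ** 2
    var_between = np.nan_to_num(var_between[:-1])  # split after bin t
    vmax = var_between.max()
    plateau = set(np.nonzero(var_between >= vmax * (1.0 - 1e-9))[0].tolist())
    best = int(np.argmax(var_between))
    # contiguous run of maximizers containing the argmax
    left = best
    while left - 1 in plateau:
        left -= 1
    right = best
    while right + 1 in plateau:
        right += 1
    mid = (left + right) // 2
    # threshold between bin mid and mid+1
    return float(edges[mid + 1])


def binarize_stack(
    stack: ImageStack,
    reference: int = -1,
    dark_foreground: bool = True,
) -> np.ndarray:
    """Binarize every frame with a single threshold taken from one reference frame.

    The threshold is deliberately fixed across the timelapse (default: from
    the last frame) so that N(t)/L(t) trends are not confounded by per-frame
    threshold drift. Foreground means wrinkle pixels: below threshold for the
    usual dark-ridge contrast, above threshold with ``dark_foreground=False``.
    """
    n = stack.n_frames
    if not -n <= reference < n:
        raise IndexError(f"reference frame {reference} out of range for {n} frames")
    thr = otsu_threshold(stack.frames[reference])
    if dark_foreground:
        return stack.frames < thr
    return stack.frames > thr


def clean_binary(mask: np.ndarray, min_size: int = 5) -> np.ndarray:
    """Remove objects smaller than ``min_size`` pixels, then apply a 3x3 binary opening."""
    mask = np.asarray(mask, bool)
    cleaned = morphology.remove_small_objects(mask, max_size=min_size - 1)
    return morphology.opening(cleaned, footprint=np.ones((3, 3), bool)).astype(bool)


@dataclass
class SkeletonGraph:
    """One-pixel-wide skeleton with 8-connected component labels and pixel counts."""

    skeleton: np.ndarray
    labels: np.ndarray
    pixel_counts: np.ndarray  # per component, 1-indexed labels -> pixel_counts[label-1]

    @property
    def n_components(self) -> int:
        return len(self.pixel_counts)


def skeletonize_and_label(mask: np.ndarray) -> SkeletonGraph:
    """Thin a cleaned binary mask to a skeleton and label its 8-connected components.

    Thinning (Guo-Hall style, via ``skimage.morphology.thin``) is used rather
    than the medial-axis transform because it preserves the arc length of
    ribbon-like objects with far smaller end/junction artifacts, which matters
    for the L metric.
    """
    mask = np.asarray(mask, bool)
    skeleton = morphology.thin(mask)
    labels = measure.label(skeleton, connectivity=2)
    counts = np.bincount(labels.ravel())[1:]
    return SkeletonGraph(skeleton=skeleton, labels=labels, pixel_counts=counts)


def geodesic_diameter_px(graph: SkeletonGraph, label: int) -> float:
    """End-to-end (geodesic) path length of one skeleton component, in pixels.

    Double-sweep estimate: a shortest-path sweep (diagonal steps sqrt(2)) from
    an arbitrary pixel finds a far endpoint; a second sweep from there gives
    the diameter. Exact on trees, a lower bound on graphs with cycles.
    Provided for comparison with the default total-length convention for L.
    """
    import networkx as nx

    pix = np.argwhere(graph.labels == label)
    if len(pix) == 0:
        raise ValueError(f"no component with label {label}")
    if len(pix) == 1:
        return 0.0
    pset = {tuple(p) for p in pix}
    g = nx.Graph()
    for r, c in pset:
        for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
            nb = (r + dr, c + dc)
            if nb in pset:
                g.add_edge((r, c), nb, weight=1.0 if dr * dc == 0 else 2**0.5)
    src = next(iter(pset))
    far = max(nx.single_source_dijkstra_path_length(g, src).items(), key=lambda kv: kv[1])[0]
    dists = nx.single_source_dijkstra_path_length(g, far)
    return float(max(dists.values()))


@dataclass
class WrinkleMetrics:
    """Per-frame wrinkle count N and longest connected wrinkle length L."""

    table: pd.DataFrame  # columns: frame, time_s, N, L_mm (or L_px if no pixel size)
    length_unit: str  # "mm" or "px"


def wrinkle_metrics(
    stack: ImageStack,
    reference: int = -1,
    min_size: int = 5,
    dark_foreground: bool = True,
    geodesic: bool = False,
) -> WrinkleMetrics:
    """Run the full binary pipeline and extract N and L for every frame.

    L is the total skeleton length of the largest 8-connected component
    (pixel count x pixel size), which is what component labeling of a
    branched network yields; ``geodesic=True`` switches to the end-to-end
    path-length variant. Lengths are reported in mm when the pixel size is
    known, otherwise in pixels with a warning.
    """
    binary = binarize_stack(stack, reference=reference, dark_foreground=dark_foreground)
    if stack.pixel_size_um is None:
        warnings.warn("pixel size unknown: L reported in pixels, not mm")
        scale, unit = 1.0, "px"
    else:
        scale, unit = stack.pixel_size_um * 1e-3, "mm"
    records = []
    for i in range(stack.n_frames):
        try:
            graph = skeletonize_and_label(clean_binary(binary[i], min_size=min_size))
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"wrinkle pipeline failed at frame {i}: {exc}") from exc
        n = graph.n_components
        if n == 0:
            length_px = 0.0
        elif geodesic:
            largest = int(np.argmax(graph.pixel_counts)) + 1
            length_px = geodesic_diameter_px(graph, largest)
        else:
            length_px = float(graph.pixel_counts.max())
        t = i * stack.frame_interval_s if stack.frame_interval_s is not None else float(i)
        records.append((i, t, n, length_px * scale))
    table = pd.DataFrame(records, columns=["frame", "time_s", "N", f"L_{unit}"])
    return WrinkleMetrics(table=table, length_unit=unit)


@dataclass
class StageSegmentation:
    """Contiguous three-stage split of the wrinkle growth curves.

    stage 1: nucleation (first nonzero N through the peak of smoothed N);
    stage 2: network connection (peak of N through the onset of the L plateau);
    stage 3: mature network (remainder; may be empty if L never plateaus).
    """

    stage1_start: int
    stage2_start: int
    stage3_start: int | None
    labels: np.ndarray  # per frame: 0 = pre-nucleation, 1/2/3 = stages
    no_plateau: bool = False


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(x.astype(float), pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")[: len(x)]


def segment_stages(
    metrics: WrinkleMetrics,
    plateau_frac: float = 0.05,
    plateau_frames: int = 5,
    smooth_window: int = 5,
) -> StageSegmentation:
    """Segment N(t)/L(t) into the three growth stages.

    The stage-1/2 boundary is the argmax of the moving-average-smoothed N(t);
    the stage-2/3 boundary is the first frame from which L stays within
    ``plateau_frac`` of its final value for ``plateau_frames`` consecutive
    frames. A monotonically growing L yields an empty stage 3, flagged via
    ``no_plateau``.
    """
    table = metrics.table
    n = table["N"].to_numpy()
    l_col = f"L_{metrics.length_unit}"
    length = table[l_col].to_numpy(float)
    if not (n > 0).any():
        raise ValueError("no wrinkles detected: N is zero on every frame")
    start = int(np.argmax(n > 0))
    smoothed = _moving_average(n, smooth_window)
    peak = start + int(np.argmax(smoothed[start:]))
    final = length[-1]
    band = plateau_frac * final
    in_band = np.abs(length - final) <= band
    stage3 = None
    for t in range(peak, len(length) - plateau_frames + 1):
        if in_band[t : t + plateau_frames].all() and in_band[t:].all():
            stage3 = t
            break
    labels = np.zeros(len(n), int)
    labels[start:] = 1
    labels[peak:] = 2
    if stage3 is not None:
        labels[stage3:] = 3
    return StageSegmentation(
        stage1_start=start,
        stage2_start=peak,
        stage3_start=stage3,
        labels=labels,
        no_plateau=stage3 is None,
    )


@dataclass
class ZStack:
    """Confocal slices ordered substrate (z=0) to lumen, with slice spacing in um."""

    slices: np.ndarray  # (Z, H, W)
    z_step_um: float

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3:
            raise ValueError("slices must be 3-D (Z, H, W)")
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be > 0")


def effective_thickness(zstack: ZStack, signal_threshold: float) -> tuple[float, np.ndarray]:
    """Effective biofilm thickness: substrate to the top of the signal column.

    Per (x, y) the thickness is the top face of the highest slice whose
    intensity exceeds the threshold (slice k spans z in (k dz, (k+1) dz]); the
    mean over the field of view is the effective average thickness. Hollow
    buckled regions therefore count their full apex height, which is exactly
    why channel formation raises the effective thickness. Returns
    ``(mean_um, map_um)``; an all-dark stack gives zero with a warning.
    """
    above = zstack.slices > signal_threshold
    if not above.any():
        warnings.warn("no voxel above threshold: thickness is 0 everywhere")
        return 0.0, np.zeros(zstack.slices.shape[1:])
    nz, _, _ = zstack.slices.shape
    # highest z index above threshold per column; -1 where none
    rev_idx = np.argmax(above[::-1], axis=0)
    any_col = above.any(axis=0)
    top = (nz - 1 - rev_idx + 1).astype(float) * zstack.z_step_um
    thickness = np.where(any_col, top, 0.0)
    return float(thickness.mean()), thickness
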