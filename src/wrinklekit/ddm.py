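"""Differential dynamic microscopy (DDM) with a Schulz-swimmer ISF fit.

DDM extracts ensemble dynamics from a high-speed movie without tracking:
for each lag tau the image structure function

    D(q, tau) = < |FFT2( I(t + tau) - I(t) )|^2 >_t,

azimuthally averaged onto radial wavenumber bins q, follows

    D(q, tau) = A(q) [1 - f(q, tau)] + B(q)

with signal amplitude A(q), camera-noise floor B(q) and the intermediate
scattering function f. For a mixed population of fraction ``alpha`` swimmers
(straight runs, speeds Schulz-distributed with mean v and shape Z, isotropic
3-D directions imaged in projection) and fraction ``1 - alpha`` passive
diffusers (diffusivity D_diff), all decorrelating diffusively as well:

    f(q, tau) = exp(-q^2 D_diff tau) * [ (1 - alpha) + alpha * S(q v tau) ]
    S(u) = (Z+1)/(Z u) * sin(Z atan(Lambda)) / (1 + Lambda^2)^(Z/2),
    Lambda = u / (Z + 1),

where S is the Schulz-weighted average of the ballistic sinc kernel. Fitting
per q over a window that avoids low-q drift and the high-q noise floor yields
the mean swim speed and its spread across q.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.fft
from scipy.optimize import curve_fit

from wrinklekit.io import ImageStack

FIT_BOUNDS = {
    "v": (1.0, 100.0),  # um/s
    "Z": (0.5, 10.0),
    "D": (0.0, 5.0),  # um^2/s
    "alpha": (0.0, 1.0),
}


@dataclass
class StructureFunction:
    """D(q, tau) matrix over radial wavenumber bins and lag times.

    ``d`` has shape (n_q, n_lags); ``q_um_inv`` holds bin centers in
    rad/um (2 pi times cycles/um); ``tau_s`` the lag times in seconds.
    """

    d: np.ndarray
    q_um_inv: np.ndarray
    tau_s: np.ndarray
    lags_frames: np.ndarray
    fps: float
    pixel_size_um: float
    n_pairs: np.ndarray = field(default=None)
    plateau: np.ndarray = field(default=None)
    """Lower bound on A(q) + B(q): 2 (<|F|^2> - |<F>|^2), which misses dynamics slower than the movie."""
    total_power: np.ndarray = field(default=None)
    """Upper bound on A(q) + B(q): 2 <|F|^2>, exact at q != 0 when nothing in view is static."""


def default_lags(n_frames: int, n_lags: int = 28) -> np.ndarray:
    """Log-spaced unique integer lags over [1, n_frames // 2].

    The longest lags carry most of the information on the slow (diffusive)
    decay, which at high speed-camera frame rates decays only partially
    within the movie; cutting lags earlier would leave the motile fraction
    and diffusivity poorly identified.
    """
    max_lag = max(n_frames // 2, 1)
    lags = np.unique(np.round(np.geomspace(1, max_lag, n_lags)).astype(int))
    return lags


def difference_power(movie: np.ndarray, lag: int, max_pairs: int = 300) -> np.ndarray:
    """Unbinned 2-D power spectrum of frame differences at one lag.

    Average over start times of |FFT2(I(t+lag) - I(t))|^2 / (H W); with this
    normalization the sum of the returned array over the full plane equals the
    mean real-space sum of squared differences (Parseval).
    """
    movie = np.asarray(movie)
    n = movie.shape[0]
    if lag >= n:
        raise ValueError(f"lag {lag} needs more than {lag} frames, movie has {n}")
    starts = np.linspace(0, n - lag - 1, min(max_pairs, n - lag)).astype(int)
    diffs = movie[starts + lag].astype(np.float64) - movie[starts].astype(np.float64)
    f = scipy.fft.fft2(diffs, workers=1)
    power = (f.real**2 + f.imag**2).mean(axis=0)
    return power / (movie.shape[1] * movie.shape[2])


def _radial_bins(shape: tuple[int, int], pixel_size_um: float, q_bins: int):
    qy = 2 * np.pi * np.fft.fftfreq(shape[0], d=pixel_size_um)
    qx = 2 * np.pi * np.fft.fftfreq(shape[1], d=pixel_size_um)
    qgrid = np.sqrt(qy[:, None] ** 2 + qx[None, :] ** 2)
    q_max = np.pi / pixel_size_um
    edges = np.linspace(0.0, q_max, q_bins + 1)
    idx = np.digitize(qgrid.ravel(), edges) - 1  # bin index, -1/q_bins = out
    valid = (idx >= 0) & (idx < q_bins)
    valid[0] = False  # exclude the zero-frequency pixel
    centers = 0.5 * (edges[:-1] + edges[1:])
    return idx, valid, centers


def image_structure_function(
    movie: ImageStack,
    lags: np.ndarray | None = None,
    q_bins: int = 64,
    max_pairs: int = 300,
) -> StructureFunction:
    """Compute D(q, tau) for an image stack.

    Frame FFTs are computed once and differenced in Fourier space (the FFT is
    linear), so each additional lag costs only the pair averaging. Start
    times are spread evenly over the movie, up to ``max_pairs`` per lag.
    """
    frames = np.asarray(movie.frames)
    n = frames.shape[0]
    if n < 2:
        raise ValueError("DDM needs at least 2 frames")
    if lags is None:
        lags = default_lags(n)
    lags = np.asarray(lags, int)
    if (lags < 1).any() or (lags >= n).any():
        feasible = f"[1, {n - 1}]"
        raise ValueError(f"lags must lie in {feasible}, got {lags[(lags < 1) | (lags >= n)]}")
    fps = movie.fps
    px = movie.pixel_size_um
    if px is None:
        raise ValueError("pixel_size_um is required for DDM")

    fft = scipy.fft.fft2(frames.astype(np.float32), workers=1).astype(np.complex64)
    norm = frames.shape[1] * frames.shape[2]
    idx, valid, centers = _radial_bins(frames.shape[1:], px, q_bins)
    flat_idx = idx[valid]
    bin_counts = np.bincount(flat_idx, minlength=q_bins)

    # D(q, tau->inf) = 2 (<|F|^2> - |<F>|^2); pinning this plateau removes the
    # amplitude/motile-fraction degeneracy when slow (diffusive) modes do not
    # fully decay within the lag range
    mean_f = fft.mean(axis=0)
    mean_power = (
        fft.real.astype(np.float64) ** 2 + fft.imag.astype(np.float64) ** 2
    ).mean(axis=0) / norm
    var_power = mean_power - (
        mean_f.real.astype(np.float64) ** 2 + mean_f.imag.astype(np.float64) ** 2
    ) / norm
    plateau_sums = np.bincount(flat_idx, weights=2.0 * var_power.ravel()[valid], minlength=q_bins)
    power_sums = np.bincount(flat_idx, weights=2.0 * mean_power.ravel()[valid], minlength=q_bins)

    d = np.empty((q_bins, len(lags)))
    n_pairs = np.empty(len(lags), int)
    for j, lag in enumerate(lags):
        starts = np.linspace(0, n - lag - 1, min(max_pairs, n - lag)).astype(int)
        n_pairs[j] = len(starts)
        diff = fft[starts + lag] - fft[starts]
        power = (diff.real.astype(np.float64) ** 2 + diff.imag.astype(np.float64) ** 2).mean(0)
        power /= norm
        sums = np.bincount(flat_idx, weights=power.ravel()[valid], minlength=q_bins)
        with np.errstate(invalid="ignore"):
            d[:, j] = sums / bin_counts
    keep = bin_counts > 0
    with np.errstate(invalid="ignore"):
        plateau = plateau_sums[keep] / bin_counts[keep]
        total_power = power_sums[keep] / bin_counts[keep]
    return StructureFunction(
        d=d[keep],
        q_um_inv=centers[keep],
        tau_s=lags / fps,
        lags_frames=lags,
        fps=fps,
        pixel_size_um=px,
        n_pairs=n_pairs,
        plateau=plateau,
        total_power=total_power,
    )


def schulz_ballistic_kernel(u: np.ndarray, z: float) -> np.ndarray:
    """Schulz-speed-averaged ballistic ISF kernel S(u), u = q v tau.

    Equals the average of sinc(q v' tau) over a Schulz (Gamma) speed
    distribution with mean v and shape Z; S(0) = 1.
    """
    u = np.asarray(u, float)
    lam = u / (z + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (z + 1.0) / (z * u) * np.sin(z * np.arctan(lam)) / (1.0 + lam**2) ** (z / 2.0)
    return np.where(np.abs(u) < 1e-9, 1.0, s)


def swimmer_isf(tau: np.ndarray, q: float, v: float, z: float, d_diff: float, alpha: float) -> np.ndarray:
    """Mixed swimmer/diffuser intermediate scattering function f(q, tau)."""
    tau = np.asarray(tau, float)
    return np.exp(-(q**2) * d_diff * tau) * (
        (1.0 - alpha) + alpha * schulz_ballistic_kernel(q * v * tau, z)
    )


def _fit_single_q(tau: np.ndarray, y: np.ndarray, q: float, plateau: float, total: float) -> dict | None:
    """Fit D(q, tau) = A (1 - f) + B at one q.

    The slow (diffusive) decay may be far from complete within the lag range,
    which makes the large-lag plateau T = A + B, the motile fraction and the
    diffusivity nearly degenerate from the curve alone. T is therefore
    constrained to its physical bracket measured from the frame spectra
    (``plateau`` <= T <= ``total``), the noise floor is anchored near the
    shortest-lag value, and the fit is multi-started over a grid of motile
    fractions.
    """
    y = np.asarray(y, float)
    b0 = max(float(min(y[0], y.min())), 1e-12)
    rng_y = max(float(y.max()) - b0, 1e-12)
    # physical bracket on the large-lag plateau T = A + B
    t_lo = max(plateau if np.isfinite(plateau) else 0.0, b0 + 0.5 * rng_y)
    t_hi = total if np.isfinite(total) and total > 0 else b0 + 4.0 * rng_y
    t_hi = max(t_hi, t_lo * (1.0 + 1e-6))
    b_hi = 1.2 * b0 + 1e-9
    half = b0 + 0.5 * rng_y
    above = np.nonzero(y >= half)[0]
    tau_half = tau[above[0]] if len(above) else tau[len(tau) // 2]
    v0 = float(np.clip(2.0 / (q * max(tau_half, 1e-9)), *FIT_BOUNDS["v"]))
    # level after the ballistic decay (q v tau ~ 6), before much diffusive decay
    i_mid = int(np.searchsorted(tau, 6.0 / (q * v0)))
    i_mid = min(max(i_mid, 1), len(tau) - 2)
    y_mid = float(np.median(y[max(i_mid - 1, 0) : i_mid + 2]))
    amp_fast = max(y_mid - b0, 1e-12)

    def model(t, total_p, b, v, z, dd, alpha):
        a = max(total_p - b, 1e-12)
        return a * (1.0 - swimmer_isf(t, q, v, z, dd, alpha)) + b

    lower = [t_lo, 0.0, FIT_BOUNDS["v"][0], FIT_BOUNDS["Z"][0], FIT_BOUNDS["D"][0], 0.0]
    upper = [t_hi, b_hi, FIT_BOUNDS["v"][1], FIT_BOUNDS["Z"][1], FIT_BOUNDS["D"][1], 1.0]
    best, best_ssr = None, np.inf
    for alpha0 in (0.3, 0.5, 0.7, 0.9):
        t0 = min(max(b0 + amp_fast / alpha0, t_lo), t_hi)
        d0 = 2.0 / (q**2 * tau[-1])
        p0 = np.clip(
            [t0, b0, v0, 2.0, d0, alpha0],
            np.asarray(lower) + 1e-12,
            np.asarray(upper) - 1e-12,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(model, tau, y, p0=p0, bounds=(lower, upper), maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        ssr = float(np.sum((y - model(tau, *popt)) ** 2))
        if ssr < best_ssr:
            best, best_ssr = popt, ssr
    if best is None:
        return None
    return {
        "A": max(best[0] - best[1], 0.0),
        "B": best[1],
        "v_um_s": best[2],
        "Z": best[3],
        "D_um2_s": best[4],
        "alpha": best[5],
        "rms_resid": float(np.sqrt(best_ssr / len(y))),
    }


def fit_swimmer_isf(
    sf: StructureFunction, q_window: tuple[float, float] = (0.5, 2.2)
) -> pd.DataFrame:
    """Independent per-q least-squares fits of the swimmer model over a q window.

    The default window excludes low q (drift/advection-dominated, poorly
    sampled annuli) and high q (noise-floor-dominated). Fits that fail to
    converge are flagged (``ok = False``) and excluded downstream rather than
    aborting the analysis.
    """
    qmin, qmax = q_window
    if qmin >= qmax:
        raise ValueError("q_window must satisfy q_min < q_max")
    sel = (sf.q_um_inv >= qmin) & (sf.q_um_inv <= qmax)
    if not sel.any():
        raise ValueError(
            f"q_window {q_window} contains no computed q bins "
            f"(range {sf.q_um_inv.min():.3g}..{sf.q_um_inv.max():.3g})"
        )
    rows = []
    for q, y, plateau, total in zip(sf.q_um_inv[sel], sf.d[sel], sf.plateau[sel], sf.total_power[sel]):
        fit = _fit_single_q(sf.tau_s, y, q, plateau, total)
        row = {"q_um_inv": q, "ok": fit is not None}
        if fit is not None:
            row.update(fit)
        rows.append(row)
    return pd.DataFrame(rows)


def fit_swimmer_isf_global(
    sf: StructureFunction,
    q_window: tuple[float, float] = (0.5, 2.2),
    per_q: pd.DataFrame | None = None,
) -> dict:
    """Joint fit over the whole q window with shared dynamics parameters.

    The per-q fits determine v well (the ballistic decay dominates the
    signal), but the motile fraction and diffusivity ride on the slow tail of
    D(q, tau), which at a single q is close to degenerate with the unknown
    amplitude when the diffusive decay is incomplete within the lag range.
    Sharing (v, Z, D_diff, alpha) across q while leaving the per-q plateau
    T(q) = A(q) + B(q) and noise floor B(q) free (each inside its physical
    bracket measured from the frame spectra) pools the tail curvature of
    every annulus and resolves the degeneracy. Residuals are relative (each
    point scaled by its value), so annuli with different signal power
    contribute comparably.
    """
    from scipy.optimize import least_squares

    qmin, qmax = q_window
    sel = (sf.q_um_inv >= qmin) & (sf.q_um_inv <= qmax)
    qs = sf.q_um_inv[sel]
    ys = sf.d[sel]
    if len(qs) < 3:
        raise ValueError("insufficient q coverage for a global fit")
    if per_q is None:
        per_q = fit_swimmer_isf(sf, q_window)
    good = per_q[per_q["ok"]]
    v0 = float(good["v_um_s"].median()) if len(good) else 25.0
    z0 = float(good["Z"].median()) if len(good) else 2.0
    tau = sf.tau_s
    nq = len(qs)

    b0 = np.maximum(np.minimum(ys[:, 0], ys.min(axis=1)), 1e-9)
    b_hi = 1.2 * b0 + 1e-9
    t_lo = np.maximum(sf.plateau[sel], b0 + 0.5 * (ys.max(axis=1) - b0))
    t_hi = np.maximum(sf.total_power[sel], t_lo * (1.0 + 1e-6))

    def unpack(p):
        v, z, dd, alpha = p[:4]
        t = p[4 : 4 + nq]
        b = p[4 + nq :]
        return v, z, dd, alpha, t, b

    def resid(p):
        v, z, dd, alpha, t, b = unpack(p)
        out = np.empty_like(ys)
        for i, q in enumerate(qs):
            a = max(t[i] - b[i], 1e-12)
            model = a * (1.0 - swimmer_isf(tau, q, v, z, dd, alpha)) + b[i]
            out[i] = (model - ys[i]) / ys[i]
        return out.ravel()

    lower = np.concatenate(
        [[FIT_BOUNDS["v"][0], FIT_BOUNDS["Z"][0], FIT_BOUNDS["D"][0], 0.0], t_lo, np.zeros(nq)]
    )
    upper = np.concatenate(
        [[FIT_BOUNDS["v"][1], FIT_BOUNDS["Z"][1], FIT_BOUNDS["D"][1], 1.0], t_hi, b_hi]
    )
    best, best_cost = None, np.inf
    for alpha0, d0 in ((0.3, 0.1), (0.5, 0.5), (0.7, 0.3), (0.9, 1.0)):
        p0 = np.clip(
            np.concatenate([[v0, z0, d0, alpha0], 0.5 * (t_lo + t_hi), b0]),
            lower + 1e-12,
            upper - 1e-12,
        )
        try:
            res = least_squares(resid, p0, bounds=(lower, upper), max_nfev=400)
        except ValueError:
            continue
        if res.cost < best_cost:
            best, best_cost = res, res.cost
    if best is None:
        raise RuntimeError("global swimmer-ISF fit did not converge")
    v, z, dd, alpha, t, b = unpack(best.x)
    return {
        "v_um_s": float(v),
        "Z": float(z),
        "D_um2_s": float(dd),
        "alpha": float(alpha),
        "A": np.maximum(t - b, 0.0),
        "B": b,
        "q_um_inv": qs,
        "cost": float(best_cost),
    }


@dataclass
class SpeedEstimate:
    """Mean swim speed over the q window, spread across q, and the per-q table."""

    v_mean_um_s: float
    v_sd_um_s: float
    table: pd.DataFrame
    q_window: tuple[float, float]


def swim_speed(fits: pd.DataFrame, q_window: tuple[float, float] = (0.5, 2.2)) -> SpeedEstimate:
    """Aggregate per-q speeds into a mean +/- sd estimate, dropping flagged fits."""
    good = fits[fits["ok"]]
    if len(good) < 3:
        raise ValueError(f"insufficient q coverage: only {len(good)} valid fits, need >= 3")
    v = good["v_um_s"].to_numpy()
    return SpeedEstimate(
        v_mean_um_s=float(v.mean()),
        v_sd_um_s=float(v.std(ddof=0)),
        table=fits,
        q_window=q_window,
    )
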