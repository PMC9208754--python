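"""Seed-deterministic synthetic data with ground truth for every pipeline stage.

Four generators emulate the raw data the analyses consume, at desk scale:

- :func:`generate_wrinkle_timelapse`: a phase-contrast-like timelapse of a
  nucleating, elongating and merging dark wrinkle network on a bright noisy
  background, with the true per-frame network graph, wrinkle count and
  longest-component length emitted alongside.
- :func:`generate_swimmer_movie`: a high-speed brightfield-like movie of
  point particles, a fraction swimming ballistically with Schulz-distributed
  speeds (isotropic 3-D directions imaged in projection) and the rest
  diffusing, with Poisson + Gaussian camera noise.
- :func:`generate_activity_movie`: a movie with swimmers confined to a known
  active region over a static textured surround, optionally freezing at a
  switch time.
- :func:`generate_contact_angles`: contact angles from a known solid via the
  forward Owens-Wendt relation plus Gaussian noise.

The generators use only forward models; the analysis modules never see their
internals, so generator truth can serve as an independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import line as draw_line
from skimage.morphology import dilation

from wrinklekit.io import ImageStack
from wrinklekit.surface_energy import ProbeLiquid, load_liquids, predict_contact_angle

# ---------------------------------------------------------------------------
# wrinkle-network timelapse
# ---------------------------------------------------------------------------


@dataclass
class WrinkleSimParams:
    """Conditions of the synthetic wrinkling timelapse.

    Defaults emulate the study conditions: one frame every 5 min; a
    nucleation-dominated first stage of 6.5 h, a connection stage of 3.5 h and
    a frozen mature stage; wrinkle ribbons ~21 um wide (3 px at 7 um/px,
    within the 20-30 um band of mature wrinkles); nucleus arc lengths drawn
    from 10-30 um. Elongation of ~2 px per frame and tip corresponds to
    ~170 um/h, which builds a field-spanning network within the connection
    stage.
    """

    shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 7.0
    frame_interval_s: float = 300.0
    stage1_frames: int = 78  # 6.5 h of nucleation + slow growth
    stage2_frames: int = 42  # 3.5 h of fast growth and merging
    stage3_frames: int = 30  # mature, frozen network
    nucleation_rate: float = 0.4  # expected nucleations per frame in stage 1
    ribbon_width_px: int = 3
    initial_diameter_um: tuple[float, float] = (10.0, 30.0)
    stage1_step_px: float = 2.0
    stage2_step_px: float = 2.5
    angle_noise: float = 0.10  # rad per growth step
    background: float = 180.0
    foreground: float = 60.0
    noise_sd: float = 8.0

    @property
    def n_frames(self) -> int:
        return self.stage1_frames + self.stage2_frames + self.stage3_frames


@dataclass
class WrinkleTruth:
    """Ground truth emitted next to the synthetic timelapse.

    ``table`` holds the true per-frame wrinkle count N and longest-component
    total length L (mm, distinct centerline pixels x pixel size). The network
    graph is given by ``polylines`` (one centerline polyline per wrinkle, in
    pixel coordinates, final state), ``n_points_per_frame`` (how many polyline
    vertices existed at each frame) and ``components_per_frame`` (sets of
    wrinkle ids that were connected at each frame), from which the metrics are
    recomputable without any image processing.
    """

    table: pd.DataFrame
    polylines: dict[int, np.ndarray]
    n_points_per_frame: list[dict[int, int]]
    components_per_frame: list[list[frozenset[int]]]
    stage2_start: int
    stage3_start: int
    params: WrinkleSimParams
    masks: np.ndarray | None = None
    """Noiseless rendered foreground masks (T, H, W), for boundary-level checks."""


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[int, int] = {}

    def add(self, x: int) -> None:
        self.parent[x] = x

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        self.parent[self.find(a)] = self.find(b)


class _Wrinkle:
    """A growing centerline polyline with two active tips.

    Each tip keeps an ordered trail of the pixels it drew, so the contact rule
    can exempt exactly the tail a tip is growing out of (and the shared
    nucleus around the origin) while still stopping a tip that curls back onto
    its own strand or runs into its sibling tip's strand.
    """

    __slots__ = ("wid", "origin", "pts", "angs", "tips", "alive", "pix", "trails")

    def __init__(self, wid: int, start: np.ndarray, ang: float):
        self.wid = wid
        self.origin = np.asarray(start, float)
        self.pts: list[np.ndarray] = [np.asarray(start, float)]
        self.angs = [ang, ang + math.pi]
        self.tips = [np.asarray(start, float), np.asarray(start, float)]
        self.alive = [True, True]
        self.pix: set[tuple[int, int]] = set()
        self.trails: tuple[list, list] = ([], [])

    def raster_add(
        self, a: np.ndarray, b: np.ndarray, owner: dict, sim_pix: set, tip_index: int
    ) -> None:
        ai = np.round(a).astype(int)
        bi = np.round(b).astype(int)
        rr, cc = draw_line(ai[0], ai[1], bi[0], bi[1])
        for r, c in zip(rr.tolist(), cc.tolist()):
            self.pix.add((r, c))
            owner.setdefault((r, c), self.wid)
            sim_pix.add((r, c))
            self.trails[tip_index].append((r, c))


def generate_wrinkle_timelapse(
    params: WrinkleSimParams | None = None, seed: int = 0
) -> tuple[ImageStack, WrinkleTruth]:
    """Simulate a wrinkling timelapse and render it with known ground truth.

    Wrinkles nucleate at random positions during stage 1 (never closer than a
    clearance distance to existing wrinkles), elongate from both tips as
    persistent random walks, and merge when a growing tip reaches another
    wrinkle: the tip is snapped onto the nearest pixel of the other wrinkle,
    which makes centerline connectivity unambiguous and identical to the
    rendered-mask connectivity. Tips approaching their own component stop
    instead of fusing, so ribbons never run alongside each other closer than
    the ribbon width. Stage 2 grows faster without nucleation; stage 3 is
    frozen. Frames render the centerlines dilated to the ribbon width as dark
    ridges on a bright background with Gaussian noise.
    """
    p = params or WrinkleSimParams()
    if p.ribbon_width_px < 3:
        raise ValueError(
            f"ribbon_width_px must be >= 3 for skeleton fidelity, got {p.ribbon_width_px}"
        )
    rng = np.random.default_rng(seed)
    radius = p.ribbon_width_px // 2
    contact = p.ribbon_width_px + 1  # min centre-line Chebyshev clearance before merge/stop
    margin = contact + radius + 1
    shape = np.array(p.shape)

    uf = _UnionFind()
    owner: dict[tuple[int, int], int] = {}
    sim_pix: set[tuple[int, int]] = set()
    wrinkles: list[_Wrinkle] = []

    def scan_near(pos: np.ndarray, wid: int | None, radius_px: float):
        """Nearest pixel within radius_px not owned by ``wid``'s own tail; returns (pixel, foreign)."""
        r0, c0 = np.round(pos).astype(int)
        rad = int(math.ceil(radius_px))
        best, bd, bforeign = None, radius_px + 1e-9, False
        for r in range(r0 - rad, r0 + rad + 1):
            for c in range(c0 - rad, c0 + rad + 1):
                o = owner.get((r, c))
                if o is None:
                    continue
                d = max(abs(r - pos[0]), abs(c - pos[1]))
                if d < bd:
                    bd, best, bforeign = d, (r, c), (wid is None or uf.find(o) != uf.find(wid))
        return best, bforeign

    def grow(w: _Wrinkle, step: float) -> None:
        for ti in range(2):
            if not w.alive[ti]:
                continue
            w.angs[ti] += rng.normal(0.0, p.angle_noise)
            new = w.tips[ti] + step * np.array([math.cos(w.angs[ti]), math.sin(w.angs[ti])])
            if (new < margin).any() or (new > shape - 1 - margin).any():
                w.alive[ti] = False
                continue
            # exempt only this tip's own recent trail and the shared nucleus
            # around the origin; any other pixel within reach stops the tip
            # (foreign component: snap-merge; own component: stop)
            tip = w.tips[ti]
            tail = set(w.trails[ti][-(4 * contact) :])
            r0, c0 = np.round(new).astype(int)
            rad = contact
            best, bd, bforeign = None, contact + 1e-9, False
            for r in range(r0 - rad, r0 + rad + 1):
                for c in range(c0 - rad, c0 + rad + 1):
                    o = owner.get((r, c))
                    if o is None:
                        continue
                    if o == w.wid and (
                        (r, c) in tail
                        or max(abs(r - w.origin[0]), abs(c - w.origin[1])) <= contact + 1
                    ):
                        continue
                    d = max(abs(r - new[0]), abs(c - new[1]))
                    if d < bd:
                        bd, best, bforeign = d, (r, c), uf.find(o) != uf.find(w.wid)
            if best is not None:
                if bforeign:
                    w.raster_add(tip, np.asarray(best, float), owner, sim_pix, ti)
                    w.pts.append(np.asarray(best, float))
                    uf.union(w.wid, owner[best])
                w.alive[ti] = False
                continue
            w.raster_add(tip, new, owner, sim_pix, ti)
            w.pts.append(new.copy())
            w.tips[ti] = new

    def nucleate(wid: int) -> bool:
        clearance = contact + 3
        for _ in range(80):
            pos = rng.uniform(margin + clearance, shape - 1 - margin - clearance, size=2)
            near, _ = scan_near(pos, None, clearance)
            if near is None:
                uf.add(wid)
                w = _Wrinkle(wid, pos, rng.uniform(0, 2 * math.pi))
                w.raster_add(pos, pos, owner, sim_pix, 0)
                wrinkles.append(w)
                # nucleus: short arc, total length drawn from the initial-diameter range
                arc_px = rng.uniform(*p.initial_diameter_um) / p.pixel_size_um
                for _ in range(max(1, round(arc_px / 2.0))):
                    grow(w, 1.0)
                return True
        return False

    frames = np.empty((p.n_frames, *p.shape), np.uint8)
    masks = np.empty((p.n_frames, *p.shape), bool)
    records = []
    n_points_per_frame: list[dict[int, int]] = []
    components_per_frame: list[list[frozenset[int]]] = []
    # square footprint: the cleaning stage's 3x3 opening is an identity on
    # masks rendered by dilation with the same (or a larger square) element
    footprint = np.ones((2 * radius + 1, 2 * radius + 1), bool)
    next_id = 0
    for f in range(p.n_frames):
        if f < p.stage1_frames:
            if rng.random() < p.nucleation_rate:
                if nucleate(next_id):
                    next_id += 1
            for w in wrinkles:
                grow(w, p.stage1_step_px)
        elif f < p.stage1_frames + p.stage2_frames:
            for w in wrinkles:
                grow(w, p.stage2_step_px)
        # truth bookkeeping
        groups: dict[int, set] = {}
        members: dict[int, set[int]] = {}
        for w in wrinkles:
            root = uf.find(w.wid)
            groups.setdefault(root, set()).update(w.pix)
            members.setdefault(root, set()).add(w.wid)
        n_true = len(groups)
        l_true_px = max((len(s) for s in groups.values()), default=0)
        records.append(
            (f, f * p.frame_interval_s, n_true, l_true_px * p.pixel_size_um * 1e-3)
        )
        n_points_per_frame.append({w.wid: len(w.pts) for w in wrinkles})
        components_per_frame.append([frozenset(m) for m in members.values()])
        # render
        centerline = np.zeros(p.shape, bool)
        if sim_pix:
            idx = np.array(list(sim_pix))
            centerline[idx[:, 0], idx[:, 1]] = True
        mask = dilation(centerline, footprint)
        masks[f] = mask
        img = np.full(p.shape, p.background, np.float64)
        img[mask] = p.foreground
        img += rng.normal(0.0, p.noise_sd, p.shape)
        frames[f] = np.clip(img, 0, 255).astype(np.uint8)

    stack = ImageStack(frames, pixel_size_um=p.pixel_size_um, frame_interval_s=p.frame_interval_s)
    truth = WrinkleTruth(
        table=pd.DataFrame(records, columns=["frame", "time_s", "N", "L_mm"]),
        polylines={w.wid: np.array(w.pts) for w in wrinkles},
        n_points_per_frame=n_points_per_frame,
        components_per_frame=components_per_frame,
        stage2_start=p.stage1_frames,
        stage3_start=p.stage1_frames + p.stage2_frames,
        params=p,
        masks=masks,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# stage-segmentation curves
# ---------------------------------------------------------------------------


def generate_stage_curves(
    stage1_h: float = 6.5,
    stage2_h: float = 3.5,
    stage3_h: float = 2.5,
    frame_interval_min: float = 5.0,
    n_peak: int = 45,
    n_final: int = 5,
    l_final_mm: float = 2.0,
    noise: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, tuple[int, int]]:
    """Synthetic N(t)/L(t) curves with known stage boundaries.

    N rises linearly through stage 1 to ``n_peak``, then decays to ``n_final``
    as wrinkles connect; L stays small through stage 1, rises with a convex
    (accelerating) profile through stage 2 and plateaus at ``l_final_mm``.
    Returns the metrics table and the true (stage2_start, stage3_start) frame
    indices.
    """
    rng = np.random.default_rng(seed)
    dt = frame_interval_min * 60.0
    f1 = round(stage1_h * 3600 / dt)
    f2 = round(stage2_h * 3600 / dt)
    f3 = round(stage3_h * 3600 / dt)
    n_frames = f1 + f2 + f3
    t = np.arange(n_frames) * dt
    n = np.empty(n_frames)
    n[:f1] = np.linspace(1, n_peak, f1)
    n[f1 : f1 + f2] = np.linspace(n_peak, n_final, f2 + 1)[1:]
    n[f1 + f2 :] = n_final
    n = np.clip(np.round(n + rng.normal(0, noise, n_frames)), 0, None)
    n[0] = max(n[0], 1)
    n[f1] = n_peak + 3 * noise  # the true peak stays the maximum under noise

    l_start = 0.05 * l_final_mm
    length = np.empty(n_frames)
    length[:f1] = np.linspace(0.2 * l_start, l_start, f1)
    x = np.linspace(0, 1, f2 + 1)[1:]
    length[f1 : f1 + f2] = l_start + (l_final_mm - l_start) * x**2
    length[f1 + f2 :] = l_final_mm
    length *= 1.0 + rng.normal(0, 0.003, n_frames)

    table = pd.DataFrame(
        {"frame": np.arange(n_frames), "time_s": t, "N": n.astype(int), "L_mm": length}
    )
    return table, (f1, f1 + f2)


# ---------------------------------------------------------------------------
# swimmer movies
# ---------------------------------------------------------------------------


@dataclass
class SwimmerTruth:
    """Ground-truth dynamics of a synthetic swimmer movie.

    ``alpha`` of the particles swim ballistically with Schulz(mean v, shape Z)
    speeds along fixed, isotropically distributed 3-D directions (the movie
    shows the in-plane projection, giving the sinc-type ISF kernel); the rest
    diffuse with ``d_diff``. ``active_mask`` confines the particles; any
    external flow advects only the static surround OUTSIDE the mask, matching
    closed channels that bulk flow cannot penetrate.
    """

    v_mean_um_s: float = 25.0
    schulz_z: float = 2.0
    d_diff_um2_s: float = 0.4
    alpha: float = 0.7
    n_particles: int = 400
    active_mask: np.ndarray | None = None
    external_flow_um_s: float = 0.0
    speeds_um_s: np.ndarray | None = field(default=None, repr=False)


def schulz_speeds(rng: np.random.Generator, n: int, v_mean: float, z: float) -> np.ndarray:
    """Draw speeds from a Schulz distribution: Gamma with shape Z+1 and mean v_mean."""
    return rng.gamma(shape=z + 1.0, scale=v_mean / (z + 1.0), size=n)


def _smooth_texture(rng: np.random.Generator, shape, scale_px: float, contrast: float) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    tex = gaussian_filter(rng.normal(0, 1, shape), scale_px)
    tex /= max(tex.std(), 1e-12)
    return contrast * tex


def generate_swimmer_movie(
    truth: SwimmerTruth | None = None,
    fps: float = 2000.0,
    pixel_size_um: float = 0.33,
    frames: int = 2000,
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    spot_sigma_px: float = 1.2,
    spot_amplitude: float = 60.0,
    background: float = 100.0,
    noise_sd: float = 2.0,
    poisson_noise: bool = True,
) -> tuple[ImageStack, SwimmerTruth]:
    """Render a high-speed movie of mixed ballistic swimmers and diffusers.

    Particles are Gaussian spots (dark on a bright background); frames carry
    Poisson shot noise plus Gaussian read noise. Without a mask the domain is
    fully periodic. With ``active_mask`` set, particles are confined to the
    mask (moves that would leave it are rejected, swimmers redrawing their
    direction), and a static smooth texture fills the surround, advected at
    ``external_flow_um_s`` along x.
    """
    truth = truth or SwimmerTruth()
    rng = np.random.default_rng(seed)
    h, w = shape
    dt = 1.0 / fps
    if truth.v_mean_um_s * dt / pixel_size_um > min(h, w):
        raise ValueError("undersampled dynamics: particles cross the field within one frame")

    n_swim = round(truth.alpha * truth.n_particles)
    n_diff = truth.n_particles - n_swim
    speeds = schulz_speeds(rng, n_swim, truth.v_mean_um_s, truth.schulz_z)
    # isotropic 3-D directions, projected onto the image plane
    u = rng.normal(size=(n_swim, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    vel_px = speeds[:, None] * u[:, :2] * dt / pixel_size_um
    diff_sd_px = math.sqrt(2.0 * truth.d_diff_um2_s * dt) / pixel_size_um

    mask = truth.active_mask
    if mask is not None:
        mask = np.asarray(mask, bool)
        if mask.shape != shape:
            raise ValueError("active_mask shape must match the frame shape")
        inside = np.argwhere(mask)
        pos = inside[rng.integers(0, len(inside), truth.n_particles)].astype(float)
        pos += rng.uniform(-0.5, 0.5, pos.shape)
        surround = background + _smooth_texture(rng, shape, 2.0, 25.0)
        flow_px_per_frame = truth.external_flow_um_s * dt / pixel_size_um
    else:
        pos = rng.uniform(0, (h, w), size=(truth.n_particles, 2))
        surround = None
        flow_px_per_frame = 0.0

    # precompute the spot stamp offsets
    rad = max(2, int(math.ceil(3 * spot_sigma_px)))
    offs = np.arange(-rad, rad + 1)
    dr, dc = np.meshgrid(offs, offs, indexing="ij")

    def in_mask(q: np.ndarray) -> np.ndarray:
        r = np.clip(np.round(q[:, 0]).astype(int), 0, h - 1)
        c = np.clip(np.round(q[:, 1]).astype(int), 0, w - 1)
        return mask[r, c]

    out = np.empty((frames, h, w), np.uint16)
    for f in range(frames):
        base = np.round(pos).astype(int)
        frac = pos - base
        amp = np.exp(
            -((dr[None] - frac[:, 0, None, None]) ** 2 + (dc[None] - frac[:, 1, None, None]) ** 2)
            / (2.0 * spot_sigma_px**2)
        ) * spot_amplitude
        rr = base[:, 0, None, None] + dr[None]
        cc = base[:, 1, None, None] + dc[None]
        if mask is None:
            rr, cc = rr % h, cc % w
            ok_px = np.ones(rr.shape, bool)
        else:
            # the masked domain is not periodic: clip stamps at the frame edge
            ok_px = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            rr, cc = np.clip(rr, 0, h - 1), np.clip(cc, 0, w - 1)
        spot_img = np.bincount(
            (rr * w + cc).ravel()[ok_px.ravel()],
            weights=amp.ravel()[ok_px.ravel()],
            minlength=h * w,
        ).reshape(h, w)
        if surround is None:
            img = background - spot_img
        else:
            shift = int(round(flow_px_per_frame * f))
            img = np.where(mask, background, np.roll(surround, shift, axis=1)) - spot_img
        if poisson_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
        img += rng.normal(0, noise_sd, shape)
        out[f] = np.clip(img, 0, 65535).astype(np.uint16)

        # advance dynamics; swimmers superimpose the same thermal diffusion on
        # their ballistic runs, matching the fitted ISF model
        step = rng.normal(0, diff_sd_px, pos.shape)
        step[:n_swim] += vel_px
        if mask is None:
            pos = (pos + step) % (h, w)
        else:
            new = pos + step
            ok = in_mask(new)
            pos[ok] = new[ok]
            # swimmers bouncing off the wall pick a fresh direction
            bad_swim = np.nonzero(~ok[:n_swim])[0]
            if len(bad_swim):
                u2 = rng.normal(size=(len(bad_swim), 3))
                u2 /= np.linalg.norm(u2, axis=1, keepdims=True)
                vel_px[bad_swim] = speeds[bad_swim, None] * u2[:, :2] * dt / pixel_size_um

    stack = ImageStack(out, pixel_size_um=pixel_size_um, frame_interval_s=dt)
    truth_out = SwimmerTruth(
        v_mean_um_s=truth.v_mean_um_s,
        schulz_z=truth.schulz_z,
        d_diff_um2_s=truth.d_diff_um2_s,
        alpha=truth.alpha,
        n_particles=truth.n_particles,
        active_mask=mask,
        external_flow_um_s=truth.external_flow_um_s,
        speeds_um_s=speeds,
    )
    return stack, truth_out


# ---------------------------------------------------------------------------
# activity movies
# ---------------------------------------------------------------------------


def generate_activity_movie(
    shape: tuple[int, int] = (128, 128),
    frames: int = 240,
    fps: float = 25.0,
    pixel_size_um: float = 0.33,
    active_mask: np.ndarray | None = None,
    n_swimmers: int = 150,
    v_mean_um_s: float = 25.0,
    schulz_z: float = 2.0,
    switch_frame: int | None = None,
    texture_contrast: float = 30.0,
    noise_sd: float = 3.0,
    spot_sigma_px: float = 1.2,
    spot_amplitude: float = 50.0,
    background: float = 120.0,
    seed: int = 0,
) -> tuple[ImageStack, np.ndarray, int | None]:
    """Movie with swimmers confined to a known region over a static surround.

    The surround carries a static smooth texture of the given contrast (the
    texture-to-noise ratio sets the SNR); the active region holds swimmers on
    a plain background. From ``switch_frame`` on, the swimmers freeze in
    place, turning the formerly active region static. Returns the stack, the
    active mask and the switch frame.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    if active_mask is None:
        active_mask = np.zeros(shape, bool)
        active_mask[:, : w // 2] = True
    active_mask = np.asarray(active_mask, bool)
    dt = 1.0 / fps

    inside = np.argwhere(active_mask)
    pos = inside[rng.integers(0, len(inside), n_swimmers)].astype(float)
    pos += rng.uniform(-0.5, 0.5, pos.shape)
    speeds = schulz_speeds(rng, n_swimmers, v_mean_um_s, schulz_z)
    u = rng.normal(size=(n_swimmers, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    vel_px = speeds[:, None] * u[:, :2] * dt / pixel_size_um

    surround = background + _smooth_texture(rng, shape, 2.0, texture_contrast)
    rad = max(2, int(math.ceil(3 * spot_sigma_px)))
    offs = np.arange(-rad, rad + 1)
    dr, dc = np.meshgrid(offs, offs, indexing="ij")

    out = np.empty((frames, h, w), np.uint16)
    for f in range(frames):
        base = np.round(pos).astype(int)
        frac = pos - base
        amp = np.exp(
            -((dr[None] - frac[:, 0, None, None]) ** 2 + (dc[None] - frac[:, 1, None, None]) ** 2)
            / (2.0 * spot_sigma_px**2)
        ) * spot_amplitude
        rr = base[:, 0, None, None] + dr[None]
        cc = base[:, 1, None, None] + dc[None]
        ok_px = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        rr, cc = np.clip(rr, 0, h - 1), np.clip(cc, 0, w - 1)
        spots = np.bincount(
            (rr * w + cc).ravel()[ok_px.ravel()],
            weights=amp.ravel()[ok_px.ravel()],
            minlength=h * w,
        ).reshape(h, w)
        img = np.where(active_mask, background, surround) - spots
        img += rng.normal(0, noise_sd, shape)
        out[f] = np.clip(img, 0, 65535).astype(np.uint16)

        if switch_frame is None or f < switch_frame:
            new = pos + vel_px
            r = np.clip(np.round(new[:, 0]).astype(int), 0, h - 1)
            c = np.clip(np.round(new[:, 1]).astype(int), 0, w - 1)
            ok = active_mask[r, c]
            pos[ok] = new[ok]
            bad = np.nonzero(~ok)[0]
            if len(bad):
                u2 = rng.normal(size=(len(bad), 3))
                u2 /= np.linalg.norm(u2, axis=1, keepdims=True)
                vel_px[bad] = speeds[bad, None] * u2[:, :2] * dt / pixel_size_um

    stack = ImageStack(out, pixel_size_um=pixel_size_um, frame_interval_s=dt)
    return stack, active_mask, switch_frame


# ---------------------------------------------------------------------------
# contact angles
# ---------------------------------------------------------------------------


def generate_contact_angles(
    gamma_s_d: float,
    gamma_s_p: float,
    liquids: dict[str, ProbeLiquid] | None = None,
    noise_deg: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Contact angles of the probe liquids on a known solid, plus Gaussian noise.

    Saturated liquids (complete wetting or dewetting implied by the forward
    relation) are flagged in the ``saturated`` column. Noisy angles are
    clipped to the physical [0, 180] degree range.
    """
    liquids = liquids or load_liquids()
    rng = np.random.default_rng(seed)
    rows = []
    for name, liq in liquids.items():
        theta, flag = predict_contact_angle(gamma_s_d, gamma_s_p, liq)
        noisy = float(np.clip(theta + rng.normal(0, noise_deg), 0.0, 180.0)) if noise_deg else theta
        rows.append({"liquid": name, "theta_deg": noisy, "saturated": flag})
    return pd.DataFrame(rows)
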