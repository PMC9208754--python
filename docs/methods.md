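# Methods

This note records the models implemented in `wrinklekit`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the known limitations. It states no empirical number that the
test suite or the analysis scripts do not themselves compute.

## Buckling-delamination mechanics

The biofilm is modelled as an isotropic elastic film (Young's modulus E_f,
Poisson ratio nu_f, thickness h) bonded to a rigid substrate and loaded by
uniform equi-biaxial compression sigma, the stress generated by confined
growth. Over a circular delaminated blister of radius R the film buckles at

    sigma_c = 1.2235 E_f / (1 - nu_f^2) (h/R)^2.

Below sigma_c the interface crack has zero energy release rate; the
implementation returns a flagged "unbuckled" state rather than raising, so
stress sweeps over a growth history are convenient. Above it, the crack
driving force normalized by the stored elastic energy
G0 = (1 - nu_f) h sigma^2 / E_f is

    G/G0 = c2 [1 - (sigma_c/sigma)^2],   c2 = 1 / (1 + 0.9021 (1 - nu_f)),

monotone in sigma and bounded by c2. Delamination advances only while
G exceeds the interface toughness Gamma; ties arrest (the crack needs a
strictly positive net driving force). Gamma is proportional to the
film-substrate adhesive strength and is exposed as a free parameter — no
number for it is available, and its dependence on mode mix is deliberately
not modelled (the deformation mode stays essentially constant during
delamination). Conventionally the literature magnitude of the biofilm shear
modulus (~1 kPa for P. aeruginosa) is inserted directly as E_f; the model
exposes E_f as a plain parameter and follows that convention rather than
applying a 2(1+nu) conversion, which would only rescale sigma_c by an O(1)
factor.

Channel hydrodynamics use the laminar infinite-parallel-plate profile:
U = Q/(w h_ch), tau_wall = 6 mu U / h_ch. For the 5:1 aspect growth channel
(500 x 100 um) the parallel-plate approximation overestimates the exact
rectangular-duct wall shear by a few percent, which is immaterial here; the
duct series solution is out of scope. All mechanics are SI internally; the
CLI converts um, ml/h and mPa s at the boundary.

## Wrinkle-network quantification

Pipeline per timelapse: (1) Otsu threshold computed once on a reference
frame — the last frame by convention, where the network is fully developed —
and applied to every frame, so N(t)/L(t) trends are not confounded by
per-frame threshold drift; (2) removal of foreground objects smaller than
5 px, then binary opening with a 3x3 square element; (3) thinning to a
one-pixel-wide, topology-preserving skeleton; (4) 8-connected component
labeling. N is the component count; L is the total skeleton length of the
largest component (pixel count x pixel size, reported in mm), which is what
a labeling-based extraction of "the longest connected path" yields for a
branched network. A true geodesic-diameter variant (double Dijkstra sweep on
the skeleton graph, diagonal steps sqrt(2)) is available behind a flag for
comparison; on branched networks it is systematically smaller than the
total-length convention.

Numerical choices that matter:

- **Otsu tie-break.** For a well-separated bimodal histogram the
  between-class variance is exactly constant across the empty gap between
  the modes. Returning the first maximizer (as common library routines do)
  leaves the threshold hugging the minority mode's noise tail, where single
  noise excursions punch holes into ribbons that the subsequent opening
  turns into spurious component splits. The implementation therefore
  returns the midpoint of the contiguous plateau of maximizers, centring
  the threshold in the gap. The test suite checks the routine against an
  exhaustive brute-force oracle with the same tie rule (agreement to one
  histogram bin, the tie-degeneracy scale).
- **Thinning, not medial axis.** `skimage.morphology.thin` preserves the arc
  length of ribbon-like objects with end/junction artifacts of ~1-2 px,
  severalfold smaller than either the Zhang-Suen skeleton (end retraction
  about half the ribbon width) or the medial-axis transform (boundary
  spurs). This matters because L is validated to 5% against ground truth.
- 8-connectivity throughout; 3x3 square structuring element for the opening
  (the operation's element is a declared choice); dark-foreground polarity
  with a flag for inverted contrast; missing pixel size degrades to pixel
  units with a warning.

Stage segmentation of the N(t)/L(t) curves: stage 1 runs from the first
nonzero N to the argmax of the moving-average-smoothed N (window 5 frames,
centered; no smoothing rule is canonical, this is a declared default);
stage 2 ends at the first frame from which L stays within 5% of its final
value for 5 consecutive frames and through the end of the series; stage 3 is
the remainder. A series whose L still rises steeply at the end yields an
empty, flagged stage 3. Segmentation is validated on constructed curves with
the study timings (6.5 h nucleation, 3.5 h connection at 5-min frames) to
within +-2 frames.

Effective thickness from confocal z-stacks: per (x, y) column the top face of
the highest slice above an intensity threshold (slice k spans
(k dz, (k+1) dz]); the field-of-view mean is the effective average
thickness. Hollow buckled ridges contribute their full apex height, which is
exactly why channel formation raises the effective thickness of a biofilm at
constant biomass. Phantom stacks reproduce area-weighted analytic means to
within one z-step.

## Differential dynamic microscopy

The image structure function is computed from frame FFTs (calculated once,
differenced in Fourier space by linearity): for each lag, the mean over up
to 300 evenly spread start times of |FFT2(I(t+tau) - I(t))|^2 / (H W),
azimuthally averaged onto 64 linear radial bins of q = 2 pi x spatial
frequency (zero-frequency pixel excluded). With this normalization the
unbinned power obeys Parseval's identity against the real-space sum of
squared differences, which the tests assert. Lags default to 28 log-spaced
values over [1, frames/2]: at high-speed-camera frame rates the diffusive
part of the signal decays only partially within the movie, and the longest
lags carry most of the information about it — restricting lags to frames/4
left the motile fraction and diffusivity unidentifiable in seed
experiments.

The fitted model is D(q, tau) = A(q)[1 - f(q, tau)] + B(q) with the mixed
swimmer/diffuser ISF

    f = exp(-q^2 D tau) [ (1 - alpha) + alpha S(q v tau) ],
    S(u) = (Z+1)/(Z u) sin(Z atan(u/(Z+1))) / (1 + (u/(Z+1))^2)^(Z/2),

where S is the Schulz-average of the ballistic sinc kernel (isotropic 3-D
run directions imaged in projection; speeds Gamma-distributed with shape
Z+1 and mean v, so sd = v/sqrt(Z+1)). All particles share the thermal
diffusivity D; swimmers superimpose it on their runs.

Identifiability is the central numerical issue: when the diffusive decay is
incomplete within the lag range, the large-lag plateau T(q) = A + B, the
motile fraction and the diffusivity are nearly degenerate along a ridge of
the per-q likelihood. Two measured brackets resolve this: the frame-spectrum
variance 2(<|F|^2> - |<F>|^2) is a lower bound on T (it misses dynamics
slower than the movie), and the raw frame power 2<|F|^2> is an upper bound
(exact at q != 0 when nothing in view is static). The per-q fits constrain
T to this bracket, anchor B near the shortest-lag value, and multi-start
over a grid of motile fractions. On top of the per-q fits (which determine
v well — the ballistic decay dominates the signal), a global refinement
shares (v, Z, D, alpha) across the q window while leaving T(q), B(q) free
inside their brackets, pooling the tail curvature of every annulus; motile
fraction and diffusivity are reported from this pooled fit. The q window
defaults to 0.5-2.2 1/um (low q drift-dominated, high q noise-dominated),
fit bounds v in [1, 100] um/s, Z in [0.5, 10], D in [0, 5] um^2/s,
alpha in [0, 1]. Fits that fail to converge at a q are flagged and excluded,
not fatal; the speed estimate is the mean +- sd of v(q) over the remaining
window and requires at least three valid q points.

## Activity maps

The ROI degree of correlation between frames tau apart is
c_I = <I_p(t) I_p(t+tau)>_r / (<I_p(t)>_r <I_p(t+tau)>_r) - 1, averaged over
(by default) 200 frame pairs with start frames stepping by one. At tau -> 0
this is the squared coefficient of variation of the ROI texture, so the raw
map is dominated by static contrast. The normalization — the quotient of the
pair-averaged map at the analysis lag (default 1 s) by the same at a
one-frame lag, clamped to [0, 1] — removes that contrast: static ROIs map to
~1, decorrelated (active) ROIs toward 0, and classification thresholds at
0.5. The normalization convention is a declared choice. ROIs are 2.5 um
squares rounded to an even pixel count; frames are cropped to an integer
grid. ROIs whose reference correlation falls below 2e-4 carry no contrast
beyond camera noise (their quotient is meaningless) and are flagged NaN
rather than classified; region-level statements therefore use means over
unflagged ROIs.

## Owens-Wendt surface energy

gamma_L (1 + cos theta) = 2 sqrt(gamma_S_d gamma_L_d) + 2 sqrt(gamma_S_p gamma_L_p),
linearized to y = sqrt(gamma_S_d) + sqrt(gamma_S_p) x with
y = gamma_L(1+cos theta)/(2 sqrt(gamma_L_d)), x = sqrt(gamma_L_p/gamma_L_d),
solved by least squares over the probe liquids. At least one polar liquid is
required (otherwise the polar component is unidentifiable and the fit
refuses); a purely dispersive liquid set can be fitted intercept-only behind
a flag. Negative fitted square roots, which arise from noise when a
component of the solid is near zero, clamp to zero with a warning. The
probe-liquid component splits are data, not code: the bundled table carries
literature-typical values (water 21.8 dispersive + 51.0 polar; hexadecane
fully dispersive 26.35; nitromethane 22.0 + 14.8 mN/m) and any CSV with the
same columns substitutes. The forward relation doubles as the test oracle:
round trips are exact to numerical precision, and +-1 degree angle noise
propagates to under ~2 mN/m per component across 100 draws.

## Synthetic data: what it emulates, and what it does not

All generators are seed-deterministic (`numpy.random.default_rng(seed)`) and
emit machine-readable ground truth beside the pixel data. They implement
forward models only; the analysis modules never import generator internals.

**Wrinkle timelapse.** Dark curvilinear ribbons on a bright noisy background
(defaults: 256x256 px at 7 um/px, one frame per 5 min; background 180,
ridges 60, Gaussian noise sd 8). Wrinkles nucleate during a 6.5-h first
stage (Bernoulli rate 0.4/frame) with nucleus arc lengths drawn from
10-30 um, elongate from both tips as persistent random walks (2.0 px/frame
per tip in stage 1, 2.5 in the 3.5-h second stage, direction noise 0.1 rad
per step), and freeze in a 2.5-h third stage. A growing tip that comes
within a Chebyshev clearance of another wrinkle snaps onto its nearest
pixel and merges (union-find bookkeeping), so centerline connectivity is
unambiguous and identical to rendered-mask connectivity; a tip meeting its
own component stops instead. Ribbons are rendered by dilating centerlines
with the same 3x3 square element the cleaning stage opens with, making the
opening an identity on noiseless geometry. Truth N is the component count;
truth L is the distinct-centerline-pixel count of the largest component.
Choices a user should know:

- Ribbon width is fixed at 3 px (21 um, inside the 20-30 um band of mature
  wrinkles); the stated 10-30 um initial wrinkle size is read as the arc
  length of the nucleus. Widths below 3 px are rejected — skeleton fidelity
  is not guaranteed there.
- Exact N preservation through threshold-binarize-clean-thin requires the
  threshold to clear both intensity modes by several noise standard
  deviations; the plateau-midpoint Otsu gives ~7 sigma margins at the
  default contrast. At much lower SNR single-pixel noise flips can split
  ribbons at the opening stage.
- With the default nucleation and elongation rates, merging sets in while
  nucleation is still running, so the observable N(t) peak precedes the
  nucleation cut-off; the three-stage segmentation is therefore validated
  on constructed N/L curves carrying the study timings, and on the
  timelapse by consistency between segmenting measured and truth curves.

Not emulated: wrinkle widening over time, curvature statistics, background
drift or illumination gradients, out-of-focus blur, and real phase-contrast
halos. Passing the fidelity tests shows the measurement chain is exact on
clean ribbon geometry, not that it is robust to every real-microscopy
artifact.

**Swimmer movies.** Gaussian spots (sigma 1.2 px, amplitude 60 below a
background of 100) at 0.33 um/px, 256x256 px, 2000 frames at 2000 fps;
Poisson shot noise plus Gaussian read noise (sd 2). A fraction alpha of the
particles (default 400 total) swim ballistically along fixed directions
drawn uniformly on the 3-D sphere and projected, with Schulz speeds; all
particles diffuse with D. Without a mask the domain is periodic. With an
active-region mask, particles are confined (rejected moves redraw the
swimmer's direction), spot stamps clip at the frame edge, and a static
smooth texture fills the surround, advected along x at the external-flow
speed — emulating closed channels that bulk flow cannot penetrate. Not
emulated: run-and-tumble reorientation, hydrodynamic interactions,
cell-shape anisotropy, out-of-plane motion loss.

**Activity movies.** Swimmers confined to a known mask over a static
textured surround (texture contrast 30, noise sd 3, i.e. texture SNR 10;
25 fps, 128x128 px); from an optional switch frame the swimmers freeze in
place, emulating loss of motility without structural change.

**Contact angles.** Forward Owens-Wendt angles of the bundled liquid table
on a specified solid, plus Gaussian noise; wetting/dewetting saturation is
flagged per liquid.

## Problem sizes

The validation suite runs the wrinkle pipeline on five 150-frame 256x256
timelapses, DDM on five 2000-frame 256x256 movies (plus two 160x160-interior
movies for the flow-independence property), activity maps on a 480-frame
128x128 movie, and 100-draw noise ensembles for the surface-energy fits —
sizes chosen so the whole suite completes in a few minutes on one CPU while
keeping every estimator in its well-sampled regime.

## Known limitations

- The mechanics module is a closed-form criterion set, not a spatiotemporal
  simulation: no blister growth dynamics, wrinkle coarsening, or
  stress-relaxation history.
- The interface toughness Gamma has no published value here; verdicts are
  conditional on a user-supplied Gamma.
- DDM assumes isotropic dynamics (azimuthal averaging) and the specific
  swimmer/diffuser ISF class; anisotropic flows inside the field of view
  violate it. The motile fraction is an amplitude fraction: it matches the
  number fraction only for identical particles.
- The activity-map normalization is single-lag; it flags but does not
  rescue ROIs without static or dynamic contrast.
- Real-data results that depend on the original raw microscopy (absolute
  N/L curves, thickness-vs-time curves, the measured PDMS surface energies)
  are outside what synthetic validation can reproduce; the suite validates
  oracle equivalence and parameter recovery instead.
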