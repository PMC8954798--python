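# Methods

This note documents the models, parameter choices and numerical
conventions behind `spheropk`, and what the synthetic generator does —
and does not — emulate.

## Dosing profiles

A dosing cycle C(t) on [0, T] (T = 24 h) is a linear ramp 0 → C_max
over [0, t_peak] followed by `n_decay_steps` equal-duration step
segments holding C_max·e^(−λ(t−t_peak)) at each step start.  Defaults:
C_max = 50 µM, t_peak = 1.5 h, 12 decay steps.  The in-vivo reference
curve behind this shape is not tabulated anywhere we can read it from,
so the profile is pinned by two constraints instead: the 50 µM peak and
the AUC-matched constant of 9.3 µM.  The decay rate is the unique λ
(the cycle average is strictly decreasing in λ) with

    (1/T)·[C_max·t_peak/2 + Σ_k C_max·e^(−λ·k·Δ)·Δ] = 9.3 µM,

found by bisection to 1e−9 µM (well inside the 1e−6 µM contract).  The
step count 12 is a free choice (any ≥ 4 gives the same calibrated
average to within the tolerance); the trough concentration at cycle end
is then ~0.01 µM, i.e. effectively zero between doses.

AUC is computed exactly per segment (rectangles for steps, trapezoids
for ramps).  The two-pump schedule is pure mass balance at constant
total flow Q = 10 µL/min: q_compound = C/C_stock·Q.  Reconstructing the
concentration from the schedule reproduces the profile to one floating
point rounding (1e−14 relative), which is what the tests assert.

## Well-mixed compartment

Transport around the spheroid is reduced to dC/dt = (Q/V)(C_in − C).
The cavity geometry is not something we model spatially; V defaults to
52.1 µL so that a concentration step reaches 90% in ~12 min at
10 µL/min (the midpoint of the 10–15 min range a spatially resolved
treatment suggests).  Integration is classical RK4 on a fixed grid with
the guard dt ≤ (V/Q)/10; each step is split at profile breakpoints and
the inflow is evaluated one ulp inside the current segment, so the
integrator never reads across a discontinuity.  This keeps the numeric
solution within 1e−6 relative of the exponential closed form and within
1e−5·C_max of a 100×-refined reference for arbitrary piecewise inflow.
Tubing delay, if needed, is a pure time shift of the profile.

## Synthetic spheroid generator

**State.**  Cells are nucleus centres with radii (default 3.5 µm, the
7-µm expected nucleus size).  The initial count is
n = 0.47·(R/r)³ for target radius R, matching the equilibrium packing
fraction of the mechanical model (~0.44–0.45) so the relaxed colony
lands within ~2% of the target diameter.  Realized Monte-Carlo packing
fractions are ~0.43 (union volume over bounding sphere), inside the
physically sensible 0.3–0.64 window.

**Mechanics.**  Neighbouring cells interact as overdamped springs with
rest length r_i + r_j: overlap repels (gain 0.6 per sweep), separation
up to 1.4·(r_i + r_j) attracts (gain 0.2), stragglers with no capture
neighbour drift toward the centroid.  This gives the packing a genuine
equilibrium spacing: the colony neither creeps denser over time nor
evaporates, the bounding radius tracks N^(1/3), and nucleus-radius
changes translate into spacing changes within a few steps.  (An earlier
design using a global centripetal pressure against one-sided repulsion
had no equilibrium density and crept toward close packing throughout a
run, systematically depressing measured growth rates.)  After every
relaxation, repair sweeps enforce the hard overlap invariant: every
pairwise distance ≥ 0.8·(r_i + r_j).

**Growth law.**  g(C) = g_max − (g_max + d_max)·C^h/(C^h + c_half^h);
per step of dt ≤ 1 h each cell divides with probability max(g, 0)·dt or
is removed with probability max(−g, 0)·dt, so the expected count
follows the discrete branching mean (1 + g·dt)^(t/dt).  Daughters are
placed just inside contact distance beside the parent.  Defaults
g_max = 0.012/h and d_max = 0.02/h are calibration choices: they give a
~1.4× vehicle area increase over 48 h and a net shrinkage under
9.3-µM constant dosing, the observed regimes for this cell model.
c_half = 1.9 µM anchors the half-effect at the reported average
transition concentration; hill = 4 makes the response steep, as
expected for a pathway-suppression readout, and places the g = 0
switchover at c_half·0.6^(1/4) ≈ 1.67 µM.

**Nucleus shrink.**  Radii scale by 1 − shrink_frac·C^h/(C^h+c_half^h).
Because the packing relaxes to contact, this modulates spacing, local
density and projected area together.  The magnitude has no published
anchor and is the generator's free calibration knob; shrink_frac = 0.04
was chosen (once, on a coarse 0.02/0.04/0.06 grid) so that the full
simulate → segment → smooth → transition chain reads out a transition
concentration of ~2.0 µM on the group curve, matching the ~1.9 µM
anchor.  Two opposing biases meet here: radius re-expansion during the
decay phase advances the measured area upturn (toward higher
concentrations), while the 10-point LOWESS window delays the detected
crossing (toward lower ones).

**Optional effect lag.**  A first-order effect compartment
(τ_effect, exact exponential update per step) can delay the
concentration the growth law sees, mimicking the latency between a
concentration change and its antiproliferative effect; default off.

**Rendering.**  Each nucleus is a 3D Gaussian with σ per axis
√((r/2)² + psf²) µm (psf 0.8 µm) on the anisotropic grid (dz = 2 µm,
dx = dy = 1 µm; 121 planes at full scale), amplitude 3000 counts on a
background of 100.  Noise is Poisson on the signal plus Gaussian read
noise (σ = 20); `rng=None` renders noise-free.  Optional exponential
depth attenuation emulates incomplete imaging of the lower hemisphere;
it is off by default so detection tests read the whole volume.
Determinism: one integer seed feeds a SeedSequence spawn tree (init /
dynamics / rendering), and identical seeds give byte-identical stacks
and tables.

**What the generator does not emulate** — and hence what passing tests
do and do not show about real data: no optical aberrations or
scattering beyond the isotropic PSF and optional depth decay, no
nucleus shape variation or mitotic figures, no necrotic core (real
spheroids are kept below the ~400–500 µm regime where cores form), no
spatial drug gradients inside the tissue (the compartment is
well-mixed), no spheroid drift or loss (QC rules are exercised on
constructed fixtures instead).  Passing the end-to-end recovery tests
shows the chain is consistent with its own generative model at realistic
noise, not that the biology of a real spheroid is this simple.

## 2D segmentation conventions

The chain is fixed: Gaussian blur σ = 1 px → external gradient
(dilation − image, disk r = 1) → global threshold at the arithmetic
mean of the gradient image → opening (disk 1) → closing (disk 3) →
fill holes → largest 8-connected component.  The threshold is applied
to the gradient image (it directly follows the gradient in the chain);
fill-holes turns the closed boundary ring into the solid object.  A
flat image returns an explicit "no object" mask.  Golden-mask tests
freeze the exact operator sequence on three fixtures.

Two consequences of this chain are worth knowing.  First, the
thresholded gradient ring extends ~3 px beyond a sharp object edge
(blur tail plus dilation), so a hard-edged disk of radius 100 px
measures ~6% large; the tests pin this halo (mask contains the object,
exceeds it by ≤ 4 px of radius) rather than pretending it away.
Second, for rendered spheroids — whose luminous edge is soft — the halo
roughly cancels the dim outer skirt, and measured areas agree with the
true cross-section within 5% (within ~2.5% in practice).  "True" radius
for a fuzzy-edged cell pack is defined as the 99th-percentile radial
extent of cell centres plus the nucleus radius; the single outermost
cell would otherwise dominate a bounding-sphere definition.

Series handling: linear interpolation onto the t = 0, 84, 168, … min
grid (grid built in integer minutes so on-node observations are exact;
no extrapolation), normalisation to a reference frame with a group
fallback to the earliest frame (index ≤ 4) available to all series.

## 3D analysis conventions

Rolling-ball background correction runs slice-wise in 2D (radius 50 µm
in-plane); the background is estimated on a 4× down-scaled copy and
resized back — it is smooth by construction, and this keeps full stacks
tractable.  Whole-spheroid segmentation is Otsu on the corrected voxel
histogram, largest 26-connected component.  "Midpoint" is the mask's
z centroid and "bottom" its deepest voxel; the 30-µm section is centred
halfway between them, boundaries inclusive.

Nucleus detection is multiscale LoG with σ₀ = d/(2√3) for expected
diameter d = 7 µm, per-axis sigmas divided by the voxel size (so the
2-µm z-step is handled natively), scale range 0.7–1.5·σ₀, relative
threshold 0.1, and greedy non-maximum suppression at d/2 minimum
separation keeping the brighter peak.  On the synthetic fixtures this
detector is essentially exact (precision/recall ≥ 0.99 at default
noise on a ~500-nucleus spheroid).

Regions: center = in-plane distance ≤ 35 µm from the vertical axis
through the mask centroid; shell = in-plane distance ≤ 35 µm from the
2D convex hull of the section nuclei (the hull of a 30-µm slab is
nearly degenerate in 3D, so the hull is taken in the section plane; the
3D variant was considered and rejected for exactly that degeneracy).
A nucleus within both bands is labelled "both", within neither
"neither".  Neighbour counts use all detected nuclei of the spheroid as
candidates (restricting to the section would truncate neighbourhoods at
the slab faces); the 20-µm radius is inclusive.  All of these are
configuration-exposed.

## Growth dynamics

Relative change is the signed ratio a_k/a_{k−1} − 1 at frame-pair
midpoints (the pure ratio is recoverable by adding 1).  Smoothing is
classic LOWESS — locally weighted linear regression with tricube
weights over each point's 10 nearest neighbours (window/n passed as the
fraction, robustness iterations on) — which reproduces constants and
straight lines to numerical precision.  Crossing times come from linear
interpolation between the bracketing smoothed points; an exact zero
sample is itself the crossing.  The concentration at each
negative→positive crossing is read off the applied profile and their
mean is the threshold estimate.  When transitions are to be compared
across spheroids, the per-spheroid relative changes are averaged on the
common frame grid first and the transitions read off the smoothed group
curve, which is substantially less noisy than per-spheroid detection.
The estimate carries an intrinsic caveat: with an effect lag
(τ_effect > 0) the measured crossing shifts into lower concentrations,
so the estimate is a lower bound in that regime.

## Quality control

A frame is "empty" if segmentation found nothing or the retained object
is smaller than 1,000 µm²; "moved out" if the mask touches the image
border.  A series is excluded if its first usable frame comes after
index 4 (which would also defeat the normalisation fallback) or if more
than 10% of its frames are empty.  All three thresholds are
configurable; excluded series keep their raw outputs and every
exclusion cites its rule.

## Problem sizes

Full-scale spheroids (225 µm diameter) contain ~15,000 model cells and
are exercised in the packing tests.  The simulation-heavy validations
run on scaled spheroids — 70 µm (~470 cells) for growth-rate recovery
and detection, 90 µm (~1,000 cells) for the 72-h dosing runs — with a
144-px field and 57 z-planes; voxel size, frame intervals, dosing and
PD parameters stay at the full-scale defaults.  `scripts/acceptance.py`
uses 5 seeds per stochastic quantity, the test suite up to 10; at these
sizes the whole suite runs in minutes on one CPU.

## Known limitations

The mechanical model has no cell polarity, adhesion heterogeneity or
migration; density gradients arise only from drug response, so the
radially increasing packing some real spheroids show is not emergent.
The PD law is phenomenological — no receptor occupancy, no resistance,
no cell-cycle structure.  The threshold-estimation procedure inherits
the smoothing delay of LOWESS: at 84-min sampling the detected crossing
lags the true one by ~1–3 h, which on a steep decay maps to a several-
fold concentration range; finer sampling reduces the error (tested down
to 42-min intervals).  The 2D halo makes absolute areas chain-specific;
relative areas and transitions are insensitive to it.
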