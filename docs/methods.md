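# Methods

`xpcsre` simulates phase-separating two-dimensional systems, synthesizes
the coherent-scattering speckle they would produce, and quantifies the
features of two-time correlation functions (TTCs) that encode the
control parameters of the non-equilibrium process.  This note records
the models, the numerical choices, and what the synthetic scenarios do
and do not establish about real data.

## The two-time correlation function

For a series of speckle frames I(**q**, t) and a ring of detector
pixels with |q| in [q − Δq, q + Δq], the TTC is estimated as the
Pearson correlation over ring pixels,

    G(q, t1, t2) = cov_p[I(t1), I(t2)] / ( sd_p[I(t1)] · sd_p[I(t2)] ),

which is exactly 1 for frozen speckle and 0 for fully decorrelated
frames.  An unnormalized variant ⟨I(t1)I(t2)⟩/(⟨I(t1)⟩⟨I(t2)⟩) is
available for comparison with other XPCS conventions.

**Radial envelope flat-fielding.**  A ring of finite q-width carries a
static radial intensity envelope: the isotropic I(|q|) profile varies
across the ring, and this fixed pattern correlates even statistically
independent frames (measured bias ≈ 0.13 for a six-pixel-wide ring on a
256² map).  By default each frame is therefore divided by its own
azimuthal mean in equal-count radial sub-bins (≥ 32 pixels each) before
correlating.  Frozen speckle still correlates at exactly 1; the
decorrelated limit drops to the estimator noise (≈ 1/√ring-size).  The
flat-fielding can be disabled (`envelope="none"`).

Frames whose ring intensity has zero variance (e.g. an empty field) are
masked: their rows and columns are reported as 0 with a validity flag.

Derived quantities: the *contrast profile* G(k, k+offset) indexed by
the pair midpoint age t_age = (t1+t2)/2; g2-like row or diagonal-band
cuts; relaxation times by interpolated 1/e threshold or a Kohlrausch
fit g = exp[−2(τ/τ_r)^γ] (the factor 2 is the intensity-correlation
convention for an amplitude decorrelation).

## Phase-field model

Spinodal decomposition after a temperature quench is integrated as the
rescaled Cahn–Hilliard equation

    ∂u/∂t = ∇·[ m(u) ∇( u³ − a·u − κ∇²u ) ],

with u the rescaled concentration (dense phase u > 0, values in
[−1, 1]), a = (T_c − T)/T_c ∈ [0, 1] the quench depth, κ the
interface-energy coefficient and m(u) the mobility.

* **Integration.**  Constant mobility: semi-implicit Fourier-spectral
  update (linear a∇²u and κ∇⁴u terms implicit, ∇²u³ explicit), periodic
  boundaries.  Defaults: 512² grid, dx = 1, dt = 0.05, κ = 1; the
  scheme is stable at these settings and conserves the spatial mean of
  u exactly (the k = 0 mode is untouched).  The Ginzburg–Landau free
  energy F[u] = ∫[−(a/2)u² + ¼u⁴ + (κ/2)|∇u|²] dr is non-increasing
  along stored frames and serves as the Lyapunov diagnostic.
* **Gel mobility.**  m(u) = 1 below a threshold concentration u_gel and
  m_min ≪ 1 above it (defaults u_gel = 0.5, m_min = 0.05), a sharp
  mobility suppression of a gelling dense phase.  Variable mobility
  rules out the spectral shortcut, so this path uses an explicit
  conservative finite-volume update (flux form, face-averaged
  mobility); it needs a smaller timestep (dt ≈ 0.01 at dx = 1) and
  raises a numeric-stability error when the field diverges.
* **Quench default.**  a = 0.7 for "deep quench" presets — well inside
  the spinodal at critical composition u0 = 0; a = 0 recovers the
  stable regime where fluctuations decay.
* **Field modifications.**  `binarize` maps u > 0 → +1 and u ≤ 0 → −1
  (the tie at exactly 0 goes to the dilute phase; a measure-zero
  choice).  `dilate_domains` applies k × pixels_per_frame iterations of
  4-neighbour morphological dilation to frame k of a binarized series,
  emulating a growth-to-dissolution rate ratio larger than the free
  dynamics would give.  At desk-scale grids one pixel per frame is a
  strong perturbation; the operation is meant for large grids and short
  series.

The coarsening diagnostic ξ_USAXS(t) = 2π/q_peak(t) uses the azimuthal
intensity profile (equal-width bins, default N/4 bins); the peak is the
argmax over interior bins with optional box smoothing and parabolic
sub-bin refinement.  A maximum on a boundary bin raises an
out-of-window error — the situation where the scattering peak has left
the measurement window.  A 256² critical quench integrated to t = 1000
(2×10⁴ steps) gives a late-decade growth exponent of 0.35 ± 0.01,
consistent with the diffusive/coalescence value 1/3.

## Particle-based heuristic model

Domains are disks (or equal-area ellipses) at random positions on a
periodic grid, painted at constant interior concentration (u_in = −1)
on a constant background (u_out = +1), with per-particle schedules for
radius, shape, concentration and motion.  This decouples the
sub-phenomena of phase separation — growth, dissolution, shape change,
concentration contrast, Brownian motion — so each TTC feature can be
attributed to one knob.

Conventions and defaults (chosen once; the values the canonical
scenarios use):

* 200 disks of initial radius 4 px on a 512² box (tests scale down to
  256²/100–150 disks); radii from a truncated normal with sd
  `radius_spread`.
* Radius schedules are piecewise linear *offsets* relative to their
  value at t = 0: particle i has r_i(t) = max(0, r0_i + S(t) − S(0)).
  A particle reaching radius 0 has dissolved and stays dissolved.
  Multiple schedules are assigned by ascending initial-size rank —
  smallest first, the Ostwald-ripening ordering.
* Overlaps are unions of interiors (no excluded volume); positions and
  shapes wrap periodically, matching the periodic FFT.
* Brownian motion is an uncorrelated Gaussian random walk (per-axis
  step RMS `step_sigma`, optionally a schedule).  The physical
  inverse-size coupling of diffusivity is *not* hard-coded; the
  early-stage preset approximates it with a decreasing schedule.
* The `brownian` preset places particles with a minimum separation of
  2.2 diameters so the ensemble has an interparticle structure-factor
  peak for the analysis ring to sit on.

**Two-step growth/dissolution.**  The square-feature scenario grows all
particles at a common rate for the first 30 % of the run, then
dissolves them at rate (growth rate)/rate_ratio with onsets staggered
by size rank over 20 % of the run (small domains dissolve first);
`rate_ratio = inf` freezes sizes instead.  Two design choices matter
here:

* A *weak random walk* (σ = 0.15 px/frame) is part of the preset.  A
  perfectly static ensemble whose radii retrace earlier values revisits
  earlier configurations exactly, producing spurious perfect-correlation
  ridges that can make slow dissolution look *more* frozen-in than no
  dissolution at all — a degeneracy no real system has.  The weak walk
  removes it; with it the square strength is strictly increasing in the
  rate ratio for every split placement tried.
* The square strength is the mean of G over the cross block
  {t1 < t_split < t2}.  For the two-step scenario the split is placed
  mid-run (inside the coarsening stage whose memory the square
  measures); the automatic default — the maximum-curvature change point
  of the row means of G — is a heuristic for data where the split is
  not known.

Note a floor on the cross-block mean: dynamics continuous at the split
always correlates the frames just before it with those just after, so
even the fastest dissolution leaves a square strength of order 10⁻²,
well above the i.i.d.-frame null of the statistic (~10⁻³ at these
sizes).  "Square feature absent" therefore means "at the continuity
floor", not "statistically indistinguishable from i.i.d. noise".

## Speckle synthesis and noise

A speckle frame is |FFT2(u − ⟨u⟩)|² with the zero frequency centred
(unnormalized FFT; only ratios enter the TTC).  Simulation q units are
2πk/(N·dx).  For experimental stacks a geometry block (photon energy,
detector distance, pixel size, beam centre) maps pixels to physical q
via λ[Å] = 12.398419843/E[keV] and q = (4π/λ)sin θ with
θ = ½ arctan(d·pixel/distance).

Detector noise is i.i.d. uniform on [0, fraction · I_max] per pixel and
frame, with I_max the maximum over the *whole series* — a constant
noise amplitude against an evolving signal.  Uniform noise keeps
intensities non-negative; the 4 %-of-I_max level is the scale at which
the near-diagonal contrast of a growth series starts tracking
I(q,t)/I_max (signal-to-noise-driven contrast fluctuations), while the
noiseless contrast stays flat.

## Tail-based characteristic lengths

For a growing system the near-diagonal contrast oscillates; local
maxima ("tails") are detected with a prominence threshold (default
0.05) and the k-th tail is assigned ξ_XPCS = (n0 + k) · 2π/q.  The
anchor n0 is user-supplied or taken from an independent early-size
estimate, rounded.

**Accuracy.**  For monodisperse disks the contrast maxima sit at the
antinodes of the disk form factor J1(qr), i.e. at mean diameter
(n + ~0.72…0.75)·2π/q — *approximately* integer multiples, with a
quarter-period offset that never vanishes.  Two consequences: the
distance of d/(2π/q) from the nearest integer converges to 0.25 from
above (measured 0.16–0.34 with frame quantization), and the relative
error of the integer ladder at the n-th multiple is ≈ 0.27/n.  Tail
analysis is therefore most accurate when the probed length 2π/q is
well below the domain size; the canonical tail scenario probes
2π/q ≈ d0/2.9 so the first detected tail is already the 3rd–4th
multiple and every ladder point lands within 10 % of the true mean
diameter (measured 2–8 %).  Merging tails from several q-rings
concatenates the (t_age, ξ) points, with a cross-ring consistency check
rather than averaging.

Modulation spacing (mean ± sd of the gaps between adjacent maxima)
flags non-constant growth speed when sd/mean > 0.25; for constant-speed
growth the spacing is uniform and halves when the speed doubles.
Coarsening exponents come from least squares on (log t, log ξ).

## Scaled-down study conditions

Test and acceptance runs use 64²–512² grids, 100–200 frames, and
100–200 particles — sizes where every scenario completes in seconds to
a few minutes on one CPU while the rings still hold 10²–10⁴ pixels.
The synthetic scenarios emulate the *statistical structure* of
phase-separation speckle (growth ladders, frozen-in epochs, Brownian
decorrelation, SNR-driven contrast), not any specific instrument: no
photon statistics, flat-field, detector gaps, polarization or mask
handling, no hydrodynamic coupling, no 3D effects.  Passing tests show
the estimators and feature extractors behave correctly on fields with
known ground truth; they do not calibrate the heuristic model to a
particular experimental system — that reverse-engineering step is, by
design, manual.

## Known limitations

* The gel-mobility path is explicit and an order of magnitude slower
  per unit simulated time than the spectral path.
* Integer-pixel boundary dilation saturates small grids within tens of
  frames.
* The tail ladder inherits the quarter-period form-factor bias above;
  for polydisperse or non-disk domains the phase differs but the 2π/q
  spacing persists.
* The automatic square-split change point is a heuristic; supply
  `t_split` when the epoch boundary is known.
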