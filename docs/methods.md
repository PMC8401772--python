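# Methods

## Scope and model

`qspt` analyses single-particle tracking data under the standard free-
diffusion observation model: a particle performs 2D Brownian motion with
diffusion coefficient D (μm²/s), sampled at frame interval δt; each observed
position carries static localization noise (i.i.d. Gaussian, std σ per axis)
and, when the camera shutter integrates over the frame, motion blur.
Quantum-dot emitters additionally blink, producing trajectories with missing
frames. The package's simulator generates data with exactly this structure
(plus engineered co-localization encounters and clustered localization maps),
so every analysis stage can be validated in closed loop against known ground
truth.

## Simulator

* **Brownian paths.** Per-axis frame increments are N(0, 2Dδt). With
  `exposure_fraction` f > 0 the reported position of a frame is the mean of
  32 within-frame sub-steps over the open-shutter window followed by one
  jump across the closed remainder. 32 sub-steps make the discrete-averaging
  error negligible next to the localization noise. A uniform shutter open
  for a fraction f of the frame implies a motion-blur coefficient R = f/6
  (`implied_blur_coefficient`): R = 0 for instantaneous sampling, 1/6 for
  full-frame exposure.
* **Blinking.** A two-state Markov chain per frame (on→off probability
  `p_off`, off→on `p_on`, first frame on). Real Qdots show power-law-
  distributed off-times; a Markov chain was chosen because it produces gaps
  with controllable, analytically known statistics (long-run on fraction
  p_on/(p_on+p_off)), which is what the downstream validation needs. Off-
  state frames are deleted; on-state positions equal the true positions plus
  noise only, so the on-mask is an exact oracle.
* **Encounter pairs.** Particle A diffuses freely; particle B is constructed
  from Brownian bridges so that it arrives within a fraction of a typical
  step of A just before `t_merge`, shares A's positions on
  `[t_merge, t_split)`, and departs from A's side at `t_split`. The fused
  interval carries the summed intensity of the two single spots — the
  physical signature of a diffraction-limited merge. In validation fixtures
  the merged interval is kept longer than the gap-closing horizon (15 frames
  vs a 10-frame maximum gap) so the linker cannot silently re-join the
  vanishing branch across the encounter.
* **Rendered movies.** Integrated-Gaussian PSF per pixel (error-function
  quadrature), constant background, Poisson shot noise.
* **Clustered maps.** Uniform disks of radius r around well-separated
  centres over a homogeneous Poisson background; every localization carries
  a ground-truth cluster label. Defaults: 10 clusters, r = 60 nm, 100
  localizations per cluster, background 884 μm⁻² (10× intra-cluster-to-
  background density contrast) in a 1100 nm field of view. The FOV is sized
  so background and clustered localization counts are roughly balanced; see
  "Limitations" for why a relative (percentile) threshold makes this the
  meaningful operating regime.
* **Reproducibility.** All randomness flows from one integer seed through
  per-particle `SeedSequence` child streams: identical seeds give
  bit-identical outputs, and individual particles are reproducible in
  isolation.

## Detection and linking

Detection is the classic centroid recipe: band-pass (Gaussian blur at the
noise scale minus a boxcar at the object scale, defaults 1 and 4 px), local
maxima above an intensity threshold, brightness-weighted centroid over a
disk (default radius 5 px), duplicate maxima within the disk merged keeping
the brighter.

For noninteracting Brownian particles the likelihood of a set of
frame-to-frame displacements factorises into Gaussians, so the most probable
label assignment minimises Σδᵢ² under a hard gate δᵢ ≤ max_disp (default
5 px). We solve this exactly per frame pair with the Jonker–Volgenant
assignment solver on a cost matrix augmented with birth/death dummies at
cost max_disp² — a feasible link always beats a death+birth pair, and the
solution is the global optimum rather than a greedy approximation (verified
against exhaustive enumeration on small fields). A second assignment pass
over (track end, track start) pairs bridges blink gaps of up to `max_gap`
frames (default 10) within the same distance gate. Tracks shorter than 50
frames are discarded, and by default only tracks containing at least one
internal gap (i.e., blinking, single-emitter-like) are retained for
diffusion analysis; the flag is exposed because gap-free synthetic studies
need it off.

Numerical notes: costs are squared distances in pixels; forbidden entries
use a large finite constant (1e15) rather than infinity; the assignment
solver is deterministic, so equal-cost solutions resolve reproducibly.

## Diffusion estimators

**MSD line (D₂–₅).** The time-averaged MSD uses all overlapping pairs. Gap
handling is explicit: `gap_aware` averages only over frame pairs observed at
the true frame lag; `reindexed` first maps observed frames onto consecutive
integers (the "no gaps" convention of common tracking tools), which
converts multi-frame excursions into apparent single-frame steps and
therefore inflates D on blinking data — an effect the validation suite
quantifies rather than hides. The line is fitted by OLS to lags 2δt–5δt
(four points; the D₂–₅ convention, skipping the noise-dominated first lag);
D = slope/4 and the intercept estimates 4σₓ². Negative slopes are retained,
not clamped — clamping would bias distribution comparisons — and such tracks
are classified immobile downstream (threshold 5×10⁻⁴ μm²/s, strict
inequality for mobility).

**Frequency-domain MLE.** The displacement sequence of a noisy, blurred
Brownian walker is stationary with per-axis variance 2Dδt + 2(σ² − 2RDδt)
and lag-one covariance −(σ² − 2RDδt). The orthonormal discrete sine
transform diagonalises this tridiagonal covariance; mode k of M
displacements has variance λ_k = 2Dδt + 2(σ² − 2RDδt)(1 − cos(πk/(M+1))).
The exact Gaussian log-likelihood, summed over x and y (isotropy), is
maximised over (D, σ²) with a bounded Nelder–Mead simplex started from
moment estimates (D₀ from variance + twice lag-one covariance, σ₀² from the
negated covariance), objective tolerance 1e-10. D ≥ 0 and σ² ≥ 0 are
enforced; solutions pinned at either boundary are flagged `on_boundary`.

*Gap policy.* The frequency-domain likelihood assumes uniform sampling, so
blinking trajectories pose a choice. The default, `gap_policy="reindexed"`,
feeds the displacement matrix of the gap-closed trajectory to the
likelihood — mirroring the common practice of running the estimator directly
on reconstructed trajectories — at the cost of an upward bias on heavily
blinking emitters (gap-bridging displacements carry several frames of
diffusion). The alternative, `"contiguous"`, fits only the longest run of
consecutive frames: statistically strict, but short segments make the
per-track estimate right-skewed and its ensemble median low. The default
reproduces the characteristic ordering seen in tool comparisons —
median D_MLE at or above the MSD-line medians on blinking data — and the
validation suite asserts that ordering against the gap-aware D₂–₅; against
the *reindexed* D₂–₅ the two estimators are inflated by the same
gap-crossing factor and are statistically indistinguishable on purely
Brownian simulations.

*Blur bracketing.* When the data's true blur satisfies σ² ≥ 2RDδt, the
profile likelihood in D is exactly invariant to the assumed R: the fitted
σ² absorbs the difference (σ̂² = σ² − 2(R_true − R_assumed)Dδt ≥ 0). The
blur-bracketing validation (R = 0 vs R = 0.25 on full-frame-exposure
simulations) is therefore run at σ = 0.04 μm, inside that regime, where the
medians agree to numerical precision. Outside it (σ² < 2R_true·D·δt) the
σ² ≥ 0 constraint binds for too-small assumed R and deflates D — a real
property of the constrained estimator worth knowing when the camera
integrates the whole frame and localization noise is very low.

## Merge-and-split analysis

A merge candidate is a track end adjacent (next frame) to a concurrent
track's point within 1 μm; a split candidate is a track start adjacent
(previous frame) to a concurrent track's point within the same gate. Merges
additionally require the trunk's intensity at the event to exceed the
brighter branch's local median intensity (5-frame window) — the fused spot's
summed brightness — because distance-only gating on blink-fragmented tracks
inflates false merges; the gate is a flag (default on). Each track end or
start joins at most one event; conflicts resolve by ascending squared
bridging distance with deterministic id-based tie-breaks. The summary
reports the fraction of merge/split-positive trajectories among tracks with
more than 50 detected spots and the histogram of splits per positive
trajectory. The lifetime of merged segments is deliberately not a headline
output — blink fragmentation makes it unreliable — but is recoverable from
the event records as a diagnostic.

## Voronoï nanocluster analysis

One Voronoï cell per localization; cell area is inversely proportional to
local density. Cells are clipped exactly to the field of view by
tessellating the points together with their mirror images across the four
FOV edges — every real cell is then a finite polygon and the cells partition
the FOV to machine precision (the validation suite checks a relative error
below 1e-6). Cells whose unclipped region was unbounded are flagged for
diagnostics. Exact duplicate coordinates (emitter overcounting) collapse to
one cell but count with multiplicity in localization totals and densities
(flag-controlled). The cluster search discards cells with area above the
per-series 50th percentile (linear interpolation) and keeps connected
components — Voronoï-edge adjacency, equivalently Delaunay adjacency — of at
least 10 retained cells. Cluster radius is √(Area/π); density is
localizations per 100 nm²; localizations are classified into small clusters
(radius < 50 nm), large clusters (≥ 50 nm; the tie goes to large so the
classes partition), or unclustered.

## Validation experiments and problem sizes

`qspt.validation` backs both the test-suite and `scripts/acceptance.py`:
MSD implementation vs a double-loop definitional oracle (100 blinking
tracks); estimator recovery at D ∈ {0.01, 0.05, 0.1} μm²/s (σ = 0.02 μm,
200-frame tracks, 500 per condition); the reindexing effect and the
MLE/MSD ordering on blinking ensembles (p_off = 0.1, p_on = 0.5, n = 500);
blur bracketing on 300 matched full-exposure tracks; linking optimality on
200 small random fields vs exhaustive enumeration plus link recovery at
0.05 particles/μm²; a 100-encounter + 400-lone-track merge/split closed
loop; tessellation conservation on 50 random maps; cluster recovery on five
validation maps and five homogeneous Poisson controls; and immobility
classification of 500 immobile noisy tracks. These sizes give binomial /
median standard errors comfortably inside the asserted tolerances while
keeping the full run around a minute.

## Limitations

* **The percentile threshold percolates on structureless data.** Retaining
  cells below the 50th area percentile is site percolation at p = 0.5 — the
  critical probability for Delaunay-type graphs — and cell areas are
  spatially correlated, so on a *homogeneous Poisson* map roughly a third of
  localizations still end up in ≥10-cell connected components (the Poisson-
  control experiment measures ≈ 35–40%). The 50th-percentile/≥10-cell rule
  therefore does not control false-positive clustering on complete spatial
  randomness; clustered fractions it reports should be compared against a
  CSR control at the same density rather than read as absolute.
* **Cluster size is regime-dependent.** With a relative threshold, detected
  cluster area depends on the background:cluster balance: dominant
  background bleeds retained background cells into clusters (inflating
  radii), while near-zero background pushes the percentile *into* the
  cluster-area distribution and truncates clusters to their dense cores.
  Radius recovery is accurate in the balanced regime the validation maps
  emulate.
* **Blinking is Markovian** in the simulator; real Qdot off-times are
  heavy-tailed, which fragments tracks more severely than the validation
  ensembles do. Passing the closed-loop tests demonstrates correctness of
  the estimators under the stated model, not robustness to every photophysical
  regime.
* **No real-data medians are reproduced here**: the published Qdot movies
  live in an external archive, and headline real-data values additionally
  depend on third-party detectors outside this package's scope. The
  package reproduces the methodological *relationships* (gap handling, blur
  bracketing, estimator ordering) on simulation instead.
* The detector implements only the band-pass/centroid scheme; Gaussian-
  mixture fitting, Laplacian-of-Gaussian detection, and motion-classification
  algorithms of other suites are out of scope.
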