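# Methods

This note documents the models and estimators the package implements, the
default parameters and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical choices that matter.

## The paracrine averaging model

Cell `i` at position `x_i` with primary (pre-paracrine, Ca²⁺-like) response
`R_i` is predicted a post-paracrine (ERK-like) response

    P_i = Σ_j w(d_ij) R_j / Σ_j w(d_ij),    w(d) = exp(−d² / 2σ²),

summing over all cells including `i` itself (`include_self=True` by default:
a cell senses its own secretion).  The spread σ is the paracrine
communication distance (PCD).  Two deliberate choices:

- **Normalization.**  The per-cell weighted *average* (not the raw areal
  convolution) is the default: the paracrine input is the average ligand
  concentration secreted by local cells, and normalization makes the
  prediction invariant to cell density and a convex combination of observed
  responses (which several invariants and tests rely on).  The unnormalized
  convolution is available via `normalized=False`.
- **Kernel convention.**  σ is the standard Gaussian sigma, so the empirical
  PCD (the sigma of a fitted Gaussian profile) and the kernel parameter are
  the same number.  An alternative convention writing the exponent as
  `−d²/PCD²` (i.e. σ = PCD/√2) is available as
  `KernelSpec(convention="exp-r2-over-pcd2")`.

**Diffusion-limited cap.**  When the downstream response begins ~5 min after
stimulation, a ligand with diffusion coefficient D cannot usefully act beyond
the 3-D rms diffusion length `√(6DT)`; `KernelSpec(cap=DiffusionCap(D, T))`
caps the effective PCD at that distance (300 µm for D = 50 µm²/s, T = 300 s).
The rms-length reading is an inference; it reproduces the reported ~300 µm
exactly at those parameters.

A PCD of exactly 0 is treated as the identity (no communication), which keeps
sweep grids starting at 0 total.

## Fidelity statistics

Cells are binned by a covariate: dose wells (`by-group`), equal-count
covariate bins (default 15 for wound fields; the bin-count sensitivity range
8–30 is exercised in the tests), or equal-width bins.  Throughout, sample
variance uses ddof = 1; bins with fewer than 2 cells are dropped with a
warning; fewer than 2 usable bins is an error.

- **SNR** = `var_bins(bin means) / mean_bins(within-bin variances)`.  The
  noise term is the *unweighted* mean across bins by default (a
  count-weighted option exists).  SNR is exactly invariant under affine
  response rescaling.  `N = 0` (all responses identical within every bin)
  raises a zero-noise error rather than returning infinity.
- **CV by bin**: per-bin `sd/mean`; two summaries with identical schemes are
  compared by a two-sample t-test on the per-bin CVs.
- **Mutual information.**  Response densities are estimated by the 1-D
  k-nearest-neighbor rule `p̂(v_i) = k / (n · 2 d_k(i))` with `k = 10`
  (`d_k` = distance to the k-th nearest other value; ≥ k exact duplicates
  substitute half the smallest nonzero width, with a warning).  Entropies are
  the plug-in averages `Ĥ = −(1/n) Σ log₂ p̂`; for each bin count
  `B ∈ {4, 6, 8, 10, 12, 16, 20}` the information is
  `I_B = Ĥ[R] − Σ_b (n_b/n) Ĥ[R | bin b]`, and the reported MI is the
  ordinary-least-squares intercept of `I_B` against `B` at `B = 0`, removing
  the estimator's bin-count dependence.  Negative intercepts are clamped to
  zero with a warning.  Units are bits; nats are emitted alongside.  The
  small-k bias of the kNN rule (a factor k/(k−1) on densities) cancels in the
  entropy *difference*, so MI is unaffected.

## PCD sweeps

For each replicate field and each grid σ the field is averaged and the
statistic computed; pairwise distances are computed once per replicate and
shared across the whole grid.  The per-replicate optimum is the best grid
point refined by the vertex of the parabola through its two neighbors
(clipped to that bracket) — the curves are smooth near the peak, so sub-grid
reporting is justified; aggregation is mean ± SEM over replicates (SEM absent
for a single replicate).  Statistic failures on individual (replicate, σ)
pairs are recorded and excluded with a warning.  The sweep has no internal
randomness.  The default grid is 0–600 µm in 10 µm steps.

For multi-well dose experiments a replicate is a *list* of per-well fields:
wells are averaged independently (communication does not cross wells) and
then pooled with the dose as the group label.

## Diffusion theory

Slab geometry: cylindrical cells (radius ρ = 10 µm, height h_c = 15 µm) in a
chamber of height h_f = 60 µm.  An instantaneous release of N_r molecules
gives `C(r,t) = N_r/(h_f·4πDt)·exp(−r²/4Dt)`; detection requires
`C_detect = N_d/(h_c πρ²)`.  Solving and maximizing the detectable radius
over time gives

    PCD = e^(−1/2)·ρ·√(ηS),    T_int = ρ²ηS/(4eD),

with η = h_c/h_f and S = N_r/N_d.  The derivation (maximize
`r²(t) = 4Dt·ln(ρ²ηS/4Dt)`; the maximum is at `4Dt* = ρ²ηS/e`) is enforced
against an independent numeric oracle (log-grid + bounded scalar
maximization) to 1e-6 relative error, including the D-independence of the
PCD.  `S` here (dimensionless signal strength) is named `s_strength` to keep
it distinct from the SNR signal.

`detection_radius` returns a flagged 0 (not NaN) when the bolus is too dilute
everywhere, keeping downstream maximization total.

**Flow.**  Péclet number `P = vL/D` with the PCD as the length scale, also
expressible as `P = √(Sη)·ρv/(D√e)`; the positional-information error due to
advection is the advected distance `P·L` as a fraction of the signaling
gradient extent (>500 µm for wound fields): 50 µm of advection over a 500 µm
gradient ≈ 10%.  Default interstitial flow v = 0.3 µm/s.

**Temporal-averaging decoding.**  An alternative decoding model (all
molecules released at t = 0, cell averages concentration over (0, t₀])
gives `C_avg(r) = −N_r/(4Dπh_f t₀)·Ei(−r²/4Dt₀)` with Ei the principal-value
exponential integral (`scipy.special.expi`; Ei of a negative argument is
negative, so C_avg > 0).  Verified against adaptive quadrature to 1e-8
relative.  `compare_decoding_weights` compares this profile with the Gaussian
kernel: both are normalized at r = 50 µm (below which the instantaneous
release assumption makes the temporal profile diverge) and, when t₀ is not
given, the averaging window is matched to the Gaussian length scale by a
bounded scalar search minimizing the maximum absolute discrepancy over
50–300 µm.  At matched scales the two profiles differ by < 0.15 in that
window, with the largest discrepancy below 50 µm.

## Cluster analysis

Single-linkage hierarchical clustering on cell centers cut at the maximal
communication distance (MCD, 200 µm) — exactly the connected components of
the ≤200 µm proximity graph (verified against a brute-force oracle).  Per
cluster, the longest center-to-center distance `d` defines the effective area
`EA = π(d/2)²` (using `d` as the circle diameter, even though this
underestimates area for collinear clusters — fidelity to the published
procedure over geometric nicety) and density `n/EA`.  Clusters with
`d > 150 µm` are flagged and excluded; singletons are excluded from SD
statistics (SD undefined).  The density-variability test is a plain Pearson
correlation of per-cluster response SD (or mean) against raw density;
constant inputs return r = 0, p = 1 rather than NaN.

## PCD estimation from point sources

Neighbor cells around a single source cell are binned by distance (20 µm
bins up to 400 µm; bins with < 2 cells dropped) and the bin means fitted with
`A·exp(−r²/2σ²) + c` by nonlinear least squares (initialization:
A₀ = range of bin means, σ₀ = quarter of the covered radial range, c₀ = min
bin mean; bounds keep all three parameters non-negative).  The baseline `c`
is included because distant cells retain basal activity.  Fitting binned
means mirrors how such profiles are measured; a per-cell fit
(`per_cell=True`) is exact on noiseless data, while the binned fit carries
only a curvature bias < 0.5%.  Fits whose σ standard error exceeds σ, whose
amplitude is indistinguishable from flat, or whose σ escapes the fitted range
are flagged `wide_ci`.  Recovery on the default synthetic source fields is
unbiased to < 1% at ~2000 neighbors and CV 0.25.

## Synthetic data: what is emulated, and what is not

All generators are seeded and reproducible byte-for-byte through CSV
round-trips.  Cell-to-cell noise is mean-one multiplicative lognormal
(responses are non-negative fold-changes; the CV is the user-facing knob).

- **Positions** come from a jittered hexagonal lattice at the exact target
  density with a guaranteed minimum spacing (default 2×10⁻³ cells/µm²,
  20 µm — about three cell diameters per 100 µm of PCD).  Confluent
  epithelial monolayers are much closer to a jittered lattice than to an
  ideal Poisson scatter, and the default density exceeds what sequential
  random (Poisson-disk) packing can reach at this spacing; densities above
  92% of the hexagonal packing bound are rejected with an explicit error.
- **Dose-response wells**: saturating Hill mean (`Rmax = 1`, `K = 2 µM`,
  `h = 1.2` over a 0.1–30 µM ladder) with noise CV calibrated *analytically*
  so the expected pre-averaging SNR of the ladder is 0.9, the regime the
  dose-response analysis operates in: `cv² = var_d(m_d)/(0.9·mean_d(m_d²))`.
- **Wound fields**: circular wound (radius 150 µm) in a 3×3 mm field;
  radial mean `A·exp(−(r−r_wound)/λ) + b` with `A = 3`, `λ = 500 µm`
  (the gradient extends beyond 500 µm), `b = 0.3`; the covariate is the raw
  distance to the wound *center*.  Gaussian and power-law profile forms are
  available, since the true profile form is not pinned down.  The noise is
  the product of an iid lognormal factor (CV 0.6) and a *spatially
  correlated* lognormal field (CV 0.3, correlation length 300 µm, built from
  a smoothed white-noise grid).  The correlated component models patchy
  cell-state heterogeneity; it is essential: purely iid noise is entirely
  removable by kernel averaging, in which case both SNR and MI would climb
  toward their estimator ceilings with ever-larger PCD instead of peaking at
  an interior optimum the way measured wound fields do.
- **Point-source fields**: mean `A·exp(−r²/2σ²) + c` around one flagged
  source cell (defaults A = 1, σ = 99.5 µm, c = 0.2, CV = 0.25, ~2000
  neighbors — matching the scale of the co-culture experiments the direct
  PCD measurement comes from).
- **Clustered fields**: 60 clusters on a jittered grid with > 400 µm
  separation (communication-isolated at the 200 µm MCD); 14–18 members each;
  per-cluster spatial spread log-uniform over ~9–56 µm, which is what drives
  the wide density range.  Responses interpolate between an individual
  factor and a locally averaged component,
  `resp_i = µ(α·a_i + (1−α)·f_i)`, with `a_i` the Gaussian-kernel local
  average of the per-cell factors at a coordination scale of 20 µm (one cell
  diameter).  The short scale is deliberate: the cluster analysis only
  retains clusters narrower than 150 µm, and the density-variability
  signature is visible only if retained clusters span weak-to-full
  coordination; with a ~100 µm coordination scale every retained cluster
  would be almost fully averaged and the signature would vanish at this
  cluster size.  `α = 0.8` mimics coordinated (ERK-like) responses (negative
  SD-density correlation, p < 0.05, in ≈98% of seeds); `α = 0` mimics
  uncoordinated (Ca²⁺-like) responses (significant in ≈8% of seeds — the
  nominal false-positive rate).

What the generators do **not** emulate: time-resolved traces (responses are
max-over-time scalars by construction), images or segmentation artifacts,
receptor-level biochemistry, well-to-well batch effects, or boundary effects
of real culture chambers.  Passing tests therefore demonstrate that the
*analysis pipeline* behaves correctly on data with the assumed statistical
structure — not that real wound data have exactly this structure.

## Problem sizes and determinism

The sweep-based checks run on scaled-down study fields chosen for desk-scale
runtimes while keeping every other study condition: dose wells of
600×600 µm (~720 cells each, 6 doses, 5 replicates), wound fields of
1.8×1.8 mm (~6300 cells, 6 replicates, grid 0–400 µm in 25 µm steps), and the
default 3×3 mm wound geometry wherever no sweep is involved.  All randomness
flows from explicit seeds (one root seed with named substreams in the
pipeline runner), so every result in the README and the acceptance script is
exactly reproducible.

## Known limitations

- The MI estimator's extrapolation is linear in the bin count by choice; for
  strongly nonlinear `I_B` curves (near-deterministic channels) the intercept
  underestimates the true MI.
- The Pearson density-variability test inherits the usual caveats of linear
  correlation on skewed densities; no weighting or log-transform is applied.
- The diffusion theory uses the slab ("cell cylinder") approximation
  throughout; no finite-element geometry is attempted.
- `effective area` via the longest chord underestimates the area of
  elongated clusters (kept deliberately, see above).
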