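# paracrine

Analysis tools for **paracrine communication distance (PCD)**: how far
secreted ligands travel to coordinate single-cell responses, and how that
distance trades noise reduction against spatial-signal flattening in wound
signaling.

When a tissue is wounded, damage signals (e.g. extracellular ATP) trigger a
fast, highly variable primary response (cytosolic Ca²⁺) in each cell. Cells
then secrete a paracrine ligand (e.g. EGF) in proportion to that response;
because the ligand diffuses, each cell's downstream response (ERK) reflects
the *local average* of its neighborhood's primary responses. Averaging over a
length scale σ — the PCD — suppresses cell-to-cell noise, but too much
averaging also flattens the spatial gradient that tells a cell how far it is
from the wound. The optimal PCD balances the two.

## What the package computes

- **Paracrine averaging** (`paracrine.kernel`): the post-paracrine prediction
  for each cell, `P_i = Σ_j w(d_ij) R_j / Σ_j w(d_ij)` with Gaussian weights
  `w(d) = exp(−d²/2σ²)`, optionally capped at the diffusion-limited distance
  `√(6DT)`.
- **Fidelity statistics** (`paracrine.fidelity`): cells binned by dose or by
  distance from the wound; signal `S = var_bins(mean_cells)`, noise
  `N = mean_bins(var_cells)`, `SNR = S/N`; per-bin coefficients of variation;
  mutual information between bin and response via k-nearest-neighbor
  entropies with linear extrapolation in the bin count.
- **PCD sweeps** (`paracrine.sweep`): fidelity as a function of σ over a grid,
  per-replicate optima (parabolic sub-grid refinement), mean ± SEM.
- **Diffusion theory** (`paracrine.theory`): for an instantaneous point
  release of `N_r` molecules in a chamber of height `h_f`, with detection
  threshold `N_d` molecules per cell volume (radius ρ, height `h_c`), the
  maximum detectable radius is `PCD = e^(−1/2)·ρ·√(ηS)` (η = h_c/h_f,
  S = N_r/N_d — independent of the diffusion coefficient) reached at
  `T_int = ρ²ηS/(4eD)`; plus Péclet-number flow analysis and a
  temporal-averaging decoding model based on the exponential integral.
- **Cluster analysis** (`paracrine.clusters`): single-linkage spatial clusters
  cut at the 200 µm maximal communication distance; Pearson test of
  within-cluster response SD against cluster density.
- **Direct PCD estimation** (`paracrine.estimation`): σ of a Gaussian fit
  to the mean response of cells around a single secreting (source) cell.
- **Synthetic fields** (`paracrine.synthetic`): generators for dose-response
  wells, wound fields, point-source fields, and clustered layouts with the
  statistical structure these analyses assume, fully seeded.

## Worked example

```python
import numpy as np
from paracrine.synthetic import default_wound_replicate, default_point_source_replicate
from paracrine.sweep import sweep_pcd
from paracrine.estimation import fit_point_source, summarize_fits

# five synthetic wound fields (1.8 mm, circular wound of radius 150 um)
reps = [default_wound_replicate(seed, field_size=1800.0) for seed in range(5)]
res = sweep_pcd(reps, np.arange(0, 401, 25.0), statistic="snr")
print(f"optimal PCD = {res.mean_argmax:.1f} +/- {res.sem_argmax:.1f} um (SEM, N=5)")
print(f"peak ensemble-mean SNR = {res.mean_curve.max():.2f} "
      f"(raw field SNR = {res.mean_curve[0]:.2f})")

# direct estimate: Gaussian sigma around twelve simulated source cells
fits = [fit_point_source(default_point_source_replicate(s)) for s in range(1, 13)]
s = summarize_fits(fits)
print(f"direct PCD estimate = {s.mean:.1f} +/- {s.sem:.1f} um (SEM, N=12)")
```

Output:

```
optimal PCD = 109.7 +/- 32.0 um (SEM, N=5)
peak ensemble-mean SNR = 1.83 (raw field SNR = 0.24)
direct PCD estimate = 98.6 +/- 1.6 um (SEM, N=12)
```

The sweep says local averaging over roughly a hundred micrometers maximizes
the fidelity of the wound-distance signal (SNR rises from 0.24 to 1.83 before
over-averaging flattens the gradient), and the direct Gaussian fit around
point sources recovers the communication distance the fields were generated
with (true σ = 99.5 µm). The two estimates agree — the package's central
point.

A command-line interface mirrors the library:

```bash
paracrine simulate --kind wound --seed 1 --width 1800 --out wound.csv
paracrine average --in wound.csv --pcd 100 --out predicted.csv
paracrine snr --in predicted.csv --bins equal-count:15
paracrine theory --nr 1e5 --nd 100      # closed-form PCD, T_int, Peclet...
paracrine run --seed 1 --out results/   # full pipeline with manifest
```

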