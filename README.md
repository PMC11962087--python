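# lpbarcode

Planning, simulation and decoding toolkit for **combinatorial optical
barcoding of single cells with laser particles (LPs)**.

Micron-scale semiconductor microdisk lasers emit sub-nanometer spectral
lines across the 1150–1650 nm window. Tagging a cell with several such
particles turns the sorted list of its emission-line photon energies,
`E = (E₁ < … < E_m)` in meV, into an optical barcode that can be read
non-destructively by spectral flow cytometry or confocal microscopy and
re-identified across measurements. This package implements the quantitative
framework needed to design and analyze such experiments:

* **Barcode counting.** With `l` distinguishable colors and `m` LPs per
  cell there are `C(l, m) ≈ l^m / m!` unique barcodes; for a continuous
  spectrum of width `Δ` and matching half-gap `δ`, the effective count is
  `B_eff = (Δ/2δ)^m / m!`.
* **Duplicate rate.** For a pool of `N` cells drawn from a line density
  `g(E)` with joint sorted-tuple density `G_m(E) = m!·∏g(Eᵢ)`,

  `ε_dup = 1 − ∫ G_m(E) · (1 − (2δ)^m G_m(E))^(N−1) dE`,

  evaluated in closed form for uniform `g` (`1 − (1 − 1/B_eff)^(N−1)`) and
  by Monte-Carlo otherwise, including a dual-mode mixture
  `G_m = (1−f_dm)·G_sm + f_dm·G_dm` for particles lasing on two
  whispering-gallery modes separated by their free spectral range.
* **Noise error.** Line-position fluctuations `φ(E′)` (Gaussian, or
  generalized Gaussian `φ ∝ exp(−(|E′|/α)^β)`) cause re-measurement
  mismatches at rate `ε_noise = 1 − (∫₋δ^δ φ)^m`. The total error
  `ε_tot = ε_dup + ε_noise − ε_dup·ε_noise` is minimized over `δ`, and the
  maximum pool size under an error budget `ε₀` is found by bisection.
* **Poisson tagging.** Stochastic tagging gives Poisson-distributed
  multiplicity; error rates are weighted across multiplicity classes and
  duplication is converted to a sample-loss figure at the gate where the
  weighted noise error equals `ε₀`.
* **Simulation.** Seeded pool generation, Chebyshev-metric duplicate
  counting (windowed search with an exact O(n²) oracle), and a cell-division
  simulator in which k-plet tagging units are inherited stochastically by
  daughter cells.
* **Decoding and matching.** Peak detection and Gaussian line fitting on
  emission spectra, spatial–spectral clustering of imaging-mode pixel peaks,
  and cross-run matching by order-preserving line alignment with a
  self-score-calibrated acceptance threshold, plus maximum-likelihood
  fitting of the generalized-Gaussian noise model from repeated
  measurements.

## Worked example

```python
import numpy as np
from lpbarcode import (JointBarcodeDistribution, NoiseModel,
                       SpectralDistribution, TaggingMixture,
                       count_duplicates, max_pool_size, optimize_delta,
                       sample_pool)

# a uniform 300 meV LP library read with 0.1 meV line noise
joint = JointBarcodeDistribution(base=SpectralDistribution.uniform(300.0))
noise = NoiseModel.gaussian(0.1)

delta_opt, eps_min = optimize_delta(joint, noise, m=3, N=10_000)
print(f"delta_opt = {delta_opt:.3f} meV, eps_min = {eps_min:.2e}")

print("max pool, m=3:", max_pool_size(joint, noise, 3, eps0=0.01))
print("max pool, m=4:", max_pool_size(joint, noise, 4, eps0=0.01))

# check the prediction against an explicit pool
pool = sample_pool(joint, TaggingMixture("fixed", m=3), 10_000, seed=1)
print("empirical duplicates:",
      count_duplicates(pool, delta_opt).pooled_fraction)
```

Output:

```
delta_opt = 0.399 meV, eps_min = 1.33e-03
max pool, m=3: 113566
max pool, m=4: 11348366
empirical duplicates: 0.001
```

So three LPs per cell keep the total identification error near 0.1% for a
10,000-cell pool, three-LP barcoding supports pools beyond 10⁵ cells at a
1% budget, and four LPs extend that past 10⁷; the simulated pool reproduces
the predicted duplicate rate.

The same functionality is exposed on the command line:

```sh
lpbarcode plan --config scenario.json --out report.json
lpbarcode synth two-run --n 10000 --lam 6 --seed 1 --out-prefix runs
lpbarcode match --c1 runs.c1.csv --c2 runs.c2.csv --out-prefix matched
```

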