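# Methods

This note documents the models implemented in `lpbarcode`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions a maintainer should know about.

## Barcode model

A cell's barcode is the ascending-sorted tuple of its laser-particle (LP)
emission-line photon energies, `E = (E₁ < … < E_m)` in meV. Energies are
used instead of wavelengths because line widths and measurement noise are
approximately constant in frequency; conversion uses
`E(meV) = 10³ · 1239.84198 / λ(nm)`. Two barcodes of the same multiplicity
are treated as identical when their Chebyshev distance
`max_i |E_{A,i} − E_{B,i}|` is at most the matching half-gap `δ`;
measurements with different multiplicity are presumed to come from
different barcodes. Duplicates are therefore only counted within a
multiplicity class.

## Error-rate theory (`lpbarcode.theory`)

**Discrete palette.** With `l` colors and `m` LPs the barcode count is
`C(l, m)`, approximated by `l^m/m!` for `l ≫ m`. The duplicate probability
for a pool of `N` cells is `ε_dup = 1 − (1 − 1/B)^(N−1) ≈ N/B`; the
planning helper inverts the approximate form (so a 1% budget for 10⁴ cells
demands 10⁶ barcodes) and also reports the exact-form solution.

**Continuous spectrum.** The single-line density `g(E)` is uniform (width
`Δ`), Gaussian (`Δ = √12·σ`, so both shapes share a standard deviation), or
a Gaussian mixture. The sorted-tuple density is `G_m(E) = m!·∏g(Eᵢ)` and

    ε_dup = 1 − ∫ G_m(E) · (1 − (2δ)^m · G_m(E))^(N−1) dE.

For a plain uniform density this is the closed form
`1 − (1 − 1/B_eff)^(N−1)` with `B_eff = (Δ/2δ)^m/m!`. All other densities
are integrated by Monte-Carlo: sample `E ~ G_m` (draw `m` i.i.d. lines and
sort), average the survival term, and report the standard error. The
integrand factor `(2δ)^m G_m(E)` is a probability and is clamped to
`[0, 1]` before exponentiation — near density peaks at large `δ` it would
otherwise exceed 1. The `(·)^(N−1)` power is evaluated as
`exp((N−1)·log1p(−p))` so that pool sizes up to 10¹² stay stable.

**Accuracy limits of the integral.** The formula assumes the density is
constant across each `2δ` cube. Where the cube is clipped — at the support
edges of a uniform density and near the sorted diagonal (`E_{i+1} − E_i ≲
2δ`) — the true collision probability is smaller. In the planning regime
(`ε ≲ 10%`) the bias is negligible, and simulated pools agree with the
integral within Monte-Carlo error; deep in saturation (duplicate rates
approaching 1, e.g. uniform `Δ = 100` meV, `δ = 0.5` meV, `m = 2`,
`N = 10⁴`, where `ε ≈ 0.86`) the integral overestimates the empirical rate
by a few parts in a thousand, which is resolvable because the between-seed
scatter collapses at saturation. This is a documented limitation, not an
implementation error: an exact-geometry computation that clips the cube
reproduces the simulated value.

**Dual-mode LPs.** A fraction `f_dm` of barcodes contains exactly one
dual-mode particle contributing a correlated line pair `(E, E + FSR)`,
`FSR ~ U[50, 70]` meV by default (the free-spectral-range window of
1.6–1.8 µm disks). The mixture density is
`G_m = (1 − f_dm)·G_sm + f_dm·G_dm`, with `G_dm` summing over which sorted
pair is the dual pair; configurations with two or more dual-mode LPs are
neglected, which is adequate for `f_dm ≪ 1` (the measured value used in
fixtures is 7.1%). The pool simulator instead flips each LP dual-mode
independently with probability `f_dm`; for small `f_dm` and low
multiplicity the two conventions coincide to first order.

**Noise.** Line fluctuations follow `φ(E′)`, either Gaussian (`σ_φ`) or the
generalized Gaussian `φ(E′) = β/(2αΓ(1/β))·exp(−(|E′|/α)^β)`; `β = 2`
recovers a Gaussian with `σ = α/√2`. The re-measurement mismatch rate is
`ε_noise = 1 − (∫₋δ^δ φ)^m`, with the inner integral `erf(δ/(σ_φ√2))` or
the regularized incomplete gamma `P(1/β, (δ/α)^β)`. Total error combines by
inclusion–exclusion: `ε_tot = ε_dup + ε_noise − ε_dup·ε_noise`.

**Optimization.** `optimize_delta` scans 200 log-spaced gates over
`[10⁻³ meV, Δ/2]` and refines the best bracket with bounded scalar
minimization; unimodality of `ε_tot(δ)` is assumed (observed throughout)
and the grid guards against violations. For Monte-Carlo densities one
sample set is drawn once and reused across all gate evaluations (common
random numbers), keeping the objective smooth. `max_pool_size` bisects
`N ∈ [2, 10¹²]` on the monotone `ε_min(N)`, returning 0 when even `N = 2`
breaches the budget and the cap when nothing does. Degenerate zero-scale
noise pins `δ_opt` at the lower search bound with a warning.

**Poisson tagging.** Stochastic tagging gives Poisson(λ) LPs per cell.
Untagged (`m = 0`) cells are unidentifiable; they are excluded from the
barcoded pool and reported as tagging loss, never folded into `ε_dup`.
Weights over `m ≥ 1` renormalize accordingly and the support is truncated
at cumulative mass `1 − 10⁻⁶`. Because duplication only happens within a
multiplicity class, the per-m duplicate rate uses the sub-pool size
`N·w_m`. `duplicate_loss` operationalizes duplicate screening: solve (by
bracketed root finding) for the gate where the weighted noise error equals
the budget `ε₀`, then report the weighted duplicate rate at that gate as
sample loss.

## Pool and division simulation (`lpbarcode.simulator`)

Pools are sampled directly from the generative model; every stochastic
operation takes an explicit seed or generator. Duplicate counting offers
two paths that must flag identical cell sets: a quadratic oracle (`cdist`
Chebyshev) and an indexed sweep that sorts each multiplicity class by its
first energy and enumerates the `[E₁ − δ, E₁ + δ]` window with
`searchsorted` — any Chebyshev neighbor must fall in that window, so the
search is exact. The sweep was chosen over per-dimension grid hashing
because the `3^m` neighbor-cell enumeration becomes untenable at the
multiplicities a λ = 6 Poisson pool reaches.

The division simulator tags `N` cells with Poisson(λ/k) k-plets (physical
units of k lines drawn from the library; the mean line count per cell is λ
for every k). At each division every plet goes to one of the two daughters
independently with probability 1/2 (`inheritance="even"` deals plets
alternately instead); line energies never change, so total line count is
conserved — a checked invariant. Per generation the gate is set by the
noise budget (weighted `ε_noise = ε₀` over the current multiplicity
distribution, mirroring the duplicate-loss rule) and a cell is identifiable
when it holds at least one plet and has no same-multiplicity Chebyshev
neighbor. Whether real readout would re-tune `δ` each generation is an
open design choice; fixing it by the noise budget is this package's
convention and is documented as such. Dual-mode LPs are disabled in
division runs by default.

## Spectral extraction (`lpbarcode.spectra`)

Peak detection uses `scipy.signal.find_peaks` with a prominence gate of
`min_prominence_mads × 1.4826 × MAD` of the intensity trace (the 1.4826
factor makes the MAD a consistent σ estimate, so the default factor 8 sits
≈ 12σ above Gaussian noise — measured false-positive rate on pure-noise
spectra is zero at 10³ trials) and a minimum separation of 1.0 meV. Line
centers are refined by a Gaussian-plus-constant least-squares fit on ±5
grid points; a window clipped by the grid edge or a singular fit falls back
to the three-point parabolic vertex and is flagged. Lines closer than the
minimum separation merge into one detection — an inherent limitation of
threshold peak finding. None of these thresholds is dictated by the
physics; all are exposed in `ExtractionParams`.

Imaging mode receives one spectrum per pixel. Pixel peaks are merged by
single-linkage clustering (connect when Chebyshev pixel distance ≤
`spatial_radius` and |ΔE| ≤ `energy_tol`); each cluster is one LP and its
energy is the unweighted mean of member centers, which exploits the
multiple spectra a scanning microscope collects per particle. Assigning
LPs to cells is an input label map, not computed — boundary segmentation is
out of scope.

## Cross-run matching (`lpbarcode.matching`)

Two barcodes are aligned by dynamic programming over their sorted line
lists: an order-preserving one-to-one assignment that maximizes the number
of matched pairs (only |ΔE| ≤ gate = 1.5 meV may pair) and, among those,
minimizes Σ|ΔE|. The score is

    s = Σ_matched (1 − |ΔE|/gate) − gap_penalty · (m_a + m_b − 2k),

with defaults gap_penalty = 0.25 and a two-line minimum for candidacy. The
gate is the experimentally motivated 1.5 meV; the linear kernel and penalty
are this package's concrete instantiation of likelihood-flavored scoring
and are fully configurable.

Candidate generation avoids the O(n²) pair scan with an inverted index over
binned line pairs (bin width = gate, ±1-bin expansion); any pair reaching
two gated alignments necessarily shares such a key, so the index is exact
for the default candidacy rule (a single-line index is used when one
matched line suffices). A brute-force path computes every score and is
held equal to the indexed path in tests.

The acceptance threshold is the `(1 − q)` upper quantile of the self-match
scores `S_self` (within-run pairs, identities excluded; default
`q = 10⁻⁵`, floored at the observed maximum when `q < 1/|S_self|`) —
correct matches form a high-score population present only in the cross-run
set. Accepted pairs are resolved one-to-one greedily by descending score
(ties: smaller mean |ΔE|, then lexicographic ids); optimal assignment is
available for small pools. The multiplicity confusion table and, when a
per-cell scalar channel (e.g. a fluorescence intensity) is present, the
matched-pair scalar correlation are reported as validation outputs — the
scalar never participates in matching.

`fit_noise` pools per-LP deviations from the per-LP mean energy across
repeated measurements and fits the zero-centered generalized Gaussian by
maximum likelihood (`scipy.stats.gennorm` with the location fixed at 0).
Centering at the finite-sample mean shrinks the spread by ≈ `1 − 1/(2r)`
for `r` repeats — under 1% at the 71-repeat design used in tests.

## Synthetic data (`lpbarcode.synthdata`)

The default library emulates a six-composition LP pool: six Gaussian
envelopes centered 825–1075 meV at 50 meV spacing, equal weights, 12 meV
envelope spread (≈ 300 meV usable width). Two noise presets reflect the two
readout regimes: flow cytometry (α = 0.25 meV, β = 1.37; single spectrum
per cell) and scanning confocal microscopy (α = 0.047 meV, β = 1.28;
many spectra per LP). Two-run experiments draw one true pool, measure it
twice with independent noise, drop whole cells from the second run
(default 10%, the between-run handling loss) and optionally drop lines
independently per measurement (default 0 — the real between-run line-loss
rate is not established, so it must be opted into). Spectra are emitted as
unit-amplitude Gaussian lines of 0.4 meV width on a 0.2 meV grid with
white noise of standard deviation 1/SNR.

What the generators do **not** emulate: lasing thresholds and pump-power
mode competition, intensity variation with particle orientation, LP loss
or exchange during culture, spectral drift beyond the stationary noise
density, and cell-boundary ambiguity in imaging. Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
model, not robustness to those instrument- and biology-level effects.

## Problem sizes and determinism

Tests and the acceptance script exercise the method at desk scale, chosen
to keep Monte-Carlo error well below the asserted tolerances: 50-seed pool
ensembles at N = 10³–10⁴ for the theory–simulation comparison, a 10⁴-cell
two-run matching experiment at λ = 6, six-generation division runs at
N = 10⁴, and the 156 LP × 71 repeat noise-fit design. Every generator is a
pure function of its inputs and seed; identical configuration and seed
reproduce outputs bit for bit, and `scripts/acceptance.py` derives all of
its generators from the single `--seed` argument.
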