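# Methods

## Data model

A `SpectrumSet` is an N × M intensity matrix on one shared, strictly
increasing wavenumber axis (cm⁻¹), with N unique labels and optional
class labels. All operations are pure: they return new sets and never
mutate inputs, labels or groups. Degenerate inputs (constant spectra,
zero areas, undefined correlations) raise errors naming the offending
spectrum rather than propagating NaNs, because silent NaNs poison the
downstream multivariate analytics.

File I/O supports two plain-text shapes: per-spectrum two-column files
(wavenumber, intensity; whitespace or comma separated, `#` comments) and
a wide CSV with a `wavenumber` first column. Parsing accepts decimal
points only — no locale comma decimals, which silently corrupt axes.
Values are written with `repr`-faithful formatting and read back with
round-trip float parsing, so write-then-read is the identity map. Axis
equality between two-column files is exact: the workflow standardizes
grids through explicit interpolation, so the reader refuses to
fuzz-match axes and instead directs the user to interpolate.

## Preprocessing chain

The canonical order is interpolate → crop → despike → smooth → baseline
→ normalize. Defaults follow common SERS practice.

**Interpolation** resamples linearly onto consecutive integer
wavenumbers within the original range (no extrapolation). **Cropping**
keeps the closed window [lo, hi]; the feature-rich 600–1600 cm⁻¹ region
is the usual choice for biomolecular SERS.

**Despiking** targets cosmic-ray artifacts: single-sample,
high-amplitude positive excursions. The detection statistic is the
signal minus its running median (window 11 by default) — robust because
a single-point spike barely moves the median — with an absolute
intensity threshold (default 300, appropriate for raw detector counts).
Flagged points are replaced by linear interpolation across the nearest
unflagged neighbors. Restricting to wavenumber regions leaves everything
outside bit-identical; with no regions the whole axis is screened.

**Savitzky–Golay smoothing** (default window 15, order 2) uses
least-squares polynomial kernels; edges are handled by evaluating the
polynomial fitted to the available one-sided window, which keeps M
unchanged and reproduces polynomials up to the fit order exactly. A
**Fourier low-pass filter** is provided as an alternative: spectra are
mirror-padded to length 2M (bounding edge ringing, deterministic),
transformed, bins above cutoff × Nyquist zeroed, and truncated back.

**airPLS baseline.** The Whittaker system (W + λ DᵀD) z = W y is solved
per iteration with a sparse symmetric factorization; D is the
difference matrix of order d ∈ {1, 2} (order 1 — the default — uses
first differences, matching the reference airPLS scheme's mapping of
"polynomial order 1"; order 2 leaves straight lines unpenalized).
Weights start at 1; after each solve, with residual r = y − z and
negative-residual mass D₋ = Σ_{r<0}|r|, weights become 0 where r ≥ 0 and
exp(t|r|/D₋) where r < 0, with both endpoints pinned at the largest
negative-residual weight to anchor the baseline. Convergence is declared
when D₋ < tol·Σ|y| (default tol 10⁻³, λ = 100, ≤ 15 iterations). On a
noise-free linear baseline under three Lorentzian bands these defaults
recover the truth to ≈ 4% RMSE of the baseline range; the spectral ends
deviate most because the first-difference penalty flattens slopes there.

**Minimum-polynomial baseline** iterates: least-squares polynomial fit,
replace the working signal by min(signal, fit), repeat until the fit
changes by < tol in relative L2 or max_iter. The equilibrium fit sits
slightly below the true background by an amount that grows with total
peak mass relative to the axis span — a known property of the method,
visible in the tests' tolerances.

**Gaussian–Lorentzian background fit.** The broad-background variant is
formulated here as n pseudo-Voigt components A·[η·w²/((x−c)²+w²) +
(1−η)·exp(−(x−c)²/2w²)] plus a constant offset, fit by bounded nonlinear
least squares with widths constrained ≥ min_width (default 200 cm⁻¹,
far above vibrational bandwidths, so narrow peaks survive subtraction).
Non-convergence is reported per spectrum with the last iterate returned.

**Normalization** offers area (trapezoidal area → 1), peak (maximum, or
the sample nearest a given position, → 1) and min/max (affine to [0, 1])
modes. The trapezoidal rule defines "integrated area" throughout the
package — on an integer grid it coincides with the interior sum, which
is what makes the relative variation equal σ_avg after area
normalization.

**Outlier screening** compares each spectrum with the leave-one-out
consensus mean on three criteria: Pearson correlation below a threshold;
mean absolute deviation above sd_thresh × the mean per-wavenumber sample
SD of the full set; Euclidean distance above dist_thresh × the median
leave-one-out distance. Criteria combine with OR by default (AND is
available). A constant consensus makes the correlation undefined; that
criterion is then skipped with a warning recorded in the report rather
than failing the screen.

## Analytics

σ_avg uses the sample (N−1) standard deviation and averages over the
current — possibly cropped — axis. The correlation heatmap appends the
grand mean spectrum of all N spectra as a final reference row/column
(each spectrum is not excluded from the mean it is compared with; at the
N ≥ 5 sizes involved the distinction is negligible).

Peak identification ranks local maxima by topographic prominence: apex
height minus the higher of the two base levels, each base level being
the signal minimum between the apex and the nearest higher point on that
side, or the axis boundary when none exists. Interior plateaus report
their midpoint (left-biased for even plateaus). Prominence is invariant
to constant offsets, which is what makes it robust to residual baseline.

Ward HCA operates on Euclidean distances between spectra; merge heights
are on the standard Ward scale (singletons a, b merge at ‖a−b‖) with the
deterministic nearest-neighbor-chain agglomeration, so dendrograms are
bit-reproducible. PCA centers columns but does not scale them — spectra
entering PCA are already normalized, and per-wavenumber standardization
would inflate noise in flat regions; it is computed by SVD with the sign
convention that each loading's largest-magnitude element is positive.
t-SNE is used contract-level as an off-the-shelf embedding (scikit-learn,
PCA initialization, exact method for small N): the package pins seed,
perplexity (default 3) and iteration count (default 500) — settings for
small sample sizes — and enforces the feasibility bound
3 × perplexity ≤ N − 1.

## Synthetic generator

Each replicate is baseline + peaks + Gaussian noise + spikes, where the
baseline is a polynomial plus optional broad Gaussian humps (width ≥
200 cm⁻¹, emulating fluorescence), peaks are Lorentzian
(A·w²/((x−c)²+w²), apex height A, HWHM w) or Gaussian
(A·exp(−(x−c)²/2w²)), and cosmic spikes are single-sample positive
excursions — matching the despiker's replacement model. Replicate
variation combines a global peak-amplitude jitter with an independent
baseline scale per replicate, which is what produces the large σ_avg
collapse at the baseline-correction step. One random stream per
replicate is derived from (seed, replicate index), so growing N never
reshuffles earlier replicates.

The shipped study conditions: the protein-like (BSA-like) set uses five
Lorentzian bands at 702/877/1087/1308/1443 cm⁻¹ on a 400–1800 cm⁻¹ axis
with 0.9 cm⁻¹ spacing (so integer-grid interpolation is non-trivial), a
sloped baseline plus a broad hump, noise SD 20 counts, spikes at 700 and
1100 cm⁻¹, N = 5 replicates, 5% amplitude and 8% baseline jitter. The
two-analyte pair (BPE-like vs R6G-like) uses disjoint band tables on
600–1600 cm⁻¹ (cross-class center separations exceed three bandwidths),
5 + 5 replicates, noise SD 6. These sizes keep the whole test suite and
the acceptance script in the seconds range.

What the generator does **not** emulate: detector shot noise (intensity-
dependent variance), wavelength-dependent instrument response, peak
position/width drift between replicates, multi-sample spike morphology,
and correlated (pink) noise. Passing tests therefore demonstrate
correctness of the algorithms under idealized additive-Gaussian
conditions, not performance on every instrument artifact real SERS data
can contain.

## Provenance and reproducibility

Pipeline configs validate fully (operation names against the registry,
parameter names and required values against each operation's signature)
before any step runs. The provenance log stores one entry per executed
step with *expanded* defaults — not just user-supplied values — so logs
are self-contained; replaying a log on the original input reproduces the
output bit-identically because every registered operation is
deterministic. The CLI's run manifest adds input SHA-256 checksums and
the tool version, making stale-input reruns detectable.

## Known limitations

- airPLS reports a singular Whittaker system rather than regularizing it
  silently; extremely large λ with pathological weight patterns can
  trigger this.
- The pseudo-Voigt background fit is a local optimizer; with several
  overlapping humps it can converge to a local minimum (reported via the
  per-spectrum flag).
- The outlier screen's deviation criterion uses the full-set SD, which
  the outlier itself inflates; a single gross outlier is therefore
  caught mainly by the distance criterion (the tests document the exact
  scores for a ×10 scaled copy).
- t-SNE coordinates are reproducible only for identical library
  versions, seed and input; only determinism, not the embedding
  geometry, is contractual.
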