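# spectrakit

A headless Python toolkit for Raman and surface-enhanced Raman (SERS)
spectral analysis: a standardized spectral data model, the full
preprocessing chain (interpolation, cropping, cosmic-ray despiking,
smoothing, baseline correction, normalization, outlier screening), an
analytics unit (reproducibility statistics, prominence-based peak
identification, correlation, Ward hierarchical clustering, PCA, t-SNE),
and a seeded synthetic-spectrum generator so every stage can be tested
offline against known ground truth.

It is aimed at spectroscopists and chemometricians who need a scriptable,
reproducible alternative to point-and-click spectral processing: every
pipeline run records the exact parameters of every step in a provenance
log that replays bit-identically.

## The core quantities

Spectra live on a shared, strictly increasing wavenumber axis
Δν₁ < … < Δν_M (cm⁻¹) as an N × M intensity matrix I_i(Δν_k).
Reproducibility across replicates is quantified by the **average spectral
variation**

    σ_avg = (1/M) Σ_k sqrt( (1/(N−1)) Σ_i ( I_i(Δν_k) − Ī(Δν_k) )² ),

the mean over wavenumbers of the across-replicate sample standard
deviation, and by the dimensionless **relative variation**
σ_avg / (trapezoidal area under the mean spectrum). After area
normalization the mean area is 1, so the two coincide.

Baseline removal uses **airPLS** (adaptive iteratively reweighted
penalized least squares): each spectrum y is fit by the weighted
Whittaker smoother

    z = argmin Σ_k w_k (y_k − z_k)² + λ Σ (Δᵈ z)² ,

starting from unit weights; after each solve the weights are set to zero
where the residual y − z is non-negative and to exp(t·|y_k − z_k|/D)
where it is negative (D being the total negative-residual mass at
iteration t), so the smoother progressively ignores peaks and settles
under them. Iteration stops when D falls below tol·Σ|y_k|. Iterative
minimum-polynomial and broad Gaussian–Lorentzian (pseudo-Voigt)
background fits are provided as alternatives.

## Worked example

Generate a 5-replicate protein-like SERS set (broad fluorescence
background, five vibrational bands, cosmic-ray spikes near 700 and
1100 cm⁻¹), run the canonical preprocessing chain, and analyze it:

```python
import spectrakit as sk

replicates, truth = sk.generate_spectra(sk.bsa_like_spec(seed=1))
chain = sk.PipelineConfig.from_steps([
    {"op": "interpolate_to_grid"},
    {"op": "crop", "lo": 600, "hi": 1600},
    {"op": "despike", "regions": [(600, 750), (1050, 1150)],
     "threshold": 300, "window": 11},
    {"op": "smooth_savgol", "window": 15, "polyorder": 2},
    {"op": "baseline_airpls", "lam": 100, "order": 1, "max_iter": 15, "tol": 0.001},
    {"op": "normalize", "mode": "area"},
])
processed, log = sk.run_pipeline(replicates, chain)
print(f"sigma_avg raw:        {sk.sigma_avg(replicates):.2f}")
print(f"sigma_avg processed:  {sk.sigma_avg(processed):.3e}")
print(f"relative variation:   {sk.relative_variation(processed):.3e}")
peaks = sk.find_peaks(processed.axis, processed.intensities.mean(axis=0), top_n=5)
print("peak positions (cm^-1):", peaks.positions.tolist())
assert sk.replay(log, replicates) == processed
```

prints

```
sigma_avg raw:        111.92
sigma_avg processed:  1.052e-04
relative variation:   1.052e-04
peak positions (cm^-1): [702.0, 877.0, 1087.0, 1308.0, 1444.0]
```

The raw replicates disagree strongly (σ_avg ≈ 112, dominated by
replicate-to-replicate baseline differences); after baseline removal and
area normalization they collapse onto a common shape (σ_avg ≈ 10⁻⁴,
equal to the relative variation, as it must be after area
normalization). The five detected band positions match the generator's
true centers (702/877/1087/1308/1443 cm⁻¹) to within one grid point.

The same workflow is available from the shell:

```sh
spectrakit simulate --spec bsa.yaml --seed 1 --out sim/
spectrakit process --config chain.yaml --in sim/spectra.csv --format wide_table --out proc/
spectrakit analyze peaks --in proc/processed.csv --out peaks.csv --top-n 5
```

where `bsa.yaml` can be as short as `preset: bsa` and `chain.yaml` lists
the steps above under a `steps:` key. Every `process` run writes a
`manifest.json` (input checksums, resolved parameters, provenance) next
to its outputs.

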