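# brinkswim

Quasi-2D Brinkman flow fields of strongly confined microswimmers.

A swimmer squeezed between two no-slip plates a distance `H` apart drives a
flow whose vertical profile is well approximated by a single Fourier mode,
`v(x, y, z) = v0(x, y) cos(pi z / H)`. Averaging the Stokes equations over
that profile turns the mid-plane flow into a 2D Brinkman problem with
screening wavenumber `kappa = pi / H`, solvable by a transverse projection
in Fourier space for point or Gaussian-regularized forces. This package
implements that theory and the analysis pipeline around it:

- **`brinkman_core`** — media, force elements, swimmer presets
  (`two_stokeslet`, `two_gaussian`, `three_stokeslet`, `three_gaussian`),
  spectral Green's functions, padded-FFT flow synthesis, the closed-form
  modified-Bessel screened Stokeslet, the parallel-plate far-field
  (source-dipole) expression for comparison, multi-swimmer superposition,
  and flow-field CSV/HDF5 I/O.
- **`flow_features`** — stagnation points, vortex centres with winding
  number and circulation sense, radial speed profiles, the normalized
  velocity–velocity correlation `Cvv(R)` and its 1/e decay length, a
  Péclet-number helper, and the quasi-2D viscous dissipation functional.
- **`force_ledger`** — Stokes drag `3 pi eta D u`, the constant-thrust
  estimate, and the contact-friction upper bound that closes the force
  balance under strong confinement.
- **`ptv_pipeline`** — particle-tracking-velocimetry reduction: cell-frame
  rotation, 6-sigma outlier removal, 2.24 um grid averaging, mask-aware
  5×5 smoothing, bilinear interpolation to 1 um, RMSD comparison on the
  normalized `v/vmax` scale, and polar speed profiles.
- **`trajectory_stats`** — mean speed, segmentwise tortuosity, MSD and its
  power-law exponent, per-track maximum displacement over a fixed lag, and
  the radius of influence of a swimmer's path.
- **`synthetic_data`** — ground-truth-known experiments: scripted swimmer
  paths, Brownian tracers advected by the model flow with the experimental
  imaging geometry (179 × 143 um field of view, 500 frames/s, ~8 s).
- **`workflows`** — end-to-end theory suite and synthetic recovery
  benchmark with JSON reports.

Units package-wide: um, s, pN, and mPa·s for viscosity.

## CLI

```sh
brinkswim model --preset two_gaussian --H 10 --window 90 --dx 1 --out field.csv
brinkswim features field.csv --report features.json
brinkswim forces --D 10 --u-weak 120 --u-strong 4 --eta 1 --out ledger.json
brinkswim synth --scenario H10 --seed 7 --out tracks.csv --pose pose.csv --truth truth.csv
brinkswim ptv tracks.csv --pose pose.csv --window 90 --out recovered.csv
brinkswim compare recovered.csv field.csv --out report.json
brinkswim stats tracks.csv --what speed,tortuosity,msd --out stats.json
brinkswim suite --H 10 --out suite.json
```

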