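# smtkit

Quantitative analysis of transcription-factor dynamics in live cell
nuclei, built around three measurements:

* **Single-molecule tracking (SMT)** — from localization/trajectory
  tables to a posterior *diffusion spectrum* (occupations over a
  log-spaced grid of diffusion coefficients) and the *chromatin-bound
  fraction*, the posterior mass at D < 0.1 µm²/s;
* **Proximity-assisted photoactivation (PAPA)** — spontaneous-corrected,
  day-control-normalized green-to-violet reactivation ratios that report
  protein–protein proximity (e.g. a TF activation domain recruiting a
  coactivator);
* **FRAP** — seven-step recovery analysis (masking, background
  subtraction, two-anchor photobleach correction, curve extraction,
  log-spaced binning, gradient-smoothing diffusion test, constrained
  single/double-exponential fits).

Every stage is paired with a synthetic-data generator carrying known
ground truth, so the whole pipeline is testable end to end without any
imaging data. The intended users are quantitative cell biologists and
microscopists who already have trajectory CSVs (quot-style), nuclear
masks, or FRAP stacks and want reproducible bound fractions, PAPA
ratios, and residence-time fits with honest, cell-level error bars.

## The model

A molecule in diffusive state D produces 2-D frame-to-frame
displacements with Rayleigh-distributed lengths,

    f(r) = (r / s²) · exp(−r² / 2s²),    s² = 2(D·Δt + σ²),

where Δt is the frame interval (7.48 ms by default) and σ the
localization error per coordinate. Trajectories are split into short
segments (≤ 3 jumps) which are treated as draws from a mixture over a
fixed grid of 100 log-spaced coefficients on [0.01, 100] µm²/s; the
occupations are estimated by EM and corrected for *defocalization* —
fast molecules leave the 0.7 µm detection slab and are therefore
under-observed. The correction divides jump-level occupations by the
expected number of observed jumps per molecule of each grid state,
computed from the acquisition model (slab geometry, photobleaching
lifetime, optional field-of-view bounds); the classic absorbing-slab
retention series is also available, both as a correction variant and
as a standalone function. Errors come from a 96-trial cell-wise
bootstrap, and a three-scheme jump-subsampling decomposition locates
the dominant variance level (pool vs within-cell vs within-day).

## A worked example

`examples/diffusion_spectrum.py` simulates a two-state TF population —
30% chromatin-bound at D = 0.005 µm²/s, 70% free at D = 2 µm²/s —
through the full acquisition model, applies the QC filter chain
(mask assignment, dense-frame truncation, ≥100-displacement cells),
and infers the spectrum. It prints:

```
60 cells pass QC, 16212 displacements
bound fraction (mass below 0.1 µm²/s): 0.303  [ground truth 0.30]
two-state fit: f_bound=0.305 (D_bound=0.0077, D_free=2.02 µm²/s)
```

The spectrum-based bound fraction recovers the simulated truth, and an
independent two-component fit of the jump-length CDF (the kinetic-model
cross-check) lands on the same value. The other examples cover
bootstrap errors and variance decomposition
(`bootstrap_and_variance.py`), PAPA ratios including the
0.36 / 0.26 → 1.4 worked normalization (`papa_ratio.py`), and FRAP
fitting with the gradient-smoothing test (`frap_fitting.py`).

A thin CLI wraps the same functions for file-to-file runs:

```sh
smtkit simulate --kind smt --seed 3 --out sim/
smtkit filter sim/trajectories.csv --out filtered.csv
smtkit spectrum filtered.csv --splitsize 3 --out spectrum.json
smtkit papa counts.csv --control control_counts.csv --out ratios.csv
smtkit frap movie.tiff --model double --out fit.json
smtkit varstats filtered.csv --out variance.csv
```

## Layout

```
src/smtkit/
  config.py      simulation configurations (SMT, PAPA, FRAP)
  simulate.py    synthetic-data generators with ground truth
  tracking.py    linking, mask assignment, QC filters, jump tables
  spectrum.py    jump likelihood, EM inference, defocalization, bound fraction
  resampling.py  cell-wise bootstrap, variance decomposition
  papa.py        phase maps, corrected/normalized ratios, segregation
  frap.py        masking, corrections, binning, gradient test, fits
  io.py          trajectory CSV, spectrum JSON, mask/movie TIFF
  cli.py         thin command-line layer
examples/        one narrative script per capability
docs/methods.md  models, assumptions, parameter choices, limitations
```
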