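# Methods

This note records the models, conventions and numerical choices behind
`mempart`, and what the synthetic benchmarks do and do not demonstrate.

## Model landscape

The reference free-energy profile along the bilayer normal z is a sum of
Gaussians,

    U(z) = -D [g_w(z - z_w) + g_w(z + z_w)] + B g_b(z),
    g(x) = exp(-(x / w)^2),

with two symmetric interfacial wells of depth D (default 10 kJ/mol) at
±z_w (default 1.2 nm) and a central barrier of height B (default
25 kJ/mol) at the midplane.  This is the canonical shape for a nonionic
amphiphile: the minimum corresponds to the tail inserted in the bilayer
core with the head group at the interface, the barrier to dragging the
polar head group through the midplane.  Width parameters are 1/e
half-widths (default 0.3 nm wells, 0.5 nm barrier); with these defaults the
components overlap negligibly, so the bulk level is exactly 0, U(0) = B to
better than 1e-5 and the evaluated minimum equals -D to better than 1%.
Gaussians were chosen over polynomial or cosine forms because they are
smooth, decay to a flat bulk and make the component amplitudes directly
interpretable as the well depth and barrier height.

## Umbrella sampling emulation

Windows sit on a ladder z_start + i·spacing (defaults -4 to 1.2 nm at
0.1 nm, i.e. 53 windows) with harmonic biases ½k(z - z0)²; the default
k = 500 kJ mol⁻¹ nm⁻² gives biased distributions of sd ≈ 0.07 nm, well
overlapping at 0.1 nm spacing.  An optional `extra_windows` list appends
irregular (center, k) pairs for protocols that densify steep regions.

Sampling is single-particle Metropolis Monte Carlo with Gaussian proposals
of sd 0.05 nm.  One sample is recorded every 20 kernel steps (the Monte
Carlo analogue of saving an MD frame every fixed number of integrator
steps); 500 initial steps are discarded so chains start equilibrated.  The
stride was chosen from mixing diagnostics — at stride 1 the chain's
correlation time in the stiff well regions is tens of steps, which inflates
the stitching error of the reconstructed profile; at stride 20 recorded
samples are effectively independent.  Any sampler with the correct
stationary distribution would serve; Metropolis was chosen for its
four-line verifiable kernel (the flat-landscape closed form
sd = sqrt(RT/k) and a near-unbiased histogram/Boltzmann comparison are both
tested).

An `equilibration_fraction` (default 5/32, mirroring a 5 ns equilibration
before 32 ns of sampling per window) is carried on the layout and applied
by the block analysis, not the generator: generated chains are already
equilibrated, but the discard keeps the bookkeeping of MD-style protocols
(32 samples -> drop 5, then one more to make the two blocks equal at 13).

## WHAM

Self-consistent iteration of the standard two equations on a shared grid
(default bin width 0.05 nm, half the window spacing).  Conventions:

- f initialised to 0; gauge fixed by f_1 = 0 after every update; the
  unbiased density renormalised to sum 1 (this fixes the PMF's additive
  constant; referencing to bulk water is a separate, explicit step).
- Convergence when max_i |Δf_i| ≤ tolerance (default 1e-7 kJ/mol,
  max_iter 1e5); an unconverged solution is returned flagged, never raised.
- Empty bins carry NaN and are excluded from exported profiles; downstream
  operations tolerate grid gaps.  No interpolation or smoothing anywhere:
  extrema are taken over stored grid points for reproducibility.
- Windows whose occupied bins form disconnected islands cannot be placed on
  one free-energy scale; this raises a diagnostic error naming the groups.
- Samples outside an explicit histogram range are counted per window;
  above 1% of all samples a warning is emitted, above 10% an error.
- The iteration residual decays over a few thousand iterations with
  occasional sub-percent wobble on plateaus; the monotonicity test allows
  5% per-step slack.

Two-block errors: per window the post-equilibration samples are split into
two equal contiguous blocks (odd counts drop the first sample — never
silently unequal blocks), WHAM runs per block on one shared grid, the two
profiles are put on a common reference (the bin nearest the requested
reference z, or their common-bin mean when none is given), and the per-bin
mean and sd (|Δ|/√2) are reported on bins occupied in both blocks.  On the
default landscape the mean two-block sd sits within a factor ~1.5 of the
across-seed sd of independently regenerated profiles.

## Features

- Referencing uses the nearest grid point to the requested z; the default
  bulk cutoff requires |z_ref| ≥ 3 nm for umbrella profiles.  For sliced
  partition profiles, which typically span only ±2 nm, the outermost slice
  serves as the bulk reference and the cutoff is relaxed to its |z| (the
  profile is already defined relative to bulk water through ln K).
- ΔG_par reports the global minimum and its location; among exact ties the
  point with largest |z| (the interface approached from bulk) is reported.
- ΔG_trans (direct) is max − min over the stored grid.
- ΔG_trans (extrapolated): per side of the midplane with ≥ 5 grid points,
  an OLS line through the 3rd–5th points closest to z = 0 (ranked by |z|;
  a point at exactly z = 0 belongs to the negative side) is evaluated at
  z = 0; with two qualifying sides the intercepts are averaged, which
  leaves symmetric profiles unchanged and de-biases asymmetric ones.  The
  result is intercept − global minimum.  Fitting one side only would match
  a single-sided protocol; the diagnostics expose both side fits so either
  convention can be read off.
- The asymmetry score is the mean |g(z) − g(−z)| over mirrored pairs with
  linear interpolation of the mirrored value; it is reference-invariant.
- Partition conversions g = −RT ln K and ln K = −g/RT use
  R = 8.314462618e-3 kJ mol⁻¹ K⁻¹ and default T = 310.15 K
  (RT = 2.5787 kJ/mol); they are exact mutual inverses.
- Replicate combination reports mean and standard error (sd/√n) per
  quantity and refuses to mix direct-maximum with extrapolated estimates.

## Partition-profile generator

Slice centers are n evenly spaced points over ±half_span (defaults 20
slices over ±2 nm ≈ 0.2 nm spacing, the convention for spanning a
membrane).  The underlying PMF is the model landscape flattened to its
value at |z| = plateau_halfwidth inside that radius — emulating the
midplane plateau of implicit-solvent models, which cannot describe the
bilayer deformation that produces a true midplane maximum — then converted
to ln K with independent Gaussian noise of sd noise_sd/RT per slice
(default 0.25 kJ/mol on the energy scale).

## Screening panel and activity generator

Four QSM categories are emulated: AHLs and their thiolactone analogues
(AHTs) as oxo/non-oxo pairs at even tail lengths 4–12 carbons, a family of
3-oxo-C12 derivatives sharing one tail, and short-tailed miscellaneous
molecules.  The partition free energy follows

    dg_par = a + s·tail_carbons + o·[3-oxo] + N(0, σ),

defaults a = 3, s = −1.5 kJ/mol per carbon, o = +5 kJ/mol, σ = 1 kJ/mol —
the amphiphile rules: hydrophobic tails drive insertion, the 3-oxo ketone
makes the head group more hydrophilic.  The translocation barrier co-varies
positively with dg_par (28 + 0.5·(dg_par + 10), clipped at 0), reflecting
that stronger partitioners face higher barriers.  Molecules can be emitted
for one or both bilayer compositions (zwitterionic DOPC and anionic
POPE/POPG) with no systematic composition effect, matching the observation
that these free energies are insensitive to the head-group charge of the
host bilayer.

Potency follows the documented monotone rule

    log10(concentration / uM) = a' + b·max(0, dg_par − threshold) + N(0, σ'),

defaults a' = 0, b = 0.15 per kJ/mol, σ' = 0.35, threshold = −10 kJ/mol:
molecules partitioning more weakly than the threshold need higher EC50/IC50
concentrations, with no potency gradient below it.  b = 0 severs the link
for null calibration.  The hinge (rather than a global linear trend) was
chosen because the observation being emulated is a threshold pattern, not a
proportionality.

What these generators do **not** emulate: correlated noise between
replicas, heteroscedastic potency errors, receptor-affinity contributions
to potency, category-specific intercepts, or outliers (e.g. strongly
active weak partitioners).  Passing tests therefore demonstrate estimator
correctness and calibration on clean linear/hinge structure, not robustness
to real assay pathologies.

## Statistics

- Trends are OLS (scipy linregress); the 3-oxo offset is the mean of
  matched-pair differences, pairs matched on (category, tail, bilayer) with
  within-cell averaging before differencing — pairing turns an "about
  5 kJ/mol by eye" claim into a computable statistic.
- The potency association reports Spearman rho with a label-permutation
  p-value (default 1e4 permutations, add-one smoothing, fixed seed: p is
  bit-reproducible and bounded in [1/(B+1), 1]), and a two-sided Wilcoxon
  rank-sum comparison at the dg_par cutoff — exact when the pooled sample
  is ≤ 30 and tie-free, otherwise the normal approximation; the method used
  is always reported.  EC50 and IC50 rows can be analysed separately or
  pooled; they measure different responses, so the per-assay filter is the
  default posture in the CLI.
- Calibration note: a calibrated two-standard-error interval covers the
  truth with probability at most 95.45%, so recovery-rate checks at a
  "95 of 100 seeds" level sit at the nominal edge; the offset estimator's
  empirical sd (0.437 over 500 seeds) matches its exact se (0.447).

## Pipeline and I/O

Window time series use an xvg-like dialect ('#'/'@' headers, two
whitespace columns); profiles and panels are TSV with '# key = value'
metadata lines carrying the configuration hash and seed; summaries are
JSON with shortest-repr floats (and round-trip float parsing on read), so
reruns with one config and seed are byte-identical.  Units are fixed: nm,
kJ/mol, kJ mol⁻¹ nm⁻², K, μM.  The `run` pipeline chains
simulate → wham → features → screen → associate, logging per-stage timing
to stderr; a stage failure aborts with the stage name.

## Problem sizes

Default pipeline runs use 1000 samples per window so a full demo completes
in seconds; the recovery benchmarks use the study conditions (53 windows,
5000 samples/window; the block-calibration study 20 seeds at 2500) chosen
to keep every statistical check comfortably resolvable on a single CPU.

## Known limitations

1D reaction coordinate only; no MBAR or autocorrelation-based errors (the
block split is the only error model); no permeability coefficients or
orientation-resolved profiles; the CLI reads only the package's own text
dialects, not native trajectory formats.
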