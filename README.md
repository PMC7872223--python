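# mempart

Membrane partitioning and translocation free-energy analysis for small
amphiphilic molecules — in particular bacterial quorum-sensing modulators
(QSMs) such as *N*-acyl homoserine lactones (AHLs), whose ability to cross
or accumulate in the lipid bilayer shapes their potency at intracellular
receptors like LasR.

The package is for computational scientists who study molecule–bilayer
thermodynamics: it reconstructs potentials of mean force (PMFs) along the
bilayer normal *z* from biased umbrella-sampling windows, converts sliced
water–membrane partition-coefficient profiles into PMFs, extracts the two
headline quantities of such studies, and relates them to screening
descriptors and potency data.

## The quantities and the methods

For a PMF *G*(*z*) referenced to zero in bulk water:

- **ΔG_par** (partition free energy) = min *G*(*z*) — the depth of the
  interfacial minimum; more negative means stronger membrane partitioning.
- **ΔG_trans** (translocation free energy) = max *G* − min *G* — the barrier
  to crossing the bilayer midplane at *z* = 0.

PMFs are reconstructed with the weighted histogram analysis method (WHAM):
per-window bin counts *n_i(b)* under harmonic biases
*u_i(z)* = ½*k_i*(*z* − *z_i*)² are combined by iterating

    rho(b) = sum_i n_i(b) / sum_i N_i exp[(f_i - u_i(b))/RT]
    f_i    = -RT ln sum_b rho(b) exp[-u_i(b)/RT]

to self-consistency, with *G*(*b*) = −RT ln ρ(*b*) + const.  Uncertainties
follow a two-block protocol: each window's production samples are split into
two contiguous blocks, WHAM is run per block, and the per-bin standard
deviation of the two profiles is reported.

Sliced partition-coefficient profiles (as produced by implicit-solvent
membrane models) are related to the PMF by

    G(z) = -RT ln K_{w->m}(z)

Such profiles plateau near the midplane, so ΔG_trans is alternatively
estimated by fitting a line through the 3rd–5th slices closest to *z* = 0
(the steep flank) and using its intercept at *z* = 0 in place of the capped
maximum.

All inputs can be generated synthetically with known ground truth: an
analytic double-well/central-barrier landscape, Metropolis-sampled umbrella
windows, plateaued ln *K* profiles, and a screening panel whose ΔG_par is a
known linear function of acyl-tail length (default −1.5 kJ/mol per carbon)
and 3-oxo head-group substitution (+5 kJ/mol), joined to EC50/IC50 records
whose potency degrades above a −10 kJ/mol partitioning threshold.

## Worked example

`examples/umbrella_to_pmf.py` samples the default landscape (wells of
−10 kJ/mol at ±1.2 nm, +25 kJ/mol barrier at *z* = 0) with 53 windows at
0.1 nm spacing and reconstructs the profile:

```
windows: 53, bins: 113
dG_par   =  -10.06 +/- 0.47 kJ/mol (truth -10.00; minimum at z = 1.20 nm)
dG_trans =   34.92 +/- 0.47 kJ/mol (truth  35.00)
asymmetry score = 0.29 kJ/mol (mean |g(z) - g(-z)| on the mirrored part of the grid)
```

The recovered minimum and barrier agree with the generating landscape well
within the two-block error bars, and the low asymmetry score confirms the
reconstruction is symmetric about the midplane, as it must be for a
symmetric bilayer.  The other example scripts cover the
partition-coefficient route (`partition_profile_features.py`), panel trends
(`screening_trends.py`) and the potency association
(`activity_association.py`).

A thin CLI chains the same stages over text artifacts:

```sh
mempart run --out demo_run --seed 1
mempart features --pmf demo_run/pmf.tsv --method direct \
    --reference-z -4.0 --out summary.json
```

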