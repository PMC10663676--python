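# capsidkit

Analysis toolkit for viral-capsid protein (VP) stoichiometry and the
physical measurements that flow from it. Built around a simple chain of
models: 214-nm capillary-gel-electrophoresis (CGE) peak areas divided by
sequence-derived molar extinction coefficients give molar VP
stoichiometry; a 60-subunit multinomial incorporation model converts
stoichiometry into particle-mass distributions comparable with
charge-detection mass spectrometry (CDMS); reciprocal buoyant densities
and an equilibrium CsCl-gradient model explain why a second, slower
isopycnic spin separates full-particle subpopulations; and
flow-cytometry potency tables correlate transduction efficiency with
(VP1+VP2)/VP3_total.

A seeded synthetic-data module generates every input the pipeline
consumes (electropherograms, CDMS ion events with calibrant peaks,
density readouts, potency tables, thermal melts) together with
ground-truth sidecars, so the whole analysis is testable offline.

## Modules

| module           | what it does                                                              |
| ---------------- | ------------------------------------------------------------------------- |
| `capsid_model`   | epsilon-214 from sequence, stoichiometry arithmetic, 60-mer assembly/mass model, composition enumeration |
| `cge_quant`      | baseline correction, peak detection/integration, species assignment, ssDNA identity check |
| `cdms_proc`      | m/z calibration, ion masses, mass-window filtering, histogram mode/FWHM, low-charge fraction |
| `ultracentrifuge`| vbar conversions, composition-based vbar, CsCl equilibrium gradient, band position/width/separation, Svedberg sphere model |
| `assays`         | relative potency vs bulk, stoichiometry-potency correlation, Tm from barycentric-mean melts |
| `synthetic_data` | seeded generators + five default scenarios with published parameter values |
| `pipeline_cli`   | orchestration (`run_pipeline`) and the `capsidkit` command-line interface |

## CLI

```sh
# write synthetic inputs (CSV/FASTA + truth.json sidecars) for all scenarios
capsidkit simulate --seed 1 --outdir out/sim

# individual stages
capsidkit cge --trace out/sim/f1_1/cge_protein.csv --out peaks.csv
capsidkit cdms calibrate --gdh out/sim/f1_1/gdh_calibration.csv
capsidkit cdms hist --events out/sim/f1_1/cdms_events.csv \
    --gdh out/sim/f1_1/gdh_calibration.csv --out hist.csv
capsidkit density --densities out/sim/f1_1/densities.csv --out bands.csv
capsidkit potency --records out/sim/potency.csv --out relative.csv
capsidkit assemble --fasta out/sim/f1_1/vp_sequences.fasta \
    --target-mass 4.6e6 --tolerance 1e4 --out compositions.csv

# full pipeline: simulate -> quantify -> model -> compare
capsidkit report --seed 1 --outdir out/report
```

`report` writes `report.json` (machine-readable) and `report.txt`
(per-scenario stoichiometry, theoretical vs CDMS masses, FWHM, density/
vbar and band tables at both rotor speeds, relative potency, and the
stoichiometry-potency correlation summary).

## Notes

- The assembly model is pure random incorporation: 60 independent
  multinomial draws over the molar fractions, no cooperativity.
- The epsilon-214 table (peptide bond 923 /M/cm plus side-chain terms)
  follows the published 214-nm prediction method; N-terminal proline
  carries its reduced coefficient and N-terminal acetylation is treated
  as absorbance-neutral.
- `band_separation` defaults to the first-order (Meselson-style)
  separation at the isoconcentration point, which scales exactly as
  1/omega^2; pass `linearized=False` for exact banding radii.
- The Svedberg sphere model assumes an anhydrous smooth sphere and is a
  consistency check, not a mass determination.
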