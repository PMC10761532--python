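# aavpack

Quantitative analysis of AAV genome-packaging heterogeneity: which inverted
terminal repeat (ITR) terminates packaging?

Recombinant AAV vectors with small genomes package replication-intermediate
multimers: a genome carrying N ITRs holds N−1 copies of the gene of interest
(GOI) and has length `L(N) = N·I + (N−1)·G`, where I is the per-junction ITR
contribution and G the internal gene segment.  `aavpack` turns that model
into a tested pipeline:

- **genome_model** — enumerate packageable multimer species for a construct
  (unit length, ITR junction length, capsid capacity), plus a single-cutter
  digest check that collapses multimers to unit-scale fragments.
- **mass_model** — predict particle masses (VP1/VP2/VP3 capsid shell +
  counterion-corrected ssDNA) and non-overlapping per-species assignment
  windows.
- **cdms_synth** — simulate charge-detection mass-spectrometry (CD-MS)
  single-ion events (m/z, charge) for a species mixture, with standard
  (charge σ 1 e) and high-resolution (0.5 e) acquisition presets and an
  optional `partial` component for intermediate-mass genomes.
- **cdms_quant** — mass histograms, window assignment of ions, relative
  subpopulation abundances, per-species charge summaries with an
  elevated-charge flag.
- **gel_model** — simulate alkaline-gel lane densitometry (log-length
  mobility, Gaussian bands) and quantify band intensity fractions, with an
  optional molar correction.
- **termination_stats** — per-ITR termination probabilities from packaged
  species abundances (empties and unassigned ions excluded), abundance
  ratios, fold changes, and CD-MS-vs-gel profile comparison (total
  variation distance).
- **pipeline** — YAML config, orchestration, seeded determinism (identical
  config + seeds ⇒ byte-identical outputs), CSV/report generation, CLI.

## CLI

All subcommands read a YAML run config (see `examples/demo.yaml`):

```sh
aavpack run-all --config examples/demo.yaml --outdir out/demo
aavpack predict-species --config examples/demo.yaml --out species.csv
aavpack mass-table      --config examples/demo.yaml --out table.csv
aavpack simulate-ions   --config examples/demo.yaml --out ions.csv --truth
aavpack quantify-ions   --config examples/demo.yaml --ions ions.csv --out quant.csv
aavpack simulate-lane   --config examples/demo.yaml --out lane.csv
aavpack quantify-lane   --config examples/demo.yaml --lane lane.csv --out bands.csv
aavpack terminate       --config examples/demo.yaml --quant quant.csv \
                        --source cdms --out profile.csv
```

`run-all` executes species prediction → mass table → ion simulation →
quantification → lane simulation → band quantification → termination
profiles → comparison, and writes every stage CSV (each with a provenance
header recording the config hash and seed) plus `report.txt`.

## Notes on defaults

- ITR junction length defaults to 130 nt — the value forced by the observed
  multimer ladders (848 → 1,566 and 1,320 → 2,510) — not the 145 nt of the
  full ITR element; it is configurable per construct.
- Genome mass uses 308.9 Da/nt and a 1.04 counterion factor (both
  configurable); the counterion correction applies to DNA mass only.
- Capsid subunit masses are config-required; an approximate AAV8 preset
  (`mass_model.AAV8_CAPSID_APPROX`, 5:5:50 stoichiometry) is provided.
- Mean particle charge is a free parameter (default 240 e) chosen so the
  standard acquisition preset reproduces the expected single-ion mass
  resolution of ~100 FWHM; it cancels out of all abundance estimates.
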