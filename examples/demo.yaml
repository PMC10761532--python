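# Demo run: 848-nt unit construct, suspension-cell subpopulation abundances,
# both CD-MS and gel arms.  Mixture/band values are relative abundances and
# are normalized internally; the residual CD-MS fraction is carried by the
# reserved "partial" component.
output_dir: out/demo

construct:
  name: TTR-848
  unit_length: 848
  itr_junction_length: 130
  capacity: 4700

capsid:            # approximate AAV8 subunit masses (Da), 5:5:50
  vp1_mass: 81600
  vp2_mass: 66600
  vp3_mass: 59800

mass_params:
  avg_nt_mass: 308.9
  counterion_factor: 1.04
  window_half_width: 0.015

cdms:
  seed: 101
  n_ions: 10000
  mode: standard          # charge sigma 1 e; use high_resolution for 0.5 e
  mixture:
    empty: 79.8
    1GOI-2ITR: 2.8
    2GOI-3ITR: 2.96
    3GOI-4ITR: 2.36
    4GOI-5ITR: 1.68
    5GOI-6ITR: 0.54
    6GOI-7ITR: 0.19
    partial: 9.67

gel:
  seed: 202
  band_fractions:         # gel termination-profile intensity shares
    1GOI-2ITR: 5.2
    2GOI-3ITR: 35.4
    3GOI-4ITR: 24.1
    4GOI-5ITR: 25.6
    5GOI-6ITR: 6.2
    6GOI-7ITR: 3.6
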