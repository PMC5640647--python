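# Starved magnetic culture stained with Pyr-546: two discrete PHA populations.
scenario_id: magnetic_pha
description: >
  Magnetic culture stained for PHA granules with pyrromethene-546: a
  low-PHA and a high-PHA subpopulation, resolved as two modes on FL1.
seed: 41
n_events: 25000
stain: {dye: PYR546, concentration: 0.5, unit: ug/mL, staining_time: 300, temperature: 30}
kinetics: {f_max: 1.0, k: 0.2}
populations:
  - label: low_pha
    fraction: 0.40
    mu:    {FSC_A: 2.3,  SSC_A: 2.0,  FL1_A: 1.8,  FL3_A: 1.5,  FL4_A: 1.5}
    sigma: {FSC_A: 0.15, SSC_A: 0.15, FL1_A: 0.20, FL3_A: 0.25, FL4_A: 0.25}
  - label: high_pha
    fraction: 0.60
    mu:    {FSC_A: 2.3,  SSC_A: 2.1,  FL1_A: 3.2,  FL3_A: 1.5,  FL4_A: 1.5}
    sigma: {FSC_A: 0.15, SSC_A: 0.15, FL1_A: 0.20, FL3_A: 0.25, FL4_A: 0.25}
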