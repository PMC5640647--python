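# Cells grown in liquid FSM medium: small, homogeneous, mostly healthy.
scenario_id: liquid_grown
description: >
  Suspension-grown culture for the morphology comparison: narrow forward-
  and side-scatter distributions (small, homogeneous cells).
seed: 29
n_events: 25000
stain: {dye: PI, concentration: 5.0, unit: ug/mL, staining_time: 600, temperature: 30}
populations:
  - label: healthy
    fraction: 0.90
    mu:    {FSC_A: 2.3,  SSC_A: 2.0,  FL1_A: 1.5,  FL3_A: 1.5,  FL4_A: 1.5}
    sigma: {FSC_A: 0.15, SSC_A: 0.15, FL1_A: 0.25, FL3_A: 0.25, FL4_A: 0.25}
  - label: injured
    fraction: 0.06
    mu:    {FSC_A: 2.3,  SSC_A: 2.0,  FL1_A: 3.5,  FL3_A: 1.5,  FL4_A: 1.5}
    sigma: {FSC_A: 0.15, SSC_A: 0.15, FL1_A: 0.25, FL3_A: 0.25, FL4_A: 0.25}
  - label: dead
    fraction: 0.03
    mu:    {FSC_A: 2.3,  SSC_A: 2.0,  FL1_A: 3.5,  FL3_A: 3.5,  FL4_A: 1.5}
    sigma: {FSC_A: 0.15, SSC_A: 0.15, FL1_A: 0.25, FL3_A: 0.25, FL4_A: 0.25}
  - label: anomalous
    fraction: 0.01
    mu:    {FSC_A: 2.3,  SSC_A: 2.0,  FL1_A: 1.5,  FL3_A: 3.5,  FL4_A: 1.5}
    sigma: {FSC_A: 0.15, SSC_A: 0.15, FL1_A: 0.25, FL3_A: 0.25, FL4_A: 0.25}
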