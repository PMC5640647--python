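# Starving magnetic culture co-stained with BOX (FL1) and PI (FL3).
scenario_id: starving_magnetic
description: >
  Carbon-starved magnetic culture: depleted healthy fraction (~35%),
  large injured fraction (~40%) and substantial death, consistent with a
  sizeable viable-but-non-culturable subpopulation.
seed: 13
n_events: 25000
stain: {dye: BOX, concentration: 10.0, unit: ug/mL, staining_time: 600, temperature: 30}
populations:
  - label: healthy
    fraction: 0.35
    mu:    {FSC_A: 2.3,  SSC_A: 2.0,  FL1_A: 1.5,  FL3_A: 1.5,  FL4_A: 1.5}
    sigma: {FSC_A: 0.15, SSC_A: 0.15, FL1_A: 0.25, FL3_A: 0.25, FL4_A: 0.25}
  - label: injured
    fraction: 0.40
    mu:    {FSC_A: 2.3,  SSC_A: 2.0,  FL1_A: 3.5,  FL3_A: 1.5,  FL4_A: 1.5}
    sigma: {FSC_A: 0.15, SSC_A: 0.15, FL1_A: 0.25, FL3_A: 0.25, FL4_A: 0.25}
  - label: dead
    fraction: 0.225
    mu:    {FSC_A: 2.3,  SSC_A: 2.0,  FL1_A: 3.5,  FL3_A: 3.5,  FL4_A: 1.5}
    sigma: {FSC_A: 0.15, SSC_A: 0.15, FL1_A: 0.25, FL3_A: 0.25, FL4_A: 0.25}
  - label: anomalous
    fraction: 0.025
    mu:    {FSC_A: 2.3,  SSC_A: 2.0,  FL1_A: 1.5,  FL3_A: 3.5,  FL4_A: 1.5}
    sigma: {FSC_A: 0.15, SSC_A: 0.15, FL1_A: 0.25, FL3_A: 0.25, FL4_A: 0.25}
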