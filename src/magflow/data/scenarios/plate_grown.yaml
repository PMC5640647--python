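# Cells scraped from agar plates: polydisperse, filamentous, higher death.
scenario_id: plate_grown
description: >
  Plate-grown culture for the morphology comparison: broader and higher
  forward/side scatter (polydisperse, filamentous cells) and a substantial
  PI-positive (dead) fraction of ~17.5%.
seed: 31
n_events: 25000
stain: {dye: PI, concentration: 5.0, unit: ug/mL, staining_time: 600, temperature: 30}
populations:
  - label: plate_filamentous
    fraction: 0.68
    mu:    {FSC_A: 2.7,  SSC_A: 2.4,  FL1_A: 1.5,  FL3_A: 1.5,  FL4_A: 1.5}
    sigma: {FSC_A: 0.30, SSC_A: 0.30, FL1_A: 0.25, FL3_A: 0.25, FL4_A: 0.25}
  - label: injured
    fraction: 0.145
    mu:    {FSC_A: 2.7,  SSC_A: 2.4,  FL1_A: 3.5,  FL3_A: 1.5,  FL4_A: 1.5}
    sigma: {FSC_A: 0.30, SSC_A: 0.30, FL1_A: 0.25, FL3_A: 0.25, FL4_A: 0.25}
  - label: dead
    fraction: 0.15
    mu:    {FSC_A: 2.7,  SSC_A: 2.4,  FL1_A: 3.5,  FL3_A: 3.5,  FL4_A: 1.5}
    sigma: {FSC_A: 0.30, SSC_A: 0.30, FL1_A: 0.25, FL3_A: 0.25, FL4_A: 0.25}
  - label: anomalous
    fraction: 0.025
    mu:    {FSC_A: 2.7,  SSC_A: 2.4,  FL1_A: 1.5,  FL3_A: 3.5,  FL4_A: 1.5}
    sigma: {FSC_A: 0.30, SSC_A: 0.30, FL1_A: 0.25, FL3_A: 0.25, FL4_A: 0.25}
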