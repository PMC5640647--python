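# Positive kill control: cells incubated with absolute ethanol, then co-stained.
scenario_id: ethanol_killed
description: >
  Ethanol-killed positive control: only ~5% of events remain BOX- PI-
  (healthy); the bulk is permeabilised and double-positive.
seed: 7
n_events: 25000
stain: {dye: BOX, concentration: 10.0, unit: ug/mL, staining_time: 600, temperature: 30}
populations:
  - label: healthy
    fraction: 0.05
    mu:    {FSC_A: 2.3,  SSC_A: 2.0,  FL1_A: 1.5,  FL3_A: 1.5,  FL4_A: 1.5}
    sigma: {FSC_A: 0.15, SSC_A: 0.15, FL1_A: 0.25, FL3_A: 0.25, FL4_A: 0.25}
  - label: injured
    fraction: 0.10
    mu:    {FSC_A: 2.3,  SSC_A: 2.0,  FL1_A: 3.5,  FL3_A: 1.5,  FL4_A: 1.5}
    sigma: {FSC_A: 0.15, SSC_A: 0.15, FL1_A: 0.25, FL3_A: 0.25, FL4_A: 0.25}
  - label: dead
    fraction: 0.83
    mu:    {FSC_A: 2.3,  SSC_A: 2.0,  FL1_A: 3.5,  FL3_A: 3.5,  FL4_A: 1.5}
    sigma: {FSC_A: 0.15, SSC_A: 0.15, FL1_A: 0.25, FL3_A: 0.25, FL4_A: 0.25}
  - label: anomalous
    fraction: 0.02
    mu:    {FSC_A: 2.3,  SSC_A: 2.0,  FL1_A: 1.5,  FL3_A: 3.5,  FL4_A: 1.5}
    sigma: {FSC_A: 0.15, SSC_A: 0.15, FL1_A: 0.25, FL3_A: 0.25, FL4_A: 0.25}
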