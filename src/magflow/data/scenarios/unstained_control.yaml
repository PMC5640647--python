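# Unstained MSR-1 cells: the dye-negative control used to place quadrant cuts.
scenario_id: unstained_control
description: >
  Exponential-phase cells resuspended in PBS without any stain; both
  fluorescence channels show only autofluorescence/background.
seed: 23
n_events: 25000
stain: {dye: NONE, concentration: 0.0, unit: ug/mL, staining_time: 0, temperature: 30}
populations:
  - label: unstained
    fraction: 1.0
    mu:    {FSC_A: 2.3,  SSC_A: 2.0,  FL1_A: 1.5,  FL3_A: 1.5,  FL4_A: 1.5}
    sigma: {FSC_A: 0.15, SSC_A: 0.15, FL1_A: 0.25, FL3_A: 0.25, FL4_A: 0.25}
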