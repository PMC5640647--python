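# Syto62-stained sample containing noise particles of cell-like size.
scenario_id: cells_with_debris
description: >
  80% genuine cells (bright far-red Syto62 signal on FL4) mixed with 20%
  noise/debris particles of similar scatter but no DNA stain; used to
  exercise the FL4 noise gate.
seed: 43
n_events: 25000
stain: {dye: SYTO62, concentration: 5.0, unit: uM, staining_time: 600, temperature: 30}
populations:
  - label: cell
    fraction: 0.80
    mu:    {FSC_A: 2.3,  SSC_A: 2.0,  FL1_A: 1.5,  FL3_A: 1.5,  FL4_A: 3.0}
    sigma: {FSC_A: 0.15, SSC_A: 0.15, FL1_A: 0.25, FL3_A: 0.25, FL4_A: 0.25}
  - label: debris
    fraction: 0.20
    mu:    {FSC_A: 2.1,  SSC_A: 1.9,  FL1_A: 1.2,  FL3_A: 1.2,  FL4_A: 1.0}
    sigma: {FSC_A: 0.30, SSC_A: 0.30, FL1_A: 0.25, FL3_A: 0.25, FL4_A: 0.25}
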