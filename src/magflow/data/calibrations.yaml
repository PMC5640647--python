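# Packaged OD565 -> concentration calibration constants.
# These are literature/instrument constants shipped for convenience, not
# fits performed by this package, hence n_points = 0 with a provenance note.
fcm_unstained:
  mode: FCM
  slope: 1.16e9
  r2: 0.95
  n_points: 0
  provenance: >
    Published shake-flask correlation of OD565 against unstained FCM event
    counts for M. gryphiswaldense MSR-1 (1 OD565 = 1.16e9 cells/mL, R2 > 0.95).
fcm_syto62:
  mode: FCM
  slope: 1.03e9
  r2: 0.95
  n_points: 0
  provenance: >
    Published correlation of OD565 against Syto62-stained FCM event counts
    (1 OD565 = 1.03e9 cells/mL); the DNA stain excludes noise particles.
cfu:
  mode: CFU
  slope: 3.3e8
  r2: 0.95
  n_points: 0
  provenance: >
    Published plate-count correlation (1 OD565 = 3.3e8 CFU/mL); lower than
    the FCM slope because colony counts miss viable-but-non-culturable cells.
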