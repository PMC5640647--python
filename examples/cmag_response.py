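"""The C_mag magnetic-response statistic from paired OD565 readings.

Magnetic cells align with a field from Helmholtz coils; the optical
density of the suspension differs between parallel and perpendicular
alignment, and their ratio (C_mag) reads out magnetosome content.
"""

import statistics

import magflow as mf
from magflow.cmag import CmagReading

for par, perp in [(0.50, 0.25), (0.44, 0.40), (0.37, 0.37)]:
    c = mf.compute_cmag(CmagReading(par, perp))
    call = mf.classify_magnetic(c)
    print(f"OD par {par:.2f} / perp {perp:.2f} -> C_mag = {c:.2f} ({call})")

# simulate replicate readings of a moderately magnetic culture
gen = mf.CmagGenerator(od_base=0.8, magnetic_fraction=0.71,
                       alignment_contrast=1.0, noise_cv=0.02)
values = [mf.compute_cmag(r) for r in mf.generate_od_pairs(gen, 6, seed=5)]
print(f"\nsimulated culture: C_mag = {statistics.mean(values):.2f} "
      f"+/- {statistics.stdev(values):.2f} (n=6), noiseless value 1.71")
print("C_mag = 2 is a strongly magnetic culture; 1.1 is very weakly")
print("magnetic; exactly 1 means no field-dependent alignment at all.")
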