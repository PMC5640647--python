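"""Relative chelatable-iron quantification by PG-SK quenching.

PG-SK fluorescence is quenched by Fe2+/Fe3+ (Stern-Volmer), so lower
signal means more intracellular iron. The fold-quench against an
iron-free reference inverts to an iron estimate in µM.
"""

import math

import magflow as mf
from magflow.events_io import ChannelMap
from magflow.synthetic import PopulationSpec, QuenchModel

model = QuenchModel(f0=3000.0, K_sv=0.1)  # per-µM Stern-Volmer constant
cm = ChannelMap(("FSC_A", "SSC_A", "FL1_A"))


def stained_sample(iron_uM, seed):
    mu = math.log10(mf.pgsk_expected_mfi(iron_uM, model))
    pop = PopulationSpec("stained", 1.0, {"FL1_A": mu}, {"FL1_A": 0.25})
    table = mf.sample_population(pop, 25_000, seed=seed, channel_map=cm)
    return mf.summarize_fluorescence(table, "FL1_A")


reference = stained_sample(0.0, seed=1)
print(f"iron-free reference MFI: {reference.mfi:.0f}")
for iron, seed in [(5.0, 2), (10.0, 3), (50.0, 4)]:
    sample = stained_sample(iron, seed)
    idx = mf.iron_index(sample, reference, model)
    print(f"true iron {iron:5.1f} uM -> MFI {sample.mfi:7.0f}, "
          f"fold-quench {idx.fold_quench:.2f}, estimated {idx.iron_uM:5.1f} uM")

print("\nThe estimate inverts the quench law; at 25 000 events it recovers")
print("the simulated iron concentration to within a few percent.")
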