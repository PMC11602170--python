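"""Ribocomputing gate layouts with coupled outputs.

Lays out a two-input OR gate driving two coupled reporters and prints the
expected qualitative truth table recorded with the design.
"""

import numpy as np

from syntce import FixtureSpec, gate_layout, make_fixture_orf, make_fixture_switch

rng = np.random.default_rng(3)
fspec = FixtureSpec(seed=3)
gfp = make_fixture_orf(fspec, name="gfp", length=120, rng=rng)
mcherry = make_fixture_orf(fspec, name="mcherry", length=120, rng=rng)
switches = [
    make_fixture_switch(name="swA", trigger="A", seed=1),
    make_fixture_switch(name="swB", trigger="B", seed=2),
]

design = gate_layout("OR", switches, [gfp, mcherry])
print(f"OR gate: {len(design.transcript)} nt transcript, "
      f"{len(design.junctions)} coupling junction(s)")
print("inputs:", design.metadata["inputs"])
print("truth table (inputs present -> expected output):")
for present, state in design.metadata["truth_table"].items():
    label = "+".join(present) if present else "none"
    print(f"  {label:<6} -> {state}")
# Any cognate trigger opens its switch module; ribosomes translating the
# first cistron couple through the synTCE to the second reporter, so both
# outputs follow the OR of the inputs.
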