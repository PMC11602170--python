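"""Assemble and validate a three-output operon transcript.

Builds three synthetic ORFs, joins them with two designed coupling
cassettes, validates both junctions and writes an annotated GenBank
record.
"""

import numpy as np

from syntce import (
    FixtureSpec,
    SynTCESpec,
    assemble_operon,
    design_candidates,
    make_fixture_orf,
    part_from_candidate,
    validate_operon,
)
from syntce import io as sio

rng = np.random.default_rng(7)
fspec = FixtureSpec(seed=7)
orfs = [make_fixture_orf(fspec, name=f"orf{i + 1}", length=120, rng=rng)
        for i in range(3)]

passing = [c for c in design_candidates(SynTCESpec(seed=42, n_candidates=50))
           if c.passes]
tces = [part_from_candidate(c, f"tce{i + 1}")
        for i, c in enumerate(passing[:2])]

design = assemble_operon([orfs[0], tces[0], orfs[1], tces[1], orfs[2]])
print(f"transcript: {len(design.transcript)} nt, "
      f"{len(design.orf_regions())} cistrons, "
      f"{len(design.junctions)} coupling junctions")

for i, report in enumerate(validate_operon(design)):
    print(f"junction {i}: intergenic distance {report.intergenic_distance} "
          f"({report.distance_class}), RBS total "
          f"{report.rbs_score.total:.2f} kcal/mol, hairpin "
          f"{'pass' if report.structure_check.passed else 'FAIL'}")

sio.write_construct(design, "three_output_operon.gb")
print("wrote three_output_operon.gb")
# Intergenic distance -1 is the overlapping stop-start (URAUG)
# configuration: translation of each downstream gene requires ribosomes
# terminating at the upstream junction, giving coupled, stoichiometric
# expression of all three outputs.
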